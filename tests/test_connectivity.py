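"""Morlet CWT correctness, phase/power windows, PLV and eigenvalues."""

import numpy as np
import pandas as pd
import pytest

from emoconn.montage import PairGroup
from emoconn.preprocess import BANDS, EEGRecording, InputError, band_filter
from emoconn.connectivity import (CWTResult, WaveletSpec, band_connectivity,
                                  cwt_morlet, cwt_recording,
                                  default_wavelet_spec, group_eigenvalues,
                                  morlet_mother, pairwise_connectivity,
                                  phase_and_power)

RATE = 500.0


def brute_force_cwt(x, rate, spec, scale_idx, b_idx):
    """Direct Riemann-sum evaluation of the defining CWT integral."""
    a = spec.scales[scale_idx]
    t = np.arange(x.size) / rate
    u = (t - t[b_idx]) / a
    return np.sum(x * np.conj(morlet_mother(u, spec.bandwidth))) \
        / (rate * np.sqrt(abs(a)))


def two_channel_series(sig_a, sig_b, band="beta", window=1.0, hop=0.5):
    rec = EEGRecording(data=np.vstack([sig_a, sig_b]), rate=RATE,
                       channels=("A", "B"))
    res = cwt_recording(rec, default_wavelet_spec(band))
    return phase_and_power(res, band, window=window, hop=hop)


AB_PAIR = [PairGroup(("A", "B"), "OTHER", 5.0)]


class TestCWT:
    def test_matches_brute_force_integral(self, rng):
        t = np.arange(1000) / RATE
        x = np.sin(2 * np.pi * 10 * t) + 0.3 * rng.standard_normal(t.size)
        spec = default_wavelet_spec("alpha")
        coeffs = cwt_morlet(x, RATE, spec)
        for _ in range(10):
            i = rng.integers(0, spec.scales.size)
            b = rng.integers(50, t.size - 50)
            oracle = brute_force_cwt(x, RATE, spec, i, b)
            assert abs(coeffs[i, b] - oracle) <= 1e-6 * abs(oracle)

    def test_zero_signal_zero_coefficients(self):
        spec = default_wavelet_spec("alpha")
        coeffs = cwt_morlet(np.zeros(500), RATE, spec)
        assert np.all(coeffs == 0)

    def test_impulse_sifting(self):
        """A unit impulse reproduces the (conjugate) wavelet shape."""
        spec = default_wavelet_spec("alpha")
        n, t0 = 2000, 1000
        x = np.zeros(n)
        x[t0] = 1.0
        coeffs = cwt_morlet(x, RATE, spec)
        a = spec.scales[3]
        t = np.arange(n) / RATE
        for b in (900, 1000, 1080):
            expected = np.conj(morlet_mother((t[t0] - t[b]) / a,
                                             spec.bandwidth)) \
                / (RATE * np.sqrt(a))
            assert coeffs[3, b] == pytest.approx(expected, rel=1e-9)

    def test_linearity(self, rng):
        spec = default_wavelet_spec("theta")
        x = rng.standard_normal(800)
        y = rng.standard_normal(800)
        lhs = cwt_morlet(2.0 * x - 0.5 * y, RATE, spec)
        rhs = 2.0 * cwt_morlet(x, RATE, spec) - 0.5 * cwt_morlet(y, RATE, spec)
        assert np.allclose(lhs, rhs, atol=1e-12)

    def test_scale_beyond_nyquist_rejected(self):
        spec = WaveletSpec(center_freq=10.0, bandwidth=1.5,
                           scales=np.array([0.001, 0.01]))
        with pytest.raises(InputError):
            cwt_morlet(np.zeros(100), RATE, spec)

    def test_nonfinite_rejected(self):
        spec = default_wavelet_spec("alpha")
        x = np.zeros(100)
        x[10] = np.nan
        with pytest.raises(InputError):
            cwt_morlet(x, RATE, spec)


class TestPhaseAndPower:
    def test_phase_ramp_of_center_frequency_sinusoid(self):
        f = default_wavelet_spec("alpha").center_freq
        t = np.arange(int(4 * RATE)) / RATE
        series = two_channel_series(np.sin(2 * np.pi * f * t),
                                    np.sin(2 * np.pi * f * t))
        interior = slice(int(0.5 * RATE), int(3.5 * RATE))
        phase = np.unwrap(series.phase[0, interior])
        slope = np.polyfit(t[interior], phase, 1)[0]
        assert slope == pytest.approx(2 * np.pi * f, rel=0.01)

    def test_power_quadratic_scaling_and_zero(self, rng):
        x = rng.standard_normal(int(4 * RATE))
        s1 = two_channel_series(x, np.zeros_like(x))
        s2 = two_channel_series(2 * x, np.zeros_like(x))
        assert np.allclose(s2.power[:, 0], 4 * s1.power[:, 0], rtol=1e-6)
        assert np.allclose(s1.power[:, 1], 0.0)

    def test_masked_windows_dropped(self, rng):
        x = rng.standard_normal(int(4 * RATE))
        rec = EEGRecording(data=np.vstack([x, x]), rate=RATE,
                           channels=("A", "B"))
        mask = rec.mask.copy()
        mask[: int(2 * RATE)] = True
        rec = EEGRecording(data=rec.data, rate=RATE, channels=rec.channels,
                           mask=mask)
        res = cwt_recording(rec, default_wavelet_spec("beta"))
        series = phase_and_power(res, "beta")
        assert series.window_starts.min() >= 1.5  # >50 %-masked dropped

    def test_all_masked_warns_empty(self, rng):
        x = rng.standard_normal(int(2 * RATE))
        rec = EEGRecording(data=x[None, :], rate=RATE, channels=("A",),
                           mask=np.ones(x.size, dtype=bool))
        res = cwt_recording(rec, default_wavelet_spec("beta"))
        with pytest.warns(UserWarning):
            series = phase_and_power(res, "beta")
        assert series.window_starts.size == 0


class TestPairwiseConnectivity:
    def test_identical_channels_self_coherent(self, rng):
        x = rng.standard_normal(int(4 * RATE))
        frame = pairwise_connectivity(two_channel_series(x, x), AB_PAIR)
        assert np.allclose(frame.plv, 1.0)
        assert np.allclose(frame.mean_phase_diff, 0.0, atol=1e-12)
        assert np.allclose(frame.signed_power_diff, 0.0)

    def test_imposed_lag_recovered(self):
        f = default_wavelet_spec("beta").center_freq
        t = np.arange(int(6 * RATE)) / RATE
        a = np.cos(2 * np.pi * f * t)
        b = np.cos(2 * np.pi * f * t - np.pi / 4)  # b lags a by pi/4
        frame = pairwise_connectivity(two_channel_series(a, b), AB_PAIR)
        assert (frame.plv > 0.99).all()
        assert np.allclose(frame.mean_phase_diff, np.pi / 4, atol=0.02)

    def test_full_montage_emits_153_pairs(self, montage, pairs, rng):
        rec = EEGRecording(data=rng.standard_normal((18, int(3 * RATE))),
                           rate=RATE, channels=montage.channels)
        frame, _ = band_connectivity(rec, montage, band="beta")
        counts = frame.groupby("window_start").size()
        assert (counts == 153).all()

    def test_reversed_pair_order_flips_signs(self, rng):
        x = rng.standard_normal(int(3 * RATE))
        y = rng.standard_normal(int(3 * RATE))
        series = two_channel_series(x, y)
        fwd = pairwise_connectivity(series, AB_PAIR)
        rev = pairwise_connectivity(
            series, [PairGroup(("B", "A"), "OTHER", 5.0)])
        assert np.allclose(rev.signed_power_diff, -fwd.signed_power_diff)
        assert np.allclose(np.abs(rev.mean_phase_diff),
                           np.abs(fwd.mean_phase_diff))
        assert np.allclose(rev.plv, fwd.plv)
        assert (rev.strong == fwd.strong).all()

    def test_plv_decreases_with_window_length(self):
        """Independent channels: spurious locking shrinks as windows grow."""
        med = {2.0: [], 20.0: []}
        for seed in range(8):
            r = np.random.default_rng(seed)
            x = r.standard_normal(int(40 * RATE))
            y = r.standard_normal(int(40 * RATE))
            for w in med:
                series = two_channel_series(x, y, window=w, hop=w)
                frame = pairwise_connectivity(series, AB_PAIR)
                med[w].append(frame.plv.median())
        assert np.median(med[2.0]) > np.median(med[20.0])

    def test_missing_channel_error(self, rng):
        series = two_channel_series(rng.standard_normal(1500),
                                    rng.standard_normal(1500))
        with pytest.raises(InputError):
            pairwise_connectivity(series,
                                  [PairGroup(("A", "XX9"), "OTHER", 1.0)])


def toy_frame():
    """Hand-built two-window frame with two pairs per group."""
    rows = []
    spds = {"LD_OF": (1.0, 3.0), "LD_PF": (-2.0, 4.0), "SD": (0.5, -0.5)}
    for w in (0.0, 0.5):
        for g, (s1, s2) in spds.items():
            for i, s in enumerate((s1, s2)):
                rows.append({"window_start": w, "band": "beta",
                             "ch_a": f"{g}{i}a", "ch_b": f"{g}{i}b",
                             "group": g, "distance_cm": 10.0, "plv": 0.5,
                             "mean_phase_diff": 0.0,
                             "signed_power_diff": s, "strong": False})
    return pd.DataFrame(rows)


class TestGroupEigenvalues:
    def test_hand_computed_means(self):
        eig = group_eigenvalues(toy_frame())
        row = eig.iloc[0]
        assert row.e_LD_OF == pytest.approx(2.0)   # mean(1, 3)
        assert row.e_LD_PF == pytest.approx(1.0)   # mean(-2, 4)
        assert row.e_SD == pytest.approx(0.0)      # mean(0.5, -0.5)
        assert row.abs_LD_OF == pytest.approx(2.0)

    def test_antisymmetry(self):
        f = toy_frame()
        neg = f.assign(signed_power_diff=-f.signed_power_diff)
        e1, e2 = group_eigenvalues(f), group_eigenvalues(neg)
        for g in ("LD_OF", "LD_PF", "SD"):
            assert np.allclose(e2[f"e_{g}"], -e1[f"e_{g}"])
            assert np.allclose(e2[f"abs_{g}"], e1[f"abs_{g}"])

    def test_identical_signals_zero_eigenvalues(self, montage, rng):
        x = rng.standard_normal(int(3 * RATE))
        rec = EEGRecording(data=np.tile(x, (18, 1)), rate=RATE,
                           channels=montage.channels)
        _, eig = band_connectivity(rec, montage, band="beta")
        for g in ("LD_OF", "LD_PF", "SD"):
            assert np.allclose(eig[f"e_{g}"], 0.0, atol=1e-10)

    def test_empty_group_error(self):
        f = toy_frame()
        with pytest.raises(InputError):
            group_eigenvalues(f[f.group != "SD"])


def test_planted_group_coupling_has_highest_plv(montage):
    """PLV planted in the LD_OF pairs dominates the other groups' PLV."""
    from emoconn.synth import CouplingEntry, SessionConfig, generate_eeg
    wins = 0
    n_runs = 20
    for seed in range(n_runs):
        cfg = SessionConfig(duration=6.0, seed=seed,
                            state_schedule=((0.0, 6.0, "emotional"),))
        entry = CouplingEntry("LD_OF", band="beta", strength=0.9,
                              phase_lag=0.2)
        rec, _ = generate_eeg(cfg, (entry,), montage=montage)
        frame, _ = band_connectivity(rec, montage, band="beta")
        means = frame.groupby("group").plv.mean()
        wins += means["LD_OF"] == means[["LD_OF", "LD_PF", "SD"]].max()
    assert wins >= 0.95 * n_runs
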