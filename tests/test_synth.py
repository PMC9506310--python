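"""Synthetic generator contracts: determinism, planted structure, study shape."""

import numpy as np
import pytest

from emoconn.connectivity import band_connectivity
from emoconn.preprocess import broadband_filter
from emoconn.synth import (ConfigurationError, CouplingEntry, SaccadeSpec,
                           SessionConfig, _lead_couplings,
                           default_session_couplings, generate_eeg,
                           generate_gaze, generate_study,
                           null_effect_profile)

TWO_STATE = ((0.0, 6.0, "non-emotional"), (6.0, 20.0, "emotional"))


class TestDeterminism:
    def test_eeg_reproducible(self, montage):
        cfg = SessionConfig(duration=4.0, seed=7)
        r1, _ = generate_eeg(cfg, montage=montage)
        r2, _ = generate_eeg(cfg, montage=montage)
        np.testing.assert_array_equal(r1.data, r2.data)

    def test_gaze_reproducible(self):
        cfg = SessionConfig(duration=4.0, seed=7,
                            gaze_events=(SaccadeSpec(1.0, 6.0),))
        g1, _ = generate_gaze(cfg)
        g2, _ = generate_gaze(cfg)
        np.testing.assert_array_equal(g1.x, g2.x)
        np.testing.assert_array_equal(g1.pupil_left, g2.pupil_left)

    def test_study_reproducible(self):
        b1 = generate_study(n_participants=3, seed=11, duration=5.0)
        b2 = generate_study(n_participants=3, seed=11, duration=5.0)
        assert b1.scores.equals(b2.scores)
        assert b1.session_configs == b2.session_configs


class TestSessionConfig:
    def test_schedule_must_tile(self):
        with pytest.raises(ConfigurationError):
            SessionConfig(duration=10.0,
                          state_schedule=((0.0, 4.0, "non-emotional"),
                                          (5.0, 10.0, "emotional")))

    def test_state_lookup(self):
        cfg = SessionConfig(duration=20.0, state_schedule=TWO_STATE)
        assert cfg.state_at(3.0) == "non-emotional"
        assert cfg.state_at(6.0) == "emotional"

    def test_empty_schedule_defaults_to_non_emotional(self):
        cfg = SessionConfig(duration=5.0)
        assert cfg.state_at(2.0) == "non-emotional"


class TestGenerateEEG:
    def test_uncoupled_channels_have_low_plv_at_long_windows(self, montage):
        meds = []
        for seed in range(3):
            cfg = SessionConfig(duration=20.0, seed=seed)
            rec, _ = generate_eeg(cfg, (), montage=montage)
            frame, _ = band_connectivity(broadband_filter(rec), montage,
                                         band="beta", window=10.0, hop=10.0)
            meds.append(frame.plv.median())
        assert np.median(meds) < 0.3

    def test_planted_lag_recovered(self, montage):
        cfg = SessionConfig(duration=20.0, seed=4,
                            state_schedule=((0.0, 20.0, "emotional"),))
        entry = CouplingEntry(("O1", "F3"), band="beta", phase_lag=np.pi / 4,
                              strength=1.0)
        rec, _ = generate_eeg(cfg, (entry,), montage=montage)
        frame, _ = band_connectivity(broadband_filter(rec), montage,
                                     band="beta")
        sub = frame[(frame.ch_a == "O1") & (frame.ch_b == "F3")]
        pooled = np.mean(sub.plv * np.exp(1j * sub.mean_phase_diff))
        assert np.angle(pooled) == pytest.approx(np.pi / 4, abs=0.05)
        assert sub.plv.mean() > 0.9

    def test_planted_power_asymmetry_gives_positive_eigenvalue(self, montage):
        """Occipital power ratio 2 drives e_LD_OF positive, session after session."""
        coup = _lead_couplings(2.0, 1.0, 1.0, 0.3, 0.9)
        wins = 0
        n_runs = 20
        for seed in range(n_runs):
            cfg = SessionConfig(duration=8.0, seed=seed,
                                state_schedule=((0.0, 8.0, "emotional"),))
            rec, _ = generate_eeg(cfg, coup, montage=montage)
            _, eig = band_connectivity(broadband_filter(rec), montage,
                                       band="beta")
            wins += eig.e_LD_OF.mean() > 0
        assert wins >= 0.95 * n_runs

    def test_unknown_channel_rejected(self, montage):
        cfg = SessionConfig(duration=2.0)
        with pytest.raises(ConfigurationError):
            generate_eeg(cfg, (CouplingEntry(("O1", "XX9")),),
                         montage=montage)

    def test_invalid_strength_rejected(self):
        with pytest.raises(ConfigurationError):
            CouplingEntry(("O1", "F3"), strength=1.5)


class TestGenerateGaze:
    def test_empty_schedule_single_fixation(self):
        from emoconn.eyetrack import detect_events
        g, _ = generate_gaze(SessionConfig(duration=5.0, seed=0))
        events = detect_events(g)
        assert [e.kind for e in events] == ["fixation"]

    def test_overlapping_events_rejected(self):
        evs = (SaccadeSpec(1.0, 5.0, duration=0.5),
               SaccadeSpec(1.2, 5.0))
        with pytest.raises(ConfigurationError):
            generate_gaze(SessionConfig(duration=5.0, gaze_events=evs))

    def test_truth_reports_schedule(self):
        evs = (SaccadeSpec(1.0, 5.0),)
        _, truth = generate_gaze(SessionConfig(duration=5.0, gaze_events=evs,
                                               seed=0))
        assert truth.gaze_events == evs


class TestGenerateStudy:
    def test_session_count(self):
        b = generate_study(n_participants=47, seed=0, duration=5.0)
        assert len(b.sessions) == 47 * 4
        assert len(b.scores) == 47 * 4

    def test_default_profile_orders_arousal_as_designed(self):
        b = generate_study(n_participants=40, seed=1, duration=5.0)
        m = b.scores.groupby("condition").arousal.mean()
        assert m["unpleasant-aroused"] > m["pleasant-aroused"] \
            > m["unpleasant-relaxed"] > m["pleasant-relaxed"]

    def test_null_profile_has_no_condition_structure(self):
        prof = null_effect_profile()
        assert len({(e.arousal_mean, e.valence_mean, e.ld_of_ratio)
                    for e in prof.values()}) == 1

    def test_missing_condition_in_profile_rejected(self):
        prof = null_effect_profile()
        prof.pop("pleasant-aroused")
        with pytest.raises(ConfigurationError):
            generate_study(n_participants=3, effect_profile=prof)

    def test_too_few_participants_rejected(self):
        with pytest.raises(ConfigurationError):
            generate_study(n_participants=1)

    def test_materialize_is_deterministic(self):
        b = generate_study(n_participants=2, seed=3, duration=4.0)
        r1, g1, t1 = b.materialize("p01", "pleasant-aroused")
        r2, g2, t2 = b.materialize("p01", "pleasant-aroused")
        np.testing.assert_array_equal(r1.data, r2.data)
        np.testing.assert_array_equal(g1.pupil_right, g2.pupil_right)


def test_two_state_session_recovered_end_to_end(montage):
    """Default planted separations survive the whole EEG analysis chain."""
    import warnings
    from emoconn.states import incremental_kmeans, label_emotional
    agree = []
    for seed in range(6):
        cfg = SessionConfig(duration=30.0, seed=seed,
                            state_schedule=((0.0, 9.0, "non-emotional"),
                                            (9.0, 30.0, "emotional")))
        rec, truth = generate_eeg(cfg, default_session_couplings(),
                                  montage=montage)
        _, eig = band_connectivity(broadband_filter(rec), montage,
                                   band="beta")
        lab = incremental_kmeans(eig, seed=seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            lab = label_emotional(lab, baseline_windows=10)
        true = truth.true_window_states(lab.window_starts, 1.0) == "emotional"
        agree.append((lab.emotional == true).mean())
    assert min(agree) >= 0.98
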