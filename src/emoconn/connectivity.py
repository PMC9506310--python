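"""Complex-Morlet wavelet connectivity and the three distance-grouped eigenvalues.

The continuous wavelet transform with a complex Morlet mother wavelet

    X_w(a, b) = |a|^(-1/2) * integral x(t) conj(phi((t - b) / a)) dt,
    phi(t)    = (pi * B)^(-1/2) * exp(-t^2 / B) * exp(2i * pi * C * t),

gives each channel an instantaneous phase and band power.  Connectivity
between an electrode pair is summarized per analysis window by

* the phase-locking value  plv = |mean_t exp(i * dphi(t))|  in [0, 1],
* the circular mean phase difference, and
* the signed band-power difference P_first - P_second (uV^2), whose sign
  encodes directionality under the montage's canonical pair order.

A pair is marked *strong* in a window when its absolute power difference is
below the mean absolute power difference over all 153 pairs of that window
and band.  The per-group "eigenvalue" (the field's name for this scalar, not
a linear-algebra eigenvalue) is the mean signed power difference over the
group's pairs; its absolute value |mean| is reported alongside.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import fftconvolve

from .montage import Montage, PairGroup, classify_pairs
from .preprocess import BANDS, BandSpec, EEGRecording, InputError, band_filter

__all__ = [
    "WaveletSpec",
    "default_wavelet_spec",
    "morlet_mother",
    "cwt_morlet",
    "CWTResult",
    "WindowedBandSeries",
    "phase_and_power",
    "pairwise_connectivity",
    "group_eigenvalues",
    "band_connectivity",
    "EIG_GROUPS",
]

#: Pair-groups that get an eigenvalue column, in reporting order.
EIG_GROUPS = ("LD_OF", "LD_PF", "SD")

#: Probe frequency per band (Hz): the band midpoint, hit by the center scale.
BAND_CENTER_FREQ = {"delta": 2.0, "theta": 6.0, "alpha": 10.0, "beta": 21.0}

DEFAULT_BANDWIDTH = 1.5  # dimensionless Gaussian envelope parameter B
_SUPPORT_SIGMAS = 8.0  # kernel truncation; envelope ~ exp(-32) there


@dataclass(frozen=True)
class WaveletSpec:
    """Morlet parameters and the discrete (scale, shift) evaluation grid.

    The mother wavelet lives in dimensionless time u with unit oscillation
    frequency (the ``cmorB-1.0`` convention), so the scale factor a carries
    seconds and probes pseudo-frequency f = 1 / a.  ``center_freq`` is the
    band's probe frequency (its midpoint); the corresponding center scale
    1 / center_freq supplies the instantaneous phase.
    """

    center_freq: float  # Hz
    bandwidth: float  # dimensionless envelope parameter B
    scales: np.ndarray  # seconds, strictly increasing
    shift_step: int = 1  # shift-factor resolution in samples

    def __post_init__(self) -> None:
        scales = np.asarray(self.scales, dtype=float)
        if scales.ndim != 1 or scales.size == 0:
            raise InputError("scales must be a non-empty 1-D grid")
        if (scales <= 0).any() or (np.diff(scales) <= 0).any():
            raise InputError("scales must be strictly positive and increasing")
        object.__setattr__(self, "scales", scales)

    @property
    def frequencies(self) -> np.ndarray:
        """Pseudo-frequency of each scale: f = 1 / a."""
        return 1.0 / self.scales

    @property
    def center_scale_index(self) -> int:
        return int(np.argmin(np.abs(self.scales - 1.0 / self.center_freq)))


def default_wavelet_spec(band: BandSpec | str, n_scales: int = 8,
                         bandwidth: float = DEFAULT_BANDWIDTH) -> WaveletSpec:
    """Log-spaced scale grid spanning one band, center scale at the midpoint.

    The grid covers [max(lo, 0.5), hi] Hz with the band midpoint inserted so
    the center scale probes it exactly.
    """
    if isinstance(band, str):
        band = BANDS[band]
    c = BAND_CENTER_FREQ.get(band.name, 0.5 * (band.lo + band.hi))
    freqs = np.geomspace(max(band.lo, 0.5), band.hi, n_scales)
    freqs[np.argmin(np.abs(freqs - c))] = c  # snap nearest grid point to c
    scales = np.sort(1.0 / freqs)
    return WaveletSpec(center_freq=c, bandwidth=bandwidth, scales=scales)


def morlet_mother(u: np.ndarray, bandwidth: float) -> np.ndarray:
    """phi(u): Gaussian-windowed unit-frequency complex exponential."""
    u = np.asarray(u, dtype=float)
    norm = (np.pi * bandwidth) ** -0.5
    return norm * np.exp(-u * u / bandwidth) * np.exp(2j * np.pi * u)


def _scale_kernel(a: float, spec: WaveletSpec, rate: float) -> np.ndarray:
    """Sampled phi(u / a) on a symmetric grid wide enough to be exact.

    conj(phi(-u)) = phi(u) (Hermitian symmetry), so correlating x with
    conj(phi((t - b)/a)) equals convolving x with phi(u / a).
    """
    sigma = a * np.sqrt(spec.bandwidth / 2.0)  # envelope sd in seconds
    half = int(np.ceil(_SUPPORT_SIGMAS * sigma * rate))
    u = np.arange(-half, half + 1) / rate
    return morlet_mother(u / a, spec.bandwidth)


def cwt_morlet(x: np.ndarray, rate: float, spec: WaveletSpec) -> np.ndarray:
    """Discrete CWT of ``x`` (1-D or channels x time) over ``spec.scales``.

    Returns complex coefficients of shape (n_scales, [n_channels,] n_time),
    evaluated at every ``shift_step``-th sample.  The discretization is the
    Riemann sum of the defining integral with dt = 1/rate, so a brute-force
    evaluation of that sum reproduces these values to rounding error.
    """
    x = np.asarray(x, dtype=float)
    if not np.isfinite(x).all():
        raise InputError("signal contains non-finite samples")
    if spec.frequencies.max() >= rate / 2:
        raise InputError(
            f"smallest scale probes {spec.frequencies.max():.3g} Hz, "
            f"beyond Nyquist ({rate / 2:.3g} Hz)"
        )
    squeeze = x.ndim == 1
    xa = x[None, :] if squeeze else x
    dt = 1.0 / rate
    out = np.empty((spec.scales.size,) + xa.shape, dtype=complex)
    for i, a in enumerate(spec.scales):
        kern = _scale_kernel(a, spec, rate)
        conv = fftconvolve(xa, kern[None, :], mode="same", axes=1)
        out[i] = conv * (dt / np.sqrt(abs(a)))
    if spec.shift_step > 1:
        out = out[..., :: spec.shift_step]
    return out[:, 0, :] if squeeze else out


@dataclass(frozen=True)
class CWTResult:
    """CWT coefficients for all channels plus the metadata to window them."""

    coeffs: np.ndarray  # (n_scales, n_channels, n_time)
    spec: WaveletSpec
    rate: float
    channels: tuple[str, ...]
    t0: float = 0.0
    mask: np.ndarray | None = None


def cwt_recording(rec: EEGRecording, spec: WaveletSpec) -> CWTResult:
    return CWTResult(
        coeffs=cwt_morlet(rec.data, rec.rate, spec),
        spec=spec, rate=rec.rate, channels=rec.channels,
        t0=rec.t0, mask=rec.mask,
    )


@dataclass(frozen=True)
class WindowedBandSeries:
    """Per-window instantaneous phase and band power for every channel."""

    band: str
    channels: tuple[str, ...]
    rate: float
    window: float
    hop: float
    window_starts: np.ndarray  # (n_windows,) seconds
    slices: tuple[slice, ...]  # sample slices into the phase array
    phase: np.ndarray  # (n_channels, n_time), wrapped to (-pi, pi]
    power: np.ndarray  # (n_windows, n_channels), uV^2
    sample_mask: np.ndarray  # (n_time,) True = rejected


def _window_slices(n: int, rate: float, window: float, hop: float) -> list[tuple[float, slice]]:
    wn = int(round(window * rate))
    hn = max(int(round(hop * rate)), 1)
    out = []
    start = 0
    while start + wn <= n:
        out.append((start / rate, slice(start, start + wn)))
        start += hn
    return out


def phase_and_power(res: CWTResult, band: BandSpec | str, window: float = 1.0,
                    hop: float = 0.5) -> WindowedBandSeries:
    """Window the CWT into phases (center scale) and mean band powers.

    Windows with more than half of their samples masked are dropped; an
    all-dropped result is returned empty with a warning.
    """
    band_name = band if isinstance(band, str) else band.name
    n_t = res.coeffs.shape[-1]
    mask = res.mask if res.mask is not None else np.zeros(n_t, dtype=bool)
    center = res.coeffs[res.spec.center_scale_index]
    phase = np.angle(center)
    sqmag = np.abs(res.coeffs) ** 2  # (n_scales, n_ch, n_t)

    starts, slices, powers = [], [], []
    for t_start, sl in _window_slices(n_t, res.rate, window, hop):
        m = mask[sl]
        if m.mean() > 0.5:
            continue
        good = ~m
        p = sqmag[:, :, sl][:, :, good].mean(axis=(0, 2))
        starts.append(res.t0 + t_start)
        slices.append(sl)
        powers.append(p)
    if not starts:
        warnings.warn("all windows were masked; empty band series", stacklevel=2)
    return WindowedBandSeries(
        band=band_name, channels=res.channels, rate=res.rate,
        window=window, hop=hop,
        window_starts=np.asarray(starts, dtype=float),
        slices=tuple(slices),
        phase=phase,
        power=(np.asarray(powers, dtype=float) if powers
               else np.empty((0, len(res.channels)))),
        sample_mask=mask,
    )


def _wrap(phi: np.ndarray) -> np.ndarray:
    return np.angle(np.exp(1j * phi))


def pairwise_connectivity(series: WindowedBandSeries,
                          pairs: list[PairGroup]) -> pd.DataFrame:
    """Per-window, per-pair PLV, mean phase difference and signed power diff.

    The *strong* flag marks pairs whose |power difference| falls below the
    mean |power difference| across all pairs of the same window and band.
    """
    ch_index = {c: i for i, c in enumerate(series.channels)}
    for pg in pairs:
        for ch in pg.pair:
            if ch not in ch_index:
                raise InputError(f"pair channel {ch!r} not present in series")

    good = ~series.sample_mask
    rows = []
    for w, (t_start, sl) in enumerate(zip(series.window_starts, series.slices)):
        keep = good[sl]
        spd_list = []
        win_rows = []
        for pg in pairs:
            ia, ib = ch_index[pg.pair[0]], ch_index[pg.pair[1]]
            dphi = _wrap(series.phase[ia, sl][keep] - series.phase[ib, sl][keep])
            resultant = np.mean(np.exp(1j * dphi))
            spd = series.power[w, ia] - series.power[w, ib]
            spd_list.append(abs(spd))
            win_rows.append({
                "window_start": t_start,
                "band": series.band,
                "ch_a": pg.pair[0],
                "ch_b": pg.pair[1],
                "group": pg.group,
                "distance_cm": pg.distance_cm,
                "plv": float(np.abs(resultant)),
                "mean_phase_diff": float(np.angle(resultant)),
                "signed_power_diff": float(spd),
            })
        thresh = float(np.mean(spd_list))
        for r in win_rows:
            r["strong"] = abs(r["signed_power_diff"]) < thresh
        rows.extend(win_rows)
    frame = pd.DataFrame(rows, columns=[
        "window_start", "band", "ch_a", "ch_b", "group", "distance_cm",
        "plv", "mean_phase_diff", "signed_power_diff", "strong",
    ])
    return frame


def group_eigenvalues(frame: pd.DataFrame,
                      groups: tuple[str, ...] = EIG_GROUPS) -> pd.DataFrame:
    """Mean signed power difference per pair-group per window, plus |mean|.

    Columns: window_start, band, e_<group>, abs_<group>.  The sign follows
    the canonical pair order (e.g. positive e_LD_OF means occipital power
    exceeds frontal power on average).
    """
    if frame.empty:
        raise InputError("empty connectivity frame")
    for g in groups:
        if not (frame["group"] == g).any():
            raise InputError(f"connectivity frame has no pairs in group {g!r}")
    sub = frame[frame["group"].isin(groups)]
    piv = (sub.groupby(["window_start", "band", "group"])["signed_power_diff"]
              .mean().unstack("group"))
    out = piv.reset_index()[["window_start", "band"] + list(groups)]
    out = out.rename(columns={g: f"e_{g}" for g in groups})
    for g in groups:
        out[f"abs_{g}"] = out[f"e_{g}"].abs()
    return out


def band_connectivity(rec: EEGRecording, montage: Montage,
                      band: BandSpec | str = "beta",
                      window: float = 1.0, hop: float = 0.5,
                      spec: WaveletSpec | None = None,
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Band filter -> CWT -> windowed phase/power -> pairwise frame + eigenvalues."""
    if isinstance(band, str):
        band = BANDS[band]
    if spec is None:
        spec = default_wavelet_spec(band)
    filtered = band_filter(rec, band)
    res = cwt_recording(filtered, spec)
    series = phase_and_power(res, band, window=window, hop=hop)
    pairs = classify_pairs(montage)
    frame = pairwise_connectivity(series, pairs)
    return frame, group_eigenvalues(frame)
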