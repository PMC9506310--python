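"""EEG conditioning: resampling, artifact masking, 0-30 Hz spectra, band filtering.

The analysis operates on four canonical frequency bands below 30 Hz:
delta (0-4 Hz), theta (4-8 Hz), alpha (8-12 Hz) and beta (12-30 Hz).
All filtering is zero-phase (forward-backward Butterworth) because the
downstream measurement is the *phase* relation between channels -- any
filter-induced phase shift would bias it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from fractions import Fraction

import numpy as np
from scipy import signal as sps

__all__ = [
    "EEGRecording",
    "BandSpec",
    "BANDS",
    "resample",
    "mask_artifacts",
    "band_filter",
    "broadband_filter",
    "spectrum",
]


class InputError(ValueError):
    """Invalid input to a preprocessing operation."""


@dataclass(frozen=True)
class BandSpec:
    name: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not (0 <= self.lo < self.hi <= 30):
            raise InputError(f"band edges must satisfy 0 <= lo < hi <= 30, got {self}")


#: The four canonical EEG bands used throughout the pipeline.
BANDS: dict[str, BandSpec] = {
    "delta": BandSpec("delta", 0.0, 4.0),
    "theta": BandSpec("theta", 4.0, 8.0),
    "alpha": BandSpec("alpha", 8.0, 12.0),
    "beta": BandSpec("beta", 12.0, 30.0),
}


@dataclass(frozen=True)
class EEGRecording:
    """Multichannel EEG: ``data`` is channels x time in microvolts.

    ``mask`` flags rejected samples (True = artifact); data values are never
    altered by masking so every step stays auditable.
    """

    data: np.ndarray
    rate: float
    channels: tuple[str, ...]
    t0: float = 0.0
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 2:
            raise InputError("data must be channels x time")
        if len(self.channels) != data.shape[0]:
            raise InputError("channel label count must match data rows")
        if self.rate <= 0:
            raise InputError("rate must be positive")
        object.__setattr__(self, "data", data)
        mask = self.mask
        if mask is None:
            mask = np.zeros(data.shape[1], dtype=bool)
        else:
            mask = np.asarray(mask, dtype=bool)
            if mask.shape != (data.shape[1],):
                raise InputError("mask length must equal number of time samples")
        object.__setattr__(self, "mask", mask)

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.rate

    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.rate


def resample(rec: EEGRecording, target_rate: float) -> EEGRecording:
    """Polyphase resampling to ``target_rate``; the mask is OR-pooled.

    Duration is preserved to within one sample period. Resampling at the
    native rate returns the data unchanged.
    """
    if target_rate <= 0:
        raise InputError("target_rate must be positive")
    if rec.n_samples == 0:
        raise InputError("cannot resample an empty recording")
    if math.isclose(target_rate, rec.rate):
        return rec
    frac = Fraction(target_rate / rec.rate).limit_denominator(1000)
    up, down = frac.numerator, frac.denominator
    data = sps.resample_poly(rec.data, up, down, axis=1)
    n_out = data.shape[1]
    # OR over the input samples that feed each output sample
    idx = (np.arange(n_out) * down) // up
    edges = np.minimum(idx, rec.n_samples - 1)
    mask = np.zeros(n_out, dtype=bool)
    for j in range(n_out):
        lo = edges[j]
        hi = min(((j + 1) * down) // up + 1, rec.n_samples)
        mask[j] = rec.mask[lo:hi].any()
    return EEGRecording(data=data, rate=target_rate, channels=rec.channels,
                        t0=rec.t0, mask=mask)


def mask_artifacts(rec: EEGRecording, amp_thresh: float = 100.0,
                   pad: float = 0.2) -> EEGRecording:
    """Flag samples exceeding ``amp_thresh`` uV on any channel, padded +-``pad`` s."""
    if amp_thresh <= 0:
        raise InputError("amp_thresh must be positive")
    if pad < 0:
        raise InputError("pad must be non-negative")
    hits = (np.abs(rec.data) > amp_thresh).any(axis=0)
    if hits.any():
        pad_n = int(round(pad * rec.rate))
        kernel = np.ones(2 * pad_n + 1, dtype=bool)
        hits = np.convolve(hits, kernel, mode="same") > 0
    return replace(rec, mask=rec.mask | hits)


def _band_sos(band: BandSpec, rate: float, order: int = 4):
    nyq = rate / 2
    if band.hi >= nyq:
        raise InputError(
            f"band edge {band.hi} Hz violates Nyquist for rate {rate} Hz"
        )
    if band.lo <= 0:
        # 0 Hz edge cannot be realized as a band-pass; use a low-pass
        return sps.butter(order, band.hi, btype="lowpass", fs=rate, output="sos")
    return sps.butter(order, [band.lo, band.hi], btype="bandpass", fs=rate,
                      output="sos")


def band_filter(rec: EEGRecording, band: BandSpec) -> EEGRecording:
    """Zero-phase 4th-order Butterworth band-pass restricted to one band."""
    sos = _band_sos(band, rec.rate)
    data = sps.sosfiltfilt(sos, rec.data, axis=1)
    return replace(rec, data=data)


def broadband_filter(rec: EEGRecording, lo: float = 0.5, hi: float = 30.0) -> EEGRecording:
    """Pre-filter to the analysis band (default 0.5-30 Hz) before anything else."""
    nyq = rec.rate / 2
    if hi >= nyq:
        raise InputError(f"upper edge {hi} Hz violates Nyquist for rate {rec.rate}")
    sos = sps.butter(4, [lo, hi], btype="bandpass", fs=rec.rate, output="sos")
    return replace(rec, data=sps.sosfiltfilt(sos, rec.data, axis=1))


def spectrum(rec: EEGRecording, fmax: float = 30.0) -> tuple[np.ndarray, np.ndarray]:
    """Per-channel one-sided Hann-windowed magnitude spectrum on [0, fmax].

    Returns ``(freqs, mag)`` with ``mag`` of shape (n_channels, n_freqs);
    magnitudes are amplitude-spectrum values (uV) so a unit sinusoid peaks
    near 1. Masked samples are excluded by restricting to the longest
    unmasked run; at least 2 s of clean data is required.
    """
    good = ~rec.mask
    if not good.any():
        raise InputError("no unmasked samples")
    # longest contiguous clean run
    runs = np.flatnonzero(np.diff(np.r_[False, good, False].astype(int)))
    starts, stops = runs[::2], runs[1::2]
    k = int(np.argmax(stops - starts))
    seg = rec.data[:, starts[k]:stops[k]]
    if seg.shape[1] < 2 * rec.rate:
        raise InputError("need at least 2 s of unmasked data for a spectrum")
    n = seg.shape[1]
    win = sps.get_window("hann", n)
    scale = 2.0 / win.sum()  # one-sided amplitude normalization
    spec = np.abs(np.fft.rfft(seg * win, axis=1)) * scale
    freqs = np.fft.rfftfreq(n, d=1.0 / rec.rate)
    keep = freqs <= fmax
    return freqs[keep], spec[:, keep]
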