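"""Gaze-stream analysis: I-VT event detection, pupil change, state aggregation.

Gaze is sampled at a nominal 60 Hz as (x, y) in degrees of visual angle plus
left/right pupil diameters in mm.  Fixations and saccades are segmented with
the velocity-threshold (I-VT) algorithm: samples whose angular velocity
exceeds a threshold belong to saccades, sufficiently long gaps between
saccades are fixations, and invalid samples split events.  Pupil response is
a percent change of mean diameter relative to a pre-stimulus baseline, which
removes inter-individual diameter offsets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import medfilt

from .preprocess import InputError
from .states import StateLabels, state_segments

__all__ = [
    "GazeRecording",
    "GazeEvent",
    "detect_events",
    "pupil_change",
    "aggregate_by_state",
    "DEFAULT_VEL_THRESH",
    "DEFAULT_MIN_FIX",
]

DEFAULT_VEL_THRESH = 30.0  # deg/s, standard I-VT threshold for 60 Hz trackers
DEFAULT_MIN_FIX = 0.1  # s, minimum fixation duration


@dataclass(frozen=True)
class GazeRecording:
    """Synchronized gaze/pupil streams (shared clock with the EEG t0)."""

    t: np.ndarray  # (n,) seconds, strictly increasing
    x: np.ndarray  # (n,) degrees of visual angle
    y: np.ndarray  # (n,) degrees
    pupil_left: np.ndarray  # (n,) mm
    pupil_right: np.ndarray  # (n,) mm
    valid: np.ndarray  # (n,) bool

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        if t.ndim != 1 or t.size < 2:
            raise InputError("need at least two gaze samples")
        if (np.diff(t) <= 0).any():
            raise InputError("timestamps must be strictly increasing")
        object.__setattr__(self, "t", t)
        for name in ("x", "y", "pupil_left", "pupil_right"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != t.shape:
                raise InputError(f"{name} length must match timestamps")
            object.__setattr__(self, name, arr)
        valid = np.asarray(self.valid, dtype=bool)
        if valid.shape != t.shape:
            raise InputError("valid length must match timestamps")
        object.__setattr__(self, "valid", valid)

    @property
    def rate(self) -> float:
        return 1.0 / float(np.median(np.diff(self.t)))


@dataclass(frozen=True)
class GazeEvent:
    kind: str  # "fixation" | "saccade"
    start: float
    end: float
    amplitude: float  # saccade displacement (deg) or fixation dispersion (deg)
    centroid: tuple[float, float]

    @property
    def duration(self) -> float:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.start + self.end)


def _runs(flags: np.ndarray) -> list[tuple[int, int]]:
    """Half-open index runs where ``flags`` is True."""
    edges = np.flatnonzero(np.diff(np.r_[False, flags, False].astype(int)))
    return list(zip(edges[::2], edges[1::2]))


def detect_events(g: GazeRecording, vel_thresh: float = DEFAULT_VEL_THRESH,
                  min_fix: float = DEFAULT_MIN_FIX) -> list[GazeEvent]:
    """I-VT segmentation of a gaze stream into saccades and fixations.

    A 3-sample median filter suppresses single-sample tracker noise before
    velocities are computed.  Saccade amplitude is the start-to-end angular
    displacement; fixation dispersion is the maximum radial deviation from
    the fixation centroid.
    """
    if g.valid.sum() / g.rate < 0.5:
        raise InputError("need at least 0.5 s of valid gaze samples")
    x = medfilt(g.x, 3)
    y = medfilt(g.y, 3)
    dt = np.diff(g.t)
    vel = np.hypot(np.diff(x), np.diff(y)) / dt
    # sample i velocity: max of adjacent segment velocities (conservative)
    v = np.zeros_like(g.t)
    v[:-1] = vel
    v[1:] = np.maximum(v[1:], vel)

    is_sacc = (v > vel_thresh) & g.valid
    events: list[GazeEvent] = []
    for i0, i1 in _runs(is_sacc):
        j = min(i1, g.t.size - 1)
        # average a few settled samples either side to beat fixation jitter
        pre = slice(max(i0 - 2, 0), i0 + 1)
        post = slice(j, min(j + 3, g.t.size))
        amp = float(np.hypot(x[post].mean() - x[pre].mean(),
                             y[post].mean() - y[pre].mean()))
        events.append(GazeEvent(
            kind="saccade", start=float(g.t[i0]), end=float(g.t[j]),
            amplitude=amp,
            centroid=(float(x[i0:j + 1].mean()), float(y[i0:j + 1].mean())),
        ))

    is_fix_candidate = ~is_sacc & g.valid
    for i0, i1 in _runs(is_fix_candidate):
        dur = float(g.t[i1 - 1] - g.t[i0]) + (1.0 / g.rate)
        if dur < min_fix or i1 - i0 < 2:
            continue
        cx, cy = float(x[i0:i1].mean()), float(y[i0:i1].mean())
        disp = float(np.hypot(x[i0:i1] - cx, y[i0:i1] - cy).max())
        events.append(GazeEvent(
            kind="fixation", start=float(g.t[i0]),
            end=float(g.t[i1 - 1]) + 1.0 / g.rate,
            amplitude=disp, centroid=(cx, cy),
        ))
    events.sort(key=lambda e: e.start)
    return events


def pupil_change(g: GazeRecording, baseline: tuple[float, float],
                 segment: tuple[float, float],
                 min_samples: int = 10) -> tuple[float, float]:
    """Percent pupil-diameter change of each eye in ``segment`` vs ``baseline``."""
    def mean_diam(lo: float, hi: float) -> tuple[float, float]:
        sel = (g.t >= lo) & (g.t < hi) & g.valid
        if sel.sum() < min_samples:
            raise InputError(
                f"interval [{lo:g}, {hi:g}) has {int(sel.sum())} valid samples, "
                f"need {min_samples}")
        return float(g.pupil_left[sel].mean()), float(g.pupil_right[sel].mean())

    bl, br = mean_diam(*baseline)
    sl, sr = mean_diam(*segment)
    return 100.0 * (sl - bl) / bl, 100.0 * (sr - br) / br


def aggregate_by_state(events: list[GazeEvent], g: GazeRecording,
                       labels: StateLabels, condition: str,
                       baseline: tuple[float, float] | None = None,
                       max_clock_skew: float = 0.5) -> pd.DataFrame:
    """Eye features per (condition, state): long-format one row per state.

    Events are assigned to the state segment containing their midpoint.
    Columns: condition, state (``emotional``/``non-emotional``),
    mean_fixation_duration_s, fixation_count, saccade_rate_hz,
    mean_saccade_amplitude_deg, pupil_change_left_pct, pupil_change_right_pct.
    States with no data are omitted (missing, not zero).
    """
    segs = state_segments(labels)
    if not segs:
        raise InputError("state labels cover no windows")
    if abs(g.t[0] - segs[0][0]) > max_clock_skew:
        raise InputError(
            f"gaze and EEG clocks misaligned by {abs(g.t[0] - segs[0][0]):.3g} s")
    if baseline is None:
        baseline = (float(g.t[0]), float(g.t[0]) + 5.0)

    def seg_of(tmid: float):
        for s in segs:
            if s[0] <= tmid < s[1]:
                return s
        return segs[-1] if tmid >= segs[-1][1] else None

    rows = []
    for flag in (False, True):
        state_segs = [s for s in segs if s[2] == flag]
        if not state_segs:
            continue
        total_time = sum(s1 - s0 for s0, s1, _ in state_segs)
        fixs, saccs = [], []
        for ev in events:
            s = seg_of(ev.midpoint)
            if s is None or s[2] != flag:
                continue
            (fixs if ev.kind == "fixation" else saccs).append(ev)
        # pupil change pooled over the state's segments
        sel = g.valid & np.any(
            [(g.t >= s0) & (g.t < s1) for s0, s1, _ in state_segs], axis=0)
        try:
            bsel = (g.t >= baseline[0]) & (g.t < baseline[1]) & g.valid
            if bsel.sum() < 10 or sel.sum() < 10:
                raise InputError("insufficient valid pupil samples")
            pl = 100.0 * (g.pupil_left[sel].mean() - g.pupil_left[bsel].mean()) \
                / g.pupil_left[bsel].mean()
            pr = 100.0 * (g.pupil_right[sel].mean() - g.pupil_right[bsel].mean()) \
                / g.pupil_right[bsel].mean()
        except InputError:
            pl = pr = np.nan
        rows.append({
            "condition": condition,
            "state": "emotional" if flag else "non-emotional",
            "mean_fixation_duration_s":
                float(np.mean([e.duration for e in fixs])) if fixs else np.nan,
            "fixation_count": len(fixs),
            "saccade_rate_hz": len(saccs) / total_time if total_time > 0 else np.nan,
            "mean_saccade_amplitude_deg":
                float(np.mean([e.amplitude for e in saccs])) if saccs else np.nan,
            "pupil_change_left_pct": pl,
            "pupil_change_right_pct": pr,
        })
    return pd.DataFrame(rows)
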