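"""Incremental k-means segmentation of the eigenvalue series into emotional states.

The three distance-group eigenvalues form a chronological series of points in
R^3.  Running k-means for k = 1..k_max ("incremental" k) and stopping when an
extra cluster no longer buys a meaningful inertia reduction picks the number
of distinct brain states in a session; in the two-state case one cluster is
flagged *emotional* -- the one whose centroid lies farther from the
pre-stimulus baseline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .connectivity import EIG_GROUPS
from .preprocess import InputError

__all__ = ["StateLabels", "incremental_kmeans", "label_emotional", "state_segments"]

DEFAULT_K_MAX = 6
DEFAULT_REL_IMPROVEMENT = 0.10


@dataclass(frozen=True)
class StateLabels:
    """Clustering of eigenvalue windows into states."""

    window_starts: np.ndarray  # (n_windows,) seconds
    hop: float  # seconds between consecutive windows
    labels: np.ndarray  # (n_windows,) int in [0, chosen_k)
    chosen_k: int
    centroids: np.ndarray  # (chosen_k, 3) in standardized eigenvalue space
    inertia: dict[int, float]  # candidate k -> within-cluster inertia
    emotional: np.ndarray | None = None  # (n_windows,) bool, set by label_emotional
    standardized: np.ndarray | None = None  # (n_windows, 3) z-scored features


def _feature_matrix(series: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    cols = [f"e_{g}" for g in EIG_GROUPS]
    missing = [c for c in cols if c not in series.columns]
    if missing:
        raise InputError(f"eigenvalue series missing columns {missing}")
    x = series[cols].to_numpy(dtype=float)
    starts = series["window_start"].to_numpy(dtype=float)
    order = np.argsort(starts, kind="stable")
    return x[order], starts[order]


def _standardize(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)  # constant columns carry no information
    return (x - mu) / sd


def incremental_kmeans(series: pd.DataFrame, k_max: int = DEFAULT_K_MAX,
                       seed: int = 0,
                       rel_improvement: float = DEFAULT_REL_IMPROVEMENT,
                       ) -> StateLabels:
    """Cluster the standardized eigenvalue triplets for k = 1..k_max.

    The chosen number of states is k-1 for the smallest k >= 2 whose inertia
    improvement over k-1 -- as a fraction of the total variance, inertia(1) --
    drops below ``rel_improvement`` (the extra cluster no longer explains a
    meaningful share of the variance); if every step helps, k_max is chosen.
    A constant series therefore yields one state.  Deterministic given
    ``seed``.
    """
    x, starts = _feature_matrix(series)
    n = x.shape[0]
    if k_max < 1:
        raise InputError("k_max must be >= 1")
    if n < k_max:
        raise InputError(f"need at least k_max={k_max} windows, got {n}")
    z = _standardize(x)

    inertia: dict[int, float] = {}
    fits: dict[int, KMeans] = {}
    with warnings.catch_warnings():
        # constant/duplicate inputs legitimately yield fewer distinct clusters
        from sklearn.exceptions import ConvergenceWarning
        warnings.simplefilter("ignore", ConvergenceWarning)
        for k in range(1, k_max + 1):
            km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(z)
            inertia[k] = float(km.inertia_)
            fits[k] = km

    total = inertia[1]
    chosen = k_max
    for k in range(2, k_max + 1):
        gain = 0.0 if total <= 0 else (inertia[k - 1] - inertia[k]) / total
        if gain < rel_improvement:
            chosen = k - 1
            break

    km = fits[chosen]
    hop = float(np.median(np.diff(starts))) if n > 1 else 1.0
    return StateLabels(
        window_starts=starts,
        hop=hop,
        labels=km.labels_.astype(int),
        chosen_k=chosen,
        centroids=km.cluster_centers_,
        inertia=inertia,
        standardized=z,
    )


def label_emotional(labels: StateLabels, baseline_windows: int = 10) -> StateLabels:
    """Flag the cluster farther from the session-start baseline as emotional.

    Sessions begin before the stimulus, so the mean of the first
    ``baseline_windows`` standardized points anchors the non-emotional state.
    With a single state everything is non-emotional (warning emitted).
    """
    n = labels.window_starts.size
    if baseline_windows >= n:
        raise InputError("baseline_windows must be smaller than the window count")
    if labels.chosen_k != 2:
        if labels.chosen_k != 1:
            warnings.warn(
                f"chosen_k={labels.chosen_k} != 2; flagging all windows "
                "non-emotional", stacklevel=2)
        else:
            warnings.warn("single state found; all windows non-emotional",
                          stacklevel=2)
        return replace(labels, emotional=np.zeros(n, dtype=bool))
    baseline = labels.standardized[:baseline_windows].mean(axis=0)
    dists = np.linalg.norm(labels.centroids - baseline, axis=1)
    emotional_cluster = int(np.argmax(dists))
    return replace(labels, emotional=labels.labels == emotional_cluster)


def state_segments(labels: StateLabels) -> list[tuple[float, float, bool]]:
    """Run-length encode the emotional flag into (start_s, end_s, flag) segments.

    Segments tile the session chronologically; each window occupies one hop.
    """
    flags = labels.emotional
    if flags is None:
        flags = np.zeros(labels.window_starts.size, dtype=bool)
    if flags.size == 0:
        return []
    starts = labels.window_starts
    segments: list[tuple[float, float, bool]] = []
    seg_start = float(starts[0])
    cur = bool(flags[0])
    for i in range(1, flags.size):
        if bool(flags[i]) != cur:
            segments.append((seg_start, float(starts[i]), cur))
            seg_start = float(starts[i])
            cur = bool(flags[i])
    segments.append((seg_start, float(starts[-1]) + labels.hop, cur))
    return segments
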