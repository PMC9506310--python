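"""Group statistics over the 2x2 valence-arousal design.

Participant-level feature values (eigenvalues, eye features, subjective
scores) are compared across the four emotion-eliciting conditions
(pleasant-aroused, pleasant-relaxed, unpleasant-relaxed, unpleasant-aroused)
with a one-way ANOVA followed by Tukey's HSD; a Bonferroni-style adjusted
per-test alpha (family alpha / number of tests) is reported alongside for
families of ANOVAs.  Eigenvalue and eye-feature condition profiles are
compared descriptively by Spearman rank concordance over the four condition
means (n = 4, so no inference is attached).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sst
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .preprocess import InputError

__all__ = [
    "CONDITIONS",
    "TukeyResult",
    "one_way_anova",
    "tukey_hsd",
    "adjusted_alpha",
    "compare_profiles",
]

#: The 2x2 valence-arousal conditions, in reporting order.
CONDITIONS = (
    "pleasant-aroused",
    "pleasant-relaxed",
    "unpleasant-relaxed",
    "unpleasant-aroused",
)


@dataclass(frozen=True)
class TukeyResult:
    """All pairwise mean comparisons of one feature across conditions."""

    table: pd.DataFrame  # condition_1, condition_2, mean_difference, lower, upper, reject
    family_alpha: float
    per_test_alpha: float

    @property
    def n_comparisons(self) -> int:
        return len(self.table)


def one_way_anova(groups: list[np.ndarray]) -> tuple[float, float, tuple[int, int]]:
    """Standard between/within decomposition; returns (F, p, (df_b, df_w)).

    Zero variance everywhere (all groups constant and equal) degenerates to
    F = 0, p = 1 with a warning instead of 0/0.
    """
    if len(groups) < 2:
        raise InputError("ANOVA needs at least two groups")
    groups = [np.asarray(g, dtype=float) for g in groups]
    for i, g in enumerate(groups):
        if g.size < 2:
            raise InputError(f"group {i} has fewer than 2 observations")
    df_b = len(groups) - 1
    df_w = sum(g.size for g in groups) - len(groups)
    allv = np.concatenate(groups)
    if np.ptp(allv) == 0:
        warnings.warn("all observations identical; F set to 0, p to 1",
                      stacklevel=2)
        return 0.0, 1.0, (df_b, df_w)
    f, p = sst.f_oneway(*groups)
    return float(f), float(p), (df_b, df_w)


def tukey_hsd(groups: dict[str, np.ndarray],
              family_alpha: float = 0.05) -> TukeyResult:
    """Tukey HSD over all condition pairs at the family alpha.

    ``mean_difference`` is mean(condition_2) - mean(condition_1); ``reject``
    is True when the studentized-range interval excludes zero.  The adjusted
    per-test alpha (family / number of comparisons... of the four-ANOVA
    family: family_alpha / 4 by default usage) is carried for bookkeeping,
    not applied on top of Tukey's own familywise control.
    """
    if len(groups) < 2:
        raise InputError("Tukey HSD needs at least two groups")
    for name, g in groups.items():
        if np.asarray(g).size < 2:
            raise InputError(f"group {name!r} has fewer than 2 observations")
    values = np.concatenate([np.asarray(g, dtype=float) for g in groups.values()])
    labels = np.concatenate([[name] * np.asarray(g).size for name, g in groups.items()])
    res = pairwise_tukeyhsd(values, labels, alpha=family_alpha)
    tbl = pd.DataFrame(res.summary().data[1:], columns=[
        "condition_1", "condition_2", "mean_difference", "p_adj",
        "lower", "upper", "reject"])
    tbl = tbl.astype({"mean_difference": float, "lower": float, "upper": float,
                      "p_adj": float, "reject": bool})
    tbl = tbl[["condition_1", "condition_2", "mean_difference",
               "lower", "upper", "p_adj", "reject"]]
    return TukeyResult(table=tbl, family_alpha=family_alpha,
                       per_test_alpha=adjusted_alpha(family_alpha, 4))


def adjusted_alpha(family_alpha: float, n_tests: int) -> float:
    """Bonferroni-style per-test alpha: family alpha split over n tests."""
    if not (0 < family_alpha < 1):
        raise InputError("family_alpha must be in (0, 1)")
    if n_tests < 1:
        raise InputError("n_tests must be >= 1")
    return family_alpha / n_tests


def compare_profiles(eig_means: pd.DataFrame,
                     eye_means: pd.DataFrame) -> pd.DataFrame:
    """Rank concordance of condition profiles: eigenvalues vs eye features.

    Both inputs are condition x feature tables indexed by the four condition
    names.  Returns a long table (eigenvalue_feature, eye_feature, spearman_rho)
    computed over the four condition means -- descriptive only at n = 4.
    """
    for df, nm in ((eig_means, "eig_means"), (eye_means, "eye_means")):
        missing = set(CONDITIONS) - set(df.index)
        if missing:
            raise InputError(f"{nm} missing conditions: {sorted(missing)}")
    eig = eig_means.loc[list(CONDITIONS)]
    eye = eye_means.loc[list(CONDITIONS)]
    rows = []
    for ec in eig.columns:
        for yc in eye.columns:
            rho = sst.spearmanr(eig[ec], eye[yc]).statistic
            rows.append({"eigenvalue_feature": ec, "eye_feature": yc,
                         "spearman_rho": float(rho)})
    return pd.DataFrame(rows)


def participant_condition_means(window_values: pd.DataFrame,
                                value_col: str) -> pd.DataFrame:
    """Aggregate window-level values to one mean per participant x condition.

    Expects columns participant, condition and ``value_col``; this is the
    aggregation applied before any ANOVA so each participant contributes a
    single observation per condition.
    """
    for col in ("participant", "condition", value_col):
        if col not in window_values.columns:
            raise InputError(f"missing column {col!r}")
    return (window_values.groupby(["participant", "condition"])[value_col]
            .mean().reset_index())
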