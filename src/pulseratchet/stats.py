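"""Group-level statistics for constriction/expansion-rate comparisons.

The effect-size rule used throughout is a conservative variant of Cohen's d,

    d = (x̄₁ − x̄₂) / (2 s),

where ``s`` is the *maximal* sample standard deviation over all groups of
the complete dataset. Because the per-cell sample sizes are large, p-values
alone are uninformative; |d| < 0.5 is treated as not significant. Alongside
it: the classic pooled two-sample t-test, one-way ANOVA with a Tukey(-Kramer)
post hoc, fold-change normalization of rates to the control-group mean, and
category-fraction summaries.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "EffectSizeResult",
    "AnovaResult",
    "FoldChangeResult",
    "TooFewValuesError",
    "DegenerateDataError",
    "cohens_d",
    "two_sample_ttest",
    "anova_oneway",
    "fold_change_rates",
    "ratio_of_changes",
    "category_fractions",
]

CATEGORY_ORDER = ("constricted", "impaired", "expanded")


class TooFewValuesError(ValueError):
    """A dispersion-based statistic needs at least two values per group."""


class DegenerateDataError(ValueError):
    """All variance is zero: the requested statistic is undefined."""


@dataclass
class EffectSizeResult:
    d: float
    mean_1: float
    mean_2: float
    s_max: float
    significant: bool


@dataclass
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float
    tukey: Optional[object] = None  # statsmodels TukeyHSDResults

    def tukey_table(self):
        """Tukey post hoc summary as a pandas DataFrame (None if not run)."""
        import pandas as pd

        if self.tukey is None:
            return None
        table = self.tukey.summary()
        return pd.DataFrame(table.data[1:], columns=table.data[0])


@dataclass
class FoldChangeResult:
    fold: float
    percent_change: float

    @property
    def fold_rounded(self) -> float:
        return round(self.fold, 1)

    @property
    def percent_change_rounded(self) -> int:
        return int(round(self.percent_change))


def _sd(values: np.ndarray) -> float:
    if values.size < 2:
        raise TooFewValuesError("need n >= 2 for a standard deviation")
    return float(np.std(values, ddof=1))


def cohens_d(
    group_1: Sequence[float],
    group_2: Sequence[float],
    all_groups: Optional[Sequence[Sequence[float]]] = None,
    threshold: float = 0.5,
) -> EffectSizeResult:
    """Effect size d = (x̄₁ − x̄₂) / (2·s_max) with the maximal-SD denominator.

    ``all_groups`` is the complete dataset whose maximal sample SD (n−1
    denominator) enters the denominator; it defaults to the two groups
    being compared. ``significant`` flags |d| ≥ ``threshold`` (0.5).
    """
    g1 = np.asarray(group_1, dtype=float)
    g2 = np.asarray(group_2, dtype=float)
    if all_groups is None:
        all_groups = [g1, g2]
    s_max = max(_sd(np.asarray(g, dtype=float)) for g in all_groups)
    if s_max == 0:
        raise DegenerateDataError("all groups have zero variance")
    d = (g1.mean() - g2.mean()) / (2.0 * s_max)
    return EffectSizeResult(
        d=float(d),
        mean_1=float(g1.mean()),
        mean_2=float(g2.mean()),
        s_max=s_max,
        significant=bool(abs(d) >= threshold),
    )


def two_sample_ttest(group_1: Sequence[float], group_2: Sequence[float]):
    """Pooled-variance two-sample t-test; returns (t, two-sided p)."""
    g1 = np.asarray(group_1, dtype=float)
    g2 = np.asarray(group_2, dtype=float)
    if g1.size < 2 or g2.size < 2:
        raise TooFewValuesError("each group needs n >= 2")
    if np.std(g1, ddof=1) == 0 and np.std(g2, ddof=1) == 0 and g1.mean() == g2.mean():
        raise DegenerateDataError("zero pooled variance with equal means")
    t, p = sps.ttest_ind(g1, g2, equal_var=True)
    return float(t), float(p)


def anova_oneway(
    groups: Sequence[Sequence[float]],
    labels: Optional[Sequence[str]] = None,
    tukey: bool = True,
    alpha: float = 0.05,
) -> AnovaResult:
    """One-way ANOVA with a Tukey(-Kramer) post hoc at ``alpha``."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2 or any(a.size < 2 for a in arrays):
        raise TooFewValuesError("need >= 2 groups with n >= 2 each")
    within = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    means = [a.mean() for a in arrays]
    if within == 0 and len(set(means)) == 1:
        raise DegenerateDataError("no variance anywhere: F is 0/0")
    f, p = sps.f_oneway(*arrays)
    df_between = len(arrays) - 1
    df_within = sum(a.size for a in arrays) - len(arrays)
    tk = None
    if tukey:
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        if labels is None:
            labels = [f"group_{i + 1}" for i in range(len(arrays))]
        values = np.concatenate(arrays)
        group_ids = np.concatenate(
            [np.repeat(lab, a.size) for lab, a in zip(labels, arrays)]
        )
        tk = pairwise_tukeyhsd(values, group_ids, alpha=alpha)
    return AnovaResult(
        F=float(f), df_between=df_between, df_within=df_within, p=float(p), tukey=tk
    )


def fold_change_rates(control_mean: float, test_mean: float) -> FoldChangeResult:
    """Fold change of a rate relative to the control-group mean."""
    if control_mean <= 0:
        raise ValueError("control mean must be positive")
    fold = test_mean / control_mean
    return FoldChangeResult(fold=float(fold), percent_change=float(100.0 * (fold - 1.0)))


def ratio_of_changes(
    percent_change_expansion: float, percent_change_constriction: float
) -> float:
    """|expansion change| / |constriction change| (how asymmetric the defect is)."""
    if percent_change_constriction == 0:
        raise ZeroDivisionError("constriction change is zero; ratio undefined")
    return abs(percent_change_expansion) / abs(percent_change_constriction)


def category_fractions(categories: Sequence[str]) -> dict:
    """Fractions and counts over the constricted/impaired/expanded classes."""
    cats = list(categories)
    if not cats:
        raise ValueError("no categorized cells")
    counts = {k: 0 for k in CATEGORY_ORDER}
    for c in cats:
        if c not in counts:
            raise ValueError(f"unknown category '{c}'")
        counts[c] += 1
    n = len(cats)
    return {
        "fractions": {k: counts[k] / n for k in CATEGORY_ORDER},
        "counts": counts,
        "n": n,
    }
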