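"""Group-level paired statistics and individual classification-flip tables.

Normality of the pairwise differences (one-sample Kolmogorov-Smirnov
against a normal with the sample's own mean and SD) selects a paired
t-test or a Wilcoxon matched-pairs signed-rank test; summaries follow
the mean +/- SD vs. median [Q1-Q3] convention per arm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "PairedMeasurements",
    "FlipTable",
    "ComparisonReport",
    "normality_check",
    "paired_compare",
    "flip_count",
]

ALPHA = 0.05


@dataclass
class PairedMeasurements:
    """Baseline/intervention values of one metric, paired by id.

    Pairs with a missing (NaN) side are excluded pairwise on creation.
    """

    metric: str
    ids: list
    baseline: np.ndarray
    intervention: np.ndarray

    def __post_init__(self) -> None:
        self.baseline = np.asarray(self.baseline, dtype=float)
        self.intervention = np.asarray(self.intervention, dtype=float)
        if not (len(self.ids) == len(self.baseline) == len(self.intervention)):
            raise ValueError("ids, baseline and intervention must have equal length")
        keep = np.isfinite(self.baseline) & np.isfinite(self.intervention)
        if not keep.all():
            self.ids = [i for i, k in zip(self.ids, keep) if k]
            self.baseline = self.baseline[keep]
            self.intervention = self.intervention[keep]

    @property
    def n(self) -> int:
        return len(self.baseline)

    @property
    def differences(self) -> np.ndarray:
        return self.intervention - self.baseline


@dataclass
class FlipTable:
    """Bookkeeping of classification changes between paired conditions."""

    metric: str
    n_total: int
    n_to_state_a: int  # flips into the below-cutoff state
    n_to_state_b: int  # flips into the above-cutoff state
    n_unchanged: int
    state_a: str
    state_b: str
    cutoff: float

    def __post_init__(self) -> None:
        if self.n_to_state_a + self.n_to_state_b + self.n_unchanged != self.n_total:
            raise ValueError("flip counts must sum to n_total")


@dataclass
class ComparisonReport:
    metric: str
    n: int
    test: str  # "paired t-test" | "wilcoxon" | "no difference"
    statistic: float
    p_value: float
    baseline_summary: str
    intervention_summary: str
    normal_differences: bool
    extra: dict = field(default_factory=dict)


def normality_check(values: np.ndarray, alpha: float = ALPHA) -> bool:
    """Kolmogorov-Smirnov check against a fitted normal; True = plausibly normal.

    Parameters are estimated from the sample (Lilliefors caveat: the
    nominal KS p-value is conservative in this use).  Degenerate constant
    samples return False.
    """
    values = np.asarray(values, dtype=float)
    if len(values) < 5:
        raise ValueError("need at least 5 values for a normality check")
    sd = values.std(ddof=1)
    if sd == 0:
        return False
    _, p = stats.kstest(values, "norm", args=(values.mean(), sd))
    return bool(p >= alpha)


def _summarize(values: np.ndarray) -> str:
    """Mean +/- SD when the arm itself passes normality, else median [Q1-Q3]."""
    values = np.asarray(values, dtype=float)
    try:
        normal = normality_check(values)
    except ValueError:
        normal = True
    if normal:
        return f"{values.mean():.4g} ± {values.std(ddof=1):.4g}"
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    return f"{med:.4g} [{q1:.4g}–{q3:.4g}]"


def paired_compare(pairs: PairedMeasurements, alpha: float = ALPHA) -> ComparisonReport:
    """Compare baseline vs. intervention with the test the data supports."""
    if pairs.n < 3:
        raise ValueError(f"need at least 3 complete pairs, got {pairs.n}")
    diffs = pairs.differences
    if np.all(diffs == 0):
        return ComparisonReport(
            metric=pairs.metric,
            n=pairs.n,
            test="no difference",
            statistic=0.0,
            p_value=1.0,
            baseline_summary=_summarize(pairs.baseline),
            intervention_summary=_summarize(pairs.intervention),
            normal_differences=False,
        )
    try:
        normal = normality_check(diffs, alpha=alpha)
    except ValueError:  # < 5 pairs: default to the parametric path
        normal = True
    if normal:
        res = stats.ttest_rel(pairs.intervention, pairs.baseline)
        test, statistic, p = "paired t-test", float(res.statistic), float(res.pvalue)
    else:
        res = stats.wilcoxon(pairs.intervention, pairs.baseline)
        test, statistic, p = "wilcoxon", float(res.statistic), float(res.pvalue)
    return ComparisonReport(
        metric=pairs.metric,
        n=pairs.n,
        test=test,
        statistic=statistic,
        p_value=p,
        baseline_summary=_summarize(pairs.baseline),
        intervention_summary=_summarize(pairs.intervention),
        normal_differences=normal,
        extra={"median_difference": float(np.median(diffs))},
    )


def flip_count(
    pairs: PairedMeasurements,
    cutoff: float,
    state_a: str = "intact",
    state_b: str = "impaired",
) -> FlipTable:
    """Count baseline -> intervention classification flips at a cutoff.

    A value above the cutoff is in ``state_b`` (e.g. impaired for Mx at
    0.3, reliable for coherence at 0.34), at or below in ``state_a``.
    """
    if pairs.n == 0:
        raise ValueError("no complete pairs")
    base_b = pairs.baseline > cutoff
    int_b = pairs.intervention > cutoff
    to_b = int(np.sum(~base_b & int_b))
    to_a = int(np.sum(base_b & ~int_b))
    return FlipTable(
        metric=pairs.metric,
        n_total=pairs.n,
        n_to_state_a=to_a,
        n_to_state_b=to_b,
        n_unchanged=pairs.n - to_a - to_b,
        state_a=state_a,
        state_b=state_b,
        cutoff=cutoff,
    )
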