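"""Cohort-level statistical comparisons of instability statistics.

Per-donor MSLG or RoSE values grouped by cell type are compared with a
classical fixed-effects one-way ANOVA followed by Holm-Sidak-adjusted
pairwise comparisons; designated pairs (e.g. the two MSN subtypes) are
additionally compared with a two-sided ratio paired t-test, i.e. a paired
t-test on log-transformed values.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps


class CohortStatsError(ValueError):
    pass


@dataclass(frozen=True)
class PairwiseComparison:
    pair: tuple[str, str]
    raw_p: float
    adjusted_p: float
    t: float


@dataclass(frozen=True)
class GroupComparisonResult:
    groups: dict[str, list[float]]
    F: float
    p_overall: float
    pairwise: tuple[PairwiseComparison, ...] = ()
    t_ratio_paired: tuple[float, float] | None = None  # (t, two-sided p)
    p_underflow: bool = False


def one_way_anova(groups: list[list[float]]) -> tuple[float, float]:
    """Classical fixed-effects one-way ANOVA (F, p); unequal sizes allowed.

    Zero within-group variance with distinct means yields an infinite F;
    p is then reported as 0.0 and flagged by callers via math.isinf(F).
    """
    if len(groups) < 2:
        raise CohortStatsError("need at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size < 2 for a in arrays):
        raise CohortStatsError("every group needs at least two values")
    f, p = sps.f_oneway(*arrays)
    if math.isnan(f):
        # all values identical in every group: no variance anywhere
        return 0.0, 1.0
    if math.isinf(f):
        return float(f), 0.0
    return float(f), float(p)


def holm_sidak(raw_p) -> np.ndarray:
    """Holm-Sidak step-down adjustment, returned in input order.

    Sorted ascending, adjusted_k = 1 - (1 - p_(k))^(m - k + 1) with a
    running maximum enforcing monotonicity, capped at 1.
    """
    p = np.asarray(raw_p, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise CohortStatsError("raw_p must be a non-empty 1-d vector")
    if np.any((p < 0) | (p > 1)):
        raise CohortStatsError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m, dtype=float)
    running = 0.0
    for k, idx in enumerate(order):  # k = 0 .. m-1 (paper's k-1)
        value = 1.0 - (1.0 - p[idx]) ** (m - k)
        running = max(running, min(value, 1.0))
        adjusted[idx] = running
    return adjusted


def ratio_paired_ttest(x, y) -> tuple[float, float]:
    """Two-sided paired t-test on log values (test of mean log ratio = 0)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise CohortStatsError("x and y must be equal-length vectors of size >= 2")
    if np.any(x <= 0) or np.any(y <= 0):
        raise CohortStatsError("ratio paired t-test requires strictly positive values")
    result = sps.ttest_rel(np.log(x), np.log(y))
    if math.isnan(result.statistic):  # identical vectors: zero variance of ratios
        return 0.0, 1.0
    return float(result.statistic), float(result.pvalue)


def _pooled_t(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    t, p = sps.ttest_ind(a, b, equal_var=True)
    if math.isnan(t):
        return 0.0, 1.0
    return float(t), float(p)


def compare_groups(
    groups: dict[str, list[float]],
    paired_pair: tuple[str, str] | None = None,
) -> GroupComparisonResult:
    """One-way ANOVA over all groups plus Holm-Sidak pairwise comparisons.

    Pairwise raw p-values come from two-sided pooled-variance t-tests.
    ``paired_pair`` optionally names two groups (matched by position, e.g.
    per-donor values in the same order) for a ratio paired t-test.
    """
    labels = list(groups)
    f, p_overall = one_way_anova([groups[k] for k in labels])
    pairs = list(itertools.combinations(labels, 2))
    raw = []
    ts = []
    for a, b in pairs:
        t, p = _pooled_t(np.asarray(groups[a], float), np.asarray(groups[b], float))
        ts.append(t)
        raw.append(p)
    adjusted = holm_sidak(raw) if raw else np.array([])
    pairwise = tuple(
        PairwiseComparison(pair=pair, raw_p=rp, adjusted_p=ap, t=t)
        for pair, rp, ap, t in zip(pairs, raw, adjusted, ts)
    )
    t_ratio = None
    if paired_pair is not None:
        a, b = paired_pair
        t_ratio = ratio_paired_ttest(groups[a], groups[b])
    return GroupComparisonResult(
        groups={k: list(v) for k, v in groups.items()},
        F=f,
        p_overall=p_overall,
        pairwise=pairwise,
        t_ratio_paired=t_ratio,
        p_underflow=math.isinf(f),
    )
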