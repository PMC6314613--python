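"""Statistical tests used in the analysis, as explicit thin contracts.

Three tests cover the reporting needs: a two-sided Wilcoxon rank-sum test
for between-condition comparisons of per-subject summaries, a 1-df
chi-square goodness-of-fit test of cooperation counts against chance
(p = 0.5) with Bonferroni correction over the four transition-vector
components, and a one-way ANOVA across state occupancies with Bonferroni-
corrected pairwise post-hoc comparisons.

All tests operate on per-session or per-subject summaries passed in
explicitly — the module never reaches into raw trial logs — so the
statistical unit of every comparison is visible at the call site.
scipy.stats provides the underlying distributions and test machinery.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "StatsConfig",
    "TestResult",
    "PairwiseResult",
    "AnovaResult",
    "rank_sum",
    "chi_square_vs_chance",
    "anova_oneway",
]


@dataclass(frozen=True)
class StatsConfig:
    alpha: float = 0.05
    bonferroni_posthoc_alpha: float = 0.0125
    chance_p: float = 0.5

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha outside (0, 1)")


@dataclass(frozen=True)
class TestResult:
    name: str
    statistic: float
    p_value: float
    threshold: float | None = None
    significant: bool | None = None


@dataclass(frozen=True)
class PairwiseResult:
    pair: tuple[int, int]
    statistic: float
    p_value: float
    threshold: float
    significant: bool


@dataclass(frozen=True)
class AnovaResult:
    f_statistic: float
    p_value: float
    degenerate: bool
    pairwise: list[PairwiseResult]


def rank_sum(sample_a: Sequence[float], sample_b: Sequence[float]) -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Uses the exact null distribution when both samples have at most 10
    observations and no ties; otherwise the normal approximation with
    continuity correction.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    exact = a.size <= 10 and b.size <= 10 and np.unique(pooled).size == pooled.size
    res = sps.mannwhitneyu(a, b, alternative="two-sided",
                           method="exact" if exact else "asymptotic",
                           use_continuity=True)
    return TestResult(name="rank_sum", statistic=float(res.statistic),
                      p_value=float(res.pvalue))


def chi_square_vs_chance(
    n_cooperate: int,
    n_total: int,
    config: StatsConfig = StatsConfig(),
    n_comparisons: int = 4,
) -> TestResult:
    """Chi-square goodness of fit of a cooperation count against chance.

    Tests the observed (cooperate, defect) split against the chance split
    (``chance_p``, default 0.5) with 1 degree of freedom.  The verdict
    compares p to ``alpha / n_comparisons`` — Bonferroni over the four
    conditional-probability components by default (threshold 0.0125).
    """
    if n_total < 1:
        raise ValueError("n_total must be >= 1")
    if n_cooperate > n_total or n_cooperate < 0:
        raise ValueError("n_cooperate must be in [0, n_total]")
    observed = np.array([n_cooperate, n_total - n_cooperate], dtype=float)
    expected = np.array([config.chance_p, 1 - config.chance_p]) * n_total
    res = sps.chisquare(observed, expected)
    threshold = config.alpha / n_comparisons
    return TestResult(
        name="chi_square_vs_chance",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        threshold=threshold,
        significant=bool(res.pvalue < threshold),
    )


def anova_oneway(
    groups: Sequence[Sequence[float]],
    config: StatsConfig = StatsConfig(),
) -> AnovaResult:
    """One-way ANOVA with Bonferroni-corrected pairwise post-hoc tests.

    Pairwise rank-sum comparisons are run only when the omnibus F test is
    significant at ``alpha``; each is judged at ``alpha / n_pairs``,
    recomputed from the actual number of pairwise comparisons.  Groups with
    zero pooled variance yield a degenerate result rather than a division
    by zero.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2 or any(a.size < 2 for a in arrays):
        raise ValueError("need >= 2 groups with >= 2 observations each")
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:
        return AnovaResult(f_statistic=float("nan"), p_value=float("nan"),
                           degenerate=True, pairwise=[])
    f_stat, p = sps.f_oneway(*arrays)
    pairwise: list[PairwiseResult] = []
    if p < config.alpha:
        pairs = list(combinations(range(len(arrays)), 2))
        threshold = config.alpha / len(pairs)
        for i, j in pairs:
            r = rank_sum(arrays[i], arrays[j])
            pairwise.append(PairwiseResult(
                pair=(i, j), statistic=r.statistic, p_value=r.p_value,
                threshold=threshold, significant=r.p_value < threshold,
            ))
    return AnovaResult(f_statistic=float(f_stat), p_value=float(p),
                       degenerate=False, pairwise=pairwise)
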