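"""Nonparametric group contrasts with Bonferroni correction.

Network parameters are compared between group pairs with two-tailed
Mann-Whitney U tests on the node-level metric vectors of the two graphs
(e.g. 16 clustering values vs 16 clustering values). Standardized test
scores are compared across all groups with the tie-corrected Kruskal-Wallis
H test followed by post hoc Dunn tests on the pooled ranks; categorical
demographics use Pearson's chi-square without continuity correction. All
families are corrected by Bonferroni, and every result carries its family
size so the convention is auditable.

Caveat: node-level metric values within one graph are not independent
observations — they are functions of a single estimated network. The U test
on them is a descriptive contrast, exactly as practiced in covariance-network
studies; :func:`metric_permutation_test` offers a subject-relabelling
alternative whose null distribution respects the graph construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from cognet.table import group_table

ALPHA = 0.05


@dataclass(frozen=True)
class ComparisonResult:
    """One test result with its multiplicity bookkeeping."""

    measure: str
    group_a: str
    group_b: str
    statistic: float
    p_raw: float
    family_size: int = 1
    df: Optional[int] = None

    @property
    def p_adjusted(self) -> float:
        return min(1.0, self.p_raw * self.family_size)

    @property
    def significant(self) -> bool:
        return self.p_adjusted < ALPHA


@dataclass(frozen=True)
class KruskalDunnResult:
    """Omnibus H test plus pairwise post hoc Dunn results."""

    measure: str
    h_statistic: float
    df: int
    p_raw: float
    dunn: tuple[ComparisonResult, ...]


def mann_whitney_metrics(
    a: Sequence[float],
    b: Sequence[float],
    measure: str = "",
    group_a: str = "a",
    group_b: str = "b",
    family_size: int = 1,
) -> ComparisonResult:
    """Two-tailed Mann-Whitney U on two node-metric vectors.

    Exact enumeration when both samples are small and untied, otherwise the
    tie-corrected normal approximation (scipy's automatic policy).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("each sample needs at least 3 values")
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return ComparisonResult(
        measure=measure,
        group_a=group_a,
        group_b=group_b,
        statistic=float(res.statistic),
        p_raw=float(min(1.0, res.pvalue)),
        family_size=family_size,
    )


def kruskal_dunn(
    scores: pd.DataFrame,
    test: str,
    groups: Sequence[str],
    family_size: Optional[int] = None,
) -> KruskalDunnResult:
    """Kruskal-Wallis H across groups with post hoc pairwise Dunn tests.

    H is tie-corrected with df = G - 1. Dunn's z for a pair uses the pooled
    mid-ranks over all groups with the tie adjustment
    T = sum(t^3 - t) / (12 (N - 1)); p-values are two-sided normal and
    Bonferroni-corrected over all C(G, 2) pairs (or an explicit
    *family_size*).
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    samples = []
    for g in groups:
        vals = group_table(scores, g)[test].dropna().to_numpy(dtype=float)
        if len(vals) < 3:
            raise ValueError(f"group {g!r}: needs >= 3 non-missing scores")
        samples.append(vals)

    pooled = np.concatenate(samples)
    if np.ptp(pooled) == 0:
        h, p = 0.0, 1.0
    else:
        h, p = stats.kruskal(*samples)
    df = len(groups) - 1

    ranks = stats.rankdata(pooled)
    sizes = [len(s) for s in samples]
    bounds = np.cumsum([0] + sizes)
    mean_ranks = [
        ranks[bounds[i] : bounds[i + 1]].mean() for i in range(len(groups))
    ]
    n_total = len(pooled)
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts)) / (12.0 * (n_total - 1))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term

    pairs = list(combinations(range(len(groups)), 2))
    fam = family_size if family_size is not None else len(pairs)
    dunn = []
    for i, j in pairs:
        se = np.sqrt(var_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
        dunn.append(
            ComparisonResult(
                measure=test,
                group_a=groups[i],
                group_b=groups[j],
                statistic=float(z),
                p_raw=float(2.0 * stats.norm.sf(abs(z))),
                family_size=fam,
            )
        )
    return KruskalDunnResult(
        measure=test,
        h_statistic=float(h),
        df=df,
        p_raw=float(p),
        dunn=tuple(dunn),
    )


def chi_square_categorical(
    counts: np.ndarray | Sequence[Sequence[float]],
    measure: str = "",
    family_size: int = 1,
) -> ComparisonResult:
    """Pearson chi-square on a contingency table, no continuity correction."""
    table = np.asarray(counts, dtype=float)
    if table.ndim != 2:
        raise ValueError("contingency table must be 2-dimensional")
    if (table < 0).any():
        raise ValueError("counts must be nonnegative")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("zero marginal in contingency table")
    chi2, p, df, _ = stats.chi2_contingency(table, correction=False)
    return ComparisonResult(
        measure=measure,
        group_a="",
        group_b="",
        statistic=float(chi2),
        p_raw=float(p),
        family_size=family_size,
        df=int(df),
    )


def metric_permutation_test(
    cohort: pd.DataFrame,
    group_a: str,
    group_b: str,
    metric: str,
    build_metrics: Callable[[pd.DataFrame], pd.DataFrame],
    n_perm: int = 200,
    seed: int = 0,
) -> ComparisonResult:
    """Subject-relabelling permutation test on a mean node metric difference.

    Subjects of the two groups are pooled and randomly re-split at the
    observed group sizes; each replicate rebuilds both graphs through
    *build_metrics* (a callable mapping a group's score table to a node
    metric table) and records the difference in the metric's mean across
    nodes. Two-sided p with the add-one correction.
    """
    sub_a = group_table(cohort, group_a)
    sub_b = group_table(cohort, group_b)

    def mean_metric(frame: pd.DataFrame) -> float:
        return float(build_metrics(frame)[metric].mean())

    observed = mean_metric(sub_a) - mean_metric(sub_b)
    pooled = pd.concat([sub_a, sub_b], ignore_index=True)
    n_a = len(sub_a)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(len(pooled))
        pa = pooled.iloc[perm[:n_a]]
        pb = pooled.iloc[perm[n_a:]]
        diff = mean_metric(pa) - mean_metric(pb)
        if abs(diff) >= abs(observed) - 1e-12:
            exceed += 1
    return ComparisonResult(
        measure=metric,
        group_a=group_a,
        group_b=group_b,
        statistic=float(observed),
        p_raw=(1 + exceed) / (n_perm + 1),
    )


def comparisons_frame(results: Sequence[ComparisonResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "measure": [r.measure for r in results],
            "group_a": [r.group_a for r in results],
            "group_b": [r.group_b for r in results],
            "statistic": [r.statistic for r in results],
            "p_raw": [r.p_raw for r in results],
            "p_adjusted": [r.p_adjusted for r in results],
            "family_size": [r.family_size for r in results],
            "significant": [r.significant for r in results],
        }
    )


__all__ = [
    "ComparisonResult",
    "KruskalDunnResult",
    "mann_whitney_metrics",
    "kruskal_dunn",
    "chi_square_categorical",
    "metric_permutation_test",
    "comparisons_frame",
]
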