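"""Group network construction from partial Spearman correlations.

For every unordered pair of tests within a group, the association is the
partial Spearman correlation controlling for age and education: both score
vectors and the covariates are rank-transformed (average ranks on ties), each
rank vector is residualized on the ranked covariates by ordinary least
squares, and the Pearson correlation of the two residual vectors is the
statistic. The analytic two-tailed p comes from the t approximation on
n - 2 - k degrees of freedom (k covariates).

Edges whose analytic p falls strictly inside a validation band (by default
0.01 < p < 0.1, the region where a threshold decision is fragile) are
re-tested by permutation: one residual vector is shuffled (a Freedman-Lane
style scheme on ranks, preserving the covariate structure of the unpermuted
variable) and the two-sided permutation p uses the add-one correction
(1 + #exceedances) / (n_perm + 1), so the smallest attainable p is explicit
and never zero.

Thresholding is an absolute significance cut: an edge exists iff p < alpha
(strict). Negative coefficients are removed by default — graph-theory metrics
are validated on positively connected networks — with a retention flag for
sensitivity analysis; retained negatives enter the binary graph as ordinary
unsigned edges.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from cognet.graph import CognitiveGraph
from cognet.table import test_columns

logger = logging.getLogger(__name__)

DEFAULT_COVARIATES = ("age", "education")
DEFAULT_VALIDATE_BAND = (0.01, 0.1)


@dataclass(frozen=True)
class EdgeStats:
    """Partial-correlation statistics for one unordered test pair."""

    test_a: str
    test_b: str
    rho: float
    p_analytic: float
    n_used: int
    covariates_used: tuple[str, ...]
    p_permutation: Optional[float] = None


# --------------------------------------------------------------------------
# the pairwise statistic


def _rank_residuals(
    x: np.ndarray, y: np.ndarray, covariates: Optional[np.ndarray]
) -> tuple[np.ndarray, np.ndarray, int]:
    """Rank x, y and the covariates; residualize the ranks by OLS.

    Returns (x residuals, y residuals, k) on complete cases; raises on
    constant variables or insufficient n.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if covariates is None:
        cov = np.empty((len(x), 0))
    else:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
    if not (len(x) == len(y) == len(cov)):
        raise ValueError("x, y and covariates must have equal length")

    keep = np.isfinite(x) & np.isfinite(y) & np.isfinite(cov).all(axis=1)
    x, y, cov = x[keep], y[keep], cov[keep]
    n, k = len(x), cov.shape[1]
    if n < k + 3:
        raise ValueError(f"insufficient complete cases: n={n}, need >= {k + 3}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant variable on complete cases")

    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    design = np.column_stack(
        [np.ones(n)] + [stats.rankdata(cov[:, j]) for j in range(k)]
    )
    coef_x, *_ = np.linalg.lstsq(design, rx, rcond=None)
    coef_y, *_ = np.linalg.lstsq(design, ry, rcond=None)
    return rx - design @ coef_x, ry - design @ coef_y, k


def partial_spearman(
    x: Sequence[float],
    y: Sequence[float],
    covariates: Optional[np.ndarray] = None,
) -> tuple[float, float]:
    """Partial Spearman rho of x and y given covariates, with analytic p.

    Incomplete cases (NaN in x, y, or any covariate) are dropped pairwise.
    Returns ``(rho, p)`` with p two-tailed from the t approximation on
    n - 2 - k degrees of freedom.
    """
    ex, ey, k = _rank_residuals(x, y, covariates)
    n = len(ex)
    denom = np.linalg.norm(ex) * np.linalg.norm(ey)
    if denom == 0:
        # ranks perfectly explained by covariates: no residual association
        return 0.0, 1.0
    rho = float(np.clip(ex @ ey / denom, -1.0, 1.0))
    df = n - 2 - k
    if abs(rho) >= 1.0:
        return rho, 0.0
    t = rho * np.sqrt(df / (1.0 - rho * rho))
    p = float(2.0 * stats.t.sf(abs(t), df))
    return rho, p


def permutation_p(
    x: Sequence[float],
    y: Sequence[float],
    covariates: Optional[np.ndarray] = None,
    n_perm: int = 5000,
    seed: int | np.random.SeedSequence = 0,
) -> float:
    """Two-sided permutation p for the partial Spearman statistic.

    The y rank residuals are permuted ``n_perm`` times (seeded, so the result
    is reproducible); p = (1 + #{|rho_perm| >= |rho_obs|}) / (n_perm + 1).
    """
    if n_perm < 100:
        raise ValueError(f"n_perm={n_perm} is uninformative; use >= 100")
    ex, ey, _ = _rank_residuals(x, y, covariates)
    nx_, ny_ = np.linalg.norm(ex), np.linalg.norm(ey)
    if nx_ == 0 or ny_ == 0:
        return 1.0
    rho_obs = abs(float(ex @ ey / (nx_ * ny_)))

    rng = np.random.default_rng(seed)
    perms = rng.permuted(np.tile(ey, (n_perm, 1)), axis=1)
    rho_perm = np.abs(perms @ ex) / (nx_ * ny_)
    exceed = int(np.sum(rho_perm >= rho_obs - 1e-12))
    return (1 + exceed) / (n_perm + 1)


# --------------------------------------------------------------------------
# all pairs of a group


def build_edge_stats(
    group_scores: pd.DataFrame,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    validate_band: Optional[tuple[float, float]] = DEFAULT_VALIDATE_BAND,
    n_perm: int = 5000,
    seed: int = 0,
) -> list[EdgeStats]:
    """Partial Spearman statistics for every unordered test pair of a group.

    Tests with no non-missing data are dropped from the node set entirely
    (e.g. a protocol that lacks both Prose Memory measures yields 14 nodes
    and C(14,2) = 91 pairs). Pairs that cannot be computed (constant scores,
    too few complete cases) are skipped with a logged reason. Permutation
    validation runs only for pairs whose analytic p lies strictly inside
    *validate_band*; each pair draws its permutations from an independent
    stream spawned from *seed*, so results do not depend on pair order.
    """
    tests = [c for c in test_columns(group_scores) if group_scores[c].notna().any()]
    if len(tests) < 2:
        raise ValueError("need at least two tests with data")
    missing_cov = [c for c in covariates if c not in group_scores.columns]
    if missing_cov:
        raise KeyError(f"covariate columns absent: {missing_cov}")
    cov = group_scores[list(covariates)].to_numpy(dtype=float)

    pairs = [
        (tests[i], tests[j])
        for i in range(len(tests))
        for j in range(i + 1, len(tests))
    ]
    streams = np.random.SeedSequence(seed).spawn(len(pairs))

    out: list[EdgeStats] = []
    for (a, b), stream in zip(pairs, streams):
        x = group_scores[a].to_numpy(dtype=float)
        y = group_scores[b].to_numpy(dtype=float)
        keep = (
            np.isfinite(x) & np.isfinite(y) & np.isfinite(cov).all(axis=1)
        )
        try:
            rho, p = partial_spearman(x, y, cov)
        except ValueError as err:
            logger.warning("skipping pair (%s, %s): %s", a, b, err)
            continue
        p_perm = None
        if (
            validate_band is not None
            and validate_band[0] < p < validate_band[1]
        ):
            p_perm = permutation_p(x, y, cov, n_perm=n_perm, seed=stream)
        out.append(
            EdgeStats(
                test_a=a,
                test_b=b,
                rho=rho,
                p_analytic=p,
                n_used=int(keep.sum()),
                covariates_used=tuple(covariates),
                p_permutation=p_perm,
            )
        )
    return out


def threshold_to_graph(
    edges: Sequence[EdgeStats],
    alpha: float = 0.05,
    drop_negative: bool = True,
    use_permutation_in_band: bool = False,
    nodes: Optional[Sequence[str]] = None,
    group: str = "",
) -> CognitiveGraph:
    """Binary adjacency from edge statistics via the absolute p < alpha cut.

    An edge is present iff its p-value is strictly below *alpha* and its
    coefficient is positive (unless ``drop_negative=False``, the sensitivity
    analysis that keeps negative correlations as unsigned edges). When
    ``use_permutation_in_band`` is set, a pair that carries a permutation p
    is decided on that p instead of the analytic one.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if nodes is None:
        seen: dict[str, None] = {}
        for e in edges:
            seen.setdefault(e.test_a)
            seen.setdefault(e.test_b)
        nodes = list(seen)
    idx = {n: i for i, n in enumerate(nodes)}
    adj = np.zeros((len(nodes), len(nodes)), dtype=np.int8)
    for e in edges:
        p = e.p_analytic
        if use_permutation_in_band and e.p_permutation is not None:
            p = e.p_permutation
        if p < alpha and (e.rho > 0 or not drop_negative):
            i, j = idx[e.test_a], idx[e.test_b]
            adj[i, j] = adj[j, i] = 1
    return CognitiveGraph(
        nodes=tuple(nodes),
        adjacency=adj,
        provenance={
            "group": group,
            "alpha": alpha,
            "drop_negative": drop_negative,
            "use_permutation_in_band": use_permutation_in_band,
        },
    )


def changed_edges(
    a: CognitiveGraph, b: CognitiveGraph
) -> set[tuple[str, str]]:
    """Edges present in exactly one of two graphs (symmetric difference).

    The covariate-sensitivity hook: build the same group's graph with and
    without education among the regressors and report which edges move.
    """
    return set(a.edges()) ^ set(b.edges())


# --------------------------------------------------------------------------
# I/O


def edge_stats_to_frame(edges: Sequence[EdgeStats]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "test_a": [e.test_a for e in edges],
            "test_b": [e.test_b for e in edges],
            "rho": [e.rho for e in edges],
            "p_analytic": [e.p_analytic for e in edges],
            "p_permutation": [e.p_permutation for e in edges],
            "n_used": [e.n_used for e in edges],
            "covariates_used": [";".join(e.covariates_used) for e in edges],
        }
    )


def write_edge_stats(edges: Sequence[EdgeStats], path: str | Path) -> None:
    edge_stats_to_frame(edges).to_csv(path, index=False)
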