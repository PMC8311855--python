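"""Cognitive-domain profiles and intra- vs inter-domain consistency.

Node metrics are averaged over the tests assigned to each of the four
cognitive domains (memory, semantic processing, abstract reasoning,
executive functioning) to give a per-domain profile. A test may belong to
more than one domain and is counted in each.

Domain consistency asks whether tests within a domain co-vary more strongly
than tests across domains: over the whole cohort, every relevant pairwise
partial Spearman correlation (controlling age, education and MMSE) is mapped
through the Fisher z transform (atanh, variance-stabilizing), and the mean z
over within-domain pairs is compared with the mean z over member-vs-nonmember
pairs. Both the z-scale means and their back-transforms (tanh of the mean z)
are reported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from cognet.battery import DOMAINS, TestBattery
from cognet.netbuild import partial_spearman
from cognet.table import test_columns

CONSISTENCY_COVARIATES = ("age", "education", "mmse")


@dataclass(frozen=True)
class DomainProfile:
    """Mean node metrics over one domain's member tests present in a graph.

    ``present`` is False (and ``means`` None) when no member test appears in
    the metric table — an absent domain is never reported as zero.
    """

    domain: str
    member_tests: tuple[str, ...]
    means: Optional[dict[str, float]]

    @property
    def present(self) -> bool:
        return self.means is not None


@dataclass(frozen=True)
class ConsistencyResult:
    """Intra- vs inter-domain mean Fisher-z correlation for one domain."""

    domain: str
    intra_mean_z: float
    inter_mean_z: float
    intra_mean_rho: float  # tanh of the mean z
    inter_mean_rho: float
    n_intra_pairs: int
    n_inter_pairs: int


def domain_means(
    metrics: pd.DataFrame, battery: TestBattery
) -> list[DomainProfile]:
    """Average each metric column over every domain's member nodes.

    Members absent from the metric table (e.g. tests missing from a group's
    protocol) are simply excluded from the mean.
    """
    numeric = [
        c for c in metrics.columns if c not in ("community", "hub")
    ]
    out = []
    for domain in DOMAINS:
        members = [
            t for t in battery.domain_members(domain) if t in metrics.index
        ]
        if not members:
            out.append(DomainProfile(domain, (), None))
            continue
        sub = metrics.loc[members, numeric]
        out.append(
            DomainProfile(
                domain,
                tuple(members),
                {c: float(sub[c].mean()) for c in numeric},
            )
        )
    return out


def domain_profiles_frame(profiles: Sequence[DomainProfile]) -> pd.DataFrame:
    rows = []
    for p in profiles:
        row: dict[str, object] = {
            "domain": p.domain,
            "n_members": len(p.member_tests),
            "members": ";".join(p.member_tests),
        }
        if p.means:
            row.update(p.means)
        rows.append(row)
    return pd.DataFrame(rows)


def domain_consistency(
    cohort: pd.DataFrame,
    battery: TestBattery,
    covariates: Sequence[str] = CONSISTENCY_COVARIATES,
) -> list[ConsistencyResult]:
    """Whole-cohort intra- vs inter-domain correlation consistency.

    For domain d with m member tests among T available tests, the intra mean
    averages the Fisher z of the C(m, 2) within-domain partial correlations
    and the inter mean averages the m*(T-m) member-vs-nonmember ones (pairs
    lost to missingness are excluded and the reported counts reflect that).
    A perfect correlation (|rho| = 1) has infinite z and raises, naming the
    pair.
    """
    missing_cov = [c for c in covariates if c not in cohort.columns]
    if missing_cov:
        raise KeyError(f"covariate columns absent: {missing_cov}")
    tests = [
        c
        for c in test_columns(cohort)
        if c in set(battery.names) and cohort[c].notna().any()
    ]
    cov = cohort[list(covariates)].to_numpy(dtype=float)

    z: dict[frozenset[str], float] = {}
    for i, a in enumerate(tests):
        for b in tests[i + 1 :]:
            try:
                rho, _ = partial_spearman(
                    cohort[a].to_numpy(float), cohort[b].to_numpy(float), cov
                )
            except ValueError:
                continue  # pair lost to missingness
            if abs(rho) >= 1.0 - 1e-12:
                raise ValueError(
                    f"pair ({a}, {b}): |rho| = 1 has infinite Fisher z"
                )
            z[frozenset((a, b))] = math.atanh(rho)

    out = []
    available = set(tests)
    for domain in DOMAINS:
        members = [t for t in battery.domain_members(domain) if t in available]
        nonmembers = [t for t in tests if t not in members]
        intra = [
            z[frozenset((a, b))]
            for i, a in enumerate(members)
            for b in members[i + 1 :]
            if frozenset((a, b)) in z
        ]
        inter = [
            z[frozenset((a, b))]
            for a in members
            for b in nonmembers
            if frozenset((a, b)) in z
        ]
        intra_z = float(np.mean(intra)) if intra else float("nan")
        inter_z = float(np.mean(inter)) if inter else float("nan")
        out.append(
            ConsistencyResult(
                domain=domain,
                intra_mean_z=intra_z,
                inter_mean_z=inter_z,
                intra_mean_rho=float(np.tanh(intra_z)),
                inter_mean_rho=float(np.tanh(inter_z)),
                n_intra_pairs=len(intra),
                n_inter_pairs=len(inter),
            )
        )
    return out


def consistency_frame(results: Sequence[ConsistencyResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "domain": [r.domain for r in results],
            "intra_mean_z": [r.intra_mean_z for r in results],
            "inter_mean_z": [r.inter_mean_z for r in results],
            "intra_mean_rho": [r.intra_mean_rho for r in results],
            "inter_mean_rho": [r.inter_mean_rho for r in results],
            "n_intra_pairs": [r.n_intra_pairs for r in results],
            "n_inter_pairs": [r.n_inter_pairs for r in results],
        }
    )
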