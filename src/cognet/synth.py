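"""Synthetic multi-group cognitive cohorts with planted correlation structure.

Scores are generated Gaussian-copula style: multivariate normal latents carry
the target correlation structure, covariate (age, education) effects are added
linearly, and an optional monotone transform skews the marginals without
touching ranks — so the *Spearman* correlation structure survives exactly.

The within/between-domain correlation targets are specified on the Spearman
scale. Because bivariate-normal latents attenuate rank correlation
(rho_S = (6/pi)·arcsin(r/2) for Pearson r), targets are de-attenuated with
the inverse map r = 2·sin(pi·rho_S/6) before the latents are drawn, so the
planted Spearman block means match the requested values.

The ``r_between`` knob is the dedifferentiation level: raising it makes
performances across unrelated domains co-vary, which is the construct the
downstream network density / clustering / efficiency metrics pick up.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd
import yaml

from cognet.battery import PROSE_MEMORY_TESTS, TestBattery, canonical_battery
from cognet.table import META_COLUMNS

PSD_TOL = 1e-10

#: monotone marginal transforms, all strictly increasing (rank-preserving)
_TRANSFORMS = {
    "none": lambda x: x,
    "monotone-skew": lambda x: np.expm1(0.5 * x),  # right-skews the marginal
}


@dataclass(frozen=True)
class GroupSpec:
    """One cohort group and its planted structure.

    Parameters
    ----------
    name
        Unique group label.
    n
        Subject count, at least 10.
    r_within, r_between
        Target Spearman correlation for test pairs sharing a primary domain
        and for all other pairs. ``r_between`` is the group's
        dedifferentiation level; ``0 <= r_between <= r_within < 1``.
    covariate_effects
        Per-test ``(beta_age, beta_edu)`` slopes added to the latent
        performance score, in performance-SD units per year. Tests not
        listed get ``(0, 0)``.
    age_range, education_range, mmse_range
        Inclusive integer sampling bounds (years / points).
    missing_tests
        Tests absent from this group's protocol; emitted as missing columns.
    marginal_transform
        ``"none"`` or ``"monotone-skew"``.
    """

    name: str
    n: int
    r_within: float = 0.0
    r_between: float = 0.0
    covariate_effects: Mapping[str, tuple[float, float]] = field(
        default_factory=dict
    )
    age_range: tuple[int, int] = (18, 80)
    education_range: tuple[int, int] = (8, 18)
    mmse_range: tuple[int, int] = (26, 30)
    missing_tests: frozenset[str] = frozenset()
    marginal_transform: str = "none"

    def __post_init__(self) -> None:
        if self.n < 10:
            raise ValueError(f"group {self.name!r}: n must be >= 10, got {self.n}")
        if not (0.0 <= self.r_between <= self.r_within < 1.0):
            raise ValueError(
                f"group {self.name!r}: need 0 <= r_between <= r_within < 1, "
                f"got r_within={self.r_within}, r_between={self.r_between}"
            )
        if self.marginal_transform not in _TRANSFORMS:
            raise ValueError(
                f"unknown marginal_transform {self.marginal_transform!r}"
            )
        for rng_ in (self.age_range, self.education_range, self.mmse_range):
            if rng_[0] > rng_[1]:
                raise ValueError(f"invalid sampling range {rng_}")


@dataclass(frozen=True)
class SyntheticConfig:
    """Full cohort recipe: groups, battery, master seed."""

    groups: tuple[GroupSpec, ...]
    seed: int
    battery: TestBattery = field(default_factory=canonical_battery)

    def __post_init__(self) -> None:
        names = [g.name for g in self.groups]
        if len(names) != len(set(names)):
            raise ValueError("group names must be unique")
        if not self.groups:
            raise ValueError("at least one group required")
        for g in self.groups:
            unknown = set(g.missing_tests) - set(self.battery.names)
            if unknown:
                raise ValueError(
                    f"group {g.name!r}: missing_tests not in battery: "
                    f"{sorted(unknown)}"
                )
            unknown = set(g.covariate_effects) - set(self.battery.names)
            if unknown:
                raise ValueError(
                    f"group {g.name!r}: covariate_effects for unknown tests: "
                    f"{sorted(unknown)}"
                )

    # ------------------------------------------------------------------ I/O

    def to_yaml(self, path: str | Path) -> None:
        doc = {
            "seed": self.seed,
            "groups": [
                {
                    "name": g.name,
                    "n": g.n,
                    "r_within": g.r_within,
                    "r_between": g.r_between,
                    "covariate_effects": {
                        t: list(map(float, v))
                        for t, v in g.covariate_effects.items()
                    },
                    "age_range": list(g.age_range),
                    "education_range": list(g.education_range),
                    "mmse_range": list(g.mmse_range),
                    "missing_tests": sorted(g.missing_tests),
                    "marginal_transform": g.marginal_transform,
                }
                for g in self.groups
            ],
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(
        cls, path: str | Path, battery: Optional[TestBattery] = None
    ) -> "SyntheticConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        groups = tuple(
            GroupSpec(
                name=g["name"],
                n=int(g["n"]),
                r_within=float(g.get("r_within", 0.0)),
                r_between=float(g.get("r_between", 0.0)),
                covariate_effects={
                    t: (float(v[0]), float(v[1]))
                    for t, v in g.get("covariate_effects", {}).items()
                },
                age_range=tuple(g.get("age_range", (18, 80))),
                education_range=tuple(g.get("education_range", (8, 18))),
                mmse_range=tuple(g.get("mmse_range", (26, 30))),
                missing_tests=frozenset(g.get("missing_tests", ())),
                marginal_transform=g.get("marginal_transform", "none"),
            )
            for g in doc["groups"]
        )
        return cls(
            groups=groups,
            seed=int(doc["seed"]),
            battery=battery or canonical_battery(),
        )


# --------------------------------------------------------------------------
# target correlation structure


def spearman_to_pearson_normal(rho_s: np.ndarray) -> np.ndarray:
    """De-attenuate a Spearman target to the Pearson scale for normal latents."""
    return 2.0 * np.sin(np.pi * np.asarray(rho_s, dtype=float) / 6.0)


def build_target_correlation(
    battery: TestBattery, r_within: float, r_between: float
) -> np.ndarray:
    """Block-structured Spearman correlation target over the battery's tests.

    Entry (i, j) is ``r_within`` when the two tests share a primary domain and
    ``r_between`` otherwise; the diagonal is 1. Tests without a primary domain
    never share a block. The result is verified positive semi-definite.
    """
    if len(battery) == 0:
        raise ValueError("battery must be nonempty")
    if not (0.0 <= r_between <= r_within < 1.0):
        raise ValueError(
            f"need 0 <= r_between <= r_within < 1, got "
            f"r_within={r_within}, r_between={r_between}"
        )
    blocks = [t.primary_domain for t in battery]
    n = len(battery)
    mat = np.full((n, n), r_between, dtype=float)
    for i in range(n):
        for j in range(n):
            if i != j and blocks[i] is not None and blocks[i] == blocks[j]:
                mat[i, j] = r_within
    np.fill_diagonal(mat, 1.0)
    _check_psd(mat, "target Spearman correlation")
    return mat


def _check_psd(mat: np.ndarray, what: str) -> None:
    lam = float(np.linalg.eigvalsh(mat)[0])
    if lam < -PSD_TOL:
        raise ValueError(
            f"{what} matrix is not positive semi-definite "
            f"(smallest eigenvalue {lam:.3e})"
        )


# --------------------------------------------------------------------------
# cohort generation


def _sample_group(
    group: GroupSpec, battery: TestBattery, rng: np.random.Generator
) -> pd.DataFrame:
    tests = battery.names
    n, t = group.n, len(tests)

    age = rng.integers(group.age_range[0], group.age_range[1] + 1, size=n)
    edu = rng.integers(
        group.education_range[0], group.education_range[1] + 1, size=n
    )
    mmse = rng.integers(group.mmse_range[0], group.mmse_range[1] + 1, size=n)

    target_s = build_target_correlation(battery, group.r_within, group.r_between)
    target_p = spearman_to_pearson_normal(target_s)
    np.fill_diagonal(target_p, 1.0)
    _check_psd(target_p, "de-attenuated Pearson latent")
    # small jitter on the diagonal guards Cholesky at the PSD boundary
    chol = np.linalg.cholesky(target_p + PSD_TOL * np.eye(t))
    latent = rng.standard_normal((n, t)) @ chol.T

    transform = _TRANSFORMS[group.marginal_transform]
    scores = np.empty((n, t), dtype=float)
    for j, name in enumerate(tests):
        beta_age, beta_edu = group.covariate_effects.get(name, (0.0, 0.0))
        performance = latent[:, j] + beta_age * age + beta_edu * edu
        raw = performance if battery[name].higher_is_better else -performance
        scores[:, j] = transform(raw)

    frame = pd.DataFrame(
        {
            "subject_id": [f"{group.name}_{i + 1:03d}" for i in range(n)],
            "group": group.name,
            "age": age,
            "education": edu,
            "mmse": mmse,
        }
    )
    for j, name in enumerate(tests):
        frame[name] = np.nan if name in group.missing_tests else scores[:, j]
    return frame


def generate_cohort(config: SyntheticConfig) -> pd.DataFrame:
    """Draw the full cohort table: all groups, deterministic under the seed.

    Each group gets an independent random stream spawned from the master
    seed, so adding or reordering groups never perturbs the draws of the
    others.
    """
    streams = np.random.SeedSequence(config.seed).spawn(len(config.groups))
    parts = [
        _sample_group(g, config.battery, np.random.default_rng(s))
        for g, s in zip(config.groups, streams)
    ]
    table = pd.concat(parts, ignore_index=True)
    return table[list(META_COLUMNS) + list(config.battery.names)]


# --------------------------------------------------------------------------
# study-shaped default cohort


def default_config(seed: int) -> SyntheticConfig:
    """Six-group cohort shaped like the study population.

    Three healthy age strata and three patient groups, with group sizes
    matching the study (75/75/70 controls, 75/60/60 patients), the youngest
    group lacking both Prose Memory measures, and a dedifferentiation
    gradient: between-domain correlation rises with age stratum and further
    with impairment, while within-domain coherence stays moderate. Covariate
    slopes are mild (performance drops ~0.01 SD per year of age, rises 0.05
    SD per year of education); marginals are right-skewed to emulate the
    non-normal score distributions typical of clinical batteries.
    """
    battery = canonical_battery()
    slopes = {t.name: (-0.01, 0.05) for t in battery}

    def g(name, n, r_b, ages, mmse, r_w=0.5, edu=(10, 18), missing=()):
        return GroupSpec(
            name=name,
            n=n,
            r_within=r_w,
            r_between=r_b,
            covariate_effects=slopes,
            age_range=ages,
            education_range=edu,
            mmse_range=mmse,
            missing_tests=frozenset(missing),
            marginal_transform="monotone-skew",
        )

    return SyntheticConfig(
        groups=(
            g("young", 75, 0.05, (18, 39), (27, 30),
              missing=PROSE_MEMORY_TESTS),
            g("middle", 75, 0.15, (40, 64), (27, 30)),
            g("older", 70, 0.30, (65, 85), (26, 30)),
            g("amci", 75, 0.40, (65, 88), (23, 27), r_w=0.55, edu=(8, 16)),
            g("namci", 60, 0.35, (62, 85), (24, 28), edu=(8, 16)),
            g("dementia", 60, 0.45, (65, 90), (17, 24), r_w=0.6, edu=(8, 16)),
        ),
        seed=seed,
        battery=battery,
    )
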