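"""Test-battery metadata: score orientation and cognitive-domain membership.

A battery lists the cognitive tests scored in a cohort. Each test carries an
orientation flag (is a higher raw score better performance?) and the set of
cognitive domains it is assigned to on a theoretical basis. Domain sets may
overlap: a test can load on more than one domain and is then counted in each.
A separate ``primary_domain`` drives the block structure of the synthetic
generator, where each test must belong to at most one correlation block.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

DOMAINS = ("memory", "semantic", "abstract", "executive")


@dataclass(frozen=True)
class TestSpec:
    """One cognitive test: name, orientation, domain memberships."""

    name: str
    higher_is_better: bool = True
    domains: frozenset[str] = field(default_factory=frozenset)
    #: block assignment used by the synthetic generator; None = no block
    primary_domain: Optional[str] = None

    def __post_init__(self) -> None:
        bad = self.domains - set(DOMAINS)
        if bad:
            raise ValueError(f"unknown domains {sorted(bad)} for test {self.name!r}")
        if self.primary_domain is not None and self.primary_domain not in DOMAINS:
            raise ValueError(
                f"unknown primary domain {self.primary_domain!r} for test {self.name!r}"
            )


@dataclass(frozen=True)
class TestBattery:
    """Ordered collection of :class:`TestSpec` with unique names."""

    tests: tuple[TestSpec, ...]

    def __post_init__(self) -> None:
        names = [t.name for t in self.tests]
        if len(names) != len(set(names)):
            raise ValueError("test names must be unique")

    def __len__(self) -> int:
        return len(self.tests)

    def __iter__(self):
        return iter(self.tests)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(t.name for t in self.tests)

    def __getitem__(self, name: str) -> TestSpec:
        for t in self.tests:
            if t.name == name:
                return t
        raise KeyError(name)

    def domain_members(self, domain: str) -> tuple[str, ...]:
        """Names of tests assigned to *domain*, in battery order."""
        if domain not in DOMAINS:
            raise ValueError(f"unknown domain {domain!r}")
        return tuple(t.name for t in self.tests if domain in t.domains)

    def subset(self, names: Iterable[str]) -> "TestBattery":
        keep = set(names)
        missing = keep - set(self.names)
        if missing:
            raise KeyError(f"tests not in battery: {sorted(missing)}")
        return TestBattery(tuple(t for t in self.tests if t.name in keep))

    # ------------------------------------------------------------------ I/O

    def to_csv(self, path: str | Path) -> None:
        """Write the battery as a delimited file (one row per test)."""
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["name", "higher_is_better", "domains", "primary_domain"])
            for t in self.tests:
                w.writerow(
                    [
                        t.name,
                        int(t.higher_is_better),
                        ";".join(sorted(t.domains)),
                        t.primary_domain or "",
                    ]
                )

    @classmethod
    def from_csv(cls, path: str | Path) -> "TestBattery":
        tests = []
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                tests.append(
                    TestSpec(
                        name=row["name"],
                        higher_is_better=bool(int(row["higher_is_better"])),
                        domains=frozenset(
                            d for d in row["domains"].split(";") if d
                        ),
                        primary_domain=row["primary_domain"] or None,
                    )
                )
        return cls(tuple(tests))


def canonical_battery() -> TestBattery:
    """The 16-test battery with its standard domain assignments.

    Memory: Rey-Osterrieth figure recall, both Prose Memory measures and
    Verbal Paired Associates. Semantic processing: Similarities, Category
    Fluency, Confrontation Naming. Abstract reasoning: Similarities, Category
    Fluency, Raven's Progressive Matrices. Executive: both Stroop
    interference measures, Letter Fluency, Digit Span backward. The Stroop
    time and error measures are the only reverse-oriented scores (more time /
    more errors = worse performance).

    Similarities and Category Fluency belong to both the semantic and
    abstract domains; that overlap is intentional and never deduplicated.
    """

    def t(name, domains=(), primary=None, higher=True):
        return TestSpec(
            name=name,
            higher_is_better=higher,
            domains=frozenset(domains),
            primary_domain=primary,
        )

    return TestBattery(
        (
            t("rocf_recall", ["memory"], "memory"),
            t("prose_memory_immediate", ["memory"], "memory"),
            t("prose_memory_delayed", ["memory"], "memory"),
            t("paired_associates", ["memory"], "memory"),
            t("raven_matrices", ["abstract"], "abstract"),
            t("similarities", ["semantic", "abstract"], "semantic"),
            t("category_fluency", ["semantic", "abstract"], "semantic"),
            t("naming", ["semantic"], "semantic"),
            t("letter_fluency", ["executive"], "executive"),
            t("stroop_time", ["executive"], "executive", higher=False),
            t("stroop_errors", ["executive"], "executive", higher=False),
            t("digit_span_backward", ["executive"], "executive"),
            t("digit_span_forward"),
            t("digit_cancellation"),
            t("rocf_copy"),
            t("token_test"),
        )
    )


#: Both Prose Memory measures — absent from the youngest group's protocol.
PROSE_MEMORY_TESTS = ("prose_memory_immediate", "prose_memory_delayed")


def block_battery(tests_per_domain: int = 4) -> TestBattery:
    """Synthetic battery with the four domains as disjoint equal-size blocks.

    Unlike the canonical battery (overlapping domains, untagged tests), every
    test here belongs to exactly one domain, so the generator plants four
    clean correlation blocks — the setting for community-recovery studies.
    """
    tests = []
    for d in DOMAINS:
        for i in range(tests_per_domain):
            tests.append(
                TestSpec(
                    name=f"{d}_{i}",
                    higher_is_better=True,
                    domains=frozenset({d}),
                    primary_domain=d,
                )
            )
    return TestBattery(tuple(tests))
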