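"""Norm-referenced z-scoring with orientation harmonization.

Raw scores become z-scores against a reference sample's mean and SD, then
every reverse-oriented score (time, errors) is multiplied by -1 so that
higher always means better performance. Three referencing schemes are used in
different parts of the analysis, exposed here as a single ``norm_source``
choice:

* ``overall``      — the pooled healthy sample (between-group score tables);
* ``own-group``    — each healthy group against itself (network formation);
* ``matched:<G>``  — a patient group against its matched control group
  (patient network formation).

Missing values propagate as missing; nothing is imputed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from cognet.battery import TestBattery
from cognet.table import META_COLUMNS, test_columns


@dataclass(frozen=True)
class NormReference:
    """Per-test reference mean and SD, with the provenance of the sample."""

    means: Mapping[str, float]
    sds: Mapping[str, float]
    provenance: str

    def __post_init__(self) -> None:
        for t, sd in self.sds.items():
            if not sd > 0:
                raise ValueError(f"non-positive SD for test {t!r}")
        if set(self.means) != set(self.sds):
            raise ValueError("means and sds must cover the same tests")

    @property
    def tests(self) -> frozenset[str]:
        return frozenset(self.means)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "test": list(self.means),
                "mean": [self.means[t] for t in self.means],
                "sd": [self.sds[t] for t in self.means],
                "provenance": self.provenance,
            }
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "NormReference":
        frame = pd.read_csv(path)
        prov = str(frame["provenance"].iloc[0]) if len(frame) else "unknown"
        return cls(
            means=dict(zip(frame["test"], frame["mean"].astype(float))),
            sds=dict(zip(frame["test"], frame["sd"].astype(float))),
            provenance=prov,
        )


def compute_norms(
    reference: pd.DataFrame,
    battery: TestBattery | None = None,
    provenance: str = "reference sample",
) -> NormReference:
    """Per-test mean and sample SD (n-1 denominator) over non-missing entries.

    Tests present in *reference* but absent from every subject, or with zero
    variance, raise — a norm with SD 0 would be meaningless.
    """
    tests = list(battery.names) if battery is not None else test_columns(reference)
    means, sds = {}, {}
    for t in tests:
        if t not in reference.columns:
            raise KeyError(f"test {t!r} not in reference table")
        vals = reference[t].dropna().to_numpy(dtype=float)
        if len(vals) < 2:
            raise ValueError(f"test {t!r}: need >= 2 non-missing reference values")
        sd = float(np.std(vals, ddof=1))
        if sd == 0.0:
            raise ValueError(f"test {t!r}: zero variance in reference sample")
        means[t] = float(np.mean(vals))
        sds[t] = sd
    return NormReference(means=means, sds=sds, provenance=provenance)


def apply_orientation(
    table: pd.DataFrame, battery: TestBattery
) -> pd.DataFrame:
    """Multiply reverse-oriented test columns by -1 (an involution)."""
    out = table.copy()
    for t in battery:
        if t.name in out.columns and not t.higher_is_better:
            out[t.name] = -out[t.name]
    return out


def zscore(
    table: pd.DataFrame,
    norms: NormReference,
    battery: TestBattery,
    orient: bool = True,
) -> pd.DataFrame:
    """Standardize test columns against *norms*; optionally orient signs.

    z = (raw - reference mean) / reference SD per test; missing stays
    missing. With ``orient=True`` (default) reverse-scored tests are then
    flipped so higher z always means better performance.
    """
    present = [c for c in test_columns(table) if c in set(battery.names)]
    absent = [t for t in present if t not in norms.tests]
    if absent:
        raise KeyError(f"tests without norms: {absent}")
    out = table.copy()
    for t in present:
        out[t] = (out[t] - norms.means[t]) / norms.sds[t]
    if orient:
        out = apply_orientation(out, battery)
    return out


def standardize_groups(
    table: pd.DataFrame,
    battery: TestBattery,
    norm_source: str = "own-group",
    healthy_groups: tuple[str, ...] = (),
    matched_controls: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Standardize every group of a cohort table under one referencing scheme.

    ``norm_source``:
      * ``"overall"``   — all groups normed against the pooled rows of
        *healthy_groups* (the overall healthy reference sample);
      * ``"own-group"`` — each group normed against itself; patient groups
        listed in *matched_controls* are normed against their matched control
        group instead (the network-formation scheme);
      * ``"matched:G"`` — every group normed against group ``G``.
    """
    matched_controls = dict(matched_controls or {})
    parts = []
    for name, sub in table.groupby("group", sort=False):
        sub = sub.copy()
        present = [
            c for c in test_columns(sub)
            if c in set(battery.names) and sub[c].notna().any()
        ]
        bat = battery.subset(present)
        if norm_source == "overall":
            if not healthy_groups:
                raise ValueError("norm_source 'overall' needs healthy_groups")
            ref = table[table["group"].isin(healthy_groups)]
            prov = "overall healthy sample"
        elif norm_source == "own-group":
            ref_group = matched_controls.get(name, name)
            ref = table[table["group"] == ref_group]
            prov = f"group {ref_group}"
        elif norm_source.startswith("matched:"):
            ref_group = norm_source.split(":", 1)[1]
            ref = table[table["group"] == ref_group]
            prov = f"group {ref_group}"
        else:
            raise ValueError(f"unknown norm_source {norm_source!r}")
        norms = compute_norms(ref, bat, provenance=prov)
        parts.append(zscore(sub, norms, bat))
    out = pd.concat(parts, ignore_index=True)
    return out[list(table.columns)]
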