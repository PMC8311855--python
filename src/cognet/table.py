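"""The subject-by-test score table and its delimited-text format.

Every stage of the pipeline consumes and produces the same tabular carrier: a
pandas DataFrame with one row per subject, the metadata columns
``subject_id, group, age, education, mmse`` first, then one column per
cognitive test. Missing scores are NaN in memory and empty fields on disk —
never zero, never imputed.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

#: reserved metadata columns, in canonical order
META_COLUMNS = ("subject_id", "group", "age", "education", "mmse")


def test_columns(table: pd.DataFrame) -> list[str]:
    """Columns of *table* that hold test scores (everything non-metadata)."""
    return [c for c in table.columns if c not in META_COLUMNS]


def validate_score_table(table: pd.DataFrame) -> None:
    missing = [c for c in META_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"score table lacks metadata columns: {missing}")
    if table["subject_id"].duplicated().any():
        raise ValueError("duplicate subject ids")


def read_score_table(path: str | Path) -> pd.DataFrame:
    """Read a comma-delimited score table; empty fields become NaN."""
    table = pd.read_csv(path)
    validate_score_table(table)
    return table


def write_score_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a score table as comma-delimited text, missing as empty field."""
    validate_score_table(table)
    table.to_csv(path, index=False, na_rep="")


def group_table(table: pd.DataFrame, group: str) -> pd.DataFrame:
    """Rows of one group, with a helpful error when the label is unknown."""
    sub = table[table["group"] == group]
    if sub.empty:
        known = sorted(table["group"].unique())
        raise KeyError(f"group {group!r} not in table (known: {known})")
    return sub.reset_index(drop=True)
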