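"""Tab-delimited interchange tables with named-column validation.

All stages exchange plain UTF-8 TSV files with a header row.  Readers
validate the schema up front and fail with a message naming the missing
column, so a mis-wired pipeline stops at the first stage rather than
producing nonsense downstream.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

__all__ = [
    "read_table",
    "write_table",
    "read_patients",
    "read_expression",
    "read_zscores",
    "read_staining",
    "read_ihc",
    "read_group_counts",
]

PATIENT_COLUMNS = [
    "patient_id",
    "consent_active",
    "alive",
    "has_ffpe",
    "has_expression",
    "tissue_type",
    "disease_setting",
]
EXPRESSION_COLUMNS = ["sample_id", "patient_id", "tissue_type", "log2_expression"]
ZSCORE_COLUMNS = ["sample_id", "z", "category"]
STAINING_COLUMNS = ["sample_id", "pct_0", "pct_1", "pct_2", "pct_3"]
IHC_COLUMNS = ["sample_id", "h_score", "positive_by_fraction", "positive_by_hscore"]
GROUP_COUNT_COLUMNS = ["stratum", "group", "n_screened", "n_ihc_positive"]


def read_table(path, required: list[str], name: str) -> pd.DataFrame:
    """Read a TSV and check that every required column is present."""
    # round_trip float parsing: a written table read back reproduces the
    # in-memory float64 values exactly
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(
            f"{name} table {Path(path).name!r} lacks required column(s): {', '.join(missing)}"
        )
    return df


def write_table(df: pd.DataFrame, path) -> None:
    """Write a TSV with header and no index.

    Floats use the shortest round-tripping representation, so reading a
    written table back reproduces the in-memory values exactly.
    """
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)


def read_patients(path) -> pd.DataFrame:
    df = read_table(path, PATIENT_COLUMNS, "patients")
    for col in ("consent_active", "alive", "has_ffpe", "has_expression"):
        df[col] = df[col].astype(bool)
    return df


def read_expression(path) -> pd.DataFrame:
    return read_table(path, EXPRESSION_COLUMNS, "expression")


def read_zscores(path) -> pd.DataFrame:
    return read_table(path, ZSCORE_COLUMNS, "zscores")


def read_staining(path) -> pd.DataFrame:
    return read_table(path, STAINING_COLUMNS, "staining")


def read_ihc(path) -> pd.DataFrame:
    df = read_table(path, IHC_COLUMNS, "ihc")
    for col in ("positive_by_fraction", "positive_by_hscore"):
        df[col] = df[col].astype(bool)
    return df


def read_group_counts(path) -> pd.DataFrame:
    """Pre-tabulated per-stratum RNA-group counts (stratum, group,
    n_screened, n_ihc_positive), one row per stratum x group."""
    return read_table(path, GROUP_COUNT_COLUMNS, "group counts")
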