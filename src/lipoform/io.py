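"""Delimited-table readers and writers with schema validation.

All tables are UTF-8, comma-delimited CSV with a header row, decimal
points, and units encoded in the column names.  Numeric output is
serialized with 10 significant digits (repr-stable for round-tripping at
that precision).
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

__all__ = [
    "CAMPAIGN_REQUIRED_COLUMNS",
    "read_campaign",
    "write_table",
    "read_titrations",
]

logger = logging.getLogger("lipoform")

#: Required campaign columns and whether they must be numeric.
CAMPAIGN_REQUIRED_COLUMNS = {
    "sample_id": False,
    "device": False,
    "tfr_ul_min": True,
    "frr": True,
    "ilc_mg_ml": True,
    "mean_diameter_nm": True,
    "pdi": True,
}

_FLOAT_FORMAT = "%.10g"


class SchemaError(ValueError):
    """A table failed validation; the message names column and row."""


def _validate_campaign(df: pd.DataFrame, source: str) -> pd.DataFrame:
    missing = [c for c in CAMPAIGN_REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{source}: missing required column(s) {missing}")
    for col, numeric in CAMPAIGN_REQUIRED_COLUMNS.items():
        if not numeric:
            continue
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        if len(bad):
            raise SchemaError(
                f"{source}: non-numeric value in column '{col}' at row(s) "
                f"{list(bad[:5])}"
            )
        df[col] = coerced
    dupes = df["sample_id"][df["sample_id"].duplicated()].unique()
    if len(dupes):
        raise SchemaError(f"{source}: duplicate sample_id(s) {list(dupes[:5])}")
    bad_dev = set(df["device"].unique()) - {"SM", "SHM"}
    if bad_dev:
        raise SchemaError(f"{source}: device must be SM or SHM, got {sorted(bad_dev)}")
    return df


def read_campaign(path) -> pd.DataFrame:
    """Read and validate a campaign CSV."""
    path = Path(path)
    df = pd.read_csv(path)
    df = _validate_campaign(df, source=path.name)
    logger.info("read %d rows x %d columns from %s", len(df), df.shape[1], path)
    return df


def read_titrations(path) -> pd.DataFrame:
    """Read a TNS titration table (sample_id, lipid_amount, intensity)."""
    path = Path(path)
    df = pd.read_csv(path)
    required = ["sample_id", "lipid_amount", "intensity"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing required column(s) {missing}")
    for col in ("lipid_amount", "intensity"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        if len(bad):
            raise SchemaError(
                f"{path.name}: non-numeric value in column '{col}' at row(s) "
                f"{list(bad[:5])}"
            )
        df[col] = coerced
    return df


def write_table(df: pd.DataFrame, path) -> None:
    """Write a CSV with the package's fixed numeric precision."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format=_FLOAT_FORMAT)
    logger.info("wrote %d rows to %s", len(df), path)
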