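"""Readers and writers for per-cell measurement tables.

Comma-separated UTF-8 text with a mandatory header row and "." as the
decimal separator.  Required columns: ``cell_id``, ``raw_red``,
``raw_green``, ``background_red``, ``background_green``.  Optional
blue-channel, region and marker-flag columns are typed when present;
unknown columns are preserved as annotations.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

__all__ = [
    "SchemaError",
    "REQUIRED_COLUMNS",
    "FLAG_COLUMNS",
    "read_measurement_table",
    "write_measurement_table",
]

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = (
    "cell_id",
    "raw_red",
    "raw_green",
    "background_red",
    "background_green",
)
INTENSITY_COLUMNS = (
    "raw_red",
    "raw_green",
    "raw_blue",
    "background_red",
    "background_green",
    "background_blue",
)
FLAG_COLUMNS = ("red_only", "ki67")


class SchemaError(ValueError):
    """Raised when a table does not conform to the measurement schema."""


def read_measurement_table(path) -> pd.DataFrame:
    """Read and validate a measurement table.

    Raises :class:`SchemaError` naming missing required columns, on
    non-numeric intensity values, and on negative intensities.  A file
    containing only a header yields an empty table with a warning.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    if len(df) == 0:
        logger.warning("%s: header-only file, no cells", path)
        return df
    for col in INTENSITY_COLUMNS:
        if col not in df.columns:
            continue
        try:
            values = pd.to_numeric(df[col], errors="raise")
        except (ValueError, TypeError) as exc:
            raise SchemaError(f"{path}: non-numeric values in {col!r}") from exc
        if values.isna().any():
            raise SchemaError(f"{path}: missing values in {col!r}")
        if (values < 0).any():
            raise SchemaError(f"{path}: negative intensity values in {col!r}")
        df[col] = values.astype(float)
    if df["cell_id"].duplicated().any():
        raise SchemaError(f"{path}: duplicate cell_id values")
    df["cell_id"] = df["cell_id"].astype(str)
    for col in FLAG_COLUMNS:
        if col in df.columns:
            df[col] = df[col].astype(bool)
    return df


def write_measurement_table(df: pd.DataFrame, path) -> None:
    """Write a measurement table its own reader accepts."""
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"refusing to write table missing columns {missing}")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
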