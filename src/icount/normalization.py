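"""Per-cell fluorescence normalization pipelines.

Two modes mirror the upstream quantification workflows:

* fixed-tissue mode — per-cell background subtraction, old-tag (red)
  percentage anchored on the mean of the 10 darkest nuclei (0%) and the
  10 brightest red-only nuclei (100%) of the tissue, new-tag (green)
  percentage anchored on the brightest green value, and the green-to-
  total fraction computed from the two percentages;
* live-imaging mode — each channel of a tracked lineage divided by the
  highest value measured within that lineage.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

__all__ = [
    "DegenerateReferenceError",
    "subtract_background",
    "normalize_red_fixed",
    "normalize_green_fixed",
    "green_fraction",
    "normalize_fixed",
    "normalize_live",
]

logger = logging.getLogger(__name__)


class DegenerateReferenceError(ValueError):
    """Raised when reference nuclei cannot anchor a normalization."""


def _channel_pairs(df: pd.DataFrame) -> list[tuple[str, str, str]]:
    pairs = []
    for ch in ("red", "green", "blue"):
        raw, bg = f"raw_{ch}", f"background_{ch}"
        if raw in df.columns:
            if bg not in df.columns:
                raise KeyError(f"missing background column {bg!r} for {raw!r}")
            pairs.append((ch, raw, bg))
    return pairs


def subtract_background(cells: pd.DataFrame) -> pd.DataFrame:
    """Background-correct every present channel independently per cell.

    Adds a plain channel column (``red``, ``green``, ``blue``) holding
    ``max(raw - background, 0)``; negative corrected values clip to 0 so
    downstream fractions stay within ``[0, 1]``.
    """
    pairs = _channel_pairs(cells)
    if not pairs:
        raise KeyError("no raw_<channel> columns found")
    out = cells.copy()
    for ch, raw, bg in pairs:
        out[ch] = np.clip(out[raw].to_numpy(float) - out[bg].to_numpy(float), 0.0, None)
    return out


def _reference_mean(values: pd.DataFrame, n_reference: int, ascending: bool) -> float:
    ordered = values.sort_values(
        ["red", "cell_id"], ascending=[ascending, True], kind="mergesort"
    )
    take = min(n_reference, len(ordered))
    return float(ordered["red"].head(take).mean())


def normalize_red_fixed(
    cells: pd.DataFrame, n_reference: int = 10
) -> pd.Series:
    """Red percentage anchored on dark and bright reference nuclei.

    0% is the mean corrected red of the ``n_reference`` darkest nuclei of
    the whole tissue; 100% the mean of the ``n_reference`` brightest
    nuclei carrying the ``red_only`` flag (non-recombined cells whose red
    content is undiluted).  Ties are broken by ``cell_id`` so the result
    does not depend on row order.  If fewer than ``n_reference`` nuclei
    are available, all of them are used (minimum 2) with a warning.
    """
    for col in ("cell_id", "red", "red_only"):
        if col not in cells.columns:
            raise KeyError(f"missing column {col!r} (run subtract_background first?)")
    bright_pool = cells.loc[cells["red_only"].astype(bool), ["red", "cell_id"]]
    if len(bright_pool) < 2:
        raise DegenerateReferenceError(
            f"need at least 2 red-only reference nuclei, found {len(bright_pool)}"
        )
    if len(bright_pool) < n_reference or len(cells) < n_reference:
        logger.warning(
            "fewer than %d reference nuclei available (%d red-only, %d total); "
            "using all of them",
            n_reference, len(bright_pool), len(cells),
        )
    dark = _reference_mean(cells[["red", "cell_id"]], n_reference, ascending=True)
    bright = _reference_mean(bright_pool, n_reference, ascending=False)
    denom = bright - dark
    if denom <= 0:
        raise DegenerateReferenceError(
            "darkest and brightest reference means coincide; cannot normalize red"
        )
    red_pct = 100.0 * (cells["red"].to_numpy(float) - dark) / denom
    return pd.Series(np.clip(red_pct, 0.0, None), index=cells.index, name="red_pct")


def normalize_green_fixed(cells: pd.DataFrame) -> pd.Series:
    """Green percentage of the brightest corrected green value in the tissue."""
    if "green" not in cells.columns:
        raise KeyError("missing column 'green' (run subtract_background first?)")
    brightest = float(cells["green"].max()) if len(cells) else 0.0
    if not brightest > 0:
        raise DegenerateReferenceError("all corrected green values are zero")
    return pd.Series(
        100.0 * cells["green"].to_numpy(float) / brightest,
        index=cells.index,
        name="green_pct",
    )


def green_fraction(cells: pd.DataFrame) -> pd.DataFrame:
    """Green-to-total fraction ``R = green_pct / (green_pct + red_pct)``.

    Cells with both percentages equal to zero get ``R = NaN`` and are
    flagged in the boolean ``undefined_fraction`` column rather than
    dropped.
    """
    for col in ("red_pct", "green_pct"):
        if col not in cells.columns:
            raise KeyError(f"missing column {col!r}")
    out = cells.copy()
    red = out["red_pct"].to_numpy(float)
    green = out["green_pct"].to_numpy(float)
    total = red + green
    undefined = total == 0.0
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(undefined, np.nan, green / np.where(undefined, 1.0, total))
    out["R"] = r
    out["undefined_fraction"] = undefined
    return out


def normalize_fixed(cells: pd.DataFrame, n_reference: int = 10) -> pd.DataFrame:
    """Full fixed-tissue pipeline: background subtraction, red and green
    percentage normalization, and the green-to-total fraction."""
    if len(cells) == 0:
        raise ValueError("empty measurement table")
    out = subtract_background(cells)
    out["red_pct"] = normalize_red_fixed(out, n_reference=n_reference)
    out["green_pct"] = normalize_green_fixed(out)
    return green_fraction(out)


def normalize_live(
    series: pd.DataFrame,
    lineage_col: str = "lineage_id",
    channels: tuple[str, ...] = ("red", "green", "blue"),
) -> pd.DataFrame:
    """Normalize each channel of a lineage time series to its lineage-wide
    maximum.

    Values end up in ``[0, 1]``.  A channel that is identically zero
    within a lineage is left as zeros with a warning (not an error), so
    pre-switch lineages remain processable.
    """
    if len(series) == 0:
        raise ValueError("empty lineage time series")
    if lineage_col not in series.columns:
        raise KeyError(f"missing column {lineage_col!r}")
    present = [ch for ch in channels if ch in series.columns]
    if not present:
        raise KeyError(f"none of the channel columns {channels} present")
    out = series.copy()
    for ch in present:
        maxima = out.groupby(lineage_col)[ch].transform("max")
        zero = maxima <= 0
        if zero.any():
            logger.warning(
                "channel %r has an all-zero lineage; leaving values at zero", ch
            )
        out[ch] = np.where(zero, 0.0, out[ch] / maxima.where(~zero, 1.0))
    return out
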