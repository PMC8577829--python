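"""Division estimation, accuracy evaluation, calibration and
division-class distribution comparison.

Works on normalized per-cell tables carrying the green-to-total fraction
``R`` (as produced by :mod:`icount.normalization`) and on ground-truth
tables from the simulator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .dilution_model import CLASS_LOWER_BOUNDS, DIVISION_CLASSES

__all__ = [
    "DivisionClassHistogram",
    "AccuracyReport",
    "ClassificationResult",
    "DistributionComparison",
    "classify_dataset",
    "evaluate_accuracy",
    "calibrate_C",
    "compare_distributions",
]

_LN2 = math.log(2.0)
_MAX_CLASS_COUNT = 4  # division counts >= 4 collapse into the "4+" class


@dataclass(frozen=True)
class DivisionClassHistogram:
    """Counts of cells per division class, with an optional group label."""

    counts: Mapping[str, int]
    label: str | None = None

    def __post_init__(self) -> None:
        unknown = set(self.counts) - set(DIVISION_CLASSES)
        if unknown:
            raise ValueError(f"unknown division classes: {sorted(unknown)}")
        if any(c < 0 for c in self.counts.values()):
            raise ValueError("counts must be nonnegative")
        object.__setattr__(
            self, "counts", {cls: int(self.counts.get(cls, 0)) for cls in DIVISION_CLASSES}
        )

    @classmethod
    def from_labels(
        cls, labels: Iterable[str], label: str | None = None
    ) -> "DivisionClassHistogram":
        counts = {c: 0 for c in DIVISION_CLASSES}
        for item in labels:
            counts[item] += 1
        return cls(counts=counts, label=label)

    @classmethod
    def from_true_divisions(
        cls, divisions: Iterable[int], label: str | None = None
    ) -> "DivisionClassHistogram":
        """Histogram of ground-truth division counts, ``k`` mapping to the
        class ``"k-(k+1)"`` and any count >= 4 to ``"4+"``."""
        return cls.from_labels(
            (DIVISION_CLASSES[min(int(k), _MAX_CLASS_COUNT)] for k in divisions),
            label=label,
        )

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def proportions(self) -> np.ndarray:
        total = self.total
        if total == 0:
            raise ValueError("histogram is empty")
        return np.array([self.counts[c] / total for c in DIVISION_CLASSES])

    def as_array(self) -> np.ndarray:
        return np.array([self.counts[c] for c in DIVISION_CLASSES], dtype=float)

    def to_dict(self) -> dict:
        return {"label": self.label, "counts": dict(self.counts), "total": self.total}


def _classify_fractions(r: np.ndarray) -> np.ndarray:
    idx = np.searchsorted(CLASS_LOWER_BOUNDS, r, side="right") - 1
    return np.asarray(DIVISION_CLASSES, dtype=object)[idx]


@dataclass(frozen=True)
class ClassificationResult:
    cells: pd.DataFrame
    histograms: dict[str, DivisionClassHistogram]
    n_excluded: int


def classify_dataset(
    cells: pd.DataFrame,
    c: float = 1.0,
    group_col: str | None = None,
) -> ClassificationResult:
    """Per-cell division estimates and per-group class histograms.

    ``cells`` must carry the green-to-total fraction column ``R``.  Cells
    whose fraction is undefined (NaN, or flagged ``undefined_fraction``)
    are excluded from the histograms and reported in ``n_excluded``.
    ``R == 1`` yields an unbounded estimate (``n_hat = inf``) and the
    ``"4+"`` class.
    """
    if len(cells) == 0:
        raise ValueError("empty input")
    if "R" not in cells.columns:
        raise KeyError("missing column 'R'")
    if not c > 0:
        raise ValueError("baseline ratio C must be positive")
    out = cells.copy()
    r = out["R"].to_numpy(float)
    valid = ~np.isnan(r)
    if "undefined_fraction" in out.columns:
        valid &= ~out["undefined_fraction"].to_numpy(bool)
    if ((r < 0) | (r > 1))[valid].any():
        raise ValueError("green fractions must lie in [0, 1]")

    n_hat = np.full(len(out), np.nan)
    with np.errstate(divide="ignore"):
        rv = r[valid]
        n_hat[valid] = (np.log1p(rv * (c - 1.0)) - np.log1p(-rv)) / _LN2
    div_class = np.full(len(out), None, dtype=object)
    div_class[valid] = _classify_fractions(r[valid])
    out["n_hat"] = n_hat
    out["div_class"] = div_class

    kept = out.loc[valid]
    histograms = {
        "all": DivisionClassHistogram.from_labels(kept["div_class"], label="all")
    }
    if group_col is not None:
        if group_col not in out.columns:
            raise KeyError(f"missing group column {group_col!r}")
        for name, grp in kept.groupby(group_col, sort=True):
            histograms[str(name)] = DivisionClassHistogram.from_labels(
                grp["div_class"], label=str(name)
            )
    return ClassificationResult(
        cells=out, histograms=histograms, n_excluded=int((~valid).sum())
    )


@dataclass(frozen=True)
class AccuracyReport:
    n_events: int
    n_correct: int
    confusion: pd.DataFrame = field(compare=False)

    @property
    def fraction_correct(self) -> float:
        return self.n_correct / self.n_events

    def to_dict(self) -> dict:
        return {
            "n_events": self.n_events,
            "n_correct": self.n_correct,
            "fraction_correct": self.fraction_correct,
            "confusion": {
                str(row): {str(col): int(v) for col, v in series.items()}
                for row, series in self.confusion.iterrows()
            },
        }


def _class_matches(div_class: np.ndarray, true_divisions: np.ndarray) -> np.ndarray:
    """A prediction is correct when the true completed division count
    falls inside the predicted class interval: class ``"k-(k+1)"``
    matches true count ``k`` (next division pending) and ``"4+"`` matches
    any count >= 4."""
    capped = np.minimum(true_divisions, _MAX_CLASS_COUNT)
    expected = np.asarray(DIVISION_CLASSES, dtype=object)[capped]
    return div_class == expected


def evaluate_accuracy(
    predictions: pd.DataFrame, ground_truth: pd.DataFrame
) -> AccuracyReport:
    """Compare predicted division classes against true division counts.

    ``predictions`` needs columns ``cell_id`` and ``div_class``;
    ``ground_truth`` needs ``cell_id`` and ``true_divisions``.  The two
    tables must describe the same set of cells.
    """
    for df, col in ((predictions, "div_class"), (ground_truth, "true_divisions")):
        if "cell_id" not in df.columns or col not in df.columns:
            raise KeyError(f"input table missing 'cell_id' or {col!r}")
    pred_ids = set(predictions["cell_id"])
    true_ids = set(ground_truth["cell_id"])
    if pred_ids != true_ids:
        missing = sorted(pred_ids ^ true_ids)[:5]
        raise ValueError(f"mismatched cell identifiers (e.g. {missing})")
    merged = predictions.merge(
        ground_truth[["cell_id", "true_divisions"]], on="cell_id", validate="1:1"
    )
    if len(merged) == 0:
        raise ValueError("no events to evaluate")
    true_k = merged["true_divisions"].to_numpy(int)
    if (true_k < 0).any():
        raise ValueError("true division counts must be nonnegative")
    div_class = merged["div_class"].to_numpy(object)
    correct = _class_matches(div_class, true_k)

    true_labels = np.asarray(DIVISION_CLASSES, dtype=object)[
        np.minimum(true_k, _MAX_CLASS_COUNT)
    ]
    confusion = pd.crosstab(
        pd.Series(true_labels, name="true"),
        pd.Series(div_class, name="predicted"),
        dropna=False,
    ).reindex(index=DIVISION_CLASSES, columns=DIVISION_CLASSES, fill_value=0)
    return AccuracyReport(
        n_events=len(merged), n_correct=int(correct.sum()), confusion=confusion
    )


def calibrate_C(green_fractions: Sequence[float]) -> float:
    """Estimate the baseline brightness ratio from known-one-division cells.

    For a cell that has divided exactly once, ``R = 1 / (1 + C)``, so
    each calibration cell gives ``C = (1 - R) / R``; the median over
    usable cells is returned.  Cells with ``R`` of exactly 0 or 1 are
    excluded; if none remain, an error is raised.
    """
    r = np.asarray(list(green_fractions), dtype=float)
    if ((r < 0) | (r > 1)).any():
        raise ValueError("green fractions must lie in [0, 1]")
    usable = r[(r > 0) & (r < 1)]
    if usable.size == 0:
        raise ValueError("no usable calibration cells (all R in {0, 1})")
    return float(np.median((1.0 - usable) / usable))


@dataclass(frozen=True)
class DistributionComparison:
    tv_distance: float
    chi2: float
    p_value: float
    per_class_difference: dict[str, float]
    n_simulations: int

    def to_dict(self) -> dict:
        return {
            "tv_distance": self.tv_distance,
            "chi2": self.chi2,
            "p_value": self.p_value,
            "per_class_difference": dict(self.per_class_difference),
            "n_simulations": self.n_simulations,
        }


def compare_distributions(
    observed: DivisionClassHistogram,
    model: DivisionClassHistogram,
    n_simulations: int = 2000,
    seed: int = 0,
) -> DistributionComparison:
    """Distance report between an observed and a model class histogram.

    Reports the total-variation distance between the two proportion
    vectors, the chi-square statistic of the observed counts against the
    model proportions, a Monte-Carlo p-value (multinomial resampling
    under the model, robust at small counts), and per-class proportion
    differences (observed minus model).
    """
    if observed.total == 0 or model.total == 0:
        raise ValueError("histograms must contain at least one cell")
    p_obs = observed.proportions
    p_model = model.proportions
    tv = 0.5 * float(np.abs(p_obs - p_model).sum())
    n = observed.total
    expected = n * p_model
    obs_counts = observed.as_array()

    def _stat(counts: np.ndarray) -> float:
        support = expected > 0
        stat = float(
            (((counts - expected) ** 2)[support] / expected[support]).sum()
        )
        if (counts[~support] > 0).any():
            return math.inf
        return stat

    chi2 = _stat(obs_counts)
    rng = np.random.default_rng(seed)
    sims = rng.multinomial(n, p_model, size=n_simulations)
    sim_stats = np.array([_stat(s) for s in sims])
    p_value = (1.0 + float((sim_stats >= chi2).sum())) / (n_simulations + 1.0)
    diffs = {
        cls: float(p_obs[i] - p_model[i]) for i, cls in enumerate(DIVISION_CLASSES)
    }
    return DistributionComparison(
        tv_distance=tv,
        chi2=chi2,
        p_value=p_value,
        per_class_difference=diffs,
        n_simulations=n_simulations,
    )
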