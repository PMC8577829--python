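"""End-to-end pipeline: simulate, measure, normalize, infer, evaluate."""

from __future__ import annotations

import json
import logging
from pathlib import Path

from .. import inference, normalization, synthetic_data
from .config import RunConfig, write_manifest
from . import tables

__all__ = ["run_pipeline"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the stage name is included."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _stage(name: str):
    def decorator(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - rethrown with stage name
                raise PipelineError(name, exc) from exc

        return wrapper

    return decorator


def run_pipeline(config: RunConfig, out_dir: str | None = None) -> dict:
    """Chain simulate -> noise -> normalize -> infer -> evaluate.

    Writes the measurement and ground-truth tables, the lineage tree,
    a JSON summary (accuracy, histograms, distribution distance) and a
    manifest under ``out_dir``.  Deterministic given the seed: two runs
    with the same config produce byte-identical summaries.
    """
    out = Path(out_dir if out_dir is not None else config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim_config = config.simulation
    if config.seed is not None:
        sim_config = sim_config.model_copy(update={"seed": config.seed})
    seed = sim_config.seed

    tree = _stage("simulate")(synthetic_data.simulate_lineages)(sim_config)
    logger.info("simulate: %d cells (%d leaves)", len(tree), len(tree.leaves()))

    measurements = _stage("measure")(synthetic_data.apply_measurement_noise)(
        tree, sim_config.noise, seed=seed + 1
    )
    logger.info("measure: %d cells measured", len(measurements))
    _stage("export")(synthetic_data.export_dataset)(tree, out, measurements)

    normalized = _stage("normalize")(normalization.normalize_fixed)(
        measurements, n_reference=config.n_reference
    )
    logger.info("normalize: %d cells normalized", len(normalized))

    group_col = config.group_col if config.group_col in normalized.columns else None
    result = _stage("infer")(inference.classify_dataset)(
        normalized, c=config.baseline_ratio, group_col=group_col
    )
    estimates_path = out / "estimates.csv"
    result.cells.to_csv(estimates_path, index=False)
    logger.info("infer: %d cells classified, %d excluded",
                len(result.cells) - result.n_excluded, result.n_excluded)

    # Evaluate on recombined cells only: red-only cells carry no
    # division signal by construction.
    truth = synthetic_data.ground_truth_table(tree)
    recombined_ids = set(truth.loc[truth["recombined"], "cell_id"])
    pred = result.cells.loc[
        result.cells["cell_id"].isin(recombined_ids), ["cell_id", "div_class"]
    ]
    truth_rec = truth.loc[truth["recombined"], ["cell_id", "true_divisions"]]
    report = _stage("evaluate")(inference.evaluate_accuracy)(pred, truth_rec)
    logger.info("evaluate: accuracy %.4f on %d events",
                report.fraction_correct, report.n_events)

    observed = inference.DivisionClassHistogram.from_labels(
        pred["div_class"], label="predicted"
    )
    truth_hist = inference.DivisionClassHistogram.from_true_divisions(
        truth_rec["true_divisions"], label="ground_truth"
    )
    comparison = _stage("compare")(inference.compare_distributions)(
        observed, truth_hist, seed=seed + 2
    )

    summary = {
        "seed": seed,
        "n_cells_simulated": len(tree),
        "n_cells_measured": len(measurements),
        "n_excluded": result.n_excluded,
        "accuracy": report.to_dict(),
        "histograms": {k: h.to_dict() for k, h in result.histograms.items()},
        "observed_vs_truth": comparison.to_dict(),
    }
    with open(out / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    write_manifest(out, config, seed)
    return summary
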