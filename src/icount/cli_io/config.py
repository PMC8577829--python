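"""Run configuration documents (JSON or YAML) and the run manifest."""

from __future__ import annotations

import json
from pathlib import Path

from pydantic import BaseModel, ConfigDict, Field

from ..synthetic_data import SimulationConfig

__all__ = ["RunConfig", "load_config", "load_run_config", "write_manifest",
           "demo_config_path"]


class RunConfig(BaseModel):
    """Parameters of an end-to-end pipeline run."""

    model_config = ConfigDict(extra="forbid")

    seed: int | None = None  # overrides simulation.seed when given
    out_dir: str = "results"
    simulation: SimulationConfig = Field(default_factory=SimulationConfig)
    n_reference: int = Field(default=10, ge=2)
    baseline_ratio: float = Field(default=1.0, gt=0)
    group_col: str | None = "region"


def load_config(path) -> dict:
    """Load a JSON or YAML configuration document as a dictionary."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if path.suffix.lower() in (".yaml", ".yml"):
        import yaml

        return yaml.safe_load(text)
    return json.loads(text)


def load_run_config(path) -> RunConfig:
    return RunConfig.model_validate(load_config(path))


def write_manifest(out_dir, config: BaseModel, seed: int) -> Path:
    """Record config, seed and software version next to the outputs."""
    from .. import __version__

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config": json.loads(config.model_dump_json()),
        "seed": seed,
        "version": __version__,
    }
    path = out / "manifest.json"
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path


def demo_config_path() -> Path:
    """Path of the packaged demonstration run configuration."""
    import importlib.resources as resources

    return Path(resources.files("icount") / "data" / "demo_run.json")
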