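"""Branching-lineage simulator with per-cell tag dilution and measurement noise.

Generates ground-truth lineage trees of asynchronously cycling cells,
recombined at a configurable time so that new tag synthesis switches
from red to green (and optionally, after a second switch, to blue);
assigns each cell a noise-free label state consistent with the
closed-form dilution model; and turns label states into noisy
per-cell measurement tables with recorded backgrounds, matching the
schema the normalization stage consumes.

Label states record the pool-completed composition of a cell: with a
deterministic partition the old-tag content after ``k`` post-switch
divisions is ``pool * 2**-k`` and the green fraction equals
``dilution_model.green_fraction_after_divisions(k, 1)`` exactly.  Cells
that exit the cycle (quiescence/differentiation) keep their label state
unchanged for the rest of the simulation.
"""

from __future__ import annotations

import math
from collections import Counter, OrderedDict, defaultdict, deque
from dataclasses import dataclass, field, replace
from typing import Iterator, Literal, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .dilution_model import POOL_LEVEL

__all__ = [
    "CHANNELS",
    "CycleTimeSpec",
    "PartitionSpec",
    "MeasurementNoiseModel",
    "SimulationConfig",
    "LabelState",
    "LineageNode",
    "LineageTree",
    "simulate_lineages",
    "apply_measurement_noise",
    "ground_truth_table",
    "simulate_cortical_population",
    "export_dataset",
    "MEASUREMENT_COLUMNS",
]

CHANNELS = ("red", "green", "blue")

#: Column order of exported measurement tables.
MEASUREMENT_COLUMNS = (
    "cell_id",
    "region",
    "raw_red",
    "raw_green",
    "raw_blue",
    "background_red",
    "background_green",
    "background_blue",
    "red_only",
    "ki67",
)


class CycleTimeSpec(BaseModel):
    """Distribution of cell-cycle lengths (hours)."""

    model_config = ConfigDict(extra="forbid")

    family: Literal["lognormal", "gamma", "fixed"] = "lognormal"
    mean_hours: float = Field(default=16.0, gt=0)
    cv: float = Field(default=0.15, ge=0)

    def sample(self, rng: np.random.Generator) -> float:
        if self.family == "fixed" or self.cv == 0.0:
            return self.mean_hours
        if self.family == "lognormal":
            sigma2 = math.log1p(self.cv**2)
            mu = math.log(self.mean_hours) - 0.5 * sigma2
            return float(rng.lognormal(mu, math.sqrt(sigma2)))
        # gamma: shape/scale parameterized by mean and CV
        shape = 1.0 / self.cv**2
        return float(rng.gamma(shape, self.mean_hours / shape))


class PartitionSpec(BaseModel):
    """How the tag pool is split between daughters at division."""

    model_config = ConfigDict(extra="forbid")

    mode: Literal["deterministic", "binomial"] = "deterministic"
    pool_size: int = Field(default=10_000, ge=1)


class MeasurementNoiseModel(BaseModel):
    """Multiplicative lognormal error plus additive Gaussian background.

    Scalar parameters apply to every channel; a mapping keyed by channel
    name overrides individual channels.
    """

    model_config = ConfigDict(extra="forbid")

    multiplicative_cv: float | dict[str, float] = 0.0
    background_mean: float | dict[str, float] = 0.0
    background_sd: float | dict[str, float] = 0.0

    @model_validator(mode="after")
    def _nonnegative(self) -> "MeasurementNoiseModel":
        for name in ("multiplicative_cv", "background_mean", "background_sd"):
            val = getattr(self, name)
            vals = val.values() if isinstance(val, dict) else (val,)
            if any(v < 0 for v in vals):
                raise ValueError(f"{name} must be nonnegative")
            if isinstance(val, dict):
                unknown = set(val) - set(CHANNELS)
                if unknown:
                    raise ValueError(f"unknown channels in {name}: {sorted(unknown)}")
        return self

    def per_channel(self, name: str) -> dict[str, float]:
        val = getattr(self, name)
        if isinstance(val, dict):
            return {ch: float(val.get(ch, 0.0)) for ch in CHANNELS}
        return {ch: float(val) for ch in CHANNELS}


class SimulationConfig(BaseModel):
    """Full configuration of a lineage simulation."""

    model_config = ConfigDict(extra="forbid")

    seed: int = 0
    n_founders: int = Field(default=4, ge=1)
    cycle_time: CycleTimeSpec = Field(default_factory=CycleTimeSpec)
    recombination_time: float = 0.0
    flp_time: float | None = None
    horizon: float = 48.0
    exit_prob: float = Field(default=0.0, ge=0.0, le=1.0)
    partition: PartitionSpec = Field(default_factory=PartitionSpec)
    detection_delay: float = Field(default=0.0, ge=0.0)
    recombined_fraction: float = Field(default=1.0, ge=0.0, le=1.0)
    founder_pool: float = Field(default=POOL_LEVEL, gt=0)
    noise: MeasurementNoiseModel = Field(default_factory=MeasurementNoiseModel)

    @model_validator(mode="after")
    def _consistent(self) -> "SimulationConfig":
        if self.horizon <= self.recombination_time:
            raise ValueError("horizon must exceed recombination_time")
        if self.flp_time is not None and self.flp_time < self.recombination_time:
            raise ValueError("flp_time must not precede recombination_time")
        return self


@dataclass(frozen=True)
class LabelState:
    """Red/green/blue tag content of one cell, arbitrary units."""

    red: float
    green: float = 0.0
    blue: float = 0.0

    def __post_init__(self) -> None:
        for name in ("red", "green", "blue"):
            object.__setattr__(self, name, float(getattr(self, name)))
        if min(self.red, self.green, self.blue) < 0:
            raise ValueError("channel contents must be nonnegative")

    @property
    def total(self) -> float:
        return self.red + self.green + self.blue

    @property
    def green_fraction(self) -> float:
        """Green over green-plus-red (the division-counting statistic)."""
        denom = self.green + self.red
        if denom == 0:
            return math.nan
        return self.green / denom

    def halved(self) -> "LabelState":
        return LabelState(self.red / 2.0, self.green / 2.0, self.blue / 2.0)


@dataclass
class LineageNode:
    cell_id: str
    parent_id: str | None
    birth_time: float
    division_time: float | None
    fate: Literal["divided", "exited", "alive_at_horizon"]
    true_divisions: int
    recombined: bool
    label: LabelState

    @property
    def is_leaf(self) -> bool:
        return self.fate != "divided"


class LineageTree:
    """Rooted forest of cells with per-node times, fates and labels."""

    def __init__(self) -> None:
        self._nodes: "OrderedDict[str, LineageNode]" = OrderedDict()
        self._children: dict[str, list[str]] = defaultdict(list)
        self.roots: list[str] = []

    def add(self, node: LineageNode) -> None:
        if node.cell_id in self._nodes:
            raise ValueError(f"duplicate cell_id {node.cell_id!r}")
        if node.parent_id is None:
            self.roots.append(node.cell_id)
        else:
            if node.parent_id not in self._nodes:
                raise ValueError(
                    f"parent {node.parent_id!r} of {node.cell_id!r} not in tree"
                )
            self._children[node.parent_id].append(node.cell_id)
        self._nodes[node.cell_id] = node

    def __len__(self) -> int:
        return len(self._nodes)

    def __iter__(self) -> Iterator[LineageNode]:
        return iter(self._nodes.values())

    def __contains__(self, cell_id: str) -> bool:
        return cell_id in self._nodes

    def node(self, cell_id: str) -> LineageNode:
        return self._nodes[cell_id]

    def children(self, cell_id: str) -> list[LineageNode]:
        return [self._nodes[c] for c in self._children.get(cell_id, [])]

    def leaves(self) -> list[LineageNode]:
        return [n for n in self._nodes.values() if n.is_leaf]

    def validate(self, time_tol: float = 1e-9) -> None:
        """Check structural and temporal consistency; raise ValueError."""
        for node in self:
            if node.parent_id is not None:
                parent = self._nodes[node.parent_id]
                if parent.division_time is None:
                    raise ValueError(
                        f"{node.cell_id}: parent {parent.cell_id} never divided"
                    )
                if abs(node.birth_time - parent.division_time) > time_tol:
                    raise ValueError(
                        f"{node.cell_id}: birth time {node.birth_time} does not "
                        f"match parent division time {parent.division_time}"
                    )
                if node.birth_time < parent.birth_time - time_tol:
                    raise ValueError(f"{node.cell_id}: born before its parent")
            if node.division_time is not None and node.division_time < node.birth_time:
                raise ValueError(f"{node.cell_id}: divides before being born")
            if node.fate == "divided" and len(self._children[node.cell_id]) != 2:
                raise ValueError(f"{node.cell_id}: divided but has no two children")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LineageTree):
            return NotImplemented
        return sorted(self.roots) == sorted(other.roots) and dict(
            self._nodes
        ) == dict(other._nodes)


def _refill_color(t: float, config: SimulationConfig) -> int:
    """Channel index of new synthesis for a cell born at time ``t``."""
    if t <= config.recombination_time:
        return 0
    if config.flp_time is not None and t > config.flp_time:
        return 2
    return 1


def _daughter_labels(
    parent: LabelState,
    birth_time: float,
    config: SimulationConfig,
    recombined: bool,
    rng: np.random.Generator,
) -> tuple[LabelState, LabelState]:
    """Pool-completed labels of the two daughters of ``parent``."""
    color = _refill_color(birth_time, config) if recombined else 0
    pool = (
        float(config.partition.pool_size)
        if config.partition.mode == "binomial"
        else config.founder_pool
    )
    channels = np.array([parent.red, parent.green, parent.blue])
    if config.partition.mode == "deterministic":
        first = channels / 2.0
        second = channels - first
    else:
        counts = np.round(channels).astype(np.int64)
        first = rng.binomial(counts, 0.5).astype(float)
        second = counts - first
    out = []
    for inherited in (first, second):
        refill = max(pool - inherited.sum(), 0.0)
        completed = inherited.copy()
        completed[color] += refill
        out.append(LabelState(*completed))
    return out[0], out[1]


def simulate_lineages(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> LineageTree:
    """Simulate a forest of cell lineages under ``config``.

    Every founder starts at time 0 with a pure old-tag (red) pool.  Each
    cycling cell draws a cycle length; it divides if the division instant
    falls within the horizon (inclusive), otherwise it is left alive at
    the horizon.  Each daughter exits the cycle permanently with
    probability ``exit_prob``, decided at birth.  Divisions completing
    strictly after ``recombination_time`` increment ``true_divisions``.
    Reproducible from ``config.seed``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    tree = LineageTree()
    pool = (
        float(config.partition.pool_size)
        if config.partition.mode == "binomial"
        else config.founder_pool
    )
    founder_label = LabelState(pool, 0.0, 0.0)

    for f in range(config.n_founders):
        recombined = bool(rng.random() < config.recombined_fraction)
        founder_id = f"c{f:04d}"
        queue: deque[LineageNode] = deque()
        founder = LineageNode(
            cell_id=founder_id,
            parent_id=None,
            birth_time=0.0,
            division_time=None,
            fate="alive_at_horizon",
            true_divisions=0,
            recombined=recombined,
            label=founder_label,
        )
        tree.add(founder)
        queue.append(founder)
        while queue:
            cell = tree.node(queue.popleft().cell_id)
            division_time = cell.birth_time + config.cycle_time.sample(rng)
            if division_time > config.horizon:
                cell.fate = "alive_at_horizon"
                continue
            cell.fate = "divided"
            cell.division_time = division_time
            counted = division_time > config.recombination_time
            k_child = cell.true_divisions + (1 if counted else 0)
            lab_a, lab_b = _daughter_labels(
                cell.label, division_time, config, cell.recombined, rng
            )
            for suffix, label in (("0", lab_a), ("1", lab_b)):
                exits = bool(rng.random() < config.exit_prob)
                child = LineageNode(
                    cell_id=f"{cell.cell_id}.{suffix}",
                    parent_id=cell.cell_id,
                    birth_time=division_time,
                    division_time=None,
                    fate="exited" if exits else "alive_at_horizon",
                    true_divisions=k_child,
                    recombined=cell.recombined,
                    label=label,
                )
                tree.add(child)
                if not exits:
                    queue.append(child)
    return tree


def apply_measurement_noise(
    tree: LineageTree,
    noise: MeasurementNoiseModel,
    seed: int,
    include_internal: bool = False,
) -> pd.DataFrame:
    """Turn label states into a raw measurement table.

    Per cell and channel, ``raw = true * m + b`` where ``m`` is a
    lognormal multiplicative factor with mean 1 and the configured CV,
    and ``b`` a Gaussian background (clipped at 0) whose sampled value is
    recorded in the matching ``background_*`` column so the
    normalization stage can subtract it.  Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    cells = list(tree) if include_internal else tree.leaves()
    cv = noise.per_channel("multiplicative_cv")
    bg_mean = noise.per_channel("background_mean")
    bg_sd = noise.per_channel("background_sd")
    n = len(cells)
    true = {
        "red": np.array([c.label.red for c in cells]),
        "green": np.array([c.label.green for c in cells]),
        "blue": np.array([c.label.blue for c in cells]),
    }
    raw: dict[str, np.ndarray] = {}
    bg: dict[str, np.ndarray] = {}
    for ch in CHANNELS:
        if cv[ch] > 0:
            sigma2 = math.log1p(cv[ch] ** 2)
            factor = rng.lognormal(-0.5 * sigma2, math.sqrt(sigma2), size=n)
        else:
            factor = np.ones(n)
        background = np.clip(rng.normal(bg_mean[ch], bg_sd[ch], size=n), 0.0, None)
        raw[ch] = true[ch] * factor + background
        bg[ch] = background
    return pd.DataFrame(
        {
            "cell_id": [c.cell_id for c in cells],
            "region": ["sim"] * n,
            "raw_red": raw["red"],
            "raw_green": raw["green"],
            "raw_blue": raw["blue"],
            "background_red": bg["red"],
            "background_green": bg["green"],
            "background_blue": bg["blue"],
            "red_only": [not c.recombined for c in cells],
            "ki67": [c.fate == "alive_at_horizon" for c in cells],
        }
    )


def ground_truth_table(tree: LineageTree, leaves_only: bool = True) -> pd.DataFrame:
    cells = tree.leaves() if leaves_only else list(tree)
    return pd.DataFrame(
        {
            "cell_id": [c.cell_id for c in cells],
            "true_divisions": [c.true_divisions for c in cells],
            "fate": [c.fate for c in cells],
            "recombined": [c.recombined for c in cells],
        }
    )


def simulate_cortical_population(
    progenitor_count: int,
    chase_hours: float,
    cycle_time: CycleTimeSpec,
    diff_prob_schedule: Sequence[float],
    seed: int = 0,
) -> pd.DataFrame:
    """Discrete-generation branching model of a proliferative zone.

    Each founder progenitor cycles; at every division each daughter
    permanently differentiates (becomes a neuron) with the probability of
    its generation, ``diff_prob_schedule[g - 1]`` for daughters of the
    ``g``-th division (the last entry extends to later generations).
    Neurons keep the division count of their birth; progenitors surviving
    to the end of the chase carry their completed division count.

    Returns a tidy table with columns ``compartment`` ("progenitor" or
    "neuron"), ``divisions`` and ``count``.
    """
    if progenitor_count < 1:
        raise ValueError("progenitor_count must be positive")
    if chase_hours <= 0:
        raise ValueError("chase_hours must be positive")
    probs = [float(p) for p in diff_prob_schedule]
    if not probs:
        raise ValueError("diff_prob_schedule must not be empty")
    if any(not 0.0 <= p <= 1.0 for p in probs):
        raise ValueError("differentiation probabilities must lie in [0, 1]")

    rng = np.random.default_rng(seed)
    counts: Counter[tuple[str, int]] = Counter()
    for _ in range(progenitor_count):
        # stack of (birth_time, completed divisions) of live progenitors
        stack: list[tuple[float, int]] = [(0.0, 0)]
        while stack:
            birth, gen = stack.pop()
            division_time = birth + cycle_time.sample(rng)
            if division_time > chase_hours:
                counts[("progenitor", gen)] += 1
                continue
            g = gen + 1
            p = probs[min(g - 1, len(probs) - 1)]
            for _ in range(2):
                if rng.random() < p:
                    counts[("neuron", g)] += 1
                else:
                    stack.append((division_time, g))
    rows = sorted(counts.items())
    return pd.DataFrame(
        {
            "compartment": [comp for (comp, _), _ in rows],
            "divisions": [k for (_, k), _ in rows],
            "count": [c for _, c in rows],
        }
    )


def export_dataset(
    tree: LineageTree,
    out_dir,
    measurements: pd.DataFrame | None = None,
) -> dict[str, str]:
    """Write the measurement table, ground-truth table, and the lineage
    tree (JSON and annotated Newick) under ``out_dir``.

    Returns a mapping of artifact name to file path.
    """
    from pathlib import Path

    from .cli_io import tables, trees

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}
    if measurements is not None:
        paths["measurements"] = str(out / "measurements.csv")
        tables.write_measurement_table(measurements, paths["measurements"])
    paths["ground_truth"] = str(out / "ground_truth.csv")
    ground_truth_table(tree).to_csv(paths["ground_truth"], index=False)
    paths["tree_json"] = str(out / "lineage_tree.json")
    trees.write_tree_json(tree, paths["tree_json"])
    paths["tree_newick"] = str(out / "lineage_tree.nwk")
    trees.write_tree_newick(tree, paths["tree_newick"])
    return paths
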