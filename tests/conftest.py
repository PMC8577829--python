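import numpy as np
import pandas as pd
import pytest

from icount.synthetic_data import (
    CycleTimeSpec,
    MeasurementNoiseModel,
    PartitionSpec,
    SimulationConfig,
    simulate_lineages,
)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def two_division_config():
    """Two synchronous divisions: every leaf has exactly 2 divisions."""
    return SimulationConfig(
        seed=0,
        n_founders=4,
        cycle_time=CycleTimeSpec(family="fixed", mean_hours=16.0, cv=0.0),
        recombination_time=0.0,
        horizon=32.0,
        exit_prob=0.0,
    )


@pytest.fixture
def asynchronous_tree():
    config = SimulationConfig(
        seed=11,
        n_founders=5,
        cycle_time=CycleTimeSpec(family="lognormal", mean_hours=14.0, cv=0.2),
        horizon=45.0,
        exit_prob=0.2,
        recombined_fraction=0.7,
    )
    return simulate_lineages(config)


def make_tissue_table(counts_per_division, n_red_only=12, n_dark=12, pool=100.0):
    """Noise-free fixed-tissue measurement table.

    ``counts_per_division`` maps a division number k to the number of
    recombined cells carrying the exact closed-form label for k.  Adds
    ``n_red_only`` undiluted red-only reference nuclei and ``n_dark``
    nearly exhausted (k = 30) recombined nuclei as dark references.
    """
    rows = []

    def add(cid, red, green, red_only, k):
        rows.append(
            {
                "cell_id": cid,
                "region": "tissue",
                "raw_red": red,
                "raw_green": green,
                "raw_blue": 0.0,
                "background_red": 0.0,
                "background_green": 0.0,
                "background_blue": 0.0,
                "red_only": red_only,
                "ki67": False,
                "true_divisions": k,
            }
        )

    i = 0
    for k, n in sorted(counts_per_division.items()):
        for _ in range(n):
            add(f"cell{i:05d}", pool * 2.0 ** -k, pool * (1 - 2.0 ** -k), False, k)
            i += 1
    for j in range(n_red_only):
        add(f"ref_bright{j:03d}", pool, 0.0, True, 0)
    for j in range(n_dark):
        add(f"ref_dark{j:03d}", pool * 2.0 ** -30, pool * (1 - 2.0 ** -30), False, 30)
    return pd.DataFrame(rows)
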