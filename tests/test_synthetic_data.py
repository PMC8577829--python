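import math
from collections import Counter

import numpy as np
import pandas as pd
import pytest
from pydantic import ValidationError

from icount.dilution_model import green_fraction_after_divisions
from icount.synthetic_data import (
    CycleTimeSpec,
    MeasurementNoiseModel,
    PartitionSpec,
    SimulationConfig,
    apply_measurement_noise,
    ground_truth_table,
    simulate_cortical_population,
    simulate_lineages,
)


class TestConfigValidation:
    def test_rejects_nonpositive_cycle_mean(self):
        with pytest.raises(ValidationError):
            CycleTimeSpec(mean_hours=0.0)

    def test_rejects_horizon_before_recombination(self):
        with pytest.raises(ValidationError):
            SimulationConfig(recombination_time=50.0, horizon=40.0)

    def test_rejects_exit_prob_out_of_range(self):
        with pytest.raises(ValidationError):
            SimulationConfig(exit_prob=1.5)

    def test_rejects_negative_noise(self):
        with pytest.raises(ValidationError):
            MeasurementNoiseModel(multiplicative_cv=-0.1)

    def test_rejects_unknown_noise_channel(self):
        with pytest.raises(ValidationError):
            MeasurementNoiseModel(background_mean={"magenta": 1.0})

    def test_rejects_zero_pool_size(self):
        with pytest.raises(ValidationError):
            PartitionSpec(mode="binomial", pool_size=0)


class TestSimulateLineages:
    def test_two_synchronous_divisions(self, two_division_config):
        tree = simulate_lineages(two_division_config)
        leaves = tree.leaves()
        assert len(leaves) == 4 * 4
        for leaf in leaves:
            assert leaf.true_divisions == 2
            assert leaf.label.green_fraction == pytest.approx(0.75, abs=1e-12)

    def test_exit_prob_one_stops_after_first_generation(self):
        config = SimulationConfig(
            seed=2,
            n_founders=6,
            cycle_time=CycleTimeSpec(family="fixed", mean_hours=10.0),
            horizon=100.0,
            exit_prob=1.0,
        )
        tree = simulate_lineages(config)
        # Founders divide once; every daughter exits and keeps its label.
        assert len(tree) == 6 * 3
        for node in tree:
            if node.parent_id is not None:
                assert node.fate == "exited"
                assert node.true_divisions == 1
                assert node.label.green_fraction == pytest.approx(0.5)

    def test_labels_match_closed_form_everywhere(self, asynchronous_tree):
        for node in asynchronous_tree:
            if not node.recombined:
                assert node.label.green == 0.0
                continue
            expected = green_fraction_after_divisions(node.true_divisions, 1.0)
            assert node.label.green_fraction == pytest.approx(expected, abs=1e-12)

    def test_tree_structure_valid(self, asynchronous_tree):
        asynchronous_tree.validate()
        for node in asynchronous_tree:
            if node.parent_id is not None:
                parent = asynchronous_tree.node(node.parent_id)
                assert node.birth_time == parent.division_time
                counted = 1 if parent.division_time > 0.0 else 0
                assert node.true_divisions == parent.true_divisions + counted

    def test_seed_determinism(self, two_division_config):
        assert simulate_lineages(two_division_config) == simulate_lineages(
            two_division_config
        )

    def test_red_conserved_at_divisions_deterministic(self, asynchronous_tree):
        # After the switch the old tag is never resynthesized, so the
        # daughters' red contents sum exactly to the parent's.
        checked = 0
        for node in asynchronous_tree:
            children = asynchronous_tree.children(node.cell_id)
            if children and node.recombined:
                assert sum(c.label.red for c in children) == pytest.approx(
                    node.label.red, abs=1e-9
                )
                checked += 1
        assert checked > 0

    def test_binomial_partition_mean_green_fraction(self):
        config = SimulationConfig(
            seed=5,
            n_founders=250,
            cycle_time=CycleTimeSpec(family="fixed", mean_hours=16.0),
            horizon=33.0,
            partition=PartitionSpec(mode="binomial", pool_size=10_000),
        )
        tree = simulate_lineages(config)
        fractions = np.array([leaf.label.green_fraction for leaf in tree.leaves()])
        assert len(fractions) == 1000
        assert all(leaf.true_divisions == 2 for leaf in tree.leaves())
        sem = fractions.std(ddof=1) / math.sqrt(len(fractions))
        assert abs(fractions.mean() - 0.75) <= 3.0 * sem + 1e-4

    def test_binomial_partition_conserves_red(self):
        config = SimulationConfig(
            seed=9,
            n_founders=20,
            cycle_time=CycleTimeSpec(family="fixed", mean_hours=16.0),
            horizon=50.0,
            partition=PartitionSpec(mode="binomial", pool_size=1000),
        )
        tree = simulate_lineages(config)
        diffs = []
        for node in tree:
            children = tree.children(node.cell_id)
            if children:
                assert sum(c.label.red for c in children) == pytest.approx(
                    node.label.red
                )
                diffs.append(children[0].label.red - node.label.red / 2.0)
        # Unbiased split: daughter red is centered on half the parent red.
        diffs = np.array(diffs)
        sem = diffs.std(ddof=1) / math.sqrt(len(diffs))
        assert abs(diffs.mean()) <= 3.0 * sem + 1e-9

    def test_non_recombined_lineages_stay_red(self):
        config = SimulationConfig(
            seed=4,
            n_founders=30,
            cycle_time=CycleTimeSpec(family="fixed", mean_hours=12.0),
            horizon=40.0,
            recombined_fraction=0.0,
        )
        tree = simulate_lineages(config)
        for node in tree:
            assert not node.recombined
            assert node.label.red == pytest.approx(100.0)
            assert node.label.green == 0.0

    def test_flp_switch_produces_blue(self):
        config = SimulationConfig(
            seed=6,
            n_founders=3,
            cycle_time=CycleTimeSpec(family="fixed", mean_hours=10.0),
            horizon=42.0,
            flp_time=20.0,
        )
        tree = simulate_lineages(config)
        late = [n for n in tree if n.birth_time > 20.0]
        assert late and all(n.label.blue > 0 for n in late)
        # Channel sum still equals the completed pool.
        for node in tree:
            assert node.label.total == pytest.approx(100.0)


class TestMeasurementNoise:
    def test_zero_noise_is_exact(self, asynchronous_tree):
        noise = MeasurementNoiseModel(background_mean=5.0)
        table = apply_measurement_noise(asynchronous_tree, noise, seed=0)
        leaves = {leaf.cell_id: leaf for leaf in asynchronous_tree.leaves()}
        for _, row in table.iterrows():
            leaf = leaves[row["cell_id"]]
            assert row["raw_red"] == leaf.label.red + 5.0
            assert row["raw_green"] == leaf.label.green + 5.0
            assert row["background_red"] == 5.0

    def test_empirical_cv(self):
        config = SimulationConfig(
            seed=3,
            n_founders=10_000,
            cycle_time=CycleTimeSpec(family="fixed", mean_hours=100.0),
            horizon=50.0,  # no divisions: every cell identical, pure red
        )
        tree = simulate_lineages(config)
        noise = MeasurementNoiseModel(multiplicative_cv=0.1)
        table = apply_measurement_noise(tree, noise, seed=7)
        values = table["raw_red"].to_numpy()
        cv = values.std(ddof=1) / values.mean()
        assert abs(cv - 0.1) <= 0.01

    def test_seed_determinism_byte_identical(self, asynchronous_tree, tmp_path):
        noise = MeasurementNoiseModel(multiplicative_cv=0.2, background_mean=3.0,
                                      background_sd=1.0)
        paths = []
        for i in (0, 1):
            table = apply_measurement_noise(asynchronous_tree, noise, seed=42)
            p = tmp_path / f"t{i}.csv"
            table.to_csv(p, index=False)
            paths.append(p)
        assert paths[0].read_bytes() == paths[1].read_bytes()

    def test_ground_truth_row_count_matches_measurements(self, asynchronous_tree):
        noise = MeasurementNoiseModel()
        table = apply_measurement_noise(asynchronous_tree, noise, seed=0)
        truth = ground_truth_table(asynchronous_tree)
        assert len(table) == len(truth)
        assert set(table["cell_id"]) == set(truth["cell_id"])


class TestCorticalPopulation:
    FIXED = CycleTimeSpec(family="fixed", mean_hours=10.0)

    def test_no_differentiation_two_divisions(self):
        hist = simulate_cortical_population(50, 20.0, self.FIXED, [0.0], seed=0)
        assert hist.to_dict("records") == [
            {"compartment": "progenitor", "divisions": 2, "count": 200}
        ]

    def test_full_differentiation_after_first_division(self):
        hist = simulate_cortical_population(50, 35.0, self.FIXED, [1.0], seed=0)
        assert hist.to_dict("records") == [
            {"compartment": "neuron", "divisions": 1, "count": 100}
        ]

    @staticmethod
    def expected_counts(generations, p):
        """Exhaustive-enumeration oracle: expected cells per (compartment,
        divisions) for one founder, enumerating daughter fates recursively."""

        def from_progenitor(gen):
            if gen == generations:
                return Counter({("progenitor", gen): 1.0})
            total = Counter()
            g = gen + 1
            for _ in range(2):  # two daughters, independent fates
                total[("neuron", g)] += p
                for key, val in from_progenitor(g).items():
                    total[key] += (1.0 - p) * val
            return total

        return from_progenitor(0)

    def test_matches_enumeration_within_three_standard_errors(self):
        p = 0.5
        chase, cycle = 30.0, CycleTimeSpec(family="fixed", mean_hours=9.9)
        expected = self.expected_counts(3, p)
        n_batches, batch = 20, 500
        per_batch = {key: [] for key in expected}
        for b in range(n_batches):
            hist = simulate_cortical_population(batch, chase, cycle, [p], seed=b)
            got = {
                (r.compartment, r.divisions): r.count / batch
                for r in hist.itertuples()
            }
            for key in per_batch:
                per_batch[key].append(got.get(key, 0.0))
        for key, samples in per_batch.items():
            samples = np.array(samples)
            sem = samples.std(ddof=1) / math.sqrt(n_batches)
            assert abs(samples.mean() - expected[key]) <= 3.0 * sem + 1e-9, key

    def test_rejects_empty_schedule(self):
        with pytest.raises(ValueError):
            simulate_cortical_population(10, 20.0, self.FIXED, [], seed=0)

    def test_rejects_bad_probability(self):
        with pytest.raises(ValueError):
            simulate_cortical_population(10, 20.0, self.FIXED, [1.5], seed=0)

    def test_rejects_nonpositive_chase(self):
        with pytest.raises(ValueError):
            simulate_cortical_population(10, 0.0, self.FIXED, [0.5], seed=0)
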