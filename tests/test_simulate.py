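"""Synthetic-data generator: tree simulation, Brownian traits, group
assignment and the paired leaf dataset with known ground truth."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from resorb.io import GROUPS, samples_to_frame
from resorb.metrics import resorption_table, species_summaries
from resorb.phylo import encode_group_trait, signal_test
from resorb.simulate import (
    SyntheticTruth,
    TABLE_GREEN_MEANS,
    assign_groups,
    generate_leaf_dataset,
    simulate_bm_traits,
    simulate_tree,
)
from resorb.tree import Phylogeny


class TestSimulateTree:
    def test_small_tree_shape(self):
        tree = simulate_tree(3, seed=1)
        assert tree.n_tips == 3
        assert tree.is_binary
        assert tree.max_depth() == pytest.approx(1.0)

    def test_node_count_and_labels(self):
        tree = simulate_tree(36, seed=7)
        internal = [nd for nd in tree.postorder() if not nd.is_tip]
        assert tree.n_tips == 36
        assert len(internal) == 35  # 2n - 1 nodes in a binary rooted tree
        assert tree.tip_labels[0] == "sp001" and tree.tip_labels[-1] == "sp036"

    def test_deterministic(self):
        assert simulate_tree(20, seed=5).to_newick() == simulate_tree(20, seed=5).to_newick()

    def test_ultrametric(self):
        depths = simulate_tree(25, seed=9).depths()
        assert np.ptp(list(depths.values())) < 1e-9

    def test_too_few_tips(self):
        with pytest.raises(ValueError):
            simulate_tree(2, seed=1)


class TestBrownianTraits:
    def test_zero_variance_limit(self):
        tree = simulate_tree(10, seed=2)
        vals = simulate_bm_traits(tree, sigma2=0.0, root_value=3.5, seed=0)["trait1"]
        assert np.allclose(vals, 3.5)

    def test_star_tree_variance_matches_branch_length(self):
        # on a star tree tip values are i.i.d. Normal(root, total branch length)
        star = Phylogeny.from_newick(
            "(" + ",".join(f"t{i}:3.0" for i in range(1000)) + ");"
        )
        vals = simulate_bm_traits(star, sigma2=1.0, root_value=0.0, seed=1)["trait1"]
        assert vals.var(ddof=1) == pytest.approx(3.0, rel=0.10)

    def test_bad_correlation_matrix(self):
        tree = simulate_tree(5, seed=3)
        with pytest.raises(ValueError, match="positive-definite"):
            simulate_bm_traits(
                tree, n_traits=2, correlation=np.array([[1.0, 2.0], [2.0, 1.0]]), seed=0
            )


class TestAssignGroups:
    def test_four_tips_one_each(self):
        tree = simulate_tree(4, seed=4)
        groups = assign_groups(tree, clustered=True, seed=0)
        assert sorted(groups) == sorted(GROUPS)

    def test_study_sizes_at_36(self):
        tree = simulate_tree(36, seed=4)
        groups = assign_groups(tree, clustered=True, seed=0)
        assert groups.value_counts().to_dict() == {"Eu": 10, "Se": 5, "Ps": 11, "Gl": 10}

    def test_random_assignment_all_groups_nonempty(self):
        tree = simulate_tree(12, seed=4)
        groups = assign_groups(tree, clustered=False, seed=8)
        assert set(groups) == set(GROUPS)

    def test_too_few_tips(self):
        tree = simulate_tree(3, seed=4)
        with pytest.raises(ValueError):
            assign_groups(tree, clustered=True, seed=0)

    def test_clustered_labels_carry_signal(self):
        # power at the survey's scale: group-coded signal test rejects in
        # most seeds when groups are contiguous blocks of the tip order
        hits = 0
        for s in range(25):
            tree = simulate_tree(36, seed=100 + s)
            groups = assign_groups(tree, clustered=True, seed=200 + s)
            p = signal_test(tree, encode_group_trait(groups), n_perm=199, seed=s).p_value
            hits += p < 0.05
        assert hits >= 20  # >= 80% of seeds

    def test_random_labels_are_null(self):
        # under random assignment the permutation p is calibrated
        rejections = 0
        for s in range(100):
            tree = simulate_tree(36, seed=300 + s)
            groups = assign_groups(tree, clustered=False, seed=400 + s)
            p = signal_test(tree, encode_group_trait(groups), n_perm=99, seed=s).p_value
            rejections += p <= 0.05
        assert rejections <= 12


class TestLeafDataset:
    def test_exact_re_recovery_at_zero_noise(self):
        truth = SyntheticTruth.default(n_species=8, seed=1, noise_sd=0.0)
        truth.true_RE.loc[:, :] = 0.5
        table = resorption_table(samples_to_frame(generate_leaf_dataset(truth)))
        assert np.allclose(table["RE_percent"], 50.0, atol=1e-12)

    def test_row_counts_paired_and_total_layouts(self):
        truth = SyntheticTruth.default(seed=2)
        paired = generate_leaf_dataset(truth, individuals_per_species=7)
        assert len(paired) == 36 * 7 * 2
        total = generate_leaf_dataset(truth, individuals_per_species=7, layout="total")
        assert len(total) == 36 * 7

    def test_eu_green_na_anchor(self, default_truth, default_dataset):
        # the generator's stated world: Eu green Na centred on 53.5 mg/g
        green = default_dataset[default_dataset["status"] == "green"]
        eu = green[green["group"] == "Eu"].groupby("species")["Na"].mean()
        anchor = TABLE_GREEN_MEANS.loc["Na", "Eu"]
        se = eu.std(ddof=1) / np.sqrt(len(eu))
        assert abs(eu.mean() - anchor) <= 2 * max(se, anchor * 0.361 / np.sqrt(len(eu)))

    def test_deterministic(self, default_truth):
        a = samples_to_frame(generate_leaf_dataset(default_truth))
        b = samples_to_frame(generate_leaf_dataset(default_truth))
        pd.testing.assert_frame_equal(a, b)

    def test_true_re_above_one_rejected(self):
        truth = SyntheticTruth.default(n_species=6, seed=3)
        truth.true_RE.iloc[0, 0] = 1.0
        with pytest.raises(ValueError, match="true_RE"):
            generate_leaf_dataset(truth)

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(
        seed=st.integers(0, 10_000),
        noise_sd=st.floats(0.0, 0.6),
        phylo_weight=st.floats(0.0, 1.0),
    )
    def test_generated_data_satisfies_invariants(self, seed, noise_sd, phylo_weight):
        truth = SyntheticTruth.default(
            n_species=8, seed=seed, noise_sd=noise_sd, phylo_weight=phylo_weight
        )
        samples = generate_leaf_dataset(truth, individuals_per_species=(1, 3))
        assert samples and all(not s.check() for s in samples)

    def test_species_mean_re_unbiased(self):
        # species-mean RE estimate is unbiased for the generator's true RE
        diffs = []
        for s in range(200):
            truth = SyntheticTruth.default(n_species=8, seed=7000 + s)
            df = samples_to_frame(generate_leaf_dataset(truth, individuals_per_species=6))
            table = resorption_table(df, level="species")
            est = table.pivot(index="unit", columns="element", values="RE_percent")
            diffs.append((est / 100.0 - truth.true_RE.loc[est.index, est.columns]).mean().mean())
        assert abs(np.mean(diffs)) < 0.02

    def test_succulence_flag_concentrates_in_euhalophytes(self, default_dataset):
        summary = species_summaries(default_dataset)
        eu_rate = summary.loc[summary["group"] == "Eu", "is_succulent"].mean()
        other_rate = summary.loc[summary["group"] != "Eu", "is_succulent"].mean()
        assert eu_rate > other_rate
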