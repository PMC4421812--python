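"""NJ trees, bootstrap support and Dollo gain/loss reconstruction."""

import numpy as np
import pandas as pd
import pytest

from kelpscan.core_io import HET, HOM_ALT, HOM_REF, MISSING, read_newick, write_newick
from kelpscan.phylo_dollo import (
    GainLossMap,
    bootstrap_support,
    clade_signature,
    dollo_brute_force,
    dollo_reconstruct,
    neighbor_joining,
    snp_distance_matrix,
    tree_path_distances,
)
from kelpscan.synthetic_data import simulate_family_evolution, simulate_two_pop
from tests.conftest import make_table, random_rooted_tree, random_unrooted_tree, unrooted_splits


class TestSnpDistance:
    def test_identical_columns_zero_matrix(self):
        table = make_table([[HOM_REF, HOM_ALT], [HOM_REF, HOM_ALT]])
        labels, d = snp_distance_matrix(table)
        assert np.allclose(d, 0.0)

    def test_site_enumeration_fixture(self):
        table = make_table(
            [
                [HOM_REF, HET, HOM_ALT, MISSING],
                [HOM_ALT, HOM_REF, HOM_ALT, HOM_REF],
            ]
        )
        _, d = snp_distance_matrix(table)
        # comparable sites: 1 (differs) and 3 (same) -> 1/2
        assert d[0, 1] == 0.5

    def test_symmetry_and_zero_diagonal(self, rng):
        gt = rng.integers(-1, 3, size=(5, 60)).astype(np.int8)
        gt[:, 0] = HOM_REF  # guarantee one comparable site everywhere
        table = make_table(gt)
        _, d = snp_distance_matrix(table)
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0.0)

    def test_zero_comparable_pair_names_samples(self):
        table = make_table([[HOM_REF, HET], [HET, HOM_REF]])
        with pytest.raises(ValueError, match="s1.*s2"):
            snp_distance_matrix(table)


class TestNeighborJoining:
    def test_three_taxon_branch_lengths(self):
        labels = ["A", "B", "C"]
        d = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], dtype=float)
        tree = neighbor_joining(labels, d)
        lengths = {lf.taxon.label: lf.edge.length for lf in tree.leaf_node_iter()}
        assert lengths == {"A": 1.0, "B": 2.0, "C": 3.0}

    def test_additive_metric_recovery(self, rng):
        for _ in range(30):
            n = int(rng.integers(4, 13))
            true_tree = random_unrooted_tree(n, rng)
            labels, dm = tree_path_distances(true_tree)
            nj_tree = neighbor_joining(labels, dm)
            labels2, dm2 = tree_path_distances(nj_tree)
            assert labels == labels2
            assert np.abs(dm - dm2).max() < 1e-9
            assert unrooted_splits(nj_tree) == unrooted_splits(true_tree)

    def test_label_order_invariance(self, rng):
        true_tree = random_unrooted_tree(7, rng)
        labels, dm = tree_path_distances(true_tree)
        perm = rng.permutation(len(labels))
        labels_p = [labels[i] for i in perm]
        dm_p = dm[np.ix_(perm, perm)]
        t1 = neighbor_joining(labels, dm)
        t2 = neighbor_joining(labels_p, dm_p)
        assert unrooted_splits(t1) == unrooted_splits(t2)

    def test_matches_scikit_bio_on_perturbed_metrics(self, rng):
        from skbio import DistanceMatrix
        from skbio.tree import nj as skbio_nj

        for rep in range(5):
            true_tree = random_unrooted_tree(8, rng)
            labels, dm = tree_path_distances(true_tree)
            noise = rng.uniform(-0.01, 0.01, dm.shape)
            noise = (noise + noise.T) / 2
            np.fill_diagonal(noise, 0.0)
            dm = dm + noise
            mine = neighbor_joining(labels, dm)
            theirs = skbio_nj(DistanceMatrix(dm, labels))
            their_splits = set()
            all_labels = frozenset(labels)
            for node in theirs.non_tips():
                side = frozenset(t.name for t in node.tips())
                if 2 <= len(side) <= len(labels) - 2:
                    their_splits.add(frozenset({side, all_labels - side}))
            assert unrooted_splits(mine) == their_splits

    def test_rejects_asymmetric_input(self):
        d = np.array([[0, 1, 2], [1.5, 0, 1], [2, 1, 0]], dtype=float)
        with pytest.raises(ValueError, match="symmetric"):
            neighbor_joining(["A", "B", "C"], d)


@pytest.fixture(scope="module")
def two_pop_table():
    return simulate_two_pop(4, 4, theta=8.0, bottleneck_severity=0.02,
                            split_time=0.5, n_windows=30,
                            window_length=10_000, seed=41)


class TestBootstrap:
    def test_separated_clades_get_full_support(self, two_pop_table):
        res = two_pop_table
        tree = bootstrap_support(res.table, n_replicates=30, seed=5)
        cult = frozenset(res.cultivated_samples)
        wild = frozenset(res.wild_samples)
        found = False
        for node in tree.preorder_internal_node_iter():
            side = clade_signature(node)
            if side in (cult, wild) and node.label is not None:
                assert node.label == "100"
                found = True
        assert found, "wild/cultivated split not present in NJ tree"

    def test_single_replicate_supports_binary(self, two_pop_table):
        tree = bootstrap_support(two_pop_table.table, n_replicates=1, seed=6)
        labels = {
            node.label
            for node in tree.preorder_internal_node_iter()
            if node.label is not None
        }
        assert labels <= {"0", "100"}

    def test_seed_reproducibility(self, two_pop_table):
        t1 = bootstrap_support(two_pop_table.table, n_replicates=10, seed=9)
        t2 = bootstrap_support(two_pop_table.table, n_replicates=10, seed=9)
        assert write_newick(t1) == write_newick(t2)


class TestDollo:
    def test_all_present_gains_at_root(self):
        tree = read_newick("((A:1,B:1):1,(C:1,D:1):1);")
        presence = pd.DataFrame([[1, 1, 1, 1]], index=["f"], columns=list("ABCD"))
        recon = dollo_reconstruct(presence, tree)
        assert recon.family_gain["f"] == frozenset("ABCD")
        assert not recon.losses

    def test_single_leaf_family(self):
        tree = read_newick("((A:1,B:1):1,(C:1,D:1):1);")
        presence = pd.DataFrame([[0, 0, 1, 0]], index=["f"], columns=list("ABCD"))
        recon = dollo_reconstruct(presence, tree)
        assert recon.family_gain["f"] == frozenset("C")
        assert not recon.losses

    def test_worked_fixture_with_one_loss(self):
        tree = read_newick("((A:1,B:1):1,(C:1,D:1):1);")
        presence = pd.DataFrame([[1, 1, 0, 1]], index=["f"], columns=list("ABCD"))
        recon = dollo_reconstruct(presence, tree)
        assert recon.family_gain["f"] == frozenset("ABCD")
        assert set(recon.losses) == {frozenset("C")}
        gain_bf, losses_bf = dollo_brute_force(frozenset("ABD"), tree)
        assert recon.family_gain["f"] == gain_bf
        assert set(recon.losses) == set(losses_bf)

    def test_matches_brute_force_on_random_fixtures(self, rng):
        for _ in range(200):
            n = int(rng.integers(4, 9))
            tree = random_rooted_tree(n, rng)
            leaves = sorted(lf.taxon.label for lf in tree.leaf_node_iter())
            row = rng.integers(0, 2, size=n)
            if row.sum() == 0:
                row[int(rng.integers(0, n))] = 1
            presence = pd.DataFrame([row], index=["f"], columns=leaves)
            recon = dollo_reconstruct(presence, tree)
            possessing = frozenset(l for l, v in zip(leaves, row) if v)
            gain_bf, losses_bf = dollo_brute_force(possessing, tree)
            assert recon.family_gain["f"] == gain_bf
            assert frozenset(recon.losses) == losses_bf

    def test_gain_recovery_on_low_loss_simulation(self, rng):
        tree = random_rooted_tree(7, rng)
        presence, truth, _ = simulate_family_evolution(tree, 2000, loss_rate=0.02,
                                                       seed=43)
        recon = dollo_reconstruct(presence, tree)
        matched = sum(
            1
            for fam, gain in recon.family_gain.items()
            if truth.family_gain[fam] == gain
        )
        assert matched / len(recon.family_gain) >= 0.99

    def test_gain_conservation(self, rng):
        tree = random_rooted_tree(6, rng)
        presence, _, _ = simulate_family_evolution(tree, 300, loss_rate=0.1, seed=44)
        recon = dollo_reconstruct(presence, tree)
        n_nonempty = int((presence.sum(axis=1) > 0).sum())
        assert sum(len(v) for v in recon.gains.values()) == n_nonempty

    def test_all_absent_family_skipped_with_warning(self, caplog):
        tree = read_newick("((A:1,B:1):1,C:1);")
        presence = pd.DataFrame([[0, 0, 0]], index=["f"], columns=list("ABC"))
        with caplog.at_level("WARNING", logger="kelpscan"):
            recon = dollo_reconstruct(presence, tree)
        assert recon.n_families == 0
        assert any("all-absent" in r.message for r in caplog.records)

    def test_taxa_mismatch_rejected(self):
        tree = read_newick("((A:1,B:1):1,C:1);")
        presence = pd.DataFrame([[1, 1]], index=["f"], columns=["A", "X"])
        with pytest.raises(ValueError, match="match"):
            dollo_reconstruct(presence, tree)
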