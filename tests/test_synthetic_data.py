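"""Generator contracts: determinism, analytic calibration, truth recording."""

import numpy as np
import pytest

from kelpscan.mol_evolution import jc_p_from_d
from kelpscan.popgen_scan import tajima_constants, window_pi
from kelpscan.synthetic_data import (
    DemographyModel,
    simulate_coalescent,
    simulate_contigs,
    simulate_family_evolution,
    simulate_paralog_pairs,
    simulate_te_decay,
    simulate_two_pop,
)
from kelpscan.phylo_dollo import clade_signature
from tests.conftest import random_rooted_tree


class TestDemographyModel:
    def test_validation(self):
        with pytest.raises(ValueError):
            DemographyModel(((0.5, 1.0),))  # must start at 0
        with pytest.raises(ValueError):
            DemographyModel(((0.0, 1.0), (0.0, 2.0)))  # not increasing
        with pytest.raises(ValueError):
            DemographyModel(((0.0, -1.0),))

    def test_size_lookup(self):
        demo = DemographyModel(((0.0, 0.05), (0.5, 1.0)))
        assert demo.size_at(0.1) == 0.05
        assert demo.size_at(0.6) == 1.0
        assert demo.next_change(0.1) == 0.5


class TestCoalescent:
    def test_expected_s_n2(self):
        # a1(2) = 1 so E[S] = theta exactly
        theta = 5.0
        _, _, truth = simulate_coalescent(2, theta, n_windows=2000,
                                          window_length=10_000, seed=11)
        S = np.array(truth.truth["per_window_S"], dtype=float)
        se = S.std(ddof=1) / np.sqrt(len(S))
        assert abs(S.mean() - theta) < 5 * se

    def test_expected_s_n10(self):
        theta = 10.0
        _, _, truth = simulate_coalescent(10, theta, n_windows=2000,
                                          window_length=100_000, seed=12)
        S = np.array(truth.truth["per_window_S"], dtype=float)
        se = S.std(ddof=1) / np.sqrt(len(S))
        assert abs(S.mean() - theta * tajima_constants(10).a1) < 5 * se

    def test_determinism(self):
        h1, t1, _ = simulate_coalescent(6, 4.0, n_windows=5, seed=42)
        h2, t2, _ = simulate_coalescent(6, 4.0, n_windows=5, seed=42)
        assert np.array_equal(h1.alleles, h2.alleles)
        assert np.array_equal(h1.positions, h2.positions)
        assert t1 == t2

    def test_validation(self):
        with pytest.raises(ValueError):
            simulate_coalescent(3, 1.0)  # odd
        with pytest.raises(ValueError):
            simulate_coalescent(4, 0.0)

    def test_mutation_overflow_raises(self):
        with pytest.raises(ValueError, match="infinite-sites"):
            simulate_coalescent(20, 1000.0, n_windows=50, window_length=10, seed=1)


class TestTwoPop:
    def test_null_case_exchangeable(self):
        res = simulate_two_pop(4, 4, theta=10.0, bottleneck_severity=1.0,
                               split_time=0.1, n_windows=500, seed=21)
        win_len = 10_000
        pis_w, pis_c = [], []
        for w in range(500):
            sel = (res.wild.positions >= w * win_len) & (
                res.wild.positions < (w + 1) * win_len)
            pis_w.append(window_pi(res.wild.alleles[:, sel]))
            pis_c.append(window_pi(res.cultivated.alleles[:, sel]))
        diff = np.array(pis_w) - np.array(pis_c)
        se = diff.std(ddof=1) / np.sqrt(len(diff))
        assert abs(diff.mean()) < 5 * se

    def test_bottleneck_reduces_cultivated_diversity(self):
        hits = 0
        reps = 20
        for rep in range(reps):
            res = simulate_two_pop(4, 4, theta=10.0, bottleneck_severity=0.05,
                                   split_time=0.1, n_windows=200, seed=100 + rep)
            win_len = 10_000
            pw = np.mean([
                window_pi(res.wild.alleles[:, (res.wild.positions >= w * win_len)
                                           & (res.wild.positions < (w + 1) * win_len)])
                for w in range(200)
            ])
            pc = np.mean([
                window_pi(res.cultivated.alleles[:,
                          (res.cultivated.positions >= w * win_len)
                          & (res.cultivated.positions < (w + 1) * win_len)])
                for w in range(200)
            ])
            hits += pc < pw
        assert hits >= 0.95 * reps

    def test_seeds_differ_schema_identical(self):
        r1 = simulate_two_pop(2, 2, n_windows=5, seed=1)
        r2 = simulate_two_pop(2, 2, n_windows=5, seed=2)
        assert not np.array_equal(r1.wild.positions, r2.wild.positions)
        assert set(r1.truth.truth) == set(r2.truth.truth)
        assert r1.truth.params == r2.truth.params

    def test_validation(self):
        with pytest.raises(ValueError):
            simulate_two_pop(2, 2, bottleneck_severity=0.0)
        with pytest.raises(ValueError):
            simulate_two_pop(2, 2, split_time=-1.0)


class TestTeDecay:
    def test_age_zero_identical(self):
        copies, _ = simulate_te_decay(500, [0.0, 0.0], seed=3)
        for c in copies:
            assert c.aligned_copy == c.aligned_consensus

    def test_substitution_probability_calibrated(self):
        d = 0.10
        copies, _ = simulate_te_decay(10_000, [d], seed=4)
        p_expected = jc_p_from_d(d)
        p_obs = copies[0].p
        se = np.sqrt(p_expected * (1 - p_expected) / 10_000)
        assert abs(p_obs - p_expected) < 3 * se

    def test_jc_estimator_recovers_age(self):
        for d_true in (0.02, 0.20):
            copies, _ = simulate_te_decay(10_000, [d_true] * 20, seed=5)
            d_hat = np.mean([c.d for c in copies])
            assert abs(d_hat - d_true) < 0.01

    def test_fragment_truncation(self):
        copies, _ = simulate_te_decay(1000, [0.0], fragment_fraction=0.4, seed=6)
        aligned = copies[0].aligned_copy
        assert len(aligned) == 1000
        assert aligned.count("-") == 600

    def test_negative_age_rejected(self):
        with pytest.raises(ValueError):
            simulate_te_decay(100, [-0.1])


class TestFamilyEvolution:
    def test_lossless_families_fill_gain_clade(self, rng):
        tree = random_rooted_tree(6, rng)
        presence, truth_map, _ = simulate_family_evolution(tree, 50, loss_rate=0.0,
                                                           seed=7)
        for fam, gain in truth_map.family_gain.items():
            present = set(presence.columns[presence.loc[fam].astype(bool)])
            assert present == set(gain)

    def test_root_gain_no_loss_is_all_ones(self, rng):
        tree = random_rooted_tree(5, rng)
        root_sig = clade_signature(tree.seed_node)
        # loss_rate=0: any family gained at the root covers every taxon
        presence, truth_map, _ = simulate_family_evolution(tree, 200, loss_rate=0.0,
                                                           seed=8)
        root_fams = [f for f, g in truth_map.family_gain.items() if g == root_sig]
        assert root_fams, "expected some families gained at the root"
        for fam in root_fams:
            assert presence.loc[fam].all()

    def test_rejects_unrooted_tree(self, rng):
        from tests.conftest import random_unrooted_tree

        tree = random_unrooted_tree(5, rng)
        with pytest.raises(ValueError, match="rooted"):
            simulate_family_evolution(tree, 10)


class TestContigs:
    def test_host_gc_calibrated(self):
        from kelpscan.seq_qc import gc_content

        contigs, _, _ = simulate_contigs(50, 0, host_gc=0.5, seed=9)
        gcs = [gc_content(c.sequence) for c in contigs]
        assert abs(np.mean(gcs) - 0.5) < 0.02

    def test_full_coding_density(self):
        from kelpscan.seq_qc import orf_density

        contigs, _, _ = simulate_contigs(0, 5, coding_density=1.0, seed=10)
        for c in contigs:
            assert orf_density(c.sequence) > 0.95

    def test_labels_match_hints(self):
        contigs, labels, _ = simulate_contigs(3, 4, seed=11)
        hints = {c.contig_id: c.taxonomy_hint for c in contigs}
        for row in labels.itertuples():
            assert hints[row.contig_id] == row.hint

    def test_degenerate_length_range(self):
        with pytest.raises(ValueError):
            simulate_contigs(1, 1, length_range=(100, 100))


class TestParalogPairs:
    def test_zero_rates_identical(self):
        pairs, _ = simulate_paralog_pairs(3, 0.0, 0.0, codon_count=150, seed=12)
        assert all(a == b for a, b in pairs)

    def test_pure_synonymous_gives_ka_zero(self):
        from kelpscan.mol_evolution import CodonAlignmentPair, ng86_ka_ks

        pairs, _ = simulate_paralog_pairs(3, 0.4, 0.0, codon_count=500, seed=13)
        for a, b in pairs:
            res = ng86_ka_ks(CodonAlignmentPair(a, b))
            assert res.ka == 0.0
            assert res.ks > 0.0

    def test_determinism(self):
        p1, _ = simulate_paralog_pairs(2, 0.2, 0.1, codon_count=200, seed=14)
        p2, _ = simulate_paralog_pairs(2, 0.2, 0.1, codon_count=200, seed=14)
        assert p1 == p2
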