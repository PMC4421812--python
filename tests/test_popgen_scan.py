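"""Window statistics, Tajima's D machinery and sweep-region calling."""

from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from kelpscan.core_io import Gene, GeneAnnotation, HET, HOM_ALT, HOM_REF, MISSING
from kelpscan.popgen_scan import (
    SweepRegion,
    candidate_regions,
    count_segregating,
    empirical_thresholds,
    genes_in_regions,
    sliding_scan,
    tajima_constants,
    tajimas_d,
    window_pi,
    window_pi_pairwise,
    window_theta_w,
)
from kelpscan.synthetic_data import simulate_two_pop
from tests.conftest import make_table


def _constants_by_hand(n: int) -> dict:
    """Independent arithmetic oracle in exact rationals."""
    a1 = sum(Fraction(1, i) for i in range(1, n))
    a2 = sum(Fraction(1, i * i) for i in range(1, n))
    b1 = Fraction(n + 1, 3 * (n - 1))
    b2 = Fraction(2 * (n * n + n + 3), 9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - Fraction(n + 2, n) / a1 + a2 / a1**2
    return dict(
        a1=a1, a2=a2, b1=b1, b2=b2, c1=c1, c2=c2,
        e1=c1 / a1, e2=c2 / (a1**2 + a2),
    )


class TestTajimaConstants:
    @pytest.mark.parametrize("n", [2, 4, 10, 100])
    def test_matches_independent_arithmetic(self, n):
        c = tajima_constants(n)
        oracle = _constants_by_hand(n)
        for name in ("a1", "a2", "b1", "b2", "c1", "c2", "e1", "e2"):
            assert abs(getattr(c, name) - float(oracle[name])) < 1e-12, name

    def test_n2_degenerate(self):
        c = tajima_constants(2)
        assert c.a1 == 1.0 and c.a2 == 1.0
        assert abs(c.c1) < 1e-15 and abs(c.c2) < 1e-15
        assert abs(c.e1) < 1e-15 and abs(c.e2) < 1e-15

    def test_n100_harmonic_asymptotic(self):
        c = tajima_constants(100)
        gamma = 0.5772156649015329
        assert abs(c.a1 - (np.log(99) + gamma)) / c.a1 < 0.01
        assert c.e1 > 0 and c.e2 > 0

    def test_rejects_n_below_2(self):
        with pytest.raises(ValueError):
            tajima_constants(1)


class TestPi:
    def test_identical_haplotypes(self):
        assert window_pi(np.zeros((4, 5), dtype=np.int8)) == 0.0

    def test_four_haplotype_fixture(self):
        # {00, 01, 10, 11}: brute force gives 8 differences / 6 pairs
        alleles = np.array([[0, 0], [0, 1], [1, 0], [1, 1]], dtype=np.int8)
        assert abs(window_pi(alleles) - 8 / 6) < 1e-12
        assert abs(window_pi_pairwise(alleles) - 8 / 6) < 1e-12

    def test_frequency_equals_pairwise_without_missing(self, rng):
        for _ in range(100):
            alleles = rng.integers(0, 2, size=(6, 20)).astype(np.int8)
            assert abs(window_pi(alleles) - window_pi_pairwise(alleles)) < 1e-10

    def test_all_sites_undercalled_is_nan(self):
        alleles = np.full((3, 2), MISSING, dtype=np.int8)
        alleles[0, 0] = 1
        assert np.isnan(window_pi(alleles))


class TestThetaWAndD:
    def test_theta_w_values(self):
        assert window_theta_w(0, 10) == 0.0
        assert window_theta_w(5, 2) == 5.0
        assert abs(window_theta_w(11, 4) - 6.0) < 1e-12

    def test_d_zero_when_pi_equals_theta_w(self):
        c = tajima_constants(6)
        S = 4
        assert tajimas_d(S / c.a1, S, 6) == pytest.approx(0.0, abs=1e-12)

    def test_worked_fixture(self):
        # n=4, S=2, pi=4/3: direct formula evaluation
        c = tajima_constants(4)
        expected = (4 / 3 - 2 / c.a1) / np.sqrt(c.e1 * 2 + c.e2 * 2 * 1)
        assert abs(tajimas_d(4 / 3, 2, 4) - expected) < 1e-12
        assert abs(tajimas_d(4 / 3, 2, 4) - 1.893) < 0.001

    def test_undefined_cases(self):
        assert np.isnan(tajimas_d(0.0, 0, 10))
        assert np.isnan(tajimas_d(1.0, 2, 2))


class TestSlidingScan:
    def test_single_window(self):
        table = make_table(
            [[HET, HOM_ALT], [HOM_REF, HOM_REF]], positions=[100, 5000]
        )
        df = sliding_scan(table, 10_000, 10_000, chrom_lengths={"chr1": 10_000})
        assert len(df) == 1
        assert df.iloc[0].S == 2

    def test_tiling_with_trailing_partial(self):
        table = make_table([[HET]], positions=[100])
        df = sliding_scan(table, 10_000, 5_000, chrom_lengths={"chr1": 20_000})
        full = df[df.full]
        assert list(zip(full.start, full.end)) == [
            (0, 10_000), (5_000, 15_000), (10_000, 20_000)
        ]
        partial = df[~df.full]
        assert list(zip(partial.start, partial.end)) == [(15_000, 20_000)]

    def test_empty_windows_emitted(self):
        table = make_table([[HET]], positions=[100])
        df = sliding_scan(table, 1_000, 1_000, chrom_lengths={"chr1": 5_000})
        assert len(df) == 5
        assert df.S.tolist() == [1, 0, 0, 0, 0]
        assert np.isnan(df.D.iloc[1])

    def test_unknown_population_sample(self):
        table = make_table([[HET]])
        with pytest.raises(KeyError):
            sliding_scan(table, 100, 100, population_samples=["ghost"])

    def test_two_pop_diversity_ordering(self):
        res = simulate_two_pop(4, 4, theta=8.0, bottleneck_severity=0.05,
                               n_windows=100, window_length=10_000, seed=7)
        lengths = {"chr1": 100 * 10_000}
        wild = sliding_scan(res.table, 10_000, 10_000,
                            population_samples=res.wild_samples,
                            chrom_lengths=lengths)
        cult = sliding_scan(res.table, 10_000, 10_000,
                            population_samples=res.cultivated_samples,
                            chrom_lengths=lengths)
        assert cult.pi.mean() < wild.pi.mean()


class TestThresholds:
    def test_linear_interpolation_oracle(self):
        values = np.arange(1, 101, dtype=float)
        low, high = empirical_thresholds(values, 0.05)
        assert abs(low - 5.95) < 1e-12
        assert abs(high - 95.05) < 1e-12

    def test_symmetric_values(self):
        v = np.concatenate([np.arange(-50, 0), np.arange(1, 51)]).astype(float)
        low, high = empirical_thresholds(v, 0.05)
        assert abs(low + high) < 1e-12

    def test_nan_excluded_and_minimum_count(self):
        v = np.concatenate([np.arange(30, dtype=float), [np.nan] * 10])
        low, high = empirical_thresholds(v, 0.1)
        assert np.isfinite(low) and np.isfinite(high)
        with pytest.raises(ValueError):
            empirical_thresholds(np.array([np.nan] * 25), 0.05)
        with pytest.raises(ValueError):
            empirical_thresholds(np.arange(10, dtype=float), 0.05)


def _window_frame(d_values, win=1000):
    return pd.DataFrame(
        dict(
            chrom="chr1",
            start=[i * win for i in range(len(d_values))],
            end=[(i + 1) * win for i in range(len(d_values))],
            D=d_values,
        )
    )


class TestCandidateRegions:
    def test_no_candidates(self):
        df = _window_frame([0.0] * 20)
        assert candidate_regions(df, -1.0, 1.0, "C") == []

    def test_hand_enumerated_fixture(self):
        d = [0.0] * 20
        d[5] = d[6] = d[7] = -3.0  # 3-window low run
        d[12] = 3.0  # isolated high window
        regions = candidate_regions(_window_frame(d), -1.0, 1.0, "C")
        assert len(regions) == 2
        cn, cp = regions
        assert (cn.label, cn.start, cn.end, cn.n_windows) == ("CN", 5000, 8000, 3)
        assert (cp.label, cp.start, cp.end, cp.n_windows) == ("CP", 12000, 13000, 1)

    def test_merging_idempotent(self):
        d = [0.0, -3.0, -3.0, 0.0, 3.0]
        first = candidate_regions(_window_frame(d), -1.0, 1.0, "W")
        # region-shaped input: one window per region with the same extremes
        df = pd.DataFrame(
            dict(
                chrom=[r.chrom for r in first],
                start=[r.start for r in first],
                end=[r.end for r in first],
                D=[-3.0 if r.label.endswith("N") else 3.0 for r in first],
            )
        )
        second = candidate_regions(df, -1.0, 1.0, "W")
        assert [(r.chrom, r.start, r.end, r.label) for r in second] == [
            (r.chrom, r.start, r.end, r.label) for r in first
        ]

    def test_bad_thresholds(self):
        with pytest.raises(ValueError):
            candidate_regions(_window_frame([0.0]), 1.0, -1.0, "C")


class TestGenesInRegions:
    def _ann(self):
        return GeneAnnotation(
            genes=[
                Gene("gA", "chr1", 900, 1100, 0),    # overlaps r1 start
                Gene("gB", "chr1", 2000, 2100, 1),   # abuts r1 end (half-open)
                Gene("gC", "chr1", 1500, 3500, 2),   # spans r1 and r2
                Gene("gD", "chr1", 3900, 3950, 3),   # inside r2
                Gene("gE", "chr2", 1000, 2000, 4),   # wrong chrom
            ]
        )

    def _regions(self):
        return [
            SweepRegion("chr1", 1000, 2000, "CN", 1),
            SweepRegion("chr1", 3000, 4000, "CP", 1),
        ]

    def test_overlap_lists_and_unique_total(self):
        regions, total = genes_in_regions(self._regions(), self._ann())
        assert regions[0].gene_ids == ("gA", "gC")
        assert regions[1].gene_ids == ("gC", "gD")
        assert total == 3  # gC counted once

    def test_brute_force_oracle(self, rng):
        genes = []
        for i in range(30):
            s = int(rng.integers(0, 9000))
            genes.append(Gene(f"g{i}", "chr1", s, s + int(rng.integers(1, 500)), i))
        ann = GeneAnnotation(genes=genes)
        regions = [
            SweepRegion("chr1", 2000, 3000, "WN", 1),
            SweepRegion("chr1", 6500, 8000, "WP", 1),
        ]
        annotated, total = genes_in_regions(regions, ann)
        for reg in annotated:
            expected = sorted(
                g.gene_id
                for g in genes
                if g.start < reg.end and reg.start < g.end
            )
            assert sorted(reg.gene_ids) == expected
        union = {g for r in annotated for g in r.gene_ids}
        assert total == len(union)

    def test_missing_chrom_warns(self, caplog):
        regions = [SweepRegion("chrX", 0, 100, "CN", 1)]
        with caplog.at_level("WARNING", logger="kelpscan"):
            annotated, total = genes_in_regions(regions, self._ann())
        assert annotated[0].gene_ids == ()
        assert total == 0
        assert any("chrX" in r.message for r in caplog.records)


@given(st.integers(min_value=3, max_value=60))
def test_theta_w_scales_inverse_harmonic(n):
    c = tajima_constants(n)
    assert window_theta_w(7, n) == pytest.approx(7 / c.a1)
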