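"""Extended-haplotype statistics: EHH/iHH oracles, iHS/Rsb behavior,
candidate regions and the Bonferroni helper."""

import math

import numpy as np
import pandas as pd
import pytest

from oracles import ehh_pair_enumeration
from riverpop.scan import (
    EHHCurve,
    HaplotypeSet,
    bonferroni_log10,
    candidate_regions,
    cross_species_overlap,
    ehh,
    ihh,
    ihs,
    rsb,
)


def hapset(rows, positions=None):
    rows = np.asarray(rows, dtype=np.int8)
    positions = positions or list(range(100, 100 * (rows.shape[1] + 1), 100))
    return HaplotypeSet(rows, np.asarray(positions))


class TestEhh:
    def test_focal_site_has_ehh_one(self):
        hs = hapset([[1, 0], [1, 1], [0, 0], [1, 1]])
        curve = ehh(hs, 0, 1)
        assert curve.left_ehh[0] == 1.0 and curve.right_ehh[0] == 1.0

    def test_identical_carriers_keep_ehh_one(self):
        hs = hapset(np.tile([1, 0, 1, 1, 0], (4, 1)))
        curve = ehh(hs, 2, 1, stop=0.0)
        assert (curve.right_ehh == 1.0).all()
        assert (curve.left_ehh == 1.0).all()

    def test_two_two_split_gives_one_third(self):
        hs = hapset([[1, 0, 0], [1, 0, 1], [1, 1, 0], [1, 1, 1]])
        curve = ehh(hs, 0, 1, stop=0.0)
        assert curve.right_ehh[1] == pytest.approx(1 / 3)

    def test_fewer_than_two_carriers_undefined(self):
        hs = hapset([[1, 0], [0, 0], [0, 1]])
        assert ehh(hs, 0, 1) is None

    def test_non_increasing_outward(self):
        rng = np.random.default_rng(0)
        hap = rng.integers(0, 2, size=(16, 40)).astype(np.int8)
        hs = hapset(hap)
        for focal in (5, 20, 35):
            for allele in (0, 1):
                curve = ehh(hs, focal, allele, stop=0.0)
                if curve is None:
                    continue
                assert (np.diff(curve.right_ehh) <= 1e-12).all()
                assert (np.diff(curve.left_ehh) <= 1e-12).all()

    def test_matches_pair_enumeration_oracle(self):
        """Exhaustive haplotype-pair enumeration on random instances with
        <= 12 haplotypes equals the prefix-grouping implementation."""
        rng = np.random.default_rng(1)
        for _ in range(40):
            n = int(rng.integers(4, 13))
            m = int(rng.integers(5, 25))
            hap = rng.integers(0, 2, size=(n, m)).astype(np.int8)
            pos = np.sort(rng.choice(10_000, m, replace=False)) + 1
            hs = HaplotypeSet(hap, pos)
            focal = int(rng.integers(m))
            allele = int(rng.integers(2))
            expected = ehh_pair_enumeration(hap, pos, focal, allele)
            curve = ehh(hs, focal, allele)
            if expected is None:
                assert curve is None
                continue
            got = dict(zip(curve.left_pos.tolist(), curve.left_ehh.tolist()))
            got.update(zip(curve.right_pos.tolist(), curve.right_ehh.tolist()))
            assert set(got) == set(expected)
            for p, e in expected.items():
                assert got[p] == pytest.approx(e)


class TestIhh:
    def test_rectangle(self):
        curve = EHHCurve(0, np.array([0]), np.array([1.0]),
                         np.array([0, 10_000]), np.array([1.0, 1.0]))
        assert ihh(curve) == pytest.approx(10_000)

    def test_triangle(self):
        curve = EHHCurve(0, np.array([0]), np.array([1.0]),
                         np.array([0, 10_000]), np.array([1.0, 0.0]))
        assert ihh(curve) == pytest.approx(5_000)

    def test_three_point_trapezoid(self):
        curve = EHHCurve(
            0, np.array([0]), np.array([1.0]),
            np.array([0, 1000, 3000]), np.array([1.0, 0.5, 0.05]),
        )
        assert ihh(curve) == pytest.approx(1300.0)


class TestIhs:
    def test_symmetric_site_scores_zero_raw(self):
        # both alleles have identical decay patterns by mirror construction
        block = np.array(
            [[1, 1, 1], [1, 1, 0], [1, 0, 1], [1, 0, 0],
             [0, 1, 1], [0, 1, 0], [0, 0, 1], [0, 0, 0]], dtype=np.int8
        )
        hs = hapset(block, positions=[100, 200, 300])
        table = ihs(hs, min_maf=0.05)
        row = table[table.site == 0]
        assert row.raw.iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_neutral_cohort_standardization(self):
        """Bin-standardized scores have mean ~0 and sd ~1 over a neutral
        single-population cohort."""
        from riverpop.synthetic import PopulationModel, simulate_haplotypes

        pm = PopulationModel(n_pops=1, samples_per_pop=25, n_sites=3000,
                             chrom_length=15_000_000, fst=0.02,
                             ld_decay_bp=30_000, seed=5)
        truth = simulate_haplotypes(pm)
        hs = HaplotypeSet(truth.haplotypes, truth.positions)
        table = ihs(hs)
        scored = table[table.standardized]
        assert len(scored) > 1000
        assert abs(scored.ihs.mean()) < 0.05
        assert 0.9 <= scored.ihs.std() <= 1.1
        # per populated bin too, by construction of the standardization
        bins = (scored.maf / 0.025).astype(int)
        for _, grp in scored.groupby(bins):
            if len(grp) >= 30:
                assert abs(grp.ihs.mean()) < 0.05
                assert 0.85 <= grp.ihs.std() <= 1.15

    def test_sweep_focal_site_in_top_percentile(self, sweep_cohort):
        _, _, truth = sweep_cohort
        hs = HaplotypeSet(
            truth.haplotypes[np.repeat(truth.pop_labels == 0, 2)],
            truth.positions,
        )
        table = ihs(hs)
        focal = table[table.site == truth.sweep_site]
        assert len(focal) == 1
        rank = (table.ihs.abs() >= abs(focal.ihs.iloc[0])).mean()
        assert rank <= 0.01


class TestRsb:
    def test_identical_groups_score_zero_raw(self):
        rng = np.random.default_rng(2)
        hap = rng.integers(0, 2, size=(10, 30)).astype(np.int8)
        hs = hapset(hap)
        table = rsb(hs, hs)
        assert np.allclose(table.raw, 0.0)

    def test_swapping_groups_negates_raw(self):
        rng = np.random.default_rng(3)
        a = hapset(rng.integers(0, 2, size=(10, 30)).astype(np.int8))
        b = hapset(rng.integers(0, 2, size=(12, 30)).astype(np.int8))
        t_ab = rsb(a, b)
        t_ba = rsb(b, a)
        merged = t_ab.merge(t_ba, on="site", suffixes=("_ab", "_ba"))
        assert np.allclose(merged.raw_ab, -merged.raw_ba)

    def test_sweep_focal_site_extreme_with_positive_sign(self, sweep_cohort):
        _, _, truth = sweep_cohort
        hs_a = HaplotypeSet(
            truth.haplotypes[np.repeat(truth.pop_labels == 0, 2)],
            truth.positions,
        )
        hs_b = HaplotypeSet(
            truth.haplotypes[np.repeat(truth.pop_labels == 1, 2)],
            truth.positions,
        )
        table = rsb(hs_a, hs_b)
        focal = table[table.site == truth.sweep_site]
        assert len(focal) == 1
        rank = (table.rsb.abs() >= abs(focal.rsb.iloc[0])).mean()
        assert rank <= 0.01
        assert focal.rsb.iloc[0] > 0      # longer homozygosity in swept group


class TestCandidateRegions:
    def scores(self, entries):
        return pd.DataFrame(entries, columns=["pos", "neglog10_p"])

    def test_eight_extreme_markers_make_a_candidate(self):
        sc = self.scores([(1000 + 100 * i, 12.0) for i in range(8)])
        regions = candidate_regions(sc)
        assert len(regions) == 1
        assert regions.loc[0, "n_extreme"] == 8

    def test_seven_markers_do_not(self):
        sc = self.scores([(1000 + 100 * i, 12.0) for i in range(7)])
        assert candidate_regions(sc).empty

    def test_adjacent_windows_merge(self):
        sc = self.scores(
            [(1000 + 100 * i, 12.0) for i in range(8)]
            + [(11_000 + 100 * i, 12.0) for i in range(8)]
        )
        regions = candidate_regions(sc)
        assert len(regions) == 1
        assert (regions.loc[0, "start"], regions.loc[0, "end"]) == (1, 20_000)

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(4)
        sc = self.scores(
            [(int(p), float(v)) for p, v in
             zip(rng.integers(1, 200_000, 600),
                 rng.uniform(0, 20, 600))]
        )
        def covered(thr):
            windows = set()
            for r in candidate_regions(sc, threshold=thr).itertuples():
                windows.update(range(r.start, r.end, 10_000))
            return windows

        prev = None
        for thr in (5.0, 10.0, 15.0):
            now = covered(thr)
            if prev is not None:
                assert now <= prev      # no window appears as threshold rises
            prev = now


class TestBonferroni:
    @pytest.mark.parametrize(
        "alpha,n,expected",
        [(0.05, 1, 1.301), (0.05, 10**6, 7.301), (0.05, 3.2e7, 8.81)],
    )
    def test_closed_form(self, alpha, n, expected):
        assert bonferroni_log10(alpha, int(n)) == pytest.approx(expected,
                                                                abs=0.005)

    def test_band_for_genome_scale_tests(self):
        # tens of millions of tests put the threshold in the 8.8-9.1 band
        assert 8.8 <= bonferroni_log10(0.05, int(3.2e7)) <= 9.1
        assert 8.8 <= bonferroni_log10(0.05, int(6e7)) <= 9.1


class TestCrossSpeciesOverlap:
    def tab(self, entries):
        return pd.DataFrame(entries, columns=["pos", "neglog10_p"])

    def test_joint_score_is_min_of_species_maxima(self):
        a = self.tab([(5000, 5.0), (6000, 3.0)])
        b = self.tab([(5500, 2.0)])
        out = cross_species_overlap({"A": a, "B": b})
        assert len(out) == 1
        assert out.loc[0, "joint_score"] == pytest.approx(2.0)

    def test_window_missing_in_one_species_excluded(self):
        a = self.tab([(5000, 5.0), (15_000, 9.0)])
        b = self.tab([(5500, 2.0)])
        out = cross_species_overlap({"A": a, "B": b})
        assert len(out) == 1
        assert out.loc[0, "window_start"] == 1

    def test_identical_tables_reduce_to_per_window_max(self):
        a = self.tab([(5000, 5.0), (6000, 3.0), (15_000, 9.0)])
        out = cross_species_overlap({"A": a, "B": a.copy()})
        assert out["joint_score"].tolist() == [9.0, 5.0]
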