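"""Relatedness, dedup, nucleotide diversity, Fst, ROH and rate scaling."""

import math

import numpy as np
import pandas as pd
import pytest

from conftest import make_gm
from oracles import roh_reference_scanner, wc_theta_direct
from riverpop.datamodel import MISSING
from riverpop.diversity import (
    RohParams,
    dedup_related,
    detect_roh,
    pi_and_polymorphic,
    ritland_relatedness,
    scale_mutation_rate,
    wc_fst,
)


class TestRitland:
    def test_monomorphic_loci_give_undefined_sentinel(self):
        gm = make_gm(np.zeros((3, 10), dtype=np.int8))
        rel = ritland_relatedness(gm)
        assert rel.isna().all().all()

    def test_shared_rare_alleles_can_exceed_one(self):
        # two samples both carrying a very rare allele at many loci
        geno = np.zeros((20, 50), dtype=np.int8)
        geno[0, :] = 1
        geno[1, :] = 1
        rel = ritland_relatedness(make_gm(geno))
        assert rel.iloc[0, 1] > 1.0

    def test_parent_offspring_mean_near_half(self):
        """Monte-Carlo pedigree: 50 simulated parent-offspring pairs at
        5000 loci should average close to r = 0.5."""
        rng = np.random.default_rng(0)
        n_loci = 5000
        p = np.clip(rng.beta(0.8, 0.8, n_loci), 0.05, 0.95)
        estimates = []
        for _ in range(50):
            par = (rng.random((2, n_loci)) < p).astype(int)
            other = (rng.random((2, n_loci)) < p).astype(int)
            child = par[rng.integers(2, size=n_loci), np.arange(n_loci)] + other[0]
            gm = make_gm(np.vstack([par.sum(0), child]).astype(np.int8),
                         positions=np.arange(1, n_loci + 1) * 10)
            rel = ritland_relatedness(gm, freqs=p)
            estimates.append(rel.iloc[0, 1])
        assert 0.45 <= np.mean(estimates) <= 0.55

    def test_symmetric(self):
        rng = np.random.default_rng(1)
        geno = rng.integers(0, 3, size=(6, 300)).astype(np.int8)
        rel = ritland_relatedness(make_gm(geno))
        assert np.allclose(rel.to_numpy(), rel.to_numpy().T, equal_nan=True)


class TestDedup:
    def _rel(self, mat, names):
        return pd.DataFrame(np.array(mat, dtype=float), index=names,
                            columns=names)

    def test_related_pair_loses_one_member(self):
        rel = self._rel([[1, 0.2], [0.2, 1]], ["a", "b"])
        assert len(dedup_related(rel)) == 1

    def test_unrelated_cohort_untouched(self):
        rel = self._rel(np.eye(3) * 0.0 + np.full((3, 3), 0.05), list("abc"))
        assert dedup_related(rel) == ["a", "b", "c"]

    def test_related_triangle_keeps_exactly_one(self):
        m = np.full((3, 3), 0.3)
        rel = self._rel(m, list("abc"))
        retained = dedup_related(rel)
        assert len(retained) == 1    # brute force: any single survivor works

    def test_no_overcutoff_pair_survives(self):
        rng = np.random.default_rng(2)
        m = rng.uniform(-0.1, 0.3, (10, 10))
        m = (m + m.T) / 2
        rel = self._rel(m, [f"s{i}" for i in range(10)])
        retained = dedup_related(rel, 0.15)
        sub = rel.loc[retained, retained].to_numpy()
        np.fill_diagonal(sub, 0)
        assert (sub < 0.15).all()


class TestPi:
    def test_single_site_small_sample_correction(self):
        # 2 diploids both 0/1: p = 0.5, m = 4 -> pi = (4/3) * 0.5 = 0.6667
        gm = make_gm(np.array([[1], [1]], dtype=np.int8))
        meta = pd.DataFrame({"sample": ["s0", "s1"], "location": ["L", "L"]})
        row = pi_and_polymorphic(gm, meta, min_depth=None).iloc[0]
        assert row["pi"] == pytest.approx(2 / 3)
        assert row["n_polymorphic"] == 1

    def test_monomorphic_sites_dilute_mean_and_dont_count(self):
        geno = np.array([[1, 0], [1, 0]], dtype=np.int8)
        gm = make_gm(geno)
        meta = pd.DataFrame({"sample": ["s0", "s1"], "location": ["L", "L"]})
        row = pi_and_polymorphic(gm, meta, min_depth=None).iloc[0]
        assert row["pi"] == pytest.approx((2 / 3) / 2)
        assert row["n_polymorphic"] == 1

    def test_all_fixed_location_has_zero_pi(self):
        gm = make_gm(np.full((3, 5), 2, dtype=np.int8))
        meta = pd.DataFrame({"sample": [f"s{i}" for i in range(3)],
                             "location": "L"})
        row = pi_and_polymorphic(gm, meta, min_depth=None).iloc[0]
        assert row["pi"] == 0.0 and row["n_polymorphic"] == 0

    def test_single_sample_location_flagged(self):
        gm = make_gm(np.array([[1, 0]], dtype=np.int8))
        meta = pd.DataFrame({"sample": ["s0"], "location": ["L"]})
        row = pi_and_polymorphic(gm, meta, min_depth=None).iloc[0]
        assert not row["ok"] and math.isnan(row["pi"])

    def test_invariant_to_sample_order_and_allele_relabeling(self):
        rng = np.random.default_rng(3)
        geno = rng.integers(0, 3, size=(8, 100)).astype(np.int8)
        meta = pd.DataFrame({"sample": [f"s{i}" for i in range(8)],
                             "location": ["A"] * 4 + ["B"] * 4})
        base = pi_and_polymorphic(make_gm(geno), meta, min_depth=None)
        flipped = pi_and_polymorphic(make_gm(2 - geno), meta, min_depth=None)
        assert np.allclose(base["pi"], flipped["pi"])
        perm = rng.permutation(8)
        permuted = pi_and_polymorphic(
            make_gm(geno).take_samples(perm),
            meta.iloc[perm].reset_index(drop=True), min_depth=None,
        )
        assert np.allclose(base.set_index("location")["pi"],
                           permuted.set_index("location").loc[["A", "B"], "pi"])


class TestWcFst:
    def test_fixed_differences_give_theta_one(self):
        geno = np.vstack([np.zeros((4, 20)), np.full((4, 20), 2)]).astype(np.int8)
        res = wc_fst(make_gm(geno), [0] * 4 + [1] * 4)
        assert res.theta == pytest.approx(1.0)

    def test_identical_populations_give_theta_near_zero(self):
        rng = np.random.default_rng(4)
        block = rng.integers(0, 3, size=(40, 4000)).astype(np.int8)
        labels = rng.permutation([0] * 20 + [1] * 20)
        res = wc_fst(make_gm(block), labels)
        assert abs(res.theta) < 0.01

    def test_four_sample_instance_matches_direct_computation(self):
        # group 1: 0/0, 0/1 ; group 2: 1/1, 1/1
        gm = make_gm(np.array([[0], [1], [2], [2]], dtype=np.int8))
        res = wc_fst(gm, [0, 0, 1, 1])
        a, b, c, theta = wc_theta_direct([[0, 1], [2, 2]])
        assert res.a[0] == pytest.approx(a)
        assert res.b[0] == pytest.approx(b)
        assert res.c[0] == pytest.approx(c)
        assert res.theta == pytest.approx(theta)

    def test_random_sites_match_direct_computation(self):
        rng = np.random.default_rng(5)
        geno = rng.integers(0, 3, size=(12, 30)).astype(np.int8)
        labels = np.array([0] * 4 + [1] * 4 + [2] * 4)
        res = wc_fst(make_gm(geno), labels)
        for j in range(30):
            groups = [geno[labels == g, j].tolist() for g in range(3)]
            if len(set(sum(groups, []))) == 1:
                continue    # monomorphic: skipped by the estimator too
            a, b, c, theta = wc_theta_direct(groups)
            if np.isfinite(res.theta_site[j]):
                assert res.theta_site[j] == pytest.approx(theta)

    def test_invariance_to_label_order_and_allele_swap(self):
        rng = np.random.default_rng(6)
        geno = rng.integers(0, 3, size=(20, 200)).astype(np.int8)
        labels = np.array([0] * 10 + [1] * 10)
        t1 = wc_fst(make_gm(geno), labels).theta
        t2 = wc_fst(make_gm(geno), 1 - labels).theta
        t3 = wc_fst(make_gm(2 - geno), labels).theta
        assert t1 == pytest.approx(t2) == pytest.approx(t3)

    def test_empty_group_raises(self):
        gm = make_gm(np.zeros((4, 5), dtype=np.int8))
        with pytest.raises(ValueError):
            wc_fst(gm, [0, 0, 0, 0])


class TestRoh:
    def test_long_homozygous_run_is_single_segment(self):
        pos = np.linspace(1, 1_200_000, 100).astype(int)
        gm = make_gm(np.zeros((1, 100), dtype=np.int8), positions=pos)
        seg, summary = detect_roh(gm)
        assert len(seg) == 1
        assert seg.loc[0, "n_snps"] == 100
        assert summary.loc[0, "total_kb"] == pytest.approx(1200.0, rel=0.01)

    def test_two_hets_per_window_block_detection(self):
        pos = np.linspace(1, 1_200_000, 100).astype(int)
        geno = np.zeros((1, 100), dtype=np.int8)
        geno[0, ::20] = 1       # >= 2 hets in every 50-SNP window
        seg, _ = detect_roh(make_gm(geno, positions=pos))
        assert seg.empty

    def test_matches_reference_scanner_on_random_instances(self):
        """Oracle equivalence on 100 random 500-SNP single-sample
        instances, exhaustive window enumeration."""
        rng = np.random.default_rng(7)
        params = RohParams()
        for _ in range(100):
            m = 500
            geno = rng.choice(
                [0, 1, 2, MISSING], p=[0.55, 0.08, 0.32, 0.05], size=(1, m)
            ).astype(np.int8)
            # carve a homozygous stretch so segments actually occur
            s = rng.integers(0, m - 200)
            geno[0, s:s + 200] = rng.choice([0, 2], 200)
            pos = np.sort(rng.choice(6_000_000, m, replace=False)) + 1
            seg, _ = detect_roh(make_gm(geno, positions=pos), params)
            expected = roh_reference_scanner(geno[0].tolist(), pos.tolist())
            got = [(r.start, r.end, r.n_snps) for r in seg.itertuples()]
            assert got == expected

    def test_injected_segment_recovered(self, roh_cohort):
        truth, gm = roh_cohort
        want = truth.roh_segments.iloc[0]
        seg, _ = detect_roh(gm)
        mine = seg[seg["sample"] == gm.samples[want["sample"]]]
        overlap = 0
        for r in mine.itertuples():
            overlap += max(0, min(r.end, want.end) - max(r.start, want.start))
        assert overlap / (want.end - want.start) >= 0.90

    def test_adding_hets_never_lengthens_roh(self):
        pos = np.linspace(1, 2_000_000, 160).astype(int)
        geno = np.zeros((1, 160), dtype=np.int8)
        base_total = detect_roh(make_gm(geno, positions=pos))[1]["total_kb"][0]
        geno2 = geno.copy()
        geno2[0, [40, 80, 120]] = 1
        with_hets = detect_roh(make_gm(geno2, positions=pos))[1]["total_kb"][0]
        assert with_hets <= base_total

    def test_unsorted_sites_rejected(self):
        with pytest.raises(ValueError):
            make_gm(np.zeros((1, 3), dtype=np.int8), positions=[10, 5, 20])


class TestScaleMutationRate:
    @pytest.mark.parametrize(
        "base,ratio,expected",
        [(8.0e-9, 1.73, 1.4e-8), (8.0e-9, 0.80, 6.4e-9), (3.3e-8, 1.0, 3.3e-8)],
    )
    def test_two_significant_figures(self, base, ratio, expected):
        assert scale_mutation_rate(base, ratio) == pytest.approx(expected, rel=1e-9)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            scale_mutation_rate(0.0, 1.0)
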