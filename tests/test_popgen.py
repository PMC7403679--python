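"""Unit tests for per-site and per-window population-genetic statistics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nichescan import (allele_counts, hard_filter_arrays, hudson_site,
                       make_windows, nucleotide_diversity, tajimas_d,
                       weir_cockerham_site, window_fst)
from nichescan.popgen import DataError, _tajima_constants, default_min_sites

from conftest import counts_from_arrays


# ---------------------------------------------------------------------------
# allele counts
# ---------------------------------------------------------------------------

class TestAlleleCounts:
    def test_simple_tally(self, random_genotypes):
        ac = allele_counts(random_genotypes)
        assert ac.populations == ["popA", "popB"]
        # brute-force per-sample loop oracle
        for j, pop in enumerate(ac.populations):
            cols = [i for i, p in enumerate(random_genotypes.sample_pops) if p == pop]
            for s in range(random_genotypes.n_snps):
                gts = [random_genotypes.geno[s, c] for c in cols]
                called = [g for g in gts if g >= 0]
                assert ac.counts[s, j] == sum(called)
                assert ac.totals[s, j] == 2 * len(called)
                assert ac.hets[s, j] == sum(1 for g in called if g == 1)

    def test_totals_even_and_bounded(self, random_genotypes):
        ac = allele_counts(random_genotypes)
        assert (ac.totals % 2 == 0).all()
        assert (ac.counts >= 0).all() and (ac.counts <= ac.totals).all()

    def test_all_missing_site_gives_zero_total(self):
        import nichescan
        gm = nichescan.GenotypeMatrix(
            contig=np.array(["c"], dtype=object), pos=np.array([0]),
            geno=np.array([[-1, -1]], dtype=np.int8),
            samples=["s1", "s2"],
            sample_pops=np.array(["popA", "popA"], dtype=object))
        ac = allele_counts(gm)
        assert ac.totals[0, 0] == 0


# ---------------------------------------------------------------------------
# Hudson estimator
# ---------------------------------------------------------------------------

class TestHudsonSite:
    def test_fixed_difference_approaches_one(self):
        num, den = hudson_site([1000], [1000], [0], [1000])
        assert den[0] == pytest.approx(1.0)
        assert num[0] / den[0] == pytest.approx(1.0, abs=1e-2)

    def test_equal_frequencies_near_zero_large_n(self):
        num, _ = hudson_site([500], [1000], [500], [1000])
        assert abs(num[0]) < 1e-3

    def test_hand_worked_example(self):
        # p1=0.2, p2=0.8, n1=n2=10 alleles
        num, den = hudson_site([2], [10], [8], [10])
        assert num[0] == pytest.approx(0.36 - 2 * 0.16 / 9, abs=1e-12)
        assert den[0] == pytest.approx(0.68)
        assert num[0] / den[0] == pytest.approx(0.4771241830065359, abs=1e-10)

    def test_same_fixed_allele_contributes_nothing(self):
        num, den = hudson_site([0], [10], [0], [10])
        assert num[0] == 0.0 and den[0] == 0.0

    def test_small_sample_skipped(self):
        num, den = hudson_site([1], [2], [5], [10])
        assert num[0] == 0.0 and den[0] == 0.0

    @given(st.integers(0, 20), st.integers(0, 20))
    @settings(deadline=None, max_examples=50)
    def test_allele_label_swap_invariance(self, c1, c2):
        t = 20
        n1, d1 = hudson_site([c1], [t], [c2], [t])
        n2, d2 = hudson_site([t - c1], [t], [t - c2], [t])
        assert n1[0] == pytest.approx(n2[0], abs=1e-12)
        assert d1[0] == pytest.approx(d2[0], abs=1e-12)


class TestWeirCockerham:
    def test_identical_populations_near_zero(self):
        num, den = weir_cockerham_site([10], [40], [6], [10], [40], [6])
        assert num[0] / den[0] == pytest.approx(0.0, abs=0.05)

    def test_fixed_difference_is_one(self):
        num, den = weir_cockerham_site([40], [40], [0], [0], [40], [0])
        assert num[0] / den[0] == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# windows
# ---------------------------------------------------------------------------

class TestMakeWindows:
    def test_scan_tiling_with_terminal_partial(self):
        w = make_windows({"c": 5000}, 2000)
        assert list(zip(w.start, w.end)) == [(0, 2000), (2000, 4000), (4000, 5000)]
        assert list(w.partial) == [False, False, True]

    def test_sliding_full_windows_only(self):
        w = make_windows({"c": 1000}, 500, 100)
        assert list(w.start) == [0, 100, 200, 300, 400, 500]
        assert all(e - s == 500 for s, e in zip(w.start, w.end))

    def test_contig_shorter_than_window(self):
        w = make_windows({"c": 300}, 2000)
        assert list(zip(w.start, w.end)) == [(0, 300)]
        assert w.partial[0]

    def test_step_must_divide_size(self):
        with pytest.raises(DataError):
            make_windows({"c": 1000}, 500, 300)

    def test_min_sites_defaults(self):
        assert default_min_sites(2000) == 5
        assert default_min_sites(500) == 2


class TestWindowFst:
    def test_single_site_window_modes_agree(self):
        ac = counts_from_arrays([10], [[2, 8]], [[10, 10]])
        w = make_windows({"chr1": 100}, 100)
        for mode in ("weighted", "unweighted"):
            t = window_fst(ac, "popA", "popB", w, mode=mode, min_sites=1)
            assert t.df["fst"][0] == pytest.approx(0.4771241830065359, abs=1e-10)

    def test_weighted_equals_ratio_of_sums(self):
        ac = counts_from_arrays([10, 20], [[2, 8], [5, 9]], [[10, 10], [10, 10]])
        w = make_windows({"chr1": 100}, 100)
        t = window_fst(ac, "popA", "popB", w, mode="weighted", min_sites=1)
        nums, dens = hudson_site(ac.counts[:, 0], ac.totals[:, 0],
                                 ac.counts[:, 1], ac.totals[:, 1])
        assert t.df["fst"][0] == pytest.approx(nums.sum() / dens.sum(), abs=1e-12)
        tu = window_fst(ac, "popA", "popB", w, mode="unweighted", min_sites=1)
        assert tu.df["fst"][0] == pytest.approx(np.mean(nums / dens), abs=1e-12)

    def test_equal_denominator_sites_make_modes_agree(self):
        # symmetric frequency pairs share one denominator value
        ac = counts_from_arrays([10, 20], [[2, 8], [8, 2]], [[10, 10], [10, 10]])
        w = make_windows({"chr1": 100}, 100)
        tw = window_fst(ac, "popA", "popB", w, mode="weighted", min_sites=1)
        tu = window_fst(ac, "popA", "popB", w, mode="unweighted", min_sites=1)
        assert tw.df["fst"][0] == pytest.approx(tu.df["fst"][0], abs=1e-12)

    def test_identical_populations_nonpositive(self):
        rng = np.random.default_rng(0)
        c = rng.integers(1, 9, size=40)
        ac = counts_from_arrays(np.arange(40) * 10,
                                np.column_stack([c, c]),
                                np.full((40, 2), 10))
        w = make_windows({"chr1": 400}, 200)
        t = window_fst(ac, "popA", "popB", w, min_sites=1)
        assert (t.valid["fst"] <= 1e-12).all()

    def test_sparse_window_flagged_invalid(self):
        ac = counts_from_arrays([10], [[2, 8]], [[10, 10]])
        w = make_windows({"chr1": 100}, 100)
        t = window_fst(ac, "popA", "popB", w, min_sites=5)
        assert not t.df["valid"][0]

    def test_windowed_values_match_per_site_loop(self):
        """Windowed F_ST equals a brute-force per-site loop (random input)."""
        rng = np.random.default_rng(42)
        n = 300
        pos = np.sort(rng.choice(3000, n, replace=False))
        totals = np.full((n, 2), 20)
        counts = rng.integers(0, 21, size=(n, 2))
        ac = counts_from_arrays(pos, counts, totals)
        w = make_windows({"chr1": 3000}, 250)
        t = window_fst(ac, "popA", "popB", w, mode="weighted", min_sites=1)
        for k in range(len(w)):
            num_sum = den_sum = 0.0
            for s in range(n):
                if not (w.start[k] <= pos[s] < w.end[k]):
                    continue
                nn, dd = hudson_site([counts[s, 0]], [20], [counts[s, 1]], [20])
                num_sum += nn[0]
                den_sum += dd[0]
            if den_sum > 0:
                assert t.df["fst"][k] == pytest.approx(num_sum / den_sum, abs=1e-10)


# ---------------------------------------------------------------------------
# diversity / Tajima's D
# ---------------------------------------------------------------------------

class TestDiversity:
    def test_monomorphic_window_zero(self):
        ac = counts_from_arrays([10, 20], [[0, 0], [10, 10]], [[10, 10], [10, 10]])
        w = make_windows({"chr1": 100}, 100)
        assert nucleotide_diversity(ac, "popA", w)["pi"][0] == 0.0

    def test_single_snp_worked_example(self):
        # p = 0.5 at n = 80 alleles in a 2000-bp window
        ac = counts_from_arrays([100], [[40, 0]], [[80, 0]])
        w = make_windows({"chr1": 2000}, 2000)
        pi = nucleotide_diversity(ac, "popA", w)["pi"][0]
        assert pi == pytest.approx((2 * 0.25 * 80 / 79) / 2000, abs=1e-12)

    def test_label_swap_invariance(self):
        w = make_windows({"chr1": 100}, 100)
        a = counts_from_arrays([10], [[3, 0]], [[10, 0]])
        b = counts_from_arrays([10], [[7, 0]], [[10, 0]])
        assert (nucleotide_diversity(a, "popA", w)["pi"][0]
                == pytest.approx(nucleotide_diversity(b, "popA", w)["pi"][0]))


class TestTajimasD:
    def test_no_segregating_sites_undefined(self):
        ac = counts_from_arrays([10], [[10, 0]], [[10, 10]])
        w = make_windows({"chr1": 100}, 100)
        assert np.isnan(tajimas_d(ac, "popA", w)["tajimas_d"][0])

    def test_theta_estimator_equality_gives_zero(self):
        # construct S sites whose summed heterozygosity equals S/a1 exactly:
        # impossible with integer counts, so check the centering algebraically
        n = 10
        k = _tajima_constants(n)
        S = 5
        pi_sum = S / k["a1"]
        D = (pi_sum - S / k["a1"]) / np.sqrt(k["e1"] * S + k["e2"] * S * (S - 1))
        assert D == 0.0

    def test_singleton_window_matches_brute_force(self):
        """n=10, S=5, singletons only: brute-force from the haplotype table."""
        S, n = 5, 10
        ac = counts_from_arrays(np.arange(S) * 10, [[1, 0]] * S, [[n, 0]] * S)
        w = make_windows({"chr1": 100}, 100)
        d = tajimas_d(ac, "popA", w, min_segregating=3)["tajimas_d"][0]
        # oracle: haplotype table with one distinct carrier per site
        hap = np.zeros((n, S), dtype=int)
        for s in range(S):
            hap[s, s] = 1
        pair_diffs = [np.sum(hap[i] != hap[j])
                      for i in range(n) for j in range(i + 1, n)]
        pi = np.mean(pair_diffs) * 1.0
        a1 = sum(1 / i for i in range(1, n))
        a2 = sum(1 / i ** 2 for i in range(1, n))
        b1 = (n + 1) / (3 * (n - 1))
        b2 = 2 * (n ** 2 + n + 3) / (9 * n * (n - 1))
        c1 = b1 - 1 / a1
        c2 = b2 - (n + 2) / (a1 * n) + a2 / a1 ** 2
        e1, e2 = c1 / a1, c2 / (a1 ** 2 + a2)
        expected = (pi - S / a1) / np.sqrt(e1 * S + e2 * S * (S - 1))
        assert d == pytest.approx(expected, abs=1e-10)

    def test_below_minimum_segregating_excluded(self):
        ac = counts_from_arrays([10, 20], [[1, 0], [2, 0]], [[10, 0], [10, 0]])
        w = make_windows({"chr1": 100}, 100)
        assert np.isnan(tajimas_d(ac, "popA", w, min_segregating=3)["tajimas_d"][0])


# ---------------------------------------------------------------------------
# hard filter
# ---------------------------------------------------------------------------

class TestHardFilter:
    def test_clean_record_retained(self):
        keep, rep = hard_filter_arrays([5.0], [1.0], [10.0])
        assert keep[0] and rep.n_removed == 0

    def test_qd_threshold_removes(self):
        keep, rep = hard_filter_arrays([1.9], [1.0], [10.0])
        assert not keep[0] and rep.removed_qd == 1

    def test_boundaries_are_strict(self):
        # QD == 2.0, SOR == 3.0, FS == 200 all pass (strict inequalities)
        keep, rep = hard_filter_arrays([2.0], [3.0], [200.0])
        assert keep[0]

    def test_missing_policy(self):
        keep_pass, _ = hard_filter_arrays([np.nan], [1.0], [1.0], "pass")
        keep_fail, _ = hard_filter_arrays([np.nan], [1.0], [1.0], "fail")
        assert keep_pass[0] and not keep_fail[0]

    def test_six_record_toy_counts(self):
        """Two single-criterion violations each + one double violation."""
        qd = [5.0, 1.0, 5.0, 1.5, 5.0, 5.0]
        sor = [1.0, 1.0, 1.0, 5.0, 1.0, 1.0]
        fs = [10.0, 10.0, 300.0, 10.0, 10.0, 10.0]
        keep, rep = hard_filter_arrays(qd, sor, fs)
        assert keep.sum() == 3
        assert rep.n_removed == 3
        assert rep.removed_qd == 2 and rep.removed_sor == 1 and rep.removed_fs == 1
        assert rep.removed_qd + rep.removed_sor + rep.removed_fs >= rep.n_removed
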