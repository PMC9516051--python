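"""Exact tests against enumeration oracles and scipy cross-checks."""

from math import comb

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from demether import stats


def fisher_oracle(a, b, c, d) -> float:
    """Exact-integer enumeration over all tables with the observed margins."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        return 1.0
    lo, hi = max(0, c1 - r2), min(r1, c1)
    nums = [comb(r1, k) * comb(r2, c1 - k) for k in range(lo, hi + 1)]
    obs = nums[a - lo]
    return sum(p for p in nums if p <= obs) / comb(n, c1)


class TestFisher:
    def test_balanced_table(self):
        assert stats.fisher_exact_2x2(5, 5, 5, 5) == pytest.approx(1.0, rel=1e-9)

    def test_genotyping_table_vs_enumeration(self):
        # 20/20 vs 9/28 plants inheriting an allele: enumeration over the
        # 21 admissible tables with these margins
        p = stats.fisher_exact_2x2(20, 0, 9, 19)
        assert p == pytest.approx(fisher_oracle(20, 0, 9, 19), rel=1e-9)
        assert p < 1e-4

    def test_row_and_column_swap_symmetry(self):
        for a, b, c, d in [(3, 7, 12, 2), (0, 9, 4, 4), (6, 6, 1, 11)]:
            p = stats.fisher_exact_2x2(a, b, c, d)
            assert stats.fisher_exact_2x2(c, d, a, b) == pytest.approx(p, rel=1e-12)
            assert stats.fisher_exact_2x2(b, a, d, c) == pytest.approx(p, rel=1e-12)

    def test_degenerate_margin_p_one(self):
        assert stats.fisher_exact_2x2(0, 0, 3, 4) == 1.0

    @given(st.integers(0, 25), st.integers(0, 25), st.integers(0, 25), st.integers(0, 25))
    @settings(max_examples=300, deadline=None)
    def test_matches_scipy(self, a, b, c, d):
        if a + b + c + d == 0:
            return
        p = stats.fisher_exact_2x2(a, b, c, d)
        assert p == pytest.approx(sps.fisher_exact([[a, b], [c, d]])[1], rel=1e-6, abs=1e-12)


class TestChi2Yates:
    def test_balanced_table(self):
        res = stats.chi2_yates(50, 50, 50, 50)
        assert res.statistic == 0 and res.pvalue == 1

    def test_sirna_dmr_table_hand_formula(self):
        # 19% vs 33% of 18,464 regions with detectable siRNAs
        a, b, c, d = 3508, 14956, 6093, 12371
        n = a + b + c + d
        expected = n * (abs(a * d - b * c) - n / 2) ** 2 / (
            (a + b) * (c + d) * (a + c) * (b + d)
        )
        res = stats.chi2_yates(a, b, c, d)
        assert res.statistic == pytest.approx(expected, rel=1e-12)
        assert res.pvalue < 1e-4

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            stats.chi2_yates(0, 0, 5, 5)

    @given(st.integers(1, 50), st.integers(1, 50), st.integers(1, 50), st.integers(1, 50))
    @settings(max_examples=200, deadline=None)
    def test_matches_scipy_and_never_exceeds_uncorrected(self, a, b, c, d):
        res = stats.chi2_yates(a, b, c, d)
        scipy_res = sps.chi2_contingency([[a, b], [c, d]], correction=True)
        assert res.statistic == pytest.approx(scipy_res.statistic, rel=1e-10, abs=1e-12)
        uncorrected = sps.chi2_contingency([[a, b], [c, d]], correction=False).statistic
        assert res.statistic <= uncorrected + 1e-12


class TestBinomial:
    def test_mode_gives_p_one(self):
        assert stats.binomial_two_sided(5, 10, 0.5) == pytest.approx(1.0, rel=1e-9)

    def test_nine_of_ten_vs_enumeration(self):
        pmf = [comb(10, i) * 0.5**10 for i in range(11)]
        expected = sum(p for p in pmf if p <= pmf[9] * (1 + 1e-7))
        assert stats.binomial_two_sided(9, 10, 0.5) == pytest.approx(expected, rel=1e-12)

    @given(st.integers(0, 40), st.integers(1, 40))
    @settings(max_examples=200, deadline=None)
    def test_symmetry_at_half(self, k, n):
        if k > n:
            return
        p1 = stats.binomial_two_sided(k, n, 0.5)
        p2 = stats.binomial_two_sided(n - k, n, 0.5)
        assert p1 == pytest.approx(p2, rel=1e-12)

    @given(st.integers(0, 60), st.integers(1, 60), st.sampled_from([0.1, 0.25, 0.5, 0.75]))
    @settings(max_examples=300, deadline=None)
    def test_matches_scipy_binomtest(self, k, n, p0):
        if k > n:
            return
        p = stats.binomial_two_sided(k, n, p0)
        assert p == pytest.approx(sps.binomtest(k, n, p0).pvalue, rel=1e-6, abs=1e-12)


class TestTTest:
    def test_identical_groups(self):
        res = stats.t_two_sample([1, 2, 3], [1, 2, 3])
        assert res.pvalue == 1.0

    def test_hand_formula(self):
        x = np.array([1.0, 2.0, 3.0])
        y = x + 10
        res = stats.t_two_sample(x, y)
        sp2 = (x.var(ddof=1) * 2 + y.var(ddof=1) * 2) / 4
        expected = (x.mean() - y.mean()) / np.sqrt(sp2 * (2 / 3))
        assert res.statistic == pytest.approx(expected, rel=1e-12)

    def test_swap_negates_statistic(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(0, 1, 10), rng.normal(1, 2, 14)
        r1 = stats.t_two_sample(x, y)
        r2 = stats.t_two_sample(y, x)
        assert r1.statistic == pytest.approx(-r2.statistic)
        assert r1.pvalue == pytest.approx(r2.pvalue)

    def test_matches_scipy(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(0, 1, 8), rng.normal(0.8, 1, 12)
        res = stats.t_two_sample(x, y)
        sp = sps.ttest_ind(x, y)
        assert res.statistic == pytest.approx(sp.statistic, rel=1e-12)
        assert res.pvalue == pytest.approx(sp.pvalue, rel=1e-12)
        welch = stats.t_two_sample(x, y, welch=True)
        spw = sps.ttest_ind(x, y, equal_var=False)
        assert welch.pvalue == pytest.approx(spw.pvalue, rel=1e-12)

    def test_degenerate_zero_variance(self):
        res = stats.t_two_sample([2, 2], [5, 5])
        assert res.degenerate and res.pvalue == 0.0


class TestSegregation:
    def test_single_heterozygous_locus(self):
        parent = stats.Parent((0,), (1,))
        probs = stats.gamete_probabilities(parent, ())
        assert probs == {(0,): 0.5, (1,): 0.5}

    def test_two_unlinked_loci_double_mutant_quarter(self):
        parent = stats.Parent((1, 1), (0, 0))
        probs = stats.gamete_probabilities(parent, (None,))
        # brute-force enumeration of the 4 equally likely gamete classes
        assert probs[(1, 1)] == pytest.approx(0.25)
        assert sum(probs.values()) == pytest.approx(1.0)

    def test_complete_linkage_parental_only(self):
        parent = stats.Parent((1, 1), (0, 0))
        probs = stats.gamete_probabilities(parent, (0.0,))
        assert set(k for k, v in probs.items() if v > 0) == {(1, 1), (0, 0)}

    def test_defective_kernel_expectation_one_in_four(self):
        # double heterozygous mother x wild-type father; defective iff the
        # megagametophyte carries both mutant alleles
        model = stats.CrossModel(
            loci=("mdr1", "dng102"),
            mother=stats.Parent((1, 1), (0, 0)),
            father=stats.Parent((0, 0), (0, 0)),
            map_distances=(None,),
        )
        probs = stats.phenotype_probabilities(
            model, lambda g: "defective" if g[0][0] == 1 and g[1][0] == 1 else "normal"
        )
        assert probs["defective"] == pytest.approx(0.25)
        assert probs["normal"] == pytest.approx(0.75)

    def test_nonfluorescent_control_expectation(self):
        # father heterozygous for two unlinked GFP markers x non-GFP mother:
        # a quarter of kernels inherit neither insertion
        model = stats.CrossModel(
            loci=("gfpA", "gfpB"),
            mother=stats.Parent((0, 0), (0, 0)),
            father=stats.Parent((1, 1), (0, 0)),
            map_distances=(None,),
        )
        probs = stats.phenotype_probabilities(
            model, lambda g: "dark" if g[0][1] == 0 and g[1][1] == 0 else "fluorescent"
        )
        assert probs["dark"] == pytest.approx(0.25)

    def test_selection_renormalizes(self):
        model = stats.CrossModel(
            loci=("m",),
            mother=stats.Parent((1,), (0,)),
            father=stats.Parent((1,), (1,)),
            selection=lambda g: g[0] == (1, 1),
        )
        probs = stats.segregation_expectation(model)
        assert probs == {((1, 1),): 1.0}

    @given(st.integers(1, 3), st.integers(0, 10))
    @settings(max_examples=50, deadline=None)
    def test_probabilities_sum_to_one(self, n_loci, seed):
        rng = np.random.default_rng(seed)
        hap = lambda: tuple(int(x) for x in rng.integers(0, 2, n_loci))
        dists = tuple(
            None if rng.random() < 0.5 else float(rng.random()) for _ in range(n_loci - 1)
        )
        model = stats.CrossModel(
            loci=tuple(f"l{i}" for i in range(n_loci)),
            mother=stats.Parent(hap(), hap()),
            father=stats.Parent(hap(), hap()),
            map_distances=dists,
        )
        probs = stats.segregation_expectation(model)
        assert sum(probs.values()) == pytest.approx(1.0)

    def test_mismatched_linkage_specification_rejected(self):
        with pytest.raises(ValueError):
            stats.CrossModel(
                loci=("a", "b", "c"),
                mother=stats.Parent((0, 0, 0), (1, 1, 1)),
                father=stats.Parent((0, 0, 0), (0, 0, 0)),
                map_distances=(None,),
            )
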