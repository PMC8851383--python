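"""Association statistics: CATT against permutation and regression
oracles, chi-square tests, PIC, heterozygosity, rank tests, and the
spurious-linkage model."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sexlink import (
    SexRegistry,
    catt,
    chisq_goodness_of_fit,
    chisq_homogeneity,
    expected_spurious,
    heterozygosity_profile,
    kruskal_wallis,
    nemenyi_posthoc,
    pic,
    required_sample_size,
    round_sig,
    spurious_probability,
)
from sexlink.codes import HET, MISSING, REF_HOM, Sex
from sexlink.stats import allele_frequency, catt_table
from tests.conftest import make_snp_matrix


def permutation_p(table: np.ndarray, n_perms: int, rng: np.random.Generator,
                  weights=(0.0, 1.0, 2.0)) -> float:
    """Conditional permutation p for the trend statistic: redraw the
    case row from the multivariate hypergeometric fixing both margins."""
    table = np.asarray(table, dtype=float)
    w = np.asarray(weights[: table.shape[1]])
    n_i = table.sum(axis=0)
    N, R = table.sum(), table[0].sum()
    var = N * (w**2 @ n_i) - (w @ n_i) ** 2
    obs = N * (N * (table[0] @ w) - R * (w @ n_i)) ** 2 / (R * (N - R) * var)
    draws = rng.multivariate_hypergeometric(n_i.astype(int), int(R), size=n_perms)
    stats = (N * (N * (draws @ w) - R * (w @ n_i)) ** 2) / (R * (N - R) * var)
    return float((stats >= obs - 1e-9).mean())


class TestCatt:
    def test_no_trend_gives_zero(self):
        res = catt(np.array([[5, 5, 5], [5, 5, 5]]))
        assert res.statistic == pytest.approx(0.0) and res.p_value == pytest.approx(1.0)

    def test_perfect_binary_separation_statistic_is_n(self):
        """15 males all HET vs 15 females all REF_HOM: the N-scaled
        trend statistic equals N = 30, and the exact permutation p is
        2 / C(30, 15) (only the two perfect splits reach the maximum)."""
        table = np.array([[0, 15, 0], [15, 0, 0]])
        res = catt(table)
        assert res.statistic == pytest.approx(30.0)
        # exact conditional p by full enumeration of the case row under
        # fixed margins: only the two perfect splits reach T = 30
        w = np.array([0.0, 1.0, 2.0])
        n_i = table.sum(axis=0)
        N, R = 30, 15
        var = N * (w**2 @ n_i) - (w @ n_i) ** 2
        p_exact = 0.0
        for r_het in range(16):  # case row is (15 - r_het, r_het, 0)
            r = np.array([15 - r_het, r_het, 0.0])
            t = N * (N * (r @ w) - R * (w @ n_i)) ** 2 / (R * (N - R) * var)
            if t >= 30.0 - 1e-9:
                p_exact += (math.comb(15, r_het) * math.comb(15, 15 - r_het)
                            / math.comb(30, 15))
        assert p_exact == pytest.approx(2 / math.comb(30, 15))
        assert res.p_value < 1e-6

    def test_all_one_category_is_degenerate(self):
        res = catt(np.array([[15, 0, 0], [15, 0, 0]]))
        assert res.degenerate and res.p_value == 1.0

    def test_statistic_equals_score_regression_oracle(self):
        """The trend statistic equals N * r^2 where r is the Pearson
        correlation between the dosage score and the case indicator."""
        rng = np.random.default_rng(4)
        for _ in range(20):
            table = rng.integers(0, 8, size=(2, 3)).astype(float)
            if table.sum(axis=1).min() < 1:
                continue
            res = catt(table)
            if res.degenerate:
                continue
            scores, cases = [], []
            for row, case in ((0, 1), (1, 0)):
                for j, w in enumerate((0, 1, 2)):
                    scores += [w] * int(table[row, j])
                    cases += [case] * int(table[row, j])
            r = np.corrcoef(scores, cases)[0, 1]
            assert res.statistic == pytest.approx(len(scores) * r**2, abs=1e-9)

    @given(a=st.floats(0.1, 10), b=st.floats(-100, 100))
    @settings(max_examples=30, deadline=None)
    def test_affine_weight_invariance(self, a, b):
        table = np.array([[8, 4, 2], [3, 6, 7]])
        base = catt(table, weights=(0.0, 1.0, 2.0))
        scaled = catt(table, weights=(b, a + b, 2 * a + b))
        assert scaled.statistic == pytest.approx(base.statistic, rel=1e-9)

    def test_tail_pvalues_agree_with_permutation_at_mc_resolution(self):
        """For strongly separated tables both the chi-square and the
        permutation p are indistinguishable from zero at 1e5-draw
        resolution."""
        rng = np.random.default_rng(1)
        table = np.array([[1, 6, 8], [13, 2, 0]])
        res = catt(table)
        p_perm = permutation_p(table, 100_000, rng)
        assert res.p_value < 1e-4 and p_perm <= 3e-4

    @pytest.mark.parametrize("table,weights,err", [
        ([[1, -2, 3], [1, 1, 1]], None, "negative"),
        ([[1, 2, 3], [1, 1, 1]], (0, 2, 1), "increasing"),
        ([[1, 2], [1, 1], [0, 0]], None, "2 x k"),
    ])
    def test_invalid_inputs(self, table, weights, err):
        with pytest.raises(ValueError, match=err):
            catt(np.array(table), weights=weights)

    def test_catt_table_counts_exclude_missing(self):
        calls = np.array([HET, HET, MISSING, REF_HOM, REF_HOM, MISSING])
        is_male = np.array([True, True, True, False, False, False])
        table = catt_table(calls, is_male, "SNP")
        assert table.tolist() == [[0, 2, 0], [2, 0, 0]]


class TestChiSquare:
    def test_exact_fit_gives_zero(self):
        res = chisq_goodness_of_fit(np.array([10, 20, 10]), np.array([0.25, 0.5, 0.25]))
        assert res.statistic == pytest.approx(0.0)

    def test_hwe_example_matches_hand_computation(self):
        """Counts (18,12,0) against HWE at allele frequency 0.8 (for the
        REF allele): expected (19.2, 9.6, 1.2), chi-square = 1.875."""
        props = np.array([0.8**2, 2 * 0.8 * 0.2, 0.2**2])
        res = chisq_goodness_of_fit(np.array([18, 12, 0]), props)
        hand = (18 - 19.2) ** 2 / 19.2 + (12 - 9.6) ** 2 / 9.6 + (0 - 1.2) ** 2 / 1.2
        assert res.statistic == pytest.approx(hand)
        assert res.df == 2

    def test_single_category_degenerate(self):
        res = chisq_goodness_of_fit(np.array([30, 0]), np.array([1.0, 0.0]))
        assert res.degenerate and res.df == 0

    def test_homogeneity_identical_rows(self):
        res = chisq_homogeneity(np.array([[10, 5], [10, 5]]))
        assert res.statistic == pytest.approx(0.0) and res.p_value == pytest.approx(1.0)

    def test_homogeneity_perfect_association(self):
        res = chisq_homogeneity(np.array([[10, 0], [0, 10]]))
        assert res.statistic == pytest.approx(20.0) and res.df == 1

    def test_homogeneity_drops_zero_margins(self):
        with_zeros = np.array([[10, 0, 5], [8, 0, 7], [0, 0, 0]])
        reduced = np.array([[10, 5], [8, 7]])
        assert chisq_homogeneity(with_zeros).statistic == \
            pytest.approx(chisq_homogeneity(reduced).statistic)


class TestPic:
    @pytest.mark.parametrize("p,expected", [(0.5, 0.5), (1.0, 0.0), (0.0, 0.0), (0.25, 0.375)])
    def test_known_values(self, p, expected):
        assert pic(p) == pytest.approx(expected)

    @given(p=st.floats(0.0, 1.0))
    @settings(max_examples=50, deadline=None)
    def test_symmetry_and_maximum(self, p):
        assert pic(p) == pytest.approx(pic(1 - p), abs=1e-12)
        assert pic(p) <= 0.5 + 1e-12

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            pic(1.2)


class TestHeterozygosity:
    def test_toy_profile_matches_enumeration(self):
        inds = ["m1", "m2", "f1", "f2"]
        matrix = make_snp_matrix([
            [HET, HET, REF_HOM, HET],
            [HET, REF_HOM, REF_HOM, MISSING],
            [HET, REF_HOM, REF_HOM, REF_HOM],
        ], inds)
        reg = SexRegistry({"m1": Sex.MALE, "m2": Sex.MALE,
                           "f1": Sex.FEMALE, "f2": Sex.FEMALE})
        prof = heterozygosity_profile(matrix, reg, matrix.locus_ids)
        assert prof.per_individual == {"m1": 1.0, "m2": pytest.approx(1 / 3),
                                       "f1": 0.0, "f2": 0.5}
        assert prof.male_mean == pytest.approx((1.0 + 1 / 3) / 2)
        assert prof.male_sd == pytest.approx(np.std([1.0, 1 / 3], ddof=1))
        assert prof.female_mean == pytest.approx(0.25)

    def test_unscored_individual_excluded(self):
        inds = ["m1", "f1", "f2"]
        matrix = make_snp_matrix([[HET, REF_HOM, MISSING]], inds)
        reg = SexRegistry({"m1": Sex.MALE, "f1": Sex.FEMALE, "f2": Sex.FEMALE})
        prof = heterozygosity_profile(matrix, reg, matrix.locus_ids)
        assert prof.excluded == ["f2"]
        assert "f2" not in prof.per_individual

    def test_empty_candidate_set_rejected(self):
        matrix = make_snp_matrix([[HET, REF_HOM]], ["a", "b"])
        reg = SexRegistry({"a": Sex.MALE, "b": Sex.FEMALE})
        with pytest.raises(ValueError):
            heterozygosity_profile(matrix, reg, [])


class TestRankTests:
    def test_identical_groups_h_zero(self):
        res = kruskal_wallis([np.ones(5), np.ones(4)])
        assert res.statistic == 0.0 and res.p_value == 1.0 and res.degenerate

    def test_h_matches_rank_sum_formula(self):
        """Groups (1,2,3) vs (4,5,6): no ties, so
        H = 12/(N(N+1)) * sum(R_g^2/n_g) - 3(N+1) = 27/7."""
        groups = [np.array([1.0, 2.0, 3.0]), np.array([4.0, 5.0, 6.0])]
        res = kruskal_wallis(groups)
        hand = 12 / (6 * 7) * (6**2 / 3 + 15**2 / 3) - 3 * 7
        assert res.statistic == pytest.approx(hand)

    def test_nemenyi_matrix_shape_and_symmetry(self):
        groups = [np.array([1.0, 2, 3, 10]), np.array([4.0, 5, 6]), np.array([7.0, 8, 9])]
        pmat = nemenyi_posthoc(groups)
        assert pmat.shape == (3, 3)
        assert np.allclose(pmat, pmat.T)
        assert np.allclose(np.diag(pmat), 1.0)
        assert ((0 <= pmat) & (pmat <= 1)).all()

    def test_nemenyi_matches_rank_arithmetic(self):
        """Two groups, no ties: q = (Rbar1-Rbar2)^2 / (N(N+1)/12 * (1/n1+1/n2))
        referred to chi-square on k-1 df."""
        from scipy.stats import chi2

        g1, g2 = np.array([1.0, 2, 3]), np.array([4.0, 5, 6])
        pmat = nemenyi_posthoc([g1, g2])
        rbar1, rbar2 = 2.0, 5.0  # ranks 1..6
        q = (rbar1 - rbar2) ** 2 / (6 * 7 / 12 * (1 / 3 + 1 / 3))
        assert pmat[0, 1] == pytest.approx(float(chi2.sf(q, df=1)))

    def test_separated_groups_more_significant_than_overlapping(self):
        sep = nemenyi_posthoc([np.arange(1.0, 7), np.arange(20.0, 26)])[0, 1]
        over = nemenyi_posthoc([np.arange(1.0, 7), np.arange(2.0, 8)])[0, 1]
        assert sep < over


class TestSpuriousModel:
    def test_cohort_of_30(self):
        assert round_sig(spurious_probability(30), 3) == pytest.approx(9.31e-10)

    @pytest.mark.parametrize("n,expected", [(1, 0.5), (10, 9.765625e-4)])
    def test_exact_small_cohorts(self, n, expected):
        assert spurious_probability(n) == expected

    def test_strictly_halves_per_individual(self):
        values = [spurious_probability(n) for n in range(1, 40)]
        for a, b in zip(values, values[1:]):
            assert b == a / 2

    def test_expected_spurious_full_panel(self):
        """101,642 loci at the 3-significant-figure per-locus probability
        give 9.463e-5 expected spurious hits; the unrounded probability
        gives 9.466e-5."""
        rounded = expected_spurious(101_642, round_sig(spurious_probability(30), 3))
        assert round_sig(rounded, 4) == pytest.approx(9.463e-5)
        exact = expected_spurious(101_642, spurious_probability(30))
        assert round_sig(exact, 4) == pytest.approx(9.466e-5)

    def test_expected_spurious_edge_cases(self):
        assert expected_spurious(0, 0.5) == 0.0
        with pytest.raises(ValueError):
            expected_spurious(-1, 0.5)

    def test_required_sample_size_by_integer_search(self):
        """Smallest n with n_loci * 0.5^n below the budget, checked
        against an independent integer search."""
        def oracle(n_loci, budget):
            return next(n for n in range(1, 200) if n_loci * 0.5**n < budget)

        for n_loci, budget in [(101_642, 1.0), (1, 1.0), (1024, 1.0), (5000, 0.01)]:
            assert required_sample_size(n_loci, budget) == oracle(n_loci, budget)
        assert required_sample_size(101_642, 1.0) == 17
        assert required_sample_size(1, 1.0) == 1
        for k in (3, 10, 16):
            assert required_sample_size(2**k, 1.0) == k + 1


def test_allele_frequency_counts_alleles():
    from sexlink.codes import ALT_HOM

    calls = np.array([REF_HOM, HET, ALT_HOM, MISSING])
    # (2*1 + 1) alt alleles over 2*3 scored alleles
    assert allele_frequency(calls) == pytest.approx(0.5)
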