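import itertools

import numpy as np
import pytest
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from intentgap.stats import (
    TestResult as StatResult,
    bh_family,
    bh_thresholds,
    cohens_d_from_t,
    paired_t,
    pearson_corr,
    wilcoxon_signed_rank,
)

#: Per-rank 3-decimal BH thresholds quoted across the study's results
#: for its 17-test family at q = 0.05.
PRINTED_THRESHOLDS = [
    0.003, 0.006, 0.009, 0.012, 0.015, 0.018, 0.021, 0.024, 0.026,
    0.029, 0.032, 0.035, 0.038, 0.041, 0.044, 0.047, 0.05,
]


class TestPairedT:
    def test_worked_example(self):
        # differences (1, 0, 1, 2): mean 1, sd sqrt(2/3), t = 1/(0.8165/2)
        res = paired_t([1, 0, 1, 2], [0, 0, 0, 0])
        assert res.statistic == pytest.approx(2.449, abs=1e-3)
        assert res.df == 3
        assert res.effect_sizes["d_z"] == pytest.approx(1 / np.sqrt(2 / 3))

    def test_zero_variance_default_errors(self):
        x = [1.0, 2.0, 3.0]
        with pytest.raises(ValueError, match="zero variance"):
            paired_t(x, x)

    def test_zero_variance_optional_zero(self):
        x = [1.0, 2.0, 3.0]
        res = paired_t(x, x, zero_variance="zero")
        assert res.statistic == 0.0
        assert res.p == 1.0

    def test_pairwise_deletion(self):
        x = [1.0, np.nan, 3.0, 4.0, 2.0]
        y = [0.0, 5.0, np.nan, 1.0, 1.0]
        assert paired_t(x, y).n_used == 3

    def test_d_from_t_identity(self):
        assert cohens_d_from_t(0.39, 144) == pytest.approx(0.0325)
        rng = np.random.default_rng(1)
        res = paired_t(rng.normal(0.3, 1, 30), rng.normal(0, 1, 30))
        assert res.effect_sizes["d_from_t"] == pytest.approx(
            res.statistic / np.sqrt(res.n_used)
        )

    def test_matches_scipy_over_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            n = rng.integers(3, 13)
            x = rng.normal(0, 1, n).round(2)
            y = x + rng.normal(0.2, 1, n).round(2)
            if np.std(x - y, ddof=1) == 0:
                continue
            mine = paired_t(x, y)
            ref = sps.ttest_rel(x, y)
            assert mine.statistic == pytest.approx(ref.statistic, abs=1e-12)
            assert mine.p == pytest.approx(ref.pvalue, abs=1e-12)


class TestPearson:
    def test_perfect_linearity(self):
        x = np.array([0.0, 1, 2, 5])
        res = pearson_corr(x, 2 * x + 1)
        assert res.statistic == pytest.approx(1.0)
        assert res.df == len(x) - 2

    def test_df_bookkeeping(self):
        rng = np.random.default_rng(0)
        res = pearson_corr(rng.normal(size=144), rng.normal(size=144))
        assert res.df == 142

    def test_p_consistent_with_t_distribution(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            n = int(rng.integers(5, 40))
            x, y = rng.normal(size=n), rng.normal(size=n)
            res = pearson_corr(x, y)
            t = res.statistic * np.sqrt(n - 2) / np.sqrt(1 - res.statistic**2)
            assert res.p == pytest.approx(2 * sps.t.sf(abs(t), n - 2), abs=1e-12)

    def test_independent_data_has_small_r(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=5000)
        res = pearson_corr(x, rng.permutation(x))
        assert abs(res.statistic) < 0.05

    def test_constant_vector_errors(self):
        with pytest.raises(ValueError, match="constant"):
            pearson_corr([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


def enumerate_signed_rank_p(ranks: np.ndarray, w: float) -> float:
    """Independent oracle: all 2^n sign assignments, two-sided 2*min tail."""
    n = len(ranks)
    totals = [
        sum(r for r, s in zip(ranks, signs) if s)
        for signs in itertools.product([False, True], repeat=n)
    ]
    totals = np.array(totals)
    lower = np.mean(totals <= w + 1e-9)
    upper = np.mean(totals >= w - 1e-9)
    return min(1.0, 2 * min(lower, upper))


class TestWilcoxon:
    def test_all_positive(self):
        res = wilcoxon_signed_rank([1, 2, 3], [0, 0, 0])
        assert res.statistic == 6

    def test_all_negative(self):
        res = wilcoxon_signed_rank([-1, -2, -3], [0, 0, 0])
        assert res.statistic == 0

    def test_tied_ranks_worked_example(self):
        # |d| = 1,1,2,2,3 -> average ranks 1.5,1.5,3.5,3.5,5; W+ = 1.5+3.5+5
        res = wilcoxon_signed_rank([1, -1, 2, -2, 3], [0, 0, 0, 0, 0])
        assert res.statistic == 10.0
        assert res.p == pytest.approx(
            enumerate_signed_rank_p(np.array([1.5, 1.5, 3.5, 3.5, 5.0]), 10.0)
        )

    def test_exact_matches_enumeration_oracle(self):
        rng = np.random.default_rng(10)
        for _ in range(150):
            n = int(rng.integers(3, 13))
            d = rng.integers(-3, 4, n)
            if np.all(d == 0):
                continue
            res = wilcoxon_signed_rank(d.astype(float), np.zeros(n))
            nz = d[d != 0]
            ranks = sps.rankdata(np.abs(nz))
            w = float(ranks[nz > 0].sum())
            assert res.statistic == w
            assert res.p == pytest.approx(enumerate_signed_rank_p(ranks, w), abs=1e-12)

    def test_normal_approx_matches_scipy_with_ties(self):
        rng = np.random.default_rng(20)
        x = rng.integers(-2, 3, 60).astype(float)
        y = rng.integers(-2, 3, 60).astype(float)
        keep = x != y
        ref = sps.wilcoxon(
            x[keep], y[keep], zero_method="wilcox", correction=False, method="approx"
        )
        res = wilcoxon_signed_rank(x, y)
        assert res.p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_pratt_policy_matches_scipy(self):
        rng = np.random.default_rng(21)
        x = rng.integers(-2, 3, 60).astype(float)
        y = rng.integers(-2, 3, 60).astype(float)
        if np.all(x == y):
            x[0] += 1
        ref = sps.wilcoxon(x, y, zero_method="pratt", correction=False, method="approx")
        res = wilcoxon_signed_rank(x, y, zero_policy="pratt")
        assert res.p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_all_zero_differences_error(self):
        with pytest.raises(ValueError, match="zero"):
            wilcoxon_signed_rank([1.0, 2.0], [1.0, 2.0])


def _family(ps):
    return [StatResult(f"t{i}", "t", 0.0, None, 10, p) for i, p in enumerate(ps)]


class TestBenjaminiHochberg:
    def test_printed_threshold_set(self):
        rounded = [round(a, 3) for a in bh_thresholds(17, 0.05)]
        assert rounded == PRINTED_THRESHOLDS
        assert rounded[0] == 0.003
        assert rounded[8] == 0.026
        assert rounded[15] == 0.047
        assert rounded[16] == 0.05

    def test_single_test_reduction(self):
        fam = bh_family(_family([0.04]), q=0.05)
        assert fam.entries[0].alpha == 0.05
        assert fam.entries[0].reject
        assert not bh_family(_family([0.06]), q=0.05).entries[0].reject

    def test_step_up_rule(self):
        # sorted p: 0.001, 0.03, 0.04, 0.9 vs thresholds 0.0125, 0.025, 0.0375, 0.05
        fam = bh_family(_family([0.9, 0.04, 0.001, 0.03]), q=0.05)
        rejected = [e.result.name for e in fam.entries if e.reject]
        assert rejected == ["t2"]

    def test_step_up_rescues_smaller_ranks(self):
        # rank 3 passes (0.037 <= 0.0375) so ranks 1-2 reject despite rank 2 failing
        fam = bh_family(_family([0.012, 0.026, 0.037, 0.9]), q=0.05)
        assert [e.reject for e in fam.entries] == [True, True, True, False]

    def test_ties_broken_by_input_order(self):
        fam = bh_family(_family([0.02, 0.02, 0.02]), q=0.05)
        ranks = [e.rank for e in fam.entries]
        assert ranks == [1, 2, 3]

    def test_matches_statsmodels_reference(self):
        rng = np.random.default_rng(17)
        for _ in range(200):
            m = int(rng.integers(1, 25))
            ps = rng.uniform(0, 0.2, m)
            fam = bh_family(_family(ps), q=0.05)
            ref_reject = multipletests(ps, alpha=0.05, method="fdr_bh")[0]
            assert [e.reject for e in fam.entries] == list(ref_reject)

    def test_empty_family_errors(self):
        with pytest.raises(ValueError, match="empty"):
            bh_family([], q=0.05)

    def test_p_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            StatResult("bad", "t", 0.0, None, 10, 1.2)
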