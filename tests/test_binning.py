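import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from nichegradient import (
    SpeciesVariableSample,
    bin_counts,
    bonferroni_alpha,
    clopper_pearson_ci,
    compute_bins,
    omnibus_chi_square,
    pairwise_significance,
)
from nichegradient.binning import (
    BinnedSample,
    attach_confidence_intervals,
    freedman_diaconis_width,
    sturges_edges,
)
from nichegradient.errors import DegenerateSampleError


def _sample(values, species="sp", variable="v"):
    return SpeciesVariableSample(species, variable, np.asarray(values, dtype=float))


class TestBinRules:
    def test_fd_width_formula(self):
        # {1..8}: IQR 3.5 under linear interpolation, n^(1/3) = 2
        values = np.arange(1.0, 9.0)
        assert freedman_diaconis_width(values) == pytest.approx(3.5)
        edges = compute_bins(_sample(values), "fd_as_written")
        assert edges[0] == 1.0
        assert np.allclose(np.diff(edges), 3.5)
        assert edges[-1] >= 8.0

    def test_sturges_bin_count(self):
        values = np.linspace(0.0, 10.0, 8)
        edges = sturges_edges(values)
        # ceil(log2 8) + 1 = 4 target classes, snapped to round edges
        assert len(edges) - 1 in (4, 5)
        assert edges[0] <= values.min() and edges[-1] >= values.max()
        widths = np.diff(edges)
        assert np.allclose(widths, widths[0])

    def test_zero_iqr_falls_back_with_warning(self):
        values = np.array([5.0] * 20 + [1.0, 9.0])
        with pytest.warns(UserWarning, match="sturges_r"):
            edges = compute_bins(_sample(values), "fd_as_written")
        assert edges[0] <= 1.0 and edges[-1] >= 9.0

    def test_all_equal_is_degenerate(self):
        with pytest.raises(DegenerateSampleError):
            compute_bins(_sample([3.0, 3.0, 3.0]))


class TestBinCounts:
    def test_half_open_bins_last_closed(self):
        binned = bin_counts(_sample([0.0, 1.0, 2.0]), np.array([0.0, 1.5, 3.0]))
        assert binned.counts.tolist() == [2, 1]
        # maximum value exactly on the last edge is counted once
        binned2 = bin_counts(_sample([0.0, 1.5, 3.0]), np.array([0.0, 1.5, 3.0]))
        assert binned2.counts.tolist() == [1, 2]
        assert binned2.N == 3

    @given(
        st.lists(st.floats(min_value=-50, max_value=50), min_size=5, max_size=60)
    )
    @settings(max_examples=50, deadline=None)
    def test_counts_conserved_and_proportions_sum_to_one(self, values):
        values = np.asarray(values)
        if np.unique(values).size < 3:
            return
        sample = _sample(values)
        binned = bin_counts(sample, compute_bins(sample))
        assert binned.counts.sum() == sample.n
        assert binned.proportions.sum() == pytest.approx(1.0)
        assert np.allclose(
            binned.midpoints, (binned.edges[:-1] + binned.edges[1:]) / 2
        )


class TestBonferroni:
    @pytest.mark.parametrize(
        "alpha,k,expected", [(0.05, 6, 0.05 / 6), (0.05, 1, 0.05), (0.05, 10, 0.005)]
    )
    def test_adjustment(self, alpha, k, expected):
        assert bonferroni_alpha(alpha, k) == pytest.approx(expected)

    def test_six_comparisons_print_as_0_0083(self):
        assert round(bonferroni_alpha(0.05, 6), 4) == 0.0083

    def test_invalid_k(self):
        with pytest.raises(ValueError):
            bonferroni_alpha(0.05, 0)


def _cp_bisection_oracle(count, n, alpha):
    """Invert the binomial tail sums directly by bisection."""

    def upper_tail(p):  # P(X >= count)
        return 1.0 - stats.binom.cdf(count - 1, n, p)

    def lower_tail(p):  # P(X <= count)
        return stats.binom.cdf(count, n, p)

    def bisect(f, target, lo, hi, increasing):
        for _ in range(200):
            mid = (lo + hi) / 2
            if (f(mid) > target) == increasing:
                hi = mid
            else:
                lo = mid
        return (lo + hi) / 2

    lower = 0.0 if count == 0 else bisect(upper_tail, alpha / 2, 0.0, 1.0, True)
    upper = 1.0 if count == n else bisect(lower_tail, alpha / 2, 0.0, 1.0, False)
    return lower, upper


class TestClopperPearson:
    def test_boundary_counts(self):
        assert clopper_pearson_ci(0, 50, 0.05)[0] == 0.0
        assert clopper_pearson_ci(239, 239, 0.05)[1] == 1.0

    @pytest.mark.parametrize("count,n", [(94, 239), (1, 50), (25, 50)])
    def test_matches_binomial_tail_inversion(self, count, n):
        alpha = 0.0083
        lower, upper = clopper_pearson_ci(count, n, alpha)
        o_lower, o_upper = _cp_bisection_oracle(count, n, alpha)
        assert lower == pytest.approx(o_lower, abs=1e-8)
        assert upper == pytest.approx(o_upper, abs=1e-8)
        assert lower <= count / n <= upper

    def test_count_exceeding_n_rejected(self):
        with pytest.raises(ValueError):
            clopper_pearson_ci(10, 5, 0.05)

    @given(st.integers(min_value=1, max_value=30))
    @settings(max_examples=30, deadline=None)
    def test_wider_k_never_narrows_any_interval(self, k):
        binned = BinnedSample(
            edges=np.arange(5.0), counts=np.array([10, 20, 30, 40]), N=100
        )
        base = attach_confidence_intervals(binned, bonferroni_alpha(0.05, 1))
        adj = attach_confidence_intervals(binned, bonferroni_alpha(0.05, k))
        assert np.all(adj.ci_lower <= base.ci_lower + 1e-12)
        assert np.all(adj.ci_upper >= base.ci_upper - 1e-12)


class TestPairwiseSignificance:
    def _binned_with_cis(self, lowers, uppers):
        k = len(lowers)
        binned = BinnedSample(
            edges=np.arange(float(k + 1)), counts=np.ones(k, dtype=int), N=k
        )
        from dataclasses import replace

        return replace(
            binned,
            alpha_adj=0.05,
            ci_lower=np.asarray(lowers, dtype=float),
            ci_upper=np.asarray(uppers, dtype=float),
        )

    def test_disjoint_intervals_significant(self):
        binned = self._binned_with_cis([0.1, 0.4], [0.3, 0.6])
        sig = pairwise_significance(binned)
        assert sig[0, 1] and sig[1, 0] and not sig[0, 0]

    def test_touching_intervals_not_significant(self):
        binned = self._binned_with_cis([0.1, 0.4], [0.4, 0.6])
        assert not pairwise_significance(binned).any()

    def test_equal_counts_nothing_significant(self):
        binned = BinnedSample(
            edges=np.arange(5.0), counts=np.array([25, 25, 25, 25]), N=100
        )
        binned = attach_confidence_intervals(binned, 0.0125)
        assert not pairwise_significance(binned).any()


class TestOmnibusChiSquare:
    def test_null_case(self):
        binned = BinnedSample(
            edges=np.arange(5.0), counts=np.array([10, 10, 10, 10]), N=40
        )
        stat, df, p = omnibus_chi_square(binned)
        assert stat == pytest.approx(0.0)
        assert df == 3
        assert p == pytest.approx(1.0)

    def test_hand_computed_two_bins(self):
        binned = BinnedSample(edges=np.arange(3.0), counts=np.array([20, 0]), N=20)
        stat, df, p = omnibus_chi_square(binned)
        assert stat == pytest.approx(20.0)  # (20-10)^2/10 * 2
        assert df == 1

    def test_invariant_under_bin_reordering(self):
        counts = np.array([5, 17, 2, 26])
        a = BinnedSample(edges=np.arange(5.0), counts=counts, N=50)
        b = BinnedSample(edges=np.arange(5.0), counts=counts[::-1], N=50)
        assert omnibus_chi_square(a)[0] == pytest.approx(omnibus_chi_square(b)[0])
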