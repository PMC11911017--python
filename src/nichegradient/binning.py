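"""Histogram construction and exact binomial inference on bin proportions.

Occurrences along a gradient are grouped into bins; each bin's count out of
the total N is treated as a binomial observation, giving a proportion with an
exact Clopper-Pearson confidence interval.  Because K proportions are compared
simultaneously, the significance level is Bonferroni-adjusted before the
intervals are built, and an omnibus chi-squared test checks whether the
proportions differ at all along the gradient.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .errors import DegenerateSampleError
from .io import SpeciesVariableSample

_NICE_MANTISSAS = (1.0, 2.0, 2.5, 5.0, 10.0)


@dataclass(frozen=True)
class BinnedSample:
    """Histogram of one species-variable sample, with per-bin inference."""

    edges: np.ndarray          # K+1 strictly increasing edges
    counts: np.ndarray         # K nonnegative integers, summing to N
    N: int
    alpha_adj: float | None = None
    ci_lower: np.ndarray | None = None
    ci_upper: np.ndarray | None = None

    def __post_init__(self) -> None:
        edges = np.asarray(self.edges, dtype=float)
        counts = np.asarray(self.counts, dtype=int)
        object.__setattr__(self, "edges", edges)
        object.__setattr__(self, "counts", counts)
        if not np.all(np.diff(edges) > 0):
            raise ValueError("edges must be strictly increasing")
        if counts.size != edges.size - 1:
            raise ValueError("need one count per bin")
        if counts.sum() != self.N:
            raise ValueError("counts must sum to N")

    @property
    def k(self) -> int:
        return int(self.counts.size)

    @property
    def midpoints(self) -> np.ndarray:
        return (self.edges[:-1] + self.edges[1:]) / 2.0

    @property
    def proportions(self) -> np.ndarray:
        return self.counts / self.N


def freedman_diaconis_width(values: np.ndarray) -> float:
    """Bin width 2*IQR/n^(1/3); IQR by linear interpolation ("type 7")."""
    values = np.asarray(values, dtype=float)
    q75, q25 = np.percentile(values, [75, 25])
    return 2.0 * (q75 - q25) / values.size ** (1.0 / 3.0)


def _nice_width(raw: float) -> float:
    """Smallest 'nice' number (1, 2, 2.5, 5 x 10^m) at or above raw."""
    if raw <= 0:
        raise ValueError("raw width must be positive")
    exponent = math.floor(math.log10(raw))
    base = 10.0 ** exponent
    for mantissa in _NICE_MANTISSAS:
        if mantissa * base >= raw * (1 - 1e-12):
            return mantissa * base
    return 10.0 * base  # unreachable, _NICE_MANTISSAS ends at 10


def sturges_edges(values: np.ndarray) -> np.ndarray:
    """ceil(log2 n)+1 classes with edges snapped to round numbers.

    Emulates R's ``hist`` default: the target class count from Sturges' rule,
    then ``pretty`` edges covering the data.
    """
    values = np.asarray(values, dtype=float)
    lo, hi = values.min(), values.max()
    k_target = math.ceil(math.log2(values.size)) + 1
    width = _nice_width((hi - lo) / k_target)
    start = math.floor(lo / width) * width
    n_bins = math.ceil((hi - start) / width)
    if start + n_bins * width <= hi:  # guard fp shortfall at the top edge
        n_bins += 1
    return start + width * np.arange(n_bins + 1)


def compute_bins(
    sample: SpeciesVariableSample, rule: str = "fd_as_written"
) -> np.ndarray:
    """Bin edges for a sample under the configured rule.

    ``fd_as_written``: width w = 2*IQR/n^(1/3), first edge at min(values),
    K = ceil((max-min)/w) equal bins.  Falls back to ``sturges_r`` with a
    warning when the IQR is zero.
    """
    values = sample.values
    lo, hi = values.min(), values.max()
    if lo == hi:
        raise DegenerateSampleError(
            f"{sample.species}/{sample.variable}: all values identical"
        )
    if rule == "sturges_r":
        return sturges_edges(values)
    if rule != "fd_as_written":
        raise ValueError(f"unknown bin rule {rule!r}")
    width = freedman_diaconis_width(values)
    # a zero or vanishing IQR (heavy ties) would give no bins or absurdly
    # many; both fall back to the Sturges-style rule
    if width == 0.0 or (hi - lo) / width > 1000:
        warnings.warn(
            f"{sample.species}/{sample.variable}: degenerate IQR, "
            "falling back to sturges_r",
            stacklevel=2,
        )
        return sturges_edges(values)
    n_bins = math.ceil((hi - lo) / width)
    edges = lo + width * np.arange(n_bins + 1)
    if edges[-1] < hi:  # fp guard: last edge must reach the maximum
        edges[-1] = hi
    return edges


def bin_counts(sample: SpeciesVariableSample, edges: np.ndarray) -> BinnedSample:
    """Count values per bin: half-open [e_i, e_{i+1}) with the last bin closed."""
    values = sample.values
    if values.min() < edges[0] or values.max() > edges[-1]:
        raise RuntimeError("edges do not cover the data (internal error)")
    counts, _ = np.histogram(values, bins=edges)
    return BinnedSample(edges=edges, counts=counts, N=sample.n)


def bonferroni_alpha(alpha: float, k: int) -> float:
    """Adjusted per-comparison level alpha/k for k simultaneous comparisons."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    return alpha / k


def clopper_pearson_ci(count: int, n: int, alpha_adj: float) -> tuple[float, float]:
    """Exact binomial confidence interval via inverse Beta tails.

    lower = Beta^{-1}(alpha/2; count, n-count+1) (0 when count = 0),
    upper = Beta^{-1}(1-alpha/2; count+1, n-count) (1 when count = n).
    """
    if not 0 <= count <= n:
        raise ValueError("need 0 <= count <= N")
    lower = 0.0 if count == 0 else float(
        stats.beta.ppf(alpha_adj / 2.0, count, n - count + 1)
    )
    upper = 1.0 if count == n else float(
        stats.beta.ppf(1.0 - alpha_adj / 2.0, count + 1, n - count)
    )
    return lower, upper


def attach_confidence_intervals(
    binned: BinnedSample, alpha_adj: float
) -> BinnedSample:
    """Return a copy with Clopper-Pearson CIs at the adjusted level."""
    bounds = np.array(
        [clopper_pearson_ci(int(c), binned.N, alpha_adj) for c in binned.counts]
    )
    return replace(
        binned, alpha_adj=alpha_adj, ci_lower=bounds[:, 0], ci_upper=bounds[:, 1]
    )


def pairwise_significance(binned: BinnedSample) -> np.ndarray:
    """Boolean K x K matrix: True where two bins' CIs strictly fail to overlap.

    Touching intervals (upper of one equal to lower of the other) count as
    overlapping, hence not significant.
    """
    if binned.ci_lower is None or binned.ci_upper is None:
        raise ValueError("confidence intervals not attached")
    upper = binned.ci_upper[:, None]
    lower = binned.ci_lower[None, :]
    sig = (upper < lower) | (upper < lower).T
    np.fill_diagonal(sig, False)
    return sig


def omnibus_chi_square(binned: BinnedSample) -> tuple[float, int, float]:
    """Global test of equal proportions across bins (uniformity of counts).

    Pearson goodness-of-fit of the K counts against equal expectation N/K;
    returns (statistic, df, p).
    """
    if binned.k < 2:
        raise ValueError("need at least two bins")
    if binned.N < binned.k:
        raise ValueError("need N >= K")
    stat, p = stats.chisquare(binned.counts)
    return float(stat), binned.k - 1, float(p)


def bin_and_infer(
    sample: SpeciesVariableSample,
    rule: str = "fd_as_written",
    family_alpha: float = 0.05,
    k: int | None = None,
) -> BinnedSample:
    """Convenience: bins -> counts -> Bonferroni-adjusted CIs in one call."""
    edges = compute_bins(sample, rule)
    binned = bin_counts(sample, edges)
    alpha_adj = bonferroni_alpha(family_alpha, k if k is not None else binned.k)
    return attach_confidence_intervals(binned, alpha_adj)
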