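# Methods

## The question

The environmental center-periphery (abundant-center) hypothesis predicts
that a species occurs most frequently near the center of its niche on an
environmental gradient, declining toward the edges. This package analyzes
that prediction one gradient at a time. The unidimensional view is
sufficient because a displacement `d_j` on a single gradient moves the
position in niche hypervolume away from the centroid by exactly
`sqrt(sum d_i^2) = |d_j|` when the other displacements are zero; the small
`centroid_displacement_distance` utility encodes that reduction.

A second, usually ignored ingredient is *natural truncation*: many
environmental variables have hard mathematical bounds (precipitation cannot
be negative, a precipitation ratio cannot exceed 1). Where the observed
range abuts such a bound, a symmetric occurrence optimum at the range
midpoint may be mathematically impossible no matter how much extra data one
collects. The pipeline quantifies both effects per species-variable
combination.

## Per-combination procedure

1. **Histogram.** Bin width `w = 2*IQR / n^(1/3)` (IQR by linear
   interpolation between order statistics, the common "type 7" quartile
   convention; the convention is fixed here because different conventions
   move bin edges). First edge at the sample minimum, `K = ceil((max-min)/w)`
   equal bins, half-open `[e_i, e_{i+1})` with the last bin closed so the
   maximum is counted once. An alternative rule (`sturges_r`,
   `ceil(log2 n)+1` classes with edges snapped to round numbers the way R's
   `hist`/`pretty` does) is available and is the automatic fallback when the
   IQR is zero or so small that more than 1000 bins would result.
2. **Proportions and exact intervals.** Each bin count out of the total `N`
   is a binomial observation; its proportion gets an exact Clopper-Pearson
   interval via inverse Beta tails. Because `K` proportions are compared
   simultaneously, the family level `alpha = 0.05` is Bonferroni-divided.
   The default divisor is the number of bins `K`; `bonferroni_k_rule =
   "n_marked"` instead re-adjusts by the number of marked points in one
   refinement pass (marking consumes the intervals, so the rule is
   inherently two-stage; one pass keeps it deterministic).
3. **Exclusion.** If no pair of intervals is strictly disjoint anywhere in
   the pairwise matrix, the sample cannot resolve any difference along the
   gradient and the combination is excluded (touching intervals count as
   overlapping — "non-overlap" is read strictly). An omnibus chi-squared
   test of the counts against equal expectation `N/K` (uniformity — the one
   null consistent with every specimen falling in exactly one bin) is
   reported alongside.
4. **Marking rules and degree.** Mark the highest bin (ties: leftmost, a
   fixed deterministic choice); scan outward on each side marking the next
   bin whose interval fails to overlap that of the most recently marked bin
   on that side; add both end bins (this prevents the fit from
   extrapolating freely at the ends); degree = marked points − 1, optionally
   adjusted by a per-combination ±1 override from the configuration
   (reproducing fits corrected after visual inspection), clamped to
   `[1, K-1]`.
5. **Polynomial logistic fit.** `p(x) = 1/(1+exp(-f(x)))` with `f` a
   polynomial of the chosen degree, fitted by maximum likelihood (IRLS,
   iteration cap 100, tolerance 1e-8) treating bin `i` as `counts[i]`
   successes in `N` trials at the bin midpoint — the same weighting that
   defines the intervals. The bin observations are therefore not
   independent; this is accepted because the curve serves only as a smooth
   density shape, not for coefficient inference. The predictor is
   standardized to `[-1, 1]` before expansion (degree-5 Vandermonde designs
   on raw scales are catastrophically conditioned); coefficients are
   reported on both scales. Non-convergence triggers a degree−1 refit
   ladder, each step flagged.
6. **Mode and highest-probability interval.** The curve on the observed
   range `[xmin, xmax]` is an unnormalized density (normalization cancels in
   every relative quantity). The mode is the grid argmax (2001 points)
   refined by bounded local search, snapping to a range endpoint when the
   argmax is within one grid cell of it and the curve is monotone into it.
   The 25% highest-probability interval is the connected component of
   `{x : p(x) >= c}` containing the mode, with the threshold `c` bisected
   (60 iterations) until the component holds 25% of the area (trapezoid on
   the grid with interpolated crossing points; tolerance 1e-4 on the mass
   fraction). An endpoint mode yields a one-sided interval automatically.
   The 25% mass is a convention: large enough to be stable, small enough to
   be a genuine "preferred interval". In strongly bimodal fits the
   component's mass can jump as the threshold crosses the saddle; the
   closest bracketing interval is then returned and flagged. A perfectly
   flat top is a measure-zero tie handled by the same bisection.
7. **Relative distance.** `xmid = (xmin+xmax)/2`;
   `relDis = (xL - xmid)/(xmax - xmin) * 100` when `xmid < xL` (positive:
   interval above the midpoint), `(xU - xmid)/(xmax - xmin) * 100` when
   `xmid > xU` (negative: below), else 0. Its domain is −50% to +50%, the
   extremes attained only in the limit of an interval collapsing onto a
   range endpoint.
8. **Truncation and expansion.** With `d1`/`d2` the shorter/longer
   mode-to-extreme distances, symmetry around the mode requires extending
   the short side to `mode ± d2`. Categories: *centered* (relDis = 0 — the
   midpoint is inside the interval; this is decided by relDis, not by
   `d1 = d2`), *undefined* (`d1 = 0`: the mode sits on an extreme, the true
   mode may lie beyond it, and `d2/d1` is uncomputable), *impossible* (the
   required limit falls outside the variable's natural domain), else
   *possible* — a truncated variable whose required limit stops short of the
   bound is still possible, and a required limit exactly on the bound counts
   as attainable. The signed expansion factor is `±d2/d1` (positive
   rightward). A required limit is also compared against the study-wide
   observed range of the variable (closed interval), answering whether the
   needed conditions are already observed somewhere in the data.

## Study-level aggregation

Pearson correlations are computed over all specimen rows pooled (one matrix,
not per species) and summarized by the distribution of `|r|` across the
`(V²−V)/2` pairs; no significance test on `r` is performed. Side counts
(below/above midpoint) are compared with an exact two-sided binomial test at
p = 1/2, defined as `min(1, 2·min(tails))` — a fixed, documented convention
that matches `scipy.stats.binomtest` at this symmetric null.

## The variable-domain registry

The shipped registry covers the study's 16 gradients: 11 nonnegative
variables, the summer/total precipitation ratio on `[0, 1]`, and four
unbounded (the three temperature variables and soil pH — pH is chemically
bounded but is analysed as untruncated, following how the variable is
treated in the field data). An editable alias table maps spreadsheet-style
headers to these canonical labels.

## Synthetic data: what it emulates and what it does not

`default_study_specs` builds a 12 × 16 grid with the study's per-species
site counts (70–321) and family choices by variable nature: temperatures and
pH Gaussian; nonnegative precipitation-like variables gamma (right-skewed,
truncated at 0); the ratio a scaled beta. Four scenario presets
(`symmetric_interior`, `skewed_interior`, `boundary_mode_truncated`,
`bimodal`) cover every verdict category and error path. Each sample carries
a truth record computed from the known generating density by independent
machinery (greedy accumulation of density-sorted grid cells rather than
threshold bisection): true mode (analytic where closed forms exist), true
25% HDI, and the true side of the midpoint, with the expected observed range
approximated by the `1/(n+1)` and `n/(n+1)` quantiles.

The generator draws sites independently (optionally with a Gaussian copula
to hit a target correlation — a device for testing the correlation screen,
not a biological model). It does not emulate spatial autocorrelation,
sampling bias toward accessible sites, or identification error, so passing
recovery tests demonstrate statistical correctness of the pipeline, not
robustness to those field realities.

## Problem sizes and numerical choices

The test suite and analysis scripts use the full 12 × 16 grid (192
combinations, ~1900 records), 200 replicates for mode-recovery rates and
10⁴ Monte-Carlo replicates for coverage and type-I checks — sizes at which
every quantity of interest is stable to well under its test tolerance while
the whole suite runs in well under a minute. Grid resolution 2001 points,
HPI mass tolerance 1e-4, GLM tolerance 1e-8 with cap 100; all recorded per
run in `run_metadata.json`.

## Known limitations

- The binomial weighting passed to the GLM (every bin a draw out of the
  full N) reproduces the interval logic but need not match other software's
  weighting to the last decimal of the coefficients.
- The exclusion rule and marking scan act on simultaneous intervals, so the
  chosen Bonferroni divisor (bins vs. marked points) shifts borderline
  combinations; both rules are implemented and logged.
- The highest-probability interval is defined as one contiguous component
  around the global mode; genuinely bimodal responses are flagged rather
  than given a disjoint-union interval.
- Reproduction of the original field study's aggregate counts requires the
  deposited occurrence table, which is not redistributable here; the
  study-reproduction profile (alias table, degree overrides, deterministic
  run) is shipped and tested against its availability.
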