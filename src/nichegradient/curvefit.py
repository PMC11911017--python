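"""Marking rules and the polynomial logistic fit.

The degree of the logistic polynomial is not chosen by a model-selection
criterion but by four marking rules on the binned proportions: mark the
highest bin, walk outward marking each bin whose confidence interval fails to
overlap the last marked one, add the two end bins, and set the degree to one
less than the number of marked points.  The fitted curve
p(x) = 1/(1 + exp(-f(x))) is then used only as a smooth occurrence-probability
density for the interval analysis, not for coefficient inference.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from numpy.polynomial import Polynomial
from scipy.special import expit

from .binning import BinnedSample
from .errors import CombinationExcluded, FitFailureError


@dataclass(frozen=True)
class MarkedPoints:
    """Outcome of the four marking rules on one binned sample."""

    indices: tuple[int, ...]
    highest_index: int
    degree: int

    @property
    def n_marked(self) -> int:
        return len(self.indices)


@dataclass(frozen=True)
class FittedDensity:
    """Polynomial logistic curve p(x) on a species' observed gradient range.

    Coefficients are stored on the standardized predictor scale
    t = (x - center)/halfwidth in [-1, 1]; ``coefficients_original`` maps them
    back.  The curve is strictly inside (0, 1) by construction.
    """

    coefficients: np.ndarray   # b0..bD on the standardized scale
    degree: int
    center: float
    halfwidth: float
    xmin: float
    xmax: float
    converged: bool
    degree_reductions: int = 0

    def standardize(self, x: np.ndarray) -> np.ndarray:
        return (np.asarray(x, dtype=float) - self.center) / self.halfwidth

    def logit(self, x: np.ndarray) -> np.ndarray:
        t = self.standardize(x)
        return np.polynomial.polynomial.polyval(t, self.coefficients)

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return expit(self.logit(x))

    @property
    def coefficients_original(self) -> np.ndarray:
        """b0..bD of f(x) on the original variable scale."""
        poly = Polynomial(
            self.coefficients,
            domain=[self.center - self.halfwidth, self.center + self.halfwidth],
            window=[-1.0, 1.0],
        )
        return poly.convert().coef


def mark_points(
    binned: BinnedSample,
    significance: np.ndarray,
    degree_override: int = 0,
) -> MarkedPoints:
    """Apply the four marking rules; raises when nothing is significant.

    (i) mark the bin with the highest proportion (ties: leftmost);
    (ii) from it, scan outward on each side, marking the next bin whose CI
    does not overlap the CI of the most recently marked bin on that side;
    (iii) mark both end bins; (iv) degree = n_marked - 1 plus any configured
    +-1 override, clamped to [1, K-1].
    """
    if not significance.any():
        raise CombinationExcluded(
            "no pair of bins differs significantly; combination excluded"
        )
    k = binned.k
    highest = int(np.argmax(binned.proportions))
    marks = {highest}
    for step in (-1, 1):
        last = highest
        j = highest + step
        while 0 <= j < k:
            if significance[last, j]:
                marks.add(j)
                last = j
            j += step
    marks.update((0, k - 1))
    degree = len(marks) - 1 + degree_override
    degree = max(1, min(degree, k - 1))
    return MarkedPoints(
        indices=tuple(sorted(marks)), highest_index=highest, degree=degree
    )


def _glm_fit(endog: np.ndarray, exog: np.ndarray):
    model = sm.GLM(endog, exog, family=sm.families.Binomial())
    return model.fit(maxiter=100, tol=1e-8)


def fit_logistic_polynomial(
    binned: BinnedSample,
    degree: int,
    xmin: float | None = None,
    xmax: float | None = None,
) -> FittedDensity:
    """Maximum-likelihood logistic fit of bin proportions vs. bin midpoints.

    Each bin contributes a binomial observation of counts[i] successes in N
    trials at x = midpoint[i] (the same weighting that defines the CIs).  The
    predictor is standardized to [-1, 1] before the polynomial expansion to
    keep degree-5 designs well conditioned.  On failure (non-convergence,
    non-finite coefficients, perfect separation) the degree is reduced by one
    and the fit retried; running out of degrees raises ``FitFailureError``.
    """
    if degree < 1:
        raise ValueError("degree must be >= 1")
    if degree > binned.k - 1:
        raise ValueError("degree must be <= K-1")
    if xmin is None:
        xmin = float(binned.edges[0])
    if xmax is None:
        xmax = float(binned.edges[-1])
    center = (xmin + xmax) / 2.0
    halfwidth = (xmax - xmin) / 2.0
    if halfwidth <= 0:
        raise ValueError("xmin must be below xmax")

    t = (binned.midpoints - center) / halfwidth
    endog = np.column_stack([binned.counts, binned.N - binned.counts])

    reductions = 0
    current = degree
    while current >= 1:
        exog = np.vander(t, current + 1, increasing=True)
        try:
            result = _glm_fit(endog, exog)
            params = np.asarray(result.params, dtype=float)
            ok = bool(result.converged) and np.all(np.isfinite(params))
        except Exception:
            ok = False
        if ok:
            return FittedDensity(
                coefficients=params,
                degree=current,
                center=center,
                halfwidth=halfwidth,
                xmin=xmin,
                xmax=xmax,
                converged=True,
                degree_reductions=reductions,
            )
        current -= 1
        reductions += 1
    raise FitFailureError("logistic fit failed at every degree down to 1")
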