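"""Mode, highest-probability interval, and midpoint distance.

The fitted logistic curve, restricted to the species' observed range
[xmin, xmax], is treated as an unnormalized probability density.  The
highest-probability interval (HPI) is the connected region around the global
mode holding a fixed fraction (default 25%) of the total area at the highest
densities — a highest-density interval.  When the mode sits on an endpoint of
the range, the interval grows from that endpoint one-sidedly.  The relative
distance relDis measures, in percent of the range, how far the range midpoint
lies outside the HPI; its mathematical domain is -50% to +50%.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import integrate, optimize

from .curvefit import FittedDensity

MASS_TOL = 1e-4
_BISECT_ITER = 60


@dataclass(frozen=True)
class HighestProbabilityInterval:
    xL: float
    xU: float
    mass: float                 # achieved fraction of the total area
    mode: float
    mode_at_endpoint: bool
    mass_shortfall: bool = False  # flagged when |mass - target| > MASS_TOL


def _grid(density: FittedDensity, grid_points: int) -> tuple[np.ndarray, np.ndarray]:
    xs = np.linspace(density.xmin, density.xmax, grid_points)
    return xs, density(xs)


def find_mode(
    density: FittedDensity, grid_points: int = 2001
) -> tuple[float, bool]:
    """Global argmax of p on [xmin, xmax], grid search + local refinement.

    Returns (mode, mode_at_endpoint); the mode snaps to the range endpoint
    when the grid argmax is within one cell of it and the curve is monotone
    into that endpoint.
    """
    xs, ps = _grid(density, grid_points)
    i = int(np.argmax(ps))
    run = min(10, grid_points - 1)
    if i <= 1 and np.all(np.diff(ps[: run + 1]) <= 0):
        return float(xs[0]), True
    if i >= grid_points - 2 and np.all(np.diff(ps[-(run + 1):]) >= 0):
        return float(xs[-1]), True
    lo = xs[max(i - 1, 0)]
    hi = xs[min(i + 1, grid_points - 1)]
    res = optimize.minimize_scalar(
        lambda x: -density(x), bounds=(lo, hi), method="bounded",
        options={"xatol": (xs[1] - xs[0]) * 1e-6},
    )
    return float(res.x), False


def total_area(density: FittedDensity, grid_points: int = 2001) -> float:
    """Integral of p over [xmin, xmax] by composite Simpson's rule."""
    xs, ps = _grid(density, grid_points)
    if not np.all(np.isfinite(ps)):
        raise ValueError("non-finite density values on the grid")
    return float(integrate.simpson(ps, x=xs))


def _component_bounds(
    xs: np.ndarray, ps: np.ndarray, mode_index: int, level: float
) -> tuple[float, float]:
    """Connected component of {p >= level} containing the mode, with the
    crossing points located by linear interpolation."""
    j = mode_index
    while j > 0 and ps[j - 1] >= level:
        j -= 1
    if j == 0:
        xl = xs[0]
    else:
        frac = (level - ps[j - 1]) / (ps[j] - ps[j - 1])
        xl = xs[j - 1] + frac * (xs[j] - xs[j - 1])
    j = mode_index
    n = len(xs)
    while j < n - 1 and ps[j + 1] >= level:
        j += 1
    if j == n - 1:
        xu = xs[-1]
    else:
        frac = (ps[j] - level) / (ps[j] - ps[j + 1])
        xu = xs[j] + frac * (xs[j + 1] - xs[j])
    return float(xl), float(xu)


def _interval_mass(
    density: FittedDensity, xs: np.ndarray, ps: np.ndarray, xl: float, xu: float
) -> float:
    """Trapezoid integral of p over [xl, xu] on the evaluation grid, with the
    partial end cells handled by interpolated endpoints."""
    inside = (xs > xl) & (xs < xu)
    pts_x = np.concatenate(([xl], xs[inside], [xu]))
    pts_p = np.concatenate(([float(density(xl))], ps[inside], [float(density(xu))]))
    return float(np.trapezoid(pts_p, pts_x))


def highest_probability_interval(
    density: FittedDensity,
    mass: float = 0.25,
    grid_points: int = 2001,
) -> HighestProbabilityInterval:
    """Contiguous highest-density interval around the global mode.

    Bisects on a density threshold c: the connected component of
    {x : p(x) >= c} containing the mode, with c tuned until the component
    holds ``mass`` of the total area (tolerance 1e-4 on the mass fraction).
    With the mode on an endpoint the component is one-sided automatically.
    In strongly bimodal fits the component's area can jump as it merges with
    a second peak; if no threshold attains the target mass the closest
    bracketing interval is returned with ``mass_shortfall`` set.
    """
    if not 0.0 < mass < 1.0:
        raise ValueError("mass must be in (0, 1)")
    xs, ps = _grid(density, grid_points)
    total = _interval_mass(density, xs, ps, xs[0], xs[-1])
    mode, at_end = find_mode(density, grid_points)
    mode_index = int(np.argmin(np.abs(xs - mode)))

    def achieved(level: float) -> tuple[float, float, float]:
        xl, xu = _component_bounds(xs, ps, mode_index, level)
        return _interval_mass(density, xs, ps, xl, xu) / total, xl, xu

    lo_level, hi_level = 0.0, float(ps[mode_index])
    best = None
    for _ in range(_BISECT_ITER):
        mid = (lo_level + hi_level) / 2.0
        frac, xl, xu = achieved(mid)
        if best is None or abs(frac - mass) < abs(best[0] - mass):
            best = (frac, xl, xu)
        if frac > mass:
            lo_level = mid
        else:
            hi_level = mid
    frac, xl, xu = best
    return HighestProbabilityInterval(
        xL=xl,
        xU=xu,
        mass=frac,
        mode=mode,
        mode_at_endpoint=at_end,
        mass_shortfall=abs(frac - mass) > MASS_TOL,
    )


def relative_distance(
    xL: float, xU: float, xmin: float, xmax: float
) -> tuple[float, str]:
    """Relative distance (percent of the range) of the midpoint from the HPI.

    Three cases: midpoint below the interval -> positive (interval above the
    midpoint), midpoint inside -> 0, midpoint above -> negative (interval
    below).  The value lives in [-50, 50].
    """
    if not xmin < xmax:
        raise ValueError("degenerate range: xmin must be below xmax")
    if not (xmin <= xL < xU <= xmax):
        raise ValueError("interval must satisfy xmin <= xL < xU <= xmax")
    xmid = (xmin + xmax) / 2.0
    span = xmax - xmin
    if xmid < xL:
        return (xL - xmid) / span * 100.0, "above"
    if xmid > xU:
        return (xU - xmid) / span * 100.0, "below"
    return 0.0, "inside"


def centroid_displacement_distance(displacements: np.ndarray) -> float:
    """Euclidean distance of a displaced niche position from the centroid.

    A displacement on a single gradient moves the position in hypervolume
    space by exactly that amount, which is why the per-gradient analysis
    suffices: sqrt(sum d_i^2) reduces to |d_j| for one nonzero term.
    """
    d = np.asarray(displacements, dtype=float)
    if d.size == 0:
        raise ValueError("need at least one displacement")
    if not np.all(np.isfinite(d)):
        raise ValueError("displacements must be finite")
    return float(np.linalg.norm(d))
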