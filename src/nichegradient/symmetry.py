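"""Gradient-truncation analysis: can the shorter tail be expanded?

For a mode at distance d1 from the nearest range extreme and d2 from the
farther one, symmetry around the mode would require extending the short side
to mode +- d2.  Whether that is feasible depends on the variable's natural
domain: precipitation cannot go below 0, a precipitation ratio cannot exceed
1.  Each species-variable combination is classified as centered (midpoint
already inside the highest-probability interval), expansion_possible,
expansion_impossible (the required limit falls outside the natural domain),
or undefined_d1_zero (mode sitting exactly on an extreme, so the true mode —
and hence the expansion factor d2/d1 — is unknowable).
"""
from __future__ import annotations

from dataclasses import dataclass

from .errors import ConfigurationError
from .io import VariableDomain

CATEGORIES = (
    "centered",
    "expansion_possible",
    "expansion_impossible",
    "undefined_d1_zero",
)


@dataclass(frozen=True)
class SymmetryAssessment:
    species: str
    variable: str
    mode: float
    d1: float
    d2: float
    expansion_side: str            # "left", "right" or "none"
    required_limit: float | None   # None when already symmetric
    category: str
    expansion_factor: float | None  # signed d2/d1; None when d1 = 0


def required_symmetric_limit(
    xmin: float, xmax: float, mode: float
) -> tuple[str, float | None, float, float]:
    """Range limit needed for the mode to sit at the midpoint of the limits.

    Returns (expansion_side, required_limit, d1, d2) with d1 the shorter and
    d2 the longer mode-to-extreme distance.  The short side must stretch to
    mode + d2 (right) or mode - d2 (left); with d1 = d2 nothing is required.
    """
    if not xmin < xmax:
        raise ValueError("xmin must be below xmax")
    if not xmin <= mode <= xmax:
        raise ValueError("mode must lie inside [xmin, xmax]")
    left, right = mode - xmin, xmax - mode
    d1, d2 = min(left, right), max(left, right)
    if left == right:
        return "none", None, d1, d2
    if right < left:  # short right tail: push the upper limit out
        return "right", mode + d2, d1, d2
    return "left", mode - d2, d1, d2


def expansion_factor(d1: float, d2: float, expansion_side: str) -> float | None:
    """Signed ratio d2/d1: positive to the right, negative to the left.

    Undefined (None) when d1 = 0 — the mode sits on an extreme and the true
    peak may lie beyond the observed range.
    """
    if d1 < 0 or d2 < d1:
        raise ValueError("need 0 <= d1 <= d2")
    if d1 == 0.0:
        return None
    if expansion_side == "none":
        return 1.0
    sign = 1.0 if expansion_side == "right" else -1.0
    return sign * d2 / d1


def classify_expansion(
    required_limit: float | None,
    expansion_side: str,
    domain: VariableDomain,
    rel_dis: float,
    d1: float,
) -> str:
    """Assign the four-way category for one species-variable combination.

    A truncated variable can still be expansion_possible when the required
    limit stops short of the bound; a required limit exactly on the bound
    counts as attainable.
    """
    if domain is None:
        raise ConfigurationError("variable has no registered domain")
    if rel_dis == 0.0:
        return "centered"
    if d1 == 0.0:
        return "undefined_d1_zero"
    if required_limit is None or expansion_side == "none":
        return "expansion_possible"
    if required_limit < domain.lower_bound or required_limit > domain.upper_bound:
        return "expansion_impossible"
    return "expansion_possible"


def assess_symmetry(
    species: str,
    variable: str,
    xmin: float,
    xmax: float,
    mode: float,
    rel_dis: float,
    domain: VariableDomain,
) -> SymmetryAssessment:
    """Full per-combination symmetry record."""
    side, limit, d1, d2 = required_symmetric_limit(xmin, xmax, mode)
    category = classify_expansion(limit, side, domain, rel_dis, d1)
    return SymmetryAssessment(
        species=species,
        variable=variable,
        mode=mode,
        d1=d1,
        d2=d2,
        expansion_side=side,
        required_limit=limit,
        category=category,
        expansion_factor=expansion_factor(d1, d2, side),
    )


def compare_required_to_observed(
    required_limit: float, study_range: tuple[float, float]
) -> bool:
    """Does the required limit already occur somewhere in the study data?

    True when it lies within the overall observed range of the variable
    across all species (closed interval: equality with an extreme counts).
    """
    lo, hi = study_range
    if not lo <= hi:
        raise ValueError("invalid study range")
    return lo <= required_limit <= hi
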