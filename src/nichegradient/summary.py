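"""Study-level aggregation: correlation screen, distance tallies, sign test."""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import OccurrenceTable


@dataclass
class StudySummary:
    n_combinations_input: int = 0
    n_excluded: int = 0
    n_analyzed: int = 0
    n_centered: int = 0
    n_below: int = 0
    n_above: int = 0
    sign_test_p: float | None = None
    per_species_centered_pct: dict[str, float] = field(default_factory=dict)
    correlation_summary: dict[str, float] | None = None
    category_counts: dict[str, int] = field(default_factory=dict)


def correlation_matrix(
    table: OccurrenceTable, variables: list[str] | None = None
) -> tuple[pd.DataFrame, dict]:
    """Pairwise Pearson r over all specimen rows pooled across species.

    Returns the full symmetric matrix and a summary of the (V^2-V)/2 unique
    off-diagonal coefficients: min/max/mean/median of |r| and the counts with
    |r| < 0.5 vs >= 0.5.  A zero-variance variable yields NaN entries, which
    are reported in ``n_undefined`` and excluded from the summary statistics.
    """
    if variables is None:
        variables = table.variables
    if len(variables) < 2:
        raise ValueError("need at least two variables")
    if len(table) < 3:
        raise ValueError("need at least three rows")
    corr = table.frame[variables].corr(method="pearson")
    iu = np.triu_indices(len(variables), k=1)
    r = corr.to_numpy()[iu]
    abs_r = np.abs(r[np.isfinite(r)])
    nan = float("nan")
    summary = {
        "n_pairs": int(r.size),
        "n_undefined": int(np.sum(~np.isfinite(r))),
        "min_abs_r": float(abs_r.min()) if abs_r.size else nan,
        "max_abs_r": float(abs_r.max()) if abs_r.size else nan,
        "mean_abs_r": float(abs_r.mean()) if abs_r.size else nan,
        "median_abs_r": float(np.median(abs_r)) if abs_r.size else nan,
        "n_below_half": int(np.sum(abs_r < 0.5)),
        "n_at_or_above_half": int(np.sum(abs_r >= 0.5)),
    }
    return corr, summary


def tally_distances(verdicts) -> tuple[int, int, int, dict[str, float]]:
    """Counts of combinations with the HPI containing / below / above the
    midpoint, plus each species' percentage of centered variables."""
    if not verdicts:
        raise ValueError("no verdicts to tally")
    sides = [v.side for v in verdicts]
    n_centered = sides.count("inside")
    n_below = sides.count("below")
    n_above = sides.count("above")
    per_species: dict[str, float] = {}
    for species in dict.fromkeys(v.species for v in verdicts):
        mine = [v for v in verdicts if v.species == species]
        inside = sum(1 for v in mine if v.side == "inside")
        per_species[species] = 100.0 * inside / len(mine)
    return n_centered, n_below, n_above, per_species


def sign_test(n_below: int, n_above: int) -> float:
    """Exact two-sided binomial test against an even split.

    p = min(1, 2 * smaller tail) under Binomial(n_below + n_above, 1/2).
    """
    n = n_below + n_above
    if n < 1:
        raise ValueError("need at least one off-center combination")
    k = min(n_below, n_above)
    return float(min(1.0, 2.0 * stats.binom.cdf(k, n, 0.5)))
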