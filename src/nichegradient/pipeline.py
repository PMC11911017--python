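"""End-to-end orchestration of the per-combination analysis.

For every species-variable combination: histogram -> Bonferroni-adjusted
Clopper-Pearson intervals -> exclusion check (no significant pair anywhere
means the sample cannot resolve differences and the combination is dropped)
-> marking rules -> polynomial logistic fit -> mode and 25%
highest-probability interval -> relative midpoint distance -> truncation /
expansion classification.  ``run_study`` sweeps the full species x variable
grid and aggregates.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import __version__
from .binning import (
    BinnedSample,
    attach_confidence_intervals,
    bin_counts,
    bonferroni_alpha,
    compute_bins,
    omnibus_chi_square,
    pairwise_significance,
)
from .curvefit import FittedDensity, MarkedPoints, fit_logistic_polynomial, mark_points
from .density import (
    HighestProbabilityInterval,
    highest_probability_interval,
    relative_distance,
    total_area,
)
from .errors import (
    CombinationExcluded,
    DegenerateSampleError,
    FitFailureError,
    NicheGradientError,
)
from .io import (
    AnalysisConfig,
    OccurrenceTable,
    SpeciesVariableSample,
    VariableDomain,
    check_domains_cover,
    extract_sample,
)
from .summary import StudySummary, correlation_matrix, sign_test, tally_distances
from .symmetry import SymmetryAssessment, assess_symmetry


@dataclass(frozen=True)
class GradientVerdict:
    """Where one species' highest-probability interval sits on one gradient."""

    species: str
    variable: str
    xmin: float
    xmax: float
    xmid: float
    xL: float
    xU: float
    rel_dis: float
    side: str  # inside | below | above


@dataclass
class CombinationResult:
    species: str
    variable: str
    n: int
    excluded: bool = False
    flags: list[str] = field(default_factory=list)
    binned: BinnedSample | None = None
    chi2_statistic: float | None = None
    chi2_df: int | None = None
    chi2_p: float | None = None
    marked: MarkedPoints | None = None
    fitted: FittedDensity | None = None
    area: float | None = None
    hpi: HighestProbabilityInterval | None = None
    verdict: GradientVerdict | None = None
    symmetry: SymmetryAssessment | None = None


def run_combination(
    sample: SpeciesVariableSample,
    domain: VariableDomain,
    config: AnalysisConfig | None = None,
) -> CombinationResult:
    """Full per-combination analysis; stage errors end up in ``flags``."""
    if config is None:
        config = AnalysisConfig()
    result = CombinationResult(sample.species, sample.variable, sample.n)
    try:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            edges = compute_bins(sample, config.bin_rule)
        if caught:
            result.flags.append("bin_rule_fallback_sturges")
        binned = bin_counts(sample, edges)
        alpha_adj = bonferroni_alpha(config.family_alpha, binned.k)
        binned = attach_confidence_intervals(binned, alpha_adj)
        sig = pairwise_significance(binned)
        override = config.degree_overrides.get((sample.species, sample.variable), 0)
        marked = mark_points(binned, sig, override)
        if config.bonferroni_k_rule == "n_marked":
            # one refinement pass: re-adjust alpha for the marked count,
            # rebuild the intervals, and re-run the marking scan once
            alpha_adj = bonferroni_alpha(config.family_alpha, marked.n_marked)
            binned = attach_confidence_intervals(binned, alpha_adj)
            sig = pairwise_significance(binned)
            marked = mark_points(binned, sig, override)
        result.binned = binned
        result.marked = marked
        stat, df, p = omnibus_chi_square(binned)
        result.chi2_statistic, result.chi2_df, result.chi2_p = stat, df, p

        fitted = fit_logistic_polynomial(
            binned, marked.degree, xmin=sample.xmin, xmax=sample.xmax
        )
        if fitted.degree_reductions:
            result.flags.append(f"degree_reduced_{fitted.degree_reductions}")
        result.fitted = fitted
        result.area = total_area(fitted, config.grid_points)
        hpi = highest_probability_interval(
            fitted, config.hpi_mass, config.grid_points
        )
        if hpi.mass_shortfall:
            result.flags.append("hpi_mass_shortfall")
        result.hpi = hpi
        rel_dis, side = relative_distance(
            hpi.xL, hpi.xU, sample.xmin, sample.xmax
        )
        result.verdict = GradientVerdict(
            species=sample.species,
            variable=sample.variable,
            xmin=sample.xmin,
            xmax=sample.xmax,
            xmid=(sample.xmin + sample.xmax) / 2.0,
            xL=hpi.xL,
            xU=hpi.xU,
            rel_dis=rel_dis,
            side=side,
        )
        result.symmetry = assess_symmetry(
            sample.species,
            sample.variable,
            sample.xmin,
            sample.xmax,
            hpi.mode,
            rel_dis,
            domain,
        )
    except CombinationExcluded:
        result.excluded = True
        result.flags.append("no_significant_pair")
    except (DegenerateSampleError, FitFailureError, NicheGradientError) as exc:
        result.excluded = True
        result.flags.append(f"stage_error:{type(exc).__name__}")
    return result


def run_study(
    table: OccurrenceTable,
    domains: Mapping[str, VariableDomain],
    config: AnalysisConfig | None = None,
    outdir: str | Path | None = None,
) -> tuple[list[CombinationResult], StudySummary]:
    """Analyze every species x variable combination and aggregate.

    Writes (when ``outdir`` is given) a results CSV with one row per
    combination, a symmetry CSV, a summary JSON and a run-metadata JSON.
    """
    if config is None:
        config = AnalysisConfig()
    check_domains_cover(table, domains)
    species = table.species
    if not species or not table.variables:
        raise ValueError("empty species x variable grid")

    results: list[CombinationResult] = []
    for sp in species:
        for var in table.variables:
            sample = extract_sample(table, sp, var)
            results.append(run_combination(sample, domains[var], config))

    analyzed = [r for r in results if not r.excluded]
    summary = StudySummary(
        n_combinations_input=len(results),
        n_excluded=len(results) - len(analyzed),
        n_analyzed=len(analyzed),
    )
    if analyzed:
        verdicts = [r.verdict for r in analyzed]
        n_c, n_b, n_a, per_species = tally_distances(verdicts)
        summary.n_centered, summary.n_below, summary.n_above = n_c, n_b, n_a
        summary.per_species_centered_pct = per_species
        if n_b + n_a:
            summary.sign_test_p = sign_test(n_b, n_a)
        for r in analyzed:
            cat = r.symmetry.category
            summary.category_counts[cat] = summary.category_counts.get(cat, 0) + 1
    if len(table.variables) >= 2 and len(table) >= 3:
        _, summary.correlation_summary = correlation_matrix(table)

    if outdir is not None:
        _write_outputs(results, summary, config, Path(outdir))
    return results, summary


def results_frame(results: list[CombinationResult]) -> pd.DataFrame:
    """One tidy row per combination, excluded or not."""
    rows = []
    for r in results:
        row: dict = {
            "species": r.species,
            "variable": r.variable,
            "n": r.n,
            "excluded": r.excluded,
            "flags": ";".join(r.flags),
        }
        if r.binned is not None:
            row.update(n_bins=r.binned.k, alpha_adj=r.binned.alpha_adj)
        if r.chi2_p is not None:
            row.update(
                chi2_statistic=r.chi2_statistic, chi2_df=r.chi2_df, chi2_p=r.chi2_p
            )
        if r.marked is not None:
            row.update(n_marked=r.marked.n_marked, degree=r.marked.degree)
        if r.fitted is not None:
            row["degree_fitted"] = r.fitted.degree
            row["coefficients_original"] = " ".join(
                repr(c) for c in r.fitted.coefficients_original
            )
        if r.verdict is not None:
            v = r.verdict
            row.update(
                xmin=v.xmin, xmax=v.xmax, xmid=v.xmid,
                mode=r.hpi.mode, xL=v.xL, xU=v.xU,
                hpi_mass=r.hpi.mass, rel_dis=v.rel_dis, side=v.side,
            )
        rows.append(row)
    return pd.DataFrame(rows)


def symmetry_frame(results: list[CombinationResult]) -> pd.DataFrame:
    """Per-combination symmetry table (required limits, categories, factors)."""
    rows = []
    # study-wide observed ranges per variable, for the "within range" check
    ranges: dict[str, tuple[float, float]] = {}
    for r in results:
        if r.verdict is None:
            continue
        lo, hi = ranges.get(r.variable, (np.inf, -np.inf))
        ranges[r.variable] = (min(lo, r.verdict.xmin), max(hi, r.verdict.xmax))
    for r in results:
        if r.symmetry is None:
            continue
        s = r.symmetry
        within = None
        if s.required_limit is not None and r.variable in ranges:
            lo, hi = ranges[r.variable]
            within = lo <= s.required_limit <= hi
        rows.append(
            {
                "species": s.species,
                "variable": s.variable,
                "mode": s.mode,
                "d1": s.d1,
                "d2": s.d2,
                "expansion_side": s.expansion_side,
                "required_limit": s.required_limit,
                "category": s.category,
                "expansion_factor": s.expansion_factor,
                "required_within_observed_range": within,
            }
        )
    return pd.DataFrame(rows)


def _write_outputs(
    results: list[CombinationResult],
    summary: StudySummary,
    config: AnalysisConfig,
    outdir: Path,
) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    results_frame(results).to_csv(outdir / "results.csv", index=False)
    symmetry_frame(results).to_csv(outdir / "symmetry.csv", index=False)
    (outdir / "summary.json").write_text(json.dumps(asdict(summary), indent=2))
    meta = {
        "package": "nichegradient",
        "version": __version__,
        "config": {
            "hpi_mass": config.hpi_mass,
            "family_alpha": config.family_alpha,
            "bin_rule": config.bin_rule,
            "bonferroni_k_rule": config.bonferroni_k_rule,
            "grid_points": config.grid_points,
            "seed": config.seed,
            "n_degree_overrides": len(config.degree_overrides),
        },
        "tolerances": {"hpi_mass_tol": 1e-4, "glm_tol": 1e-8, "glm_maxiter": 100},
    }
    (outdir / "run_metadata.json").write_text(json.dumps(meta, indent=2))
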