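"""Core data types and table input/output.

The unit of analysis is one species on one environmental gradient: a
:class:`SpeciesVariableSample`.  An :class:`OccurrenceTable` holds the raw
collection records (one row per site per species, with every environmental
variable filled in) from which samples are extracted.  Each variable carries a
:class:`VariableDomain` describing its natural mathematical domain — e.g.
precipitation cannot be negative, a precipitation ratio cannot exceed 1 —
which is what drives the gradient-truncation logic downstream.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError, FormatError, ParseError

REQUIRED_COLUMNS = ("species", "site_id", "longitude", "latitude")


@dataclass(frozen=True)
class VariableDomain:
    """Natural mathematical domain of an environmental variable.

    Unbounded sides are represented by ``-inf`` / ``+inf``.
    """

    variable: str
    lower_bound: float = -math.inf
    upper_bound: float = math.inf

    def __post_init__(self) -> None:
        if not self.variable:
            raise ConfigurationError("variable name must be non-empty")
        if not self.lower_bound < self.upper_bound:
            raise ConfigurationError(
                f"{self.variable}: lower bound {self.lower_bound} must be "
                f"below upper bound {self.upper_bound}"
            )

    @property
    def is_truncated(self) -> bool:
        """True when at least one side has a finite (binding) bound."""
        return math.isfinite(self.lower_bound) or math.isfinite(self.upper_bound)

    def contains(self, value: float) -> bool:
        return self.lower_bound <= value <= self.upper_bound


@dataclass(frozen=True)
class SpeciesVariableSample:
    """Raw occurrence values of one species on one environmental gradient."""

    species: str
    variable: str
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 1 or values.size < 2:
            raise ValueError("sample needs at least two values")
        if not np.all(np.isfinite(values)):
            raise ValueError(f"{self.species}/{self.variable}: non-finite values")

    @property
    def n(self) -> int:
        return int(self.values.size)

    @property
    def xmin(self) -> float:
        return float(self.values.min())

    @property
    def xmax(self) -> float:
        return float(self.values.max())


@dataclass(frozen=True)
class AnalysisConfig:
    """Tunable knobs of the per-combination pipeline.

    hpi_mass
        Fraction of the area under the fitted curve inside the
        highest-probability interval (0.25: the quarter of occurrences found
        with highest probability).
    family_alpha
        Family-wide error rate before Bonferroni adjustment.
    bin_rule
        ``fd_as_written`` — bin width 2*IQR/n^(1/3); ``sturges_r`` —
        ceil(log2 n)+1 bins with edges snapped to round numbers.
    bonferroni_k_rule
        What k divides alpha: ``n_bins`` (default) or ``n_marked``.
    degree_overrides
        Per (species, variable) adjustment of +-1 to the polynomial degree,
        reproducing manual corrections applied after visual inspection.
    """

    hpi_mass: float = 0.25
    family_alpha: float = 0.05
    bin_rule: str = "fd_as_written"
    bonferroni_k_rule: str = "n_bins"
    grid_points: int = 2001
    degree_overrides: Mapping[tuple[str, str], int] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.hpi_mass < 1.0:
            raise ConfigurationError("hpi_mass must be in (0, 1)")
        if not 0.0 < self.family_alpha < 1.0:
            raise ConfigurationError("family_alpha must be in (0, 1)")
        if self.bin_rule not in ("fd_as_written", "sturges_r"):
            raise ConfigurationError(f"unknown bin_rule {self.bin_rule!r}")
        if self.bonferroni_k_rule not in ("n_bins", "n_marked"):
            raise ConfigurationError(
                f"unknown bonferroni_k_rule {self.bonferroni_k_rule!r}"
            )
        if self.grid_points < 101:
            raise ConfigurationError("grid_points must be >= 101")


class OccurrenceTable:
    """Validated table of georeferenced collection records.

    One row per (species, site); columns ``species``, ``site_id``,
    ``longitude``, ``latitude`` plus one numeric column per environmental
    variable.  Coordinates are carried through but never computed on.
    """

    def __init__(self, frame: pd.DataFrame, variables: list[str] | None = None):
        frame = frame.reset_index(drop=True)
        missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
        if missing:
            raise FormatError(f"missing required columns: {missing}")
        if variables is None:
            variables = [c for c in frame.columns if c not in REQUIRED_COLUMNS]
        if not variables:
            raise FormatError("no environmental-variable columns declared")
        self.variables = list(variables)
        self._validate(frame)
        self.frame = frame

    def _validate(self, frame: pd.DataFrame) -> None:
        if frame["species"].astype(str).str.len().eq(0).any():
            raise ParseError("empty species label")
        dup = frame.duplicated(subset=["species", "site_id"])
        if dup.any():
            row = int(np.flatnonzero(dup.to_numpy())[0])
            raise ParseError(
                f"duplicated (species, site_id) pair at row {row}: "
                f"{frame.loc[row, 'species']!r}/{frame.loc[row, 'site_id']!r}"
            )
        for col in self.variables:
            if col not in frame.columns:
                raise FormatError(f"declared variable {col!r} not in table")
            numeric = pd.to_numeric(frame[col], errors="coerce")
            bad = numeric.isna()
            if bad.any():
                row = int(np.flatnonzero(bad.to_numpy())[0])
                raise ParseError(
                    f"non-numeric or missing value in column {col!r}, row {row} "
                    f"(species {frame.loc[row, 'species']!r})"
                )
            frame[col] = numeric.astype(float)

    @property
    def species(self) -> list[str]:
        return list(dict.fromkeys(self.frame["species"]))

    @property
    def n_rows(self) -> int:
        return len(self.frame)

    def __len__(self) -> int:
        return self.n_rows


def load_occurrence_table(
    path: str | Path,
    fmt: str | None = None,
    aliases: Mapping[str, str] | None = None,
) -> OccurrenceTable:
    """Read an occurrence table from CSV/TSV/XLSX and validate it.

    ``aliases`` optionally renames spreadsheet-style headers to canonical
    variable labels before validation (the packaged registry ships a default
    alias table; pass ``load_default_aliases()``).
    """
    path = Path(path)
    if fmt is None:
        fmt = {".csv": "csv", ".tsv": "tsv", ".xlsx": "xlsx"}.get(path.suffix.lower())
        if fmt is None:
            raise FormatError(f"cannot infer format from suffix {path.suffix!r}")
    if fmt == "csv":
        frame = pd.read_csv(path)
    elif fmt == "tsv":
        frame = pd.read_csv(path, sep="\t")
    elif fmt == "xlsx":
        frame = pd.read_excel(path)
    else:
        raise FormatError(f"unknown format {fmt!r}")
    if aliases:
        frame = frame.rename(columns=dict(aliases))
    return OccurrenceTable(frame)


def write_occurrence_table(table: OccurrenceTable, path: str | Path) -> None:
    """Write to CSV with shortest-round-trip float formatting (lossless)."""
    frame = table.frame.copy()
    for col in table.variables:
        frame[col] = frame[col].map(repr)
    frame.to_csv(path, index=False)


def extract_sample(
    table: OccurrenceTable, species: str, variable: str
) -> SpeciesVariableSample:
    """Pull one species-variable sample out of the table, in row order."""
    if variable not in table.variables:
        raise KeyError(f"unknown variable {variable!r}")
    mask = table.frame["species"] == species
    if not mask.any():
        raise KeyError(f"unknown species {species!r}")
    values = table.frame.loc[mask, variable].to_numpy(dtype=float)
    return SpeciesVariableSample(species, variable, values)


def _domains_from_mapping(spec: Mapping) -> dict[str, VariableDomain]:
    registry: dict[str, VariableDomain] = {}
    for name, bounds in spec.items():
        lower = bounds.get("lower")
        upper = bounds.get("upper")
        registry[name] = VariableDomain(
            variable=name,
            lower_bound=-math.inf if lower is None else float(lower),
            upper_bound=math.inf if upper is None else float(upper),
        )
    return registry


def _packaged_config() -> dict:
    text = (
        resources.files("nichegradient") / "_data" / "variable_domains.yml"
    ).read_text()
    return yaml.safe_load(text)


def default_variable_domains() -> dict[str, VariableDomain]:
    """The shipped registry for the study's 16 environmental gradients."""
    return _domains_from_mapping(_packaged_config()["variables"])


def load_default_aliases() -> dict[str, str]:
    return dict(_packaged_config()["aliases"])


def load_variable_domains(path: str | Path | None = None) -> dict[str, VariableDomain]:
    """Load a domain registry from a YAML file (or the packaged default)."""
    if path is None:
        return default_variable_domains()
    spec = yaml.safe_load(Path(path).read_text())
    if "variables" not in spec:
        raise ConfigurationError("domain config must have a 'variables' mapping")
    return _domains_from_mapping(spec["variables"])


def check_domains_cover(
    table: OccurrenceTable, domains: Mapping[str, VariableDomain]
) -> None:
    """Every variable in the table must be registered and contain its data."""
    for var in table.variables:
        if var not in domains:
            raise ConfigurationError(f"variable {var!r} absent from domain registry")
        dom = domains[var]
        values = table.frame[var]
        if (values < dom.lower_bound).any() or (values > dom.upper_bound).any():
            raise ConfigurationError(
                f"values of {var!r} fall outside its domain "
                f"[{dom.lower_bound}, {dom.upper_bound}]"
            )


def load_analysis_config(path: str | Path) -> AnalysisConfig:
    """Read an AnalysisConfig from a YAML key/value file."""
    spec = yaml.safe_load(Path(path).read_text()) or {}
    overrides = {}
    for entry in spec.pop("degree_overrides", []) or []:
        overrides[(entry["species"], entry["variable"])] = int(entry["adjustment"])
    return AnalysisConfig(degree_overrides=overrides, **spec)
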