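"""Core domain types and CSV I/O for tree- and plot-level forest tables.

The package works on a simple two-table layout: a tree table (one row per
measured stem: plot id, species code, diameter at breast height in cm, total
height in m) and a plot table (one row per sample plot: area and the site /
soil / climate covariates).  Units are fixed: cm for diameters, m for heights
and elevation, ha for plot area, mm for precipitation, g/kg for soil
concentrations.  No unit inference is attempted.

Heights are measured from the ground, so a usable height must exceed the
1.3 m breast-height offset of the allometric model; violations are flagged by
:func:`validate_dataset` rather than silently dropped.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

BREAST_HEIGHT_M = 1.3
#: survey threshold: stems below this diameter are excluded from modelling
MIN_MODEL_DBH_CM = 5.0
#: species with fewer stems than this are excluded from per-species fits
DEFAULT_MIN_SPECIES_N = 100

#: default column-name schema for tree tables
TREE_SCHEMA = {
    "plot_id": "plot_id",
    "species": "species",
    "dbh_cm": "dbh_cm",
    "height_m": "height_m",
}
#: default column-name schema for plot tables (plot_id and area are required,
#: everything else is picked up as a covariate column if present)
PLOT_SCHEMA = {
    "plot_id": "plot_id",
    "area_ha": "area_ha",
}

CLIMATE_VARIABLES = (
    "MAT", "MWMT", "MCMT", "TD", "MAP", "AHM", "DD_0", "DD5", "DD_18",
    "DD18", "NFFD", "PAS", "EMT", "EXT", "Eref", "CMD",
)


class SchemaError(ValueError):
    """A required column is missing or unresolvable."""


class ParseError(ValueError):
    """A cell failed to parse; carries the offending line number."""


@dataclass(frozen=True)
class TreeRecord:
    """One measured stem."""

    plot_id: str
    species: str
    dbh_cm: float
    height_m: float | None = None

    def __post_init__(self) -> None:
        if not self.dbh_cm > 0:
            raise ValueError(f"dbh_cm must be positive, got {self.dbh_cm}")

    @property
    def has_valid_height(self) -> bool:
        return self.height_m is not None and self.height_m > BREAST_HEIGHT_M


@dataclass
class PlotRecord:
    """One sample plot with its site, soil and climate covariates.

    ``covariates`` holds every numeric plot-level variable (soil, site,
    climate and any derived stand metric that has been attached); well-known
    names (SOC, MAP, EL, SL, ...) are plain keys of this mapping.
    """

    plot_id: str
    area_ha: float
    covariates: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.area_ha > 0:
            raise ValueError(f"area_ha must be positive, got {self.area_ha}")

    def validate(self) -> list[str]:
        """Return a list of human-readable range violations (empty if clean)."""
        problems: list[str] = []
        c = self.covariates
        sl = c.get("SL")
        if sl is not None and not (0 <= sl < 90):
            problems.append(f"plot {self.plot_id}: slope {sl} outside [0, 90)")
        texture = [c.get(k) for k in ("Sand", "Silt", "Clay")]
        if all(v is not None for v in texture):
            tot = sum(texture)  # type: ignore[arg-type]
            if not 95 <= tot <= 105:
                problems.append(
                    f"plot {self.plot_id}: sand+silt+clay = {tot:.1f}% outside [95, 105]"
                )
        map_mm = c.get("MAP")
        if map_mm is not None and map_mm < 0:
            problems.append(f"plot {self.plot_id}: MAP {map_mm} < 0")
        mat = c.get("MAT")
        if mat is not None and mat <= -10 and ("AHM" in c or "M" in c):
            problems.append(
                f"plot {self.plot_id}: AHM/M undefined for MAT {mat} <= -10"
            )
        return problems


@dataclass
class ValidationReport:
    """Outcome of :func:`validate_dataset` (report-only, never raises)."""

    orphan_trees: list[int] = field(default_factory=list)
    out_of_range: list[str] = field(default_factory=list)
    below_breast_height: list[int] = field(default_factory=list)
    excluded_species: dict[str, int] = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return not (self.orphan_trees or self.out_of_range or self.below_breast_height)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)


@dataclass
class ForestDataset:
    """Trees plus plots plus the species registry, as one unit."""

    trees: list[TreeRecord]
    plots: dict[str, PlotRecord]
    species_registry: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.species_registry:
            seen: dict[str, None] = {}
            for t in self.trees:
                seen.setdefault(t.species, None)
            self.species_registry = list(seen)

    def trees_in_plot(self, plot_id: str) -> list[TreeRecord]:
        return [t for t in self.trees if t.plot_id == plot_id]

    def modelling_subset(
        self, min_dbh_cm: float = MIN_MODEL_DBH_CM
    ) -> "ForestDataset":
        """Trees usable for height modelling: D >= threshold, height above 1.3 m."""
        kept = [
            t for t in self.trees
            if t.dbh_cm >= min_dbh_cm and t.has_valid_height and t.plot_id in self.plots
        ]
        n_dropped = len(self.trees) - len(kept)
        if n_dropped:
            logger.warning(
                "modelling_subset: dropped %d of %d trees (small D, missing/"
                "sub-breast-height H, or orphan plot)", n_dropped, len(self.trees),
            )
        return ForestDataset(kept, dict(self.plots), list(self.species_registry))

    def to_frame(self) -> pd.DataFrame:
        """Tree table joined with each tree's plot covariates (one row per stem)."""
        rows = []
        for t in self.trees:
            row: dict[str, object] = {
                "plot_id": t.plot_id,
                "species": t.species,
                "dbh_cm": t.dbh_cm,
                "height_m": t.height_m,
            }
            plot = self.plots.get(t.plot_id)
            if plot is not None:
                row["area_ha"] = plot.area_ha
                row.update(plot.covariates)
            rows.append(row)
        return pd.DataFrame(rows)


def _resolve_columns(
    df: pd.DataFrame, schema: Mapping[str, str], required: Iterable[str]
) -> dict[str, str]:
    resolved = {}
    for key in required:
        col = schema.get(key, key)
        if col not in df.columns:
            raise SchemaError(
                f"required column '{col}' (for field '{key}') not found; "
                f"available: {list(df.columns)}"
            )
        resolved[key] = col
    return resolved


def read_trees(
    path, schema: Mapping[str, str] | None = None
) -> list[TreeRecord]:
    """Read a tree table from CSV.

    ``schema`` maps the canonical field names (plot_id, species, dbh_cm,
    height_m) to the file's column names; missing entries default to the
    canonical name itself.  Heights may be blank (missing).
    """
    schema = {**TREE_SCHEMA, **(schema or {})}
    df = pd.read_csv(path, dtype=str)
    cols = _resolve_columns(df, schema, ["plot_id", "species", "dbh_cm"])
    height_col = schema["height_m"] if schema["height_m"] in df.columns else None

    trees: list[TreeRecord] = []
    errors: list[str] = []
    for idx, row in df.iterrows():
        line = idx + 2  # header is line 1
        try:
            dbh = float(row[cols["dbh_cm"]])
        except (TypeError, ValueError):
            errors.append(f"line {line}: non-numeric dbh {row[cols['dbh_cm']]!r}")
            continue
        height: float | None = None
        if height_col is not None:
            raw = row[height_col]
            if raw is not None and str(raw).strip() not in ("", "nan", "NA"):
                try:
                    height = float(raw)
                except ValueError:
                    errors.append(f"line {line}: non-numeric height {raw!r}")
                    continue
        try:
            trees.append(
                TreeRecord(str(row[cols["plot_id"]]), str(row[cols["species"]]), dbh, height)
            )
        except ValueError as exc:
            errors.append(f"line {line}: {exc}")
    if errors:
        raise ParseError("; ".join(errors))
    return trees


def read_plots(
    path, schema: Mapping[str, str] | None = None
) -> dict[str, PlotRecord]:
    """Read a plot table from CSV; every numeric column beyond id/area becomes
    a covariate."""
    schema = {**PLOT_SCHEMA, **(schema or {})}
    df = pd.read_csv(path)
    cols = _resolve_columns(df, schema, ["plot_id", "area_ha"])
    plots: dict[str, PlotRecord] = {}
    for idx, row in df.iterrows():
        pid = str(row[cols["plot_id"]])
        if pid in plots:
            raise ParseError(f"duplicate plot_id {pid!r} at line {idx + 2}")
        covs = {}
        for col in df.columns:
            if col in (cols["plot_id"], cols["area_ha"]):
                continue
            val = row[col]
            if pd.notna(val):
                covs[col] = float(val)
        rec = PlotRecord(pid, float(row[cols["area_ha"]]), covs)
        problems = rec.validate()
        if problems:
            raise ParseError("; ".join(problems))
        plots[pid] = rec
    return plots


def write_trees(trees: Sequence[TreeRecord], path) -> None:
    pd.DataFrame(
        {
            "plot_id": [t.plot_id for t in trees],
            "species": [t.species for t in trees],
            "dbh_cm": [t.dbh_cm for t in trees],
            "height_m": [t.height_m for t in trees],
        }
    ).to_csv(path, index=False)


def write_plots(plots: Mapping[str, PlotRecord], path) -> None:
    rows = []
    for rec in plots.values():
        row = {"plot_id": rec.plot_id, "area_ha": rec.area_ha}
        row.update(rec.covariates)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def validate_dataset(
    ds: ForestDataset, min_species_n: int = DEFAULT_MIN_SPECIES_N
) -> ValidationReport:
    """Report (never fix) structural and range problems in a dataset.

    Lists orphan trees (plot_id with no plot record), plot covariates outside
    their physical ranges, trees whose recorded height is at or below breast
    height, and species with fewer than ``min_species_n`` stems, which are
    marked for exclusion from per-species fits.
    """
    report = ValidationReport()
    counts: dict[str, int] = {}
    for i, t in enumerate(ds.trees):
        counts[t.species] = counts.get(t.species, 0) + 1
        if t.plot_id not in ds.plots:
            report.orphan_trees.append(i)
        if t.height_m is not None and t.height_m <= BREAST_HEIGHT_M:
            report.below_breast_height.append(i)
        if not math.isfinite(t.dbh_cm):
            report.out_of_range.append(f"tree {i}: non-finite dbh")
    for rec in ds.plots.values():
        report.out_of_range.extend(rec.validate())
    report.excluded_species = {
        sp: n for sp, n in counts.items() if n < min_species_n
    }
    for sp, n in report.excluded_species.items():
        logger.info("species %s has %d < %d trees: excluded from per-species fits",
                    sp, n, min_species_n)
    return report
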