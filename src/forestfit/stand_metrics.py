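"""Derived stand, site, diversity and climate-composite covariates.

Everything here is a deterministic function of the tree list and the raw
plot covariates: quadratic mean diameter (QMD), mean diameter (MD), basal
area (BA) and stem density per hectare, basal-area-in-larger-trees (BAL),
dominant height (DH), Gini-Simpson and Shannon diversity indices, the Stage
slope-elevation composites (SIE/CIE), the de Martonne aridity index M and
the annual heat:moisture index (AHM).

Conventions:

* BAL uses *strictly* greater diameters, so the unique largest tree of a
  plot has BAL exactly 0 and equal-diameter trees contribute nothing to each
  other; BAL, BA and stem counts are expressed per hectare.
* The Simpson index is the Gini-Simpson form 1 - sum(p_i^2), which is 0 for
  a pure stand.
* Slope is recorded in degrees and converted to radians before sin/cos.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data_model import ForestDataset, TreeRecord


@dataclass
class StandMetrics:
    """Per-plot bundle of derived covariates (units in field names)."""

    plot_id: str
    qmd_cm: float
    md_cm: float
    ba_m2_ha: float
    n_per_ha: float
    dh_m: float | None
    sim: float
    shi: float
    bal_by_tree: dict[int, float] = field(default_factory=dict)

    def as_dict(self) -> dict[str, float]:
        d = {
            "QMD": self.qmd_cm,
            "MD": self.md_cm,
            "BA": self.ba_m2_ha,
            "N": self.n_per_ha,
            "SIM": self.sim,
            "SHI": self.shi,
        }
        if self.dh_m is not None:
            d["DH"] = self.dh_m
        return d


def tree_basal_area(dbh_cm: float) -> float:
    """Cross-sectional stem area at breast height, m², from D in cm."""
    if not dbh_cm > 0:
        raise ValueError(f"dbh must be positive, got {dbh_cm}")
    return math.pi * (dbh_cm / 200.0) ** 2


def compute_qmd(dbh_list: Sequence[float]) -> float:
    """Quadratic mean diameter: sqrt of the mean squared D, cm."""
    d = np.asarray(dbh_list, dtype=float)
    if d.size == 0:
        raise ValueError("QMD undefined for an empty diameter list")
    if np.any(d <= 0):
        raise ValueError("all diameters must be positive")
    return float(np.sqrt(np.mean(d**2)))


def compute_bal(dbh_list: Sequence[float], area_ha: float) -> np.ndarray:
    """Basal area of strictly larger trees, m²/ha, aligned with the input.

    The one-sided competition index: for each stem, the summed basal area of
    all plot neighbours with strictly greater D, scaled to a per-hectare
    basis.  Ties contribute nothing to each other, so every maximal tree has
    BAL exactly 0.
    """
    if not area_ha > 0:
        raise ValueError(f"area_ha must be positive, got {area_ha}")
    d = np.asarray(dbh_list, dtype=float)
    if d.size == 0:
        return np.empty(0)
    ba = np.pi * (d / 200.0) ** 2
    order = np.argsort(d, kind="stable")  # ascending
    d_sorted = d[order]
    ba_sorted = ba[order]
    # suffix sums of basal area over strictly larger diameters
    suffix = np.concatenate([np.cumsum(ba_sorted[::-1])[::-1], [0.0]])
    # for each tree, index of first strictly greater D in the sorted array
    first_greater = np.searchsorted(d_sorted, d, side="right")
    return suffix[first_greater] / area_ha


def simpson_index(abundances: Mapping[str, float]) -> float:
    """Gini-Simpson diversity 1 - sum(p_i^2); 0 for a pure stand."""
    counts = np.asarray([c for c in abundances.values()], dtype=float)
    if np.any(counts < 0):
        raise ValueError("abundances must be non-negative")
    total = counts.sum()
    if total <= 0:
        raise ValueError("at least one abundance must be positive")
    p = counts / total
    return float(1.0 - np.sum(p**2))


def shannon_index(abundances: Mapping[str, float]) -> float:
    """Shannon diversity -sum(p_i ln p_i) over species with p_i > 0."""
    counts = np.asarray([c for c in abundances.values()], dtype=float)
    if np.any(counts < 0):
        raise ValueError("abundances must be non-negative")
    total = counts.sum()
    if total <= 0:
        raise ValueError("at least one abundance must be positive")
    p = counts[counts > 0] / total
    return float(-np.sum(p * np.log(p)))


def stage_transforms(slope_deg: float, elevation_m: float) -> tuple[float, float]:
    """Stage slope-elevation composites (SIE, CIE).

    SIE = sin(SL)·ln(EL) and CIE = cos(SL)·ln(EL), with the slope converted
    from degrees to radians before the trigonometric call.
    """
    if not elevation_m > 1:
        raise ValueError(f"elevation must exceed 1 m for ln(EL), got {elevation_m}")
    rad = math.radians(slope_deg)
    ln_el = math.log(elevation_m)
    return math.sin(rad) * ln_el, math.cos(rad) * ln_el


def de_martonne(map_mm: float, mat_c: float) -> float:
    """de Martonne aridity index M = MAP / (MAT + 10)."""
    if not mat_c > -10:
        raise ValueError(f"M undefined for MAT <= -10 °C, got {mat_c}")
    return map_mm / (mat_c + 10.0)


def annual_heat_moisture(mat_c: float, map_mm: float) -> float:
    """Annual heat:moisture index AHM = (MAT + 10) / (MAP / 1000)."""
    if not map_mm > 0:
        raise ValueError(f"AHM undefined for MAP <= 0, got {map_mm}")
    if not mat_c > -10:
        raise ValueError(f"AHM undefined for MAT <= -10 °C, got {mat_c}")
    return (mat_c + 10.0) / (map_mm / 1000.0)


def dominant_height(trees_in_plot: Sequence[TreeRecord]) -> float:
    """Dominant height: mean over species of the tallest stem per species, m."""
    maxima: dict[str, float] = {}
    for t in trees_in_plot:
        if t.height_m is not None:
            prev = maxima.get(t.species)
            if prev is None or t.height_m > prev:
                maxima[t.species] = t.height_m
    if not maxima:
        raise ValueError("no measured heights in plot")
    return float(np.mean(list(maxima.values())))


def species_abundances(
    trees_in_plot: Sequence[TreeRecord],
    min_dbh_cm: float = 5.0,
    extra_counts: Mapping[str, float] | None = None,
) -> dict[str, float]:
    """Stem counts per species for the diversity indices.

    Defaults to stems with D >= 5 cm; tallied counts of smaller stems (the
    survey records them separately) can be merged via ``extra_counts``.
    """
    counts: dict[str, float] = {}
    for t in trees_in_plot:
        if t.dbh_cm >= min_dbh_cm:
            counts[t.species] = counts.get(t.species, 0) + 1
    for sp, n in (extra_counts or {}).items():
        counts[sp] = counts.get(sp, 0) + n
    return counts


def compute_stand_metrics(
    ds: ForestDataset,
    plot_id: str,
    min_dbh_cm: float = 5.0,
    small_tree_counts: Mapping[str, float] | None = None,
) -> StandMetrics:
    """Assemble all derived stand metrics for one plot.

    ``bal_by_tree`` is keyed by the tree's index within the dataset's tree
    list, so values align with the global table order.
    """
    plot = ds.plots[plot_id]
    indexed = [(i, t) for i, t in enumerate(ds.trees) if t.plot_id == plot_id]
    if not indexed:
        raise ValueError(f"plot {plot_id!r} has no trees")
    trees = [t for _, t in indexed]
    d = [t.dbh_cm for t in trees]
    bal = compute_bal(d, plot.area_ha)
    abund = species_abundances(trees, min_dbh_cm, small_tree_counts)
    try:
        dh: float | None = dominant_height(trees)
    except ValueError:
        dh = None
    return StandMetrics(
        plot_id=plot_id,
        qmd_cm=compute_qmd(d),
        md_cm=float(np.mean(d)),
        ba_m2_ha=float(sum(tree_basal_area(x) for x in d) / plot.area_ha),
        n_per_ha=len(trees) / plot.area_ha,
        dh_m=dh,
        sim=simpson_index(abund),
        shi=shannon_index(abund),
        bal_by_tree={i: float(b) for (i, _), b in zip(indexed, bal)},
    )


def attach_stand_metrics(ds: ForestDataset, min_dbh_cm: float = 5.0) -> pd.DataFrame:
    """Compute metrics for every plot, store them on the plot records, and
    return the tree-level frame with per-tree BAL and plot covariates joined.

    Adds QMD, MD, BA, N, SIM, SHI (and DH where heights exist) to each
    ``PlotRecord.covariates``, and derives M and AHM when MAT and MAP are
    present.  Returns the modelling frame with a ``BAL`` column.
    """
    bal_all: dict[int, float] = {}
    for pid, rec in ds.plots.items():
        if not any(t.plot_id == pid for t in ds.trees):
            continue
        m = compute_stand_metrics(ds, pid, min_dbh_cm)
        rec.covariates.update(m.as_dict())
        if "MAT" in rec.covariates and "MAP" in rec.covariates:
            rec.covariates["M"] = de_martonne(rec.covariates["MAP"], rec.covariates["MAT"])
            rec.covariates["AHM"] = annual_heat_moisture(
                rec.covariates["MAT"], rec.covariates["MAP"])
        if "SL" in rec.covariates and "EL" in rec.covariates and rec.covariates["EL"] > 1:
            sie, cie = stage_transforms(rec.covariates["SL"], rec.covariates["EL"])
            rec.covariates["SIE"] = sie
            rec.covariates["CIE"] = cie
        bal_all.update(m.bal_by_tree)
    frame = ds.to_frame()
    frame["BAL"] = [bal_all.get(i, np.nan) for i in range(len(ds.trees))]
    return frame


def plot_metrics_table(ds: ForestDataset) -> pd.DataFrame:
    """One row per plot with all stored covariates (for CSV export)."""
    rows = []
    for rec in ds.plots.values():
        row: dict[str, object] = {"plot_id": rec.plot_id, "area_ha": rec.area_ha}
        row.update(rec.covariates)
        rows.append(row)
    return pd.DataFrame(rows)
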