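"""Allometric-exponent analysis and covariate-gradient height simulation.

Metabolic scaling theory predicts H proportional to D^(2/3); comparing each
species' fitted exponent (with its Wald interval) against 2/3 diagnoses how
species traits and environment modulate the allometry.  The gradient
simulation sweeps one covariate across its empirical 5th/50th/95th
percentiles while the others sit at their means, tracing population-level
height curves over a D grid.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import DEFAULT_MIN_SPECIES_N
from .nls_fitting import (
    DBH_COLUMN,
    FixedEffects,
    PowerHeightModel,
    predict_height,
)
from .nlme_engine import NlmeFitResult

#: metabolic-scaling-theory exponent
THEORY_EXPONENT = 2.0 / 3.0


@dataclass
class ExponentReport:
    by_species: pd.DataFrame
    cross_species: float
    cross_species_se: float
    theory: float = THEORY_EXPONENT


@dataclass
class GradientGrid:
    target_covariate: str
    nodes: dict[str, float]           # percentile label -> node value
    other_covariates: dict[str, float]
    curves: pd.DataFrame              # columns: node, dbh_cm, height_m


def species_exponents(
    frame: pd.DataFrame, y_col: str = "height_m", species_col: str = "species",
    min_species_n: int = DEFAULT_MIN_SPECIES_N, conf_level: float = 0.95,
) -> ExponentReport:
    """Per-species base-model exponents plus the pooled cross-species fit.

    Flags species whose Wald confidence interval excludes the theoretical
    2/3 exponent.
    """
    z = stats.norm.ppf(0.5 + conf_level / 2)
    rows = []
    for sp, grp in frame.groupby(species_col):
        if len(grp) < min_species_n:
            continue
        est = PowerHeightModel().fit(grp, grp[y_col])
        b1, se = est.fixed_effects_.beta1, est.se_.beta1
        rows.append({"species": sp, "n": len(grp), "beta1": b1, "se": se,
                     "ci_low": b1 - z * se, "ci_high": b1 + z * se,
                     "excludes_theory": not (b1 - z * se <= THEORY_EXPONENT <= b1 + z * se)})
    pooled = PowerHeightModel().fit(frame, frame[y_col])
    return ExponentReport(pd.DataFrame(rows), pooled.fixed_effects_.beta1,
                          pooled.se_.beta1)


def _fixed_effects_of(fit) -> FixedEffects:
    if isinstance(fit, FixedEffects):
        return fit
    if isinstance(fit, NlmeFitResult):
        return fit.fixed
    if hasattr(fit, "estimates"):
        return fit.estimates
    if hasattr(fit, "fixed_effects_"):
        return fit.fixed_effects_
    raise TypeError(f"cannot extract fixed effects from {type(fit)!r}")


def gradient_simulation(
    fit, frame: pd.DataFrame, target: str,
    d_grid: np.ndarray | None = None,
    percentiles: Sequence[float] = (5, 50, 95),
) -> GradientGrid:
    """Population-level height curves with ``target`` at its empirical
    percentile nodes and every other model covariate at its mean.

    Percentiles are linear-interpolation empirical quantiles of the frame's
    covariate column; random effects are set to zero (the curves describe
    the fixed-effect structure).
    """
    fe = _fixed_effects_of(fit)
    if target not in fe.exponent_coefs:
        raise KeyError(f"covariate {target!r} is not in the fitted model")
    if d_grid is None:
        d_grid = np.linspace(5.0, float(frame[DBH_COLUMN].max()), 50)
    d_grid = np.asarray(d_grid, dtype=float)
    others = {c: float(frame[c].mean()) for c in fe.exponent_coefs if c != target}
    nodes = {f"p{int(q) if float(q).is_integer() else q}":
             float(np.percentile(frame[target].to_numpy(dtype=float), q))
             for q in percentiles}
    rows = []
    for label, val in nodes.items():
        covs = {**others, target: val}
        h = predict_height(fe, d_grid, covs)
        for dv, hv in zip(d_grid, h):
            rows.append({"node": label, "node_value": val, "dbh_cm": dv, "height_m": hv})
    return GradientGrid(target, nodes, others, pd.DataFrame(rows))


def slope_summary(
    fit, frame: pd.DataFrame, species_col: str = "species",
    rel_step: float = 0.01,
) -> pd.DataFrame:
    """Marginal finite-difference slope dH/dx per (species, covariate).

    Evaluated at the species' median D with every covariate at the species
    mean; the step is ``rel_step`` times the covariate SD (falling back to
    |mean| or 1 for constant covariates).
    """
    fe = _fixed_effects_of(fit)
    rows = []
    for sp, grp in frame.groupby(species_col):
        d_med = float(grp[DBH_COLUMN].median())
        means = {c: float(grp[c].mean()) for c in fe.exponent_coefs}
        for cov in fe.exponent_coefs:
            sd = float(grp[cov].std())
            step = rel_step * (sd if sd > 0 else max(abs(means[cov]), 1.0))
            hi = dict(means)
            lo = dict(means)
            hi[cov] += step
            lo[cov] -= step
            slope = (predict_height(fe, d_med, hi) - predict_height(fe, d_med, lo)) / (2 * step)
            rows.append({"species": sp, "covariate": cov, "median_dbh": d_med,
                         "slope": float(slope)})
    return pd.DataFrame(rows)
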