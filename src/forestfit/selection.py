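"""Two-stage covariate selection with VIF screening and the AIC ladder.

Stage 1 fits the base power model separately per species, then screens
candidate covariates by the Pearson correlation between the species-level
coefficients (or optional plot-level refits) and each covariate.  Stage 2
keeps a multicollinearity-free subset via iterated variance-inflation-factor
(VIF) filtering at VIF <= 5, and ranks nested covariate combinations by AIC:
starting from the base model, covariates are added one group at a time
(developmental stage, competition, diversity, climate, soil by default) and
each rung's AIC, log-likelihood and R² are reported.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import DEFAULT_MIN_SPECIES_N
from .evaluation import r2 as _r2
from .nls_fitting import PowerHeightModel

logger = logging.getLogger(__name__)

#: canonical build-up order of the covariate ladder: stand developmental
#: stage, competition, species diversity, climate, soil
DEFAULT_LADDER_ORDER: tuple[tuple[str, str], ...] = (
    ("developmental stage", "QMD"),
    ("competition", "BAL"),
    ("species diversity", "SIM"),
    ("climate", "MAP"),
    ("soil", "SOC"),
)

VIF_THRESHOLD = 5.0


@dataclass
class CandidateSet:
    """Candidate covariates grouped by theme, with their per-unit values."""

    groups: dict[str, list[str]]
    values: pd.DataFrame

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for g, names in self.groups.items():
            for nm in names:
                if nm in seen:
                    raise ValueError(f"covariate {nm!r} appears in two groups")
                seen.add(nm)
                if nm not in self.values.columns:
                    raise KeyError(f"covariate {nm!r} has no column in values")
                if not np.issubdtype(self.values[nm].dtype, np.number):
                    raise TypeError(f"covariate {nm!r} is not numeric")

    @property
    def all_names(self) -> list[str]:
        return [nm for names in self.groups.values() for nm in names]


@dataclass
class SelectionResult:
    chosen: list[str] = field(default_factory=list)
    vif_table: dict[str, float] = field(default_factory=dict)
    stage1_correlations: pd.DataFrame | None = None
    aic_ladder: pd.DataFrame | None = None

    def to_json(self) -> str:
        return json.dumps({
            "chosen": self.chosen,
            "vif_table": self.vif_table,
            "stage1_correlations": (self.stage1_correlations.to_dict("records")
                                    if self.stage1_correlations is not None else None),
            "aic_ladder": (self.aic_ladder.to_dict("records")
                           if self.aic_ladder is not None else None),
        }, indent=2, default=float)


def stage1_species_fits(
    frame: pd.DataFrame, y_col: str = "height_m", species_col: str = "species",
    min_species_n: int = DEFAULT_MIN_SPECIES_N,
) -> pd.DataFrame:
    """Per-species base-model fits: one row per included species with
    (beta0, beta1) and their SEs; failures are recorded, not fatal."""
    rows = []
    for sp, grp in frame.groupby(species_col):
        if len(grp) < min_species_n:
            continue
        try:
            est = PowerHeightModel().fit(grp, grp[y_col])
            rows.append({"species": sp, "n": len(grp),
                         "beta0": est.fixed_effects_.beta0,
                         "beta1": est.fixed_effects_.beta1,
                         "se_beta0": est.se_.beta0, "se_beta1": est.se_.beta1,
                         "converged": est.converged_})
        except Exception as exc:  # noqa: BLE001 — per-species failures are reported
            logger.warning("species %s base fit failed: %s", sp, exc)
            rows.append({"species": sp, "n": len(grp), "beta0": np.nan,
                         "beta1": np.nan, "se_beta0": np.nan, "se_beta1": np.nan,
                         "converged": False})
    return pd.DataFrame(rows)


def stage1_correlations(
    coef_table: pd.DataFrame, candidates: CandidateSet,
    coefficients: Sequence[str] = ("beta0", "beta1"),
) -> pd.DataFrame:
    """Pearson correlations (with two-sided p-values) between fitted
    coefficients and each candidate covariate, over matched units.

    ``coef_table`` and ``candidates.values`` must be row-aligned (same
    units: species-level coefficients against species-mean covariates, or
    plot-level refits against plot covariates).  Constant covariates are
    reported with NaN correlation and flagged undefined.
    """
    if len(coef_table) != len(candidates.values):
        raise ValueError("coefficient table and covariate table are not row-aligned")
    if len(coef_table) < 3:
        raise ValueError("need at least 3 units for a correlation")
    rows = []
    for coef in coefficients:
        cv = coef_table[coef].to_numpy(dtype=float)
        for group, names in candidates.groups.items():
            for nm in names:
                xv = candidates.values[nm].to_numpy(dtype=float)
                ok = np.isfinite(cv) & np.isfinite(xv)
                if ok.sum() < 3 or np.std(xv[ok]) == 0 or np.std(cv[ok]) == 0:
                    rows.append({"coefficient": coef, "group": group, "covariate": nm,
                                 "r": np.nan, "p_value": np.nan, "defined": False})
                    continue
                r, p = stats.pearsonr(cv[ok], xv[ok])
                rows.append({"coefficient": coef, "group": group, "covariate": nm,
                             "r": float(r), "p_value": float(p), "defined": True})
    return pd.DataFrame(rows)


def vif_filter(
    candidates: pd.DataFrame, threshold: float = VIF_THRESHOLD,
) -> tuple[list[str], dict[str, float]]:
    """Iteratively drop the highest-VIF covariate until all VIF <= threshold.

    VIF_j = 1 / (1 - R²_j) from regressing covariate j on the others (with
    intercept).  Exact collinearity gives an infinite VIF and an immediate
    drop; ties break lexicographically.  Returns the kept columns (input
    order) and the final VIF table.
    """
    cols = list(candidates.columns)
    if len(cols) < 2:
        raise ValueError("need at least 2 candidate covariates")
    if len(candidates) <= len(cols):
        raise ValueError("need more rows than covariates for VIF")
    work = candidates.astype(float)

    def _vifs(names: list[str]) -> dict[str, float]:
        out = {}
        Xall = work[names].to_numpy()
        for j, nm in enumerate(names):
            yv = Xall[:, j]
            Xo = np.column_stack([np.ones(len(yv)),
                                  np.delete(Xall, j, axis=1)])
            coef, *_ = np.linalg.lstsq(Xo, yv, rcond=None)
            resid = yv - Xo @ coef
            sst = np.sum((yv - yv.mean()) ** 2)
            if sst == 0:
                out[nm] = np.inf
                continue
            r2j = 1.0 - np.sum(resid**2) / sst
            out[nm] = np.inf if r2j >= 1.0 - 1e-12 else 1.0 / (1.0 - r2j)
        return out

    kept = cols[:]
    while len(kept) >= 2:
        table = _vifs(kept)
        worst = max(table.values())
        if worst <= threshold:
            break
        # descending VIF, lexicographic tie-break
        drop = sorted(table.items(), key=lambda kv: (-kv[1], kv[0]))[0][0]
        if not np.isfinite(worst):
            logger.info("dropping %s: exact collinearity (infinite VIF)", drop)
        else:
            logger.info("dropping %s: VIF %.2f > %.2f", drop, worst, threshold)
        kept.remove(drop)
    final = _vifs(kept) if len(kept) >= 2 else {kept[0]: 1.0}
    return kept, final


def aic_ladder(
    frame: pd.DataFrame, y_col: str = "height_m",
    order: Sequence[tuple[str, str]] = DEFAULT_LADDER_ORDER,
) -> pd.DataFrame:
    """Fit the nested covariate build-up and report AIC / LL / R² per rung.

    Rung 0 is the base power model; rung m adds the m-th covariate of
    ``order`` (label, covariate) to the exponent.  A non-convergent rung is
    recorded with NaN statistics and the ladder continues.
    """
    y = frame[y_col].to_numpy(dtype=float)
    rows = []
    covs: list[str] = []
    labels = ["basic"] + [f"M{i+1}" for i in range(len(order))]
    additions = [("", None)] + list(order)
    for label, (group, cov) in zip(labels, additions):
        if cov is not None:
            covs.append(cov)
        try:
            est = PowerHeightModel(tuple(covs)).fit(frame, y)
            rows.append({
                "model": label,
                "variables": " + ".join(["D"] + covs),
                "added": group or None,
                "aic": est.aic_, "loglik": est.loglik_,
                "r2": _r2(y, est.predict(frame)),
                "n_params": est.n_params_, "converged": est.converged_,
            })
        except Exception as exc:  # noqa: BLE001
            logger.warning("ladder rung %s failed: %s", label, exc)
            rows.append({"model": label, "variables": " + ".join(["D"] + covs),
                         "added": group or None, "aic": np.nan, "loglik": np.nan,
                         "r2": np.nan, "n_params": np.nan, "converged": False})
    return pd.DataFrame(rows)


def select_covariates(
    frame: pd.DataFrame, candidates: CandidateSet,
    coef_table: pd.DataFrame | None = None,
    candidate_units: pd.DataFrame | None = None,
    threshold: float = VIF_THRESHOLD,
    y_col: str = "height_m",
    order: Sequence[tuple[str, str]] = DEFAULT_LADDER_ORDER,
) -> SelectionResult:
    """Run the full two-stage procedure and the AIC ladder.

    ``candidates.values`` holds the plot-level covariate table used for the
    VIF screen (tree-level covariates such as BAL should enter as plot
    means).  When ``coef_table``/``candidate_units`` are given, stage-1
    correlations are computed on those aligned units.
    """
    result = SelectionResult()
    if coef_table is not None and candidate_units is not None:
        result.stage1_correlations = stage1_correlations(
            coef_table, CandidateSet(candidates.groups, candidate_units))
    kept, vifs = vif_filter(candidates.values[candidates.all_names], threshold)
    result.chosen = kept
    result.vif_table = vifs
    result.aic_ladder = aic_ladder(frame, y_col=y_col, order=order)
    return result
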