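"""Goodness-of-fit statistics and the partial-R² covariate decomposition.

Three scalar indicators summarise a fit: the coefficient of determination
R² = 1 - SSE/SST, the root mean square error RMSE (m), and the total
relative error TRE = 100 * sum(O - E) / sum(E) (%), a *signed* aggregate
bias (positive when observations exceed predictions in total).

The partial R² of a covariate is the drop in R² when the model is refit
without it; the leave-one-out models are refit from scratch, so single-
covariate drops need not sum to the full-vs-base R² gap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .nls_fitting import ModelSpec, PowerHeightModel


def r2(observed, predicted) -> float:
    """Coefficient of determination about the observed mean."""
    o = np.asarray(observed, dtype=float)
    e = np.asarray(predicted, dtype=float)
    if o.shape != e.shape or o.size < 2:
        raise ValueError("observed and predicted must be equal-length, n >= 2")
    sst = np.sum((o - o.mean()) ** 2)
    if sst == 0:
        raise ValueError("R^2 undefined: observed values are constant (SST = 0)")
    return float(1.0 - np.sum((o - e) ** 2) / sst)


def rmse(observed, predicted) -> float:
    """Root mean square error, in the units of the response."""
    o = np.asarray(observed, dtype=float)
    e = np.asarray(predicted, dtype=float)
    if o.shape != e.shape:
        raise ValueError("observed and predicted must have equal length")
    return float(np.sqrt(np.mean((o - e) ** 2)))


def tre(observed, predicted) -> float:
    """Total relative error in percent: 100 * sum(O - E) / sum(E), signed."""
    o = np.asarray(observed, dtype=float)
    e = np.asarray(predicted, dtype=float)
    if o.shape != e.shape:
        raise ValueError("observed and predicted must have equal length")
    denom = e.sum()
    if denom == 0:
        raise ValueError("TRE undefined: predictions sum to zero")
    return float(100.0 * (o - e).sum() / denom)


@dataclass
class EvalReport:
    r2: float
    rmse: float
    tre: float
    n: int
    by_species: dict[str, tuple[float, float, float]] = field(default_factory=dict)
    partial_r2: dict[str, float] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [{"group": "overall", "r2": self.r2, "rmse": self.rmse,
                 "tre": self.tre, "n": self.n}]
        for sp, (a, b, c) in self.by_species.items():
            rows.append({"group": sp, "r2": a, "rmse": b, "tre": c, "n": None})
        return pd.DataFrame(rows)


def evaluate(observed, predicted, species=None) -> EvalReport:
    """Overall (and optionally per-species) R², RMSE and TRE."""
    o = np.asarray(observed, dtype=float)
    e = np.asarray(predicted, dtype=float)
    rep = EvalReport(r2(o, e), rmse(o, e), tre(o, e), len(o))
    if species is not None:
        sp = np.asarray(species)
        for s in pd.unique(sp):
            m = sp == s
            if m.sum() >= 2 and np.std(o[m]) > 0:
                rep.by_species[str(s)] = (r2(o[m], e[m]), rmse(o[m], e[m]), tre(o[m], e[m]))
    return rep


def partial_r2(
    X: pd.DataFrame, y, full_spec: ModelSpec,
    fitter: Callable[[ModelSpec], object] | None = None,
) -> dict[str, float]:
    """Refit-difference partial R² for each exponent covariate and for D.

    For covariate j: R²(full) - R²(model without j).  For D itself the
    reduced model is the intercept-only mean height (R² = 0), so D's share
    is R²(base power model).  Non-convergent reduced fits are recorded as
    NaN.  Returned mapping is sorted by decreasing share.
    """
    y = np.asarray(y, dtype=float)

    def _fit_r2(spec: ModelSpec) -> float:
        est = PowerHeightModel(spec.exponent_covariates).fit(X, y)
        if not est.converged_:
            return np.nan
        return r2(y, est.predict(X))

    r2_full = _fit_r2(full_spec)
    out: dict[str, float] = {"dbh_cm": _fit_r2(ModelSpec(()))}
    for name in full_spec.exponent_covariates:
        reduced = ModelSpec(tuple(c for c in full_spec.exponent_covariates if c != name))
        out[name] = r2_full - _fit_r2(reduced)
    return dict(sorted(out.items(), key=lambda kv: (np.isnan(kv[1]), -kv[1])))
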