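"""Fixed-effects estimation of the power-law height-diameter model.

The base allometry is ``H = 1.3 + b0 * D**b1`` (heights in m, D in cm, the
1.3 m offset is breast height).  The environment-sensitive extension keeps
the power-law shape but lets the exponent vary linearly with plot- and
tree-level covariates::

    H = 1.3 + b0 * D ** (b1 + b2*SOC + b3*MAP + b4*SIM + b5*BAL + b6*QMD)

Estimation is damped Gauss-Newton / Levenberg-Marquardt nonlinear least
squares with an analytic Jacobian.  Covariates are z-scaled internally (raw
magnitudes such as MAP ~ 450 make the exponent surface ill-conditioned) and
the coefficients and their standard errors are transformed back exactly, so
the reported fit is on the raw scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator, RegressorMixin

BREAST_HEIGHT_M = 1.3

DBH_COLUMN = "dbh_cm"


@dataclass
class ModelSpec:
    """Which covariates enter the exponent (empty tuple = base model)."""

    exponent_covariates: tuple[str, ...] = ()

    @property
    def param_names(self) -> list[str]:
        return ["beta0", "beta1"] + [f"b[{c}]" for c in self.exponent_covariates]

    @property
    def n_params(self) -> int:
        return 2 + len(self.exponent_covariates)


@dataclass
class FixedEffects:
    """The power-law parameters: scale b0, exponent intercept b1, and the
    per-covariate exponent slopes."""

    beta0: float
    beta1: float
    exponent_coefs: dict[str, float] = field(default_factory=dict)

    def as_vector(self, covariates: Sequence[str]) -> np.ndarray:
        return np.array(
            [self.beta0, self.beta1] + [self.exponent_coefs.get(c, 0.0) for c in covariates]
        )

    @classmethod
    def from_vector(cls, theta: np.ndarray, covariates: Sequence[str]) -> "FixedEffects":
        return cls(float(theta[0]), float(theta[1]),
                   {c: float(v) for c, v in zip(covariates, theta[2:])})

    def effective_exponent(self, covs: Mapping[str, float] | pd.DataFrame) -> np.ndarray | float:
        e = self.beta1
        for name, coef in self.exponent_coefs.items():
            if isinstance(covs, pd.DataFrame):
                if name not in covs.columns:
                    raise KeyError(f"covariate {name!r} required by the model is missing")
                e = e + coef * covs[name].to_numpy(dtype=float)
            else:
                if name not in covs:
                    raise KeyError(f"covariate {name!r} required by the model is missing")
                e = e + coef * covs[name]
        return e


@dataclass
class NlsFitResult:
    estimates: FixedEffects
    se: FixedEffects
    sigma: float
    loglik: float
    aic: float
    bic: float
    residuals: np.ndarray
    converged: bool
    n_iter: int
    n_obs: int
    n_params: int
    p_values: dict[str, float] = field(default_factory=dict)
    cov_params: np.ndarray | None = None

    def to_dict(self) -> dict:
        return {
            "estimates": {"beta0": self.estimates.beta0, "beta1": self.estimates.beta1,
                          **self.estimates.exponent_coefs},
            "se": {"beta0": self.se.beta0, "beta1": self.se.beta1, **self.se.exponent_coefs},
            "sigma": self.sigma, "loglik": self.loglik, "aic": self.aic, "bic": self.bic,
            "converged": self.converged, "n_iter": self.n_iter,
            "n_obs": self.n_obs, "n_params": self.n_params, "p_values": self.p_values,
        }


def predict_height(
    fe: FixedEffects, dbh_cm, covs: Mapping[str, float] | pd.DataFrame | None = None
):
    """Population-level height prediction 1.3 + b0 * D**e(x)."""
    d = np.asarray(dbh_cm, dtype=float)
    if np.any(d <= 0):
        raise ValueError("dbh must be positive")
    e = fe.effective_exponent(covs if covs is not None else {})
    return BREAST_HEIGHT_M + fe.beta0 * d**e


def auto_start(dbh_cm, height_m) -> FixedEffects:
    """Starting values from the log-linearised model.

    OLS of ln(H - 1.3) on ln D gives the exact optimum for noiseless
    power-law data; covariate slopes start at zero.  Rows with H <= 1.3 are
    excluded (the logarithm is undefined there).
    """
    d = np.asarray(dbh_cm, dtype=float)
    h = np.asarray(height_m, dtype=float)
    ok = (h > BREAST_HEIGHT_M) & (d > 0)
    if ok.sum() < 3:
        raise ValueError("need at least 3 observations with H > 1.3 m")
    x = np.log(d[ok])
    y = np.log(h[ok] - BREAST_HEIGHT_M)
    slope, intercept = np.polyfit(x, y, 1)
    return FixedEffects(float(np.exp(intercept)), float(slope))


class PowerHeightModel(RegressorMixin, BaseEstimator):
    """Power-law height-diameter regressor with a covariate-driven exponent.

    Parameters
    ----------
    exponent_covariates : tuple of str
        Column names entering the exponent linearly. Empty = base model.
    scale_covariates : bool
        Z-scale covariates internally for conditioning (coefficients are
        reported back on the raw scale either way).
    start : FixedEffects or None
        Starting values; by default the log-linearised OLS start.
    tol, gtol, max_iter
        Relative SSE-change and gradient-norm stopping rules for the
        Levenberg-Marquardt iterations.

    Attributes
    ----------
    fixed_effects_ : FixedEffects
    se_ : FixedEffects (same shape, standard errors)
    sigma_ : float, residual SD (ML, SSE/n)
    loglik_, aic_, bic_ : float
    residuals_ : ndarray
    converged_ : bool
    n_iter_ : int

    The estimator follows the scikit-learn protocol: ``X`` is a DataFrame
    holding a ``dbh_cm`` column plus the exponent covariates (or an ndarray
    whose first column is D followed by the covariates in declared order),
    ``y`` is height in m.
    """

    def __init__(self, exponent_covariates: tuple[str, ...] = (),
                 scale_covariates: bool = True, start: FixedEffects | None = None,
                 tol: float = 1e-10, gtol: float = 1e-8, max_iter: int = 200):
        self.exponent_covariates = exponent_covariates
        self.scale_covariates = scale_covariates
        self.start = start
        self.tol = tol
        self.gtol = gtol
        self.max_iter = max_iter

    # -- plumbing ---------------------------------------------------------
    def _design(self, X) -> tuple[np.ndarray, np.ndarray]:
        names = list(self.exponent_covariates)
        if isinstance(X, pd.DataFrame):
            if DBH_COLUMN not in X.columns:
                raise KeyError(f"X must contain a {DBH_COLUMN!r} column")
            d = X[DBH_COLUMN].to_numpy(dtype=float)
            missing = [c for c in names if c not in X.columns]
            if missing:
                raise KeyError(f"missing exponent covariates in X: {missing}")
            C = X[names].to_numpy(dtype=float) if names else np.empty((len(d), 0))
        else:
            arr = np.asarray(X, dtype=float)
            if arr.ndim == 1:
                arr = arr[:, None]
            if arr.shape[1] != 1 + len(names):
                raise ValueError(
                    f"expected {1 + len(names)} columns (dbh + covariates), got {arr.shape[1]}")
            d, C = arr[:, 0], arr[:, 1:]
        if np.any(d <= 0):
            raise ValueError("dbh must be positive")
        return d, C

    def fit(self, X, y):
        d, C = self._design(X)
        h = np.asarray(y, dtype=float)
        n, p = len(d), 2 + C.shape[1]
        if n < p + 1:
            raise ValueError(f"need at least {p + 1} observations, got {n}")

        if self.scale_covariates and C.shape[1]:
            mu = C.mean(axis=0)
            sd = C.std(axis=0)
            sd = np.where(sd > 0, sd, 1.0)
            Cs = (C - mu) / sd
        else:
            mu = np.zeros(C.shape[1])
            sd = np.ones(C.shape[1])
            Cs = C

        names = list(self.exponent_covariates)
        if self.start is not None:
            theta_raw = self.start.as_vector(names)
        else:
            fe0 = auto_start(d, h)
            theta_raw = np.concatenate([[fe0.beta0, fe0.beta1], np.zeros(C.shape[1])])
        # raw -> scaled parameterisation: b1s = b1 + sum(bc*mu), bcs = bc*sd
        theta0 = theta_raw.copy()
        theta0[1] = theta_raw[1] + theta_raw[2:] @ mu
        theta0[2:] = theta_raw[2:] * sd

        ln_d = np.log(d)

        def resid(th):
            e = th[1] + Cs @ th[2:]
            return BREAST_HEIGHT_M + th[0] * d**e - h

        def jac(th):
            e = th[1] + Cs @ th[2:]
            de = d**e
            g = th[0] * de * ln_d
            return np.column_stack([de, g] + [g * Cs[:, j] for j in range(Cs.shape[1])])

        sol = optimize.least_squares(
            resid, theta0, jac=jac, method="lm" if n > p else "trf",
            ftol=self.tol, gtol=self.gtol, xtol=1e-12, max_nfev=self.max_iter * (p + 1))
        theta_s = sol.x
        sse = 2.0 * sol.cost
        J = jac(theta_s)

        # exact back-transform to raw-covariate coefficients
        A = np.eye(p)
        for j in range(C.shape[1]):
            A[2 + j, 2 + j] = 1.0 / sd[j]
            A[1, 2 + j] = -mu[j] / sd[j]
        theta = A @ theta_s

        sigma2_ml = sse / n
        dof = max(n - p, 1)
        JTJ = J.T @ J
        try:
            cov_s = np.linalg.inv(JTJ) * (sse / dof)
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                "singular Jacobian; consider rescaling covariates") from exc
        cov = A @ cov_s @ A.T
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))

        self.param_names_ = ["beta0", "beta1"] + names
        self.fixed_effects_ = FixedEffects.from_vector(theta, names)
        self.se_ = FixedEffects.from_vector(se, names)
        self.cov_params_ = cov
        self.sigma_ = float(np.sqrt(sigma2_ml))
        self.loglik_ = float(-0.5 * n * (np.log(2 * np.pi * sigma2_ml) + 1.0))
        k = p + 1  # fixed effects + sigma
        self.n_params_ = k
        self.aic_ = -2.0 * self.loglik_ + 2.0 * k
        self.bic_ = -2.0 * self.loglik_ + np.log(n) * k
        self.residuals_ = -resid(theta_s)
        self.converged_ = bool(sol.status > 0)
        self.n_iter_ = int(sol.nfev)
        self.n_obs_ = n
        z = np.divide(theta, se, out=np.full(p, np.inf), where=se > 0)
        self.p_values_ = {
            nm: float(2 * stats.norm.sf(abs(zi))) for nm, zi in zip(self.param_names_, z)}

        eff = theta[1] + C @ theta[2:]
        if np.any(eff <= 0) or np.any(eff >= 2):
            import warnings
            warnings.warn("effective exponent outside (0, 2) over the observed "
                          "covariate range", stacklevel=2)
        return self

    def predict(self, X):
        d, C = self._design(X)
        fe = self.fixed_effects_
        names = list(self.exponent_covariates)
        e = fe.beta1 + (C @ fe.as_vector(names)[2:] if names else 0.0)
        return BREAST_HEIGHT_M + fe.beta0 * d**e

    def result_(self) -> NlsFitResult:
        return NlsFitResult(
            estimates=self.fixed_effects_, se=self.se_, sigma=self.sigma_,
            loglik=self.loglik_, aic=self.aic_, bic=self.bic_,
            residuals=self.residuals_, converged=self.converged_,
            n_iter=self.n_iter_, n_obs=self.n_obs_, n_params=self.n_params_,
            p_values=self.p_values_, cov_params=self.cov_params_)


def fit_nls(
    X: pd.DataFrame, y, spec: ModelSpec | None = None,
    start: FixedEffects | None = None, tol: float = 1e-10, max_iter: int = 200,
) -> NlsFitResult:
    """Functional wrapper over :class:`PowerHeightModel`."""
    spec = spec or ModelSpec()
    est = PowerHeightModel(spec.exponent_covariates, start=start, tol=tol,
                           max_iter=max_iter).fit(X, y)
    return est.result_()
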