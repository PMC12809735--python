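"""Independent brute-force / dense-numerical oracles used by the tests.

Everything here is deliberately naive (double loops, dense grids) and shares
no code with the implementation paths it checks.
"""

import numpy as np
from scipy import stats


def bal_double_loop(dbh, area_ha):
    """O(n^2) basal-area-in-larger-trees."""
    dbh = np.asarray(dbh, dtype=float)
    out = np.zeros(len(dbh))
    for i, di in enumerate(dbh):
        total = 0.0
        for j, dj in enumerate(dbh):
            if dj > di:
                total += np.pi * (dj / 200.0) ** 2
        out[i] = total / area_ha
    return out


def dense_marginal_loglik(fe, re_spec, var_spec, frame, sigma,
                          npts=401, half=9.0):
    """Marginal log-likelihood by dense trapezoid integration over the plot
    random effects (1 or 2 of them), plot by plot."""
    psi = np.asarray(re_spec.plot_cov, dtype=float)
    q = psi.shape[0]
    L = np.linalg.cholesky(psi + 1e-14 * np.eye(q))
    total = 0.0
    for _, grp in frame.groupby("plot_id"):
        d = grp["dbh_cm"].to_numpy()
        h = grp["height_m"].to_numpy()
        sd = sigma * var_spec.g(d)
        z = np.linspace(-half, half, npts)
        if q == 1:
            vals = np.empty(npts)
            for i, zi in enumerate(z):
                bvec = L @ np.array([zi])
                b0 = fe.beta0 + (bvec[0] if re_spec.plot_level[0] == "beta0" else 0.0)
                e = fe.beta1 + (bvec[0] if re_spec.plot_level[0] == "beta1" else 0.0)
                mu = 1.3 + b0 * d**e
                vals[i] = np.sum(stats.norm.logpdf(h, mu, sd)) + stats.norm.logpdf(zi)
            m = vals.max()
            total += m + np.log(np.trapezoid(np.exp(vals - m), z))
        elif q == 2:
            vals = np.empty((npts, npts))
            for i1 in range(npts):
                bv = L @ np.vstack([np.full(npts, z[i1]), z])
                b0 = fe.beta0 + (bv[0] if re_spec.plot_level[0] == "beta0" else 0.0)
                e = fe.beta1 + (bv[1] if re_spec.plot_level[1] == "beta1" else 0.0)
                mu = 1.3 + b0[None, :] * d[:, None] ** e[None, :]
                vals[i1] = (np.sum(stats.norm.logpdf(h[:, None], mu, sd[:, None]), axis=0)
                            + stats.norm.logpdf(z[i1]) + stats.norm.logpdf(z))
            m = vals.max()
            inner = np.trapezoid(np.exp(vals - m), z, axis=1)
            total += m + np.log(np.trapezoid(inner, z))
        else:
            raise ValueError("oracle supports 1 or 2 plot random effects")
    return float(total)


def nls_grid_search_sse(d, h, b0_grid, b1_grid):
    """Minimum SSE of the base power model over a (b0, b1) grid."""
    best = np.inf
    for b0 in b0_grid:
        pred = 1.3 + b0 * d[None, :] ** np.asarray(b1_grid)[:, None]
        sse = np.sum((h[None, :] - pred) ** 2, axis=1)
        best = min(best, float(sse.min()))
    return best
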