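"""Independent brute-force oracles used by the tests.

These deliberately avoid the package's profiled-likelihood code path: the
mixed-model oracle builds full covariance matrices and optimises the two
variance components jointly with a coarse grid plus Nelder-Mead polish.
"""

from __future__ import annotations

import numpy as np
from scipy import optimize


def full_cov_loglik(y, X, Z, s2u, s2e, method):
    """(RE)ML log-likelihood from explicit n x n covariance matrices."""
    n, p = X.shape
    V = s2u * (Z @ Z.T) + s2e * np.eye(n)
    _, logdetV = np.linalg.slogdet(V)
    Vi = np.linalg.inv(V)
    A = X.T @ Vi @ X
    beta = np.linalg.solve(A, X.T @ Vi @ y)
    r = y - X @ beta
    quad = float(r @ Vi @ r)
    if method == "ML":
        ll = -0.5 * (n * np.log(2 * np.pi) + logdetV + quad)
    else:
        _, logdetA = np.linalg.slogdet(A)
        ll = -0.5 * ((n - p) * np.log(2 * np.pi) + logdetV + logdetA + quad)
    return float(ll), beta


def oracle_fit(y, X, groups, method="REML"):
    """Joint optimisation over (beta, sigma2_u, sigma2_e); beta by GLS."""
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    groups = np.asarray(groups)
    levels = np.unique(groups)
    Z = (groups[:, None] == levels[None, :]).astype(float)

    def nll(t):
        return -full_cov_loglik(y, X, Z, np.exp(t[0]), np.exp(t[1]), method)[0]

    best = None
    for lu in np.linspace(-10.0, 3.0, 14):
        for le in np.linspace(-5.0, 3.0, 9):
            v = nll((lu, le))
            if best is None or v < best[0]:
                best = (v, (lu, le))
    res = optimize.minimize(
        nll, best[1], method="Nelder-Mead",
        options={"xatol": 1e-12, "fatol": 1e-13, "maxiter": 6000, "maxfev": 6000},
    )
    s2u, s2e = float(np.exp(res.x[0])), float(np.exp(res.x[1]))
    ll, beta = full_cov_loglik(y, X, Z, s2u, s2e, method)
    return {"beta": beta, "sigma2_u": s2u, "sigma2_e": s2e, "loglik": ll}


def naive_rolling_rmse(trace, window):
    """Recompute every rolling RMSE straight from the stored trace."""
    out = []
    for i in range(len(trace)):
        if i + 1 < window:
            out.append(np.nan)
        else:
            recent = trace[i + 1 - window : i + 1]
            out.append(
                float(np.sqrt(np.mean([(t["recommended"] - t["corrected"]) ** 2 for t in recent])))
            )
    return out


def naive_buffer_mean(xs, ys, scores, cx, cy, radius):
    """Plain-loop buffer aggregation."""
    vals = [s for x, y, s in zip(xs, ys, scores) if ((x - cx) ** 2 + (y - cy) ** 2) ** 0.5 <= radius]
    if not vals:
        return None, 0
    return sum(vals) / len(vals), len(vals)
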