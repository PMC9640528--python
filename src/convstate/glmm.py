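"""Maximum-likelihood logistic mixed model via adaptive Gauss-Hermite
quadrature.

Fits  logit P(y_ij = 1) = x_ij' beta + u_i (+ v_i z_ij)  with a scalar
random intercept u_i ~ N(0, sigma_u^2) per cluster (subject) and,
optionally, an independent random slope v_i ~ N(0, sigma_v^2) on one
designated column.  The marginal log-likelihood integrates the random
effects out with Gauss-Hermite quadrature adapted per cluster: nodes are
centered at the posterior mode of the random effect (found by Newton
iterations) and scaled by the local curvature, which keeps a small node
count accurate even for large clusters.

The optimizer works on (beta, log sigma); standard errors come from the
numerical Hessian of the marginal log-likelihood at the optimum.  The
model exposes a true log-likelihood, so nested fits support likelihood
ratio tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import log_expit

__all__ = ["LogisticMixedResult", "fit_logistic_mixed"]

_DEFAULT_NODES_1D = 11
_DEFAULT_NODES_2D = 7


@dataclass
class LogisticMixedResult:
    """Fitted random-effects logistic regression.

    ``params``/``bse``/``pvalues`` are indexed by fixed-effect name;
    ``sigma_u`` (and ``sigma_v`` when a random slope is present) are the
    random-effect standard deviations; ``llf`` is the marginal
    log-likelihood and ``n_params`` counts all free parameters, so nested
    models can be compared by likelihood ratio.
    """

    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    conf_int: pd.DataFrame
    sigma_u: float
    llf: float
    n_params: int
    converged: bool
    n_obs: int
    n_groups: int
    sigma_v: float | None = None
    slope_col: str | None = None
    message: str = ""
    optimizer_result: object = field(default=None, repr=False)


def _prepare(y, X, groups):
    y = np.asarray(y, dtype=float).ravel()
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    groups = np.asarray(groups)
    if not (len(y) == len(X) == len(groups)):
        raise ValueError("y, X and groups must have equal length")
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("outcome must be binary 0/1")
    order = np.argsort(groups, kind="stable")
    y, X, groups = y[order], X[order], groups[order]
    uniq, starts = np.unique(groups, return_index=True)
    bounds = np.append(np.sort(starts), len(y))
    return y, X, groups, uniq, bounds, order


def _check_separation(y, X, names):
    # a predictor perfectly splitting the outcome makes the MLE diverge
    for j, name in enumerate(names):
        col = X[:, j]
        if np.ptp(col) == 0:
            continue
        if col[y == 1].size and col[y == 0].size:
            if col[y == 1].min() > col[y == 0].max() or col[y == 0].min() > col[y == 1].max():
                raise ValueError(
                    f"complete separation detected for predictor {name!r}"
                )


def fit_logistic_mixed(
    y: np.ndarray,
    X: np.ndarray | pd.DataFrame,
    groups: np.ndarray,
    names: list[str] | None = None,
    slope_col: str | None = None,
    n_nodes: int | None = None,
    se: bool = True,
    maxiter: int = 300,
) -> LogisticMixedResult:
    """Fit the random-intercept (+ optional random-slope) logistic model.

    Parameters
    ----------
    y, X, groups
        Binary outcome, fixed-effect design (a constant column is NOT
        added automatically), and cluster labels.
    slope_col
        Name of the column receiving an independent random slope, or None
        for the intercept-only model.
    """
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        X = X.to_numpy(dtype=float)
    if names is None:
        names = [f"x{j}" for j in range(np.atleast_2d(X).shape[1])]
    y, X, groups, uniq, bounds, _ = _prepare(y, X, groups)
    n, p = X.shape
    if len(names) != p:
        raise ValueError("names length must match design columns")
    if y.min() == y.max():
        raise ValueError("outcome is degenerate (all 0 or all 1)")
    _check_separation(y, X, names)
    slope_idx = None
    if slope_col is not None:
        if slope_col not in names:
            raise ValueError(f"slope_col {slope_col!r} not among predictors {names}")
        slope_idx = names.index(slope_col)
    two_dim = slope_idx is not None
    if n_nodes is None:
        n_nodes = _DEFAULT_NODES_2D if two_dim else _DEFAULT_NODES_1D
    nodes, weights = np.polynomial.hermite.hermgauss(n_nodes)
    log_w = np.log(weights) + nodes**2  # for exp(a^2) * w form

    z_slope = X[:, slope_idx] if two_dim else None
    group_idx_of_row = np.repeat(np.arange(len(uniq)), np.diff(bounds))

    def _cluster_sums(values: np.ndarray) -> np.ndarray:
        """Sum rows (or row-blocks) within clusters. values: (n,) or (n,k)."""
        return np.add.reduceat(values, bounds[:-1], axis=0)

    def _loglik_terms(eta: np.ndarray) -> np.ndarray:
        # Bernoulli log-likelihood: y*eta - log(1+e^eta) = log_expit(s*eta), s=2y-1
        s = (2.0 * y - 1.0)[:, None] if eta.ndim == 2 else 2.0 * y - 1.0
        return log_expit(s * eta)

    def _mode_1d(eta_fix: np.ndarray, sigma: float):
        """Posterior mode/curvature of u per cluster (Newton, vectorized)."""
        G = len(uniq)
        u = np.zeros(G)
        for _ in range(25):
            eta = eta_fix + u[group_idx_of_row]
            mu = 1.0 / (1.0 + np.exp(-eta))
            g = _cluster_sums(y - mu) - u / sigma**2
            h = -_cluster_sums(mu * (1 - mu)) - 1.0 / sigma**2
            step = g / h
            u -= step
            if np.max(np.abs(step)) < 1e-9:
                break
        eta = eta_fix + u[group_idx_of_row]
        mu = 1.0 / (1.0 + np.exp(-eta))
        h = -_cluster_sums(mu * (1 - mu)) - 1.0 / sigma**2
        return u, np.sqrt(-1.0 / h)

    def negloglik(theta: np.ndarray) -> float:
        beta = theta[:p]
        sigma_u = np.exp(theta[p])
        eta_fix = X @ beta
        if not two_dim:
            u_hat, tau = _mode_1d(eta_fix, sigma_u)
            # nodes per cluster: u = u_hat + sqrt(2) tau a_q
            u_nodes = u_hat[:, None] + np.sqrt(2.0) * tau[:, None] * nodes[None, :]
            eta = eta_fix[:, None] + u_nodes[group_idx_of_row]
            ll_rows = _loglik_terms(eta)
            ll_clusters = _cluster_sums(ll_rows)  # (G, Q)
            log_prior = -0.5 * (u_nodes / sigma_u) ** 2 - np.log(sigma_u) - 0.5 * np.log(2 * np.pi)
            g_vals = ll_clusters + log_prior + log_w[None, :]
            m = g_vals.max(axis=1, keepdims=True)
            integral = np.exp(g_vals - m).sum(axis=1)
            ll = np.sum(
                m.ravel()
                + np.log(integral)
                + 0.5 * np.log(2.0)
                + np.log(tau)
            )
            return -ll
        # independent random intercept + random slope: 2-D adaptive tensor grid
        sigma_v = np.exp(theta[p + 1])
        G = len(uniq)
        uv = np.zeros((G, 2))
        for _ in range(30):
            eta = eta_fix + uv[group_idx_of_row, 0] + uv[group_idx_of_row, 1] * z_slope
            mu = 1.0 / (1.0 + np.exp(-eta))
            w_r = mu * (1 - mu)
            r = y - mu
            g1 = _cluster_sums(r) - uv[:, 0] / sigma_u**2
            g2 = _cluster_sums(r * z_slope) - uv[:, 1] / sigma_v**2
            h11 = -_cluster_sums(w_r) - 1.0 / sigma_u**2
            h12 = -_cluster_sums(w_r * z_slope)
            h22 = -_cluster_sums(w_r * z_slope**2) - 1.0 / sigma_v**2
            det = h11 * h22 - h12**2
            du = (g1 * h22 - g2 * h12) / det
            dv = (g2 * h11 - g1 * h12) / det
            uv[:, 0] -= du
            uv[:, 1] -= dv
            if max(np.max(np.abs(du)), np.max(np.abs(dv))) < 1e-9:
                break
        eta = eta_fix + uv[group_idx_of_row, 0] + uv[group_idx_of_row, 1] * z_slope
        mu = 1.0 / (1.0 + np.exp(-eta))
        w_r = mu * (1 - mu)
        h11 = -_cluster_sums(w_r) - 1.0 / sigma_u**2
        h12 = -_cluster_sums(w_r * z_slope)
        h22 = -_cluster_sums(w_r * z_slope**2) - 1.0 / sigma_v**2
        # Cholesky of -H^{-1} per cluster (2x2, closed form)
        Hn11, Hn12, Hn22 = -h11, -h12, -h22
        det = Hn11 * Hn22 - Hn12**2
        # inverse of -H
        i11, i12, i22 = Hn22 / det, -Hn12 / det, Hn11 / det
        L11 = np.sqrt(i11)
        L21 = i12 / L11
        L22 = np.sqrt(np.maximum(i22 - L21**2, 1e-300))
        A, B = np.meshgrid(nodes, nodes, indexing="ij")
        aq, bq = A.ravel(), B.ravel()  # (Q2,)
        lw2 = (log_w[:, None] + log_w[None, :]).ravel()
        u_nodes = uv[:, 0][:, None] + np.sqrt(2.0) * (L11[:, None] * aq[None, :])
        v_nodes = uv[:, 1][:, None] + np.sqrt(2.0) * (
            L21[:, None] * aq[None, :] + L22[:, None] * bq[None, :]
        )
        eta = (
            eta_fix[:, None]
            + u_nodes[group_idx_of_row]
            + v_nodes[group_idx_of_row] * z_slope[:, None]
        )
        ll_clusters = _cluster_sums(_loglik_terms(eta))
        log_prior = (
            -0.5 * (u_nodes / sigma_u) ** 2
            - 0.5 * (v_nodes / sigma_v) ** 2
            - np.log(sigma_u * sigma_v)
            - np.log(2 * np.pi)
        )
        g_vals = ll_clusters + log_prior + lw2[None, :]
        m = g_vals.max(axis=1, keepdims=True)
        integral = np.exp(g_vals - m).sum(axis=1)
        ll = np.sum(
            m.ravel() + np.log(integral) + np.log(2.0) + np.log(L11 * L22)
        )
        return -ll

    # starting values: plain logistic fit, modest random-effect scale
    import statsmodels.api as sm

    glm = sm.GLM(y, X, family=sm.families.Binomial()).fit()
    x0 = np.concatenate([glm.params, [np.log(0.5)]])
    if two_dim:
        x0 = np.concatenate([x0, [np.log(0.3)]])
    res = optimize.minimize(
        negloglik,
        x0,
        method="L-BFGS-B",
        options={"maxiter": maxiter, "ftol": 1e-11, "gtol": 1e-7},
    )
    theta = res.x
    llf = -float(res.fun)
    beta = theta[:p]
    sigma_u = float(np.exp(theta[p]))
    sigma_v = float(np.exp(theta[p + 1])) if two_dim else None
    n_params = p + (2 if two_dim else 1)

    bse = np.full(p, np.nan)
    if se:
        # numerical Hessian of the negative log-likelihood (central differences)
        k = len(theta)
        h = 1e-4 * np.maximum(1.0, np.abs(theta))
        H = np.empty((k, k))
        f0 = res.fun
        fp = np.empty(k)
        fm = np.empty(k)
        for i in range(k):
            e = np.zeros(k)
            e[i] = h[i]
            fp[i] = negloglik(theta + e)
            fm[i] = negloglik(theta - e)
            H[i, i] = (fp[i] - 2 * f0 + fm[i]) / h[i] ** 2
        for i in range(k):
            for j in range(i + 1, k):
                ei = np.zeros(k)
                ej = np.zeros(k)
                ei[i] = h[i]
                ej[j] = h[j]
                fpp = negloglik(theta + ei + ej)
                fmm = negloglik(theta - ei - ej)
                H[i, j] = H[j, i] = (
                    fpp - fp[i] - fp[j] + 2 * f0 - fm[i] - fm[j] + fmm
                ) / (2 * h[i] * h[j])
        try:
            cov = np.linalg.inv(H)
            var = np.diag(cov)[:p]
            bse = np.sqrt(np.where(var > 0, var, np.nan))
        except np.linalg.LinAlgError:
            pass

    zvals = beta / bse
    pvals = 2 * stats.norm.sf(np.abs(zvals))
    ci = np.column_stack([beta - 1.959963984540054 * bse, beta + 1.959963984540054 * bse])
    return LogisticMixedResult(
        params=pd.Series(beta, index=names),
        bse=pd.Series(bse, index=names),
        pvalues=pd.Series(pvals, index=names),
        conf_int=pd.DataFrame(ci, index=names, columns=["lower", "upper"]),
        sigma_u=sigma_u,
        sigma_v=sigma_v,
        llf=llf,
        n_params=n_params,
        converged=bool(res.success),
        n_obs=n,
        n_groups=len(uniq),
        slope_col=slope_col,
        message=str(res.message),
        optimizer_result=res,
    )
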