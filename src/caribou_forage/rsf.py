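"""Landscape-scale resource selection: mixed-effects logistic regression.

The use-availability response (used = 1, available = 0) is modeled with a
logit link, fixed effects for the candidate covariates, and one normal
random intercept per animal-year. The marginal likelihood integrates the
random effect by adaptive Gauss-Hermite quadrature: each group's integrand
is recentered on its posterior mode and rescaled by the curvature there, so
15 nodes give near-exact one-dimensional integrals. Fixed-effect standard
errors come from the observed information (numerical Hessian of the marginal
log-likelihood at the optimum).

Relative-selection scores are exp(fixed linear predictor without intercept
or random effect) - a monotone ranking quantity, not a probability.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, logsumexp

from .design import apply_standardization
from .model_specs import FitResult, ModelSpec, design_matrix

_SQRT2 = np.sqrt(2.0)
_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)


class ConvergenceError(RuntimeError):
    """Raised when an optimizer fails to reach its convergence criteria."""


def _softplus(x):
    return np.logaddexp(0.0, x)


def _plain_logistic(X, y, max_iter=100, tol=1e-10):
    """Newton-Raphson logistic regression with step halving."""
    n, p = X.shape
    beta = np.zeros(p)
    ll_old = -np.inf
    for _ in range(max_iter):
        eta = X @ beta
        mu = expit(eta)
        ll = float(np.sum(y * eta - _softplus(eta)))
        g = X.T @ (y - mu)
        W = mu * (1 - mu)
        H = (X * W[:, None]).T @ X
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError as e:
            raise ConvergenceError(f"singular information matrix: {e}") from e
        # step halving against likelihood decreases
        t = 1.0
        for _ in range(30):
            cand = beta + t * step
            eta_c = X @ cand
            ll_c = float(np.sum(y * eta_c - _softplus(eta_c)))
            if ll_c >= ll - 1e-12:
                break
            t /= 2
        beta = beta + t * step
        if np.max(np.abs(g)) < 1e-6 and abs(ll_c - ll_old) <= tol * (1 + abs(ll_c)):
            ll_old = ll_c
            break
        ll_old = ll_c
    mu = expit(X @ beta)
    H = (X * (mu * (1 - mu))[:, None]).T @ X
    vcov = np.linalg.inv(H)
    return beta, vcov, ll_old


class _MarginalLik:
    """Adaptive GH machinery for one design (X, y, groups)."""

    def __init__(self, X, y, gidx, n_groups, n_quad=15):
        self.X, self.y, self.gidx, self.G = X, y, gidx, n_groups
        z, w = np.polynomial.hermite.hermgauss(n_quad)
        self.z, self.logw = z, np.log(w)

    def _modes(self, eta0, sig2, n_iter=40):
        """Posterior mode and curvature of the random intercept per group."""
        b = np.zeros(self.G)
        for _ in range(n_iter):
            p = expit(eta0 + b[self.gidx])
            score = np.bincount(self.gidx, self.y - p, self.G) - b / sig2
            curv = np.bincount(self.gidx, p * (1 - p), self.G) + 1.0 / sig2
            step = score / curv
            b += np.clip(step, -4.0, 4.0)
            if np.max(np.abs(step)) < 1e-12:
                break
        p = expit(eta0 + b[self.gidx])
        curv = np.bincount(self.gidx, p * (1 - p), self.G) + 1.0 / sig2
        return b, 1.0 / np.sqrt(curv)

    def nll_grad(self, theta):
        X, y, gidx, G = self.X, self.y, self.gidx, self.G
        p_dim = X.shape[1]
        beta, log_sigma = theta[:p_dim], theta[p_dim]
        sigma = np.exp(log_sigma)
        sig2 = sigma * sigma
        eta0 = X @ beta
        bhat, tau = self._modes(eta0, sig2)

        K = len(self.z)
        terms = np.empty((G, K))
        bk_all = bhat[:, None] + _SQRT2 * tau[:, None] * self.z[None, :]
        for k in range(K):
            bk = bk_all[:, k]
            eta = eta0 + bk[gidx]
            ll_g = np.bincount(gidx, y * eta - _softplus(eta), G)
            h = ll_g - bk * bk / (2 * sig2) - np.log(sigma) - _LOG_SQRT_2PI
            terms[:, k] = self.logw[k] + self.z[k] ** 2 + h
        log_Lg = np.log(_SQRT2 * tau) + logsumexp(terms, axis=1)
        nll = -float(np.sum(log_Lg))

        omega = np.exp(terms - logsumexp(terms, axis=1, keepdims=True))
        grad_beta = np.zeros(p_dim)
        grad_ls = 0.0
        for k in range(K):
            bk = bk_all[:, k]
            eta = eta0 + bk[gidx]
            r = (y - expit(eta)) * omega[gidx, k]
            grad_beta += X.T @ r
            grad_ls += float(np.sum(omega[:, k] * (bk * bk / sig2 - 1.0)))
        return nll, -np.concatenate([grad_beta, [grad_ls]])


def mixed_logit_loglik(X, y, groups, beta, sigma, n_quad=15) -> float:
    """Marginal log-likelihood at given parameters (for oracle comparisons)."""
    gcodes, gidx = np.unique(np.asarray(groups), return_inverse=True)
    lik = _MarginalLik(np.asarray(X, float), np.asarray(y, float), gidx,
                       len(gcodes), n_quad)
    if sigma <= 0:
        eta = X @ beta
        return float(np.sum(y * eta - _softplus(eta)))
    nll, _ = lik.nll_grad(np.concatenate([beta, [np.log(sigma)]]))
    return -nll


def fit_rsf_mixed(rows: pd.DataFrame, spec: ModelSpec, n_quad: int = 15,
                  re_variance: float | None = None, max_iter: int = 300
                  ) -> FitResult:
    """Fit the mixed logistic RSF for one candidate structure.

    ``re_variance`` fixes the random-intercept variance (0 reduces the model
    to plain logistic regression); ``None`` estimates it. Requires at least
    two animal-year groups unless the variance is fixed. Non-convergence
    raises ``ConvergenceError``; a boundary variance estimate (~0) is
    reported in ``extra['boundary']`` with the fit still returned.
    """
    X, names, y = design_matrix(rows, spec)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient after screening")
    groups = rows["animal_year_id"].to_numpy()
    gcodes, gidx = np.unique(groups, return_inverse=True)
    G = len(gcodes)

    if re_variance == 0 or (re_variance is None and G < 2):
        if re_variance is None and G < 2:
            raise ValueError("need >= 2 animal-year groups for a random intercept")
        beta, vcov, ll = _plain_logistic(X, y)
        return FitResult(
            spec=spec, coef=pd.Series(beta, index=names),
            se=pd.Series(np.sqrt(np.diag(vcov)), index=names),
            loglik=ll, n_obs=len(y), k=len(names), converged=True,
            vcov=vcov, re_var=0.0, n_groups=G,
            extra={"scale": "landscape", "manifest": rows.attrs.get("manifest")},
        )

    lik = _MarginalLik(X, y, gidx, G, n_quad)
    beta0, _, _ = _plain_logistic(X, y, max_iter=25)
    x0 = np.concatenate([beta0, [np.log(0.5)]])
    bounds = [(None, None)] * X.shape[1] + [(-8.0, 5.0)]
    if re_variance is not None:
        ls = 0.5 * np.log(re_variance)
        x0[-1] = ls
        bounds[-1] = (ls, ls)
    res = minimize(lik.nll_grad, x0, jac=True, method="L-BFGS-B", bounds=bounds,
                   options={"maxiter": max_iter, "ftol": 1e-13, "gtol": 1e-7})
    _, g = lik.nll_grad(res.x)
    if re_variance is not None:
        g = g[:-1]
    if not (res.success or np.max(np.abs(g)) < 1e-3 * (1 + abs(res.fun))):
        raise ConvergenceError(
            f"mixed logistic fit did not converge: {res.message} "
            f"(max|grad| = {np.max(np.abs(g)):.3g})")

    theta = res.x
    sigma = np.exp(theta[-1])
    boundary = theta[-1] <= bounds[-1][0] + 1e-6 if re_variance is None else False

    # observed information by central differences of the analytic gradient
    free = len(theta) - (1 if re_variance is not None else 0)
    H = np.zeros((free, free))
    for j in range(free):
        h = 1e-5 * max(1.0, abs(theta[j]))
        tp, tm = theta.copy(), theta.copy()
        tp[j] += h
        tm[j] -= h
        _, gp = lik.nll_grad(tp)
        _, gm = lik.nll_grad(tm)
        H[:, j] = (gp[:free] - gm[:free]) / (2 * h)
    H = (H + H.T) / 2
    try:
        vcov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        vcov = np.linalg.pinv(H)
    se_all = np.sqrt(np.clip(np.diag(vcov), 0, None))

    p_dim = X.shape[1]
    return FitResult(
        spec=spec, coef=pd.Series(theta[:p_dim], index=names),
        se=pd.Series(se_all[:p_dim], index=names),
        loglik=-res.fun, n_obs=len(y),
        k=p_dim + (0 if re_variance is not None else 1),
        converged=True, vcov=vcov[:p_dim, :p_dim],
        re_var=float(sigma ** 2), n_groups=G,
        extra={"boundary": bool(boundary), "log_sigma": float(theta[-1]),
               "manifest": rows.attrs.get("manifest")},
    )


def predict_relative_selection(fit: FitResult, new_rows: pd.DataFrame,
                               manifest: dict | None = None) -> np.ndarray:
    """exp(fixed linear predictor without intercept/random effect).

    A monotone relative-selection score on standardized inputs, used for
    ranking, validation, and effect displays only. If a scaling manifest is
    supplied, the new rows are assumed raw and are standardized with the
    training means/sds first.
    """
    rows = apply_standardization(new_rows, manifest) if manifest else new_rows
    X, names, _ = design_matrix(rows, fit.spec)
    beta = fit.coef.reindex(names).to_numpy()
    if "intercept" in names:
        j = names.index("intercept")
        beta = beta.copy()
        beta[j] = 0.0
    lp = X @ np.nan_to_num(beta)
    return np.exp(lp)
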