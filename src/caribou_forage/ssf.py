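"""Patch-scale step selection: conditional logistic regression.

Each stratum matches one used step with its available steps; the conditional
likelihood is prod_s exp(beta' x_used) / sum_j exp(beta' x_j), maximized by
Newton-Raphson with step halving. Naive covariance is the inverse observed
information; the robust covariance is a sandwich whose meat sums stratum
scores within animal-year clusters (steps by one animal in one summer are
not independent), with the G/(G-1) small-sample correction. Step length
enters every candidate as a nuisance covariate to de-bias the kernel-based
availability sample.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .model_specs import FitResult, ModelSpec, design_matrix

# |beta| beyond this on standardized covariates signals separation: the
# conditional likelihood is maximized at infinity and Newton runs away
_DIVERGE_BOUND = 10.0


def _stratum_structures(rows: pd.DataFrame):
    order = rows["stratum"].astype(str).to_numpy().argsort(kind="stable")
    strata = rows["stratum"].astype(str).to_numpy()[order]
    starts = np.flatnonzero(np.r_[True, strata[1:] != strata[:-1]])
    return order, starts


def clogit_loglik(X, y, starts, beta):
    """Conditional log-likelihood given stratum start offsets (sorted rows)."""
    eta = X @ beta if X.shape[1] else np.zeros(len(y))
    # logsumexp per stratum via reduceat on max-shifted exponentials
    seg_max = np.maximum.reduceat(eta, starts)
    rep = np.diff(np.r_[starts, len(eta)])
    shifted = np.exp(eta - np.repeat(seg_max, rep))
    lse = seg_max + np.log(np.add.reduceat(shifted, starts))
    return float(eta @ y - lse.sum()), eta, lse, rep


def fit_ssf_clogit(rows: pd.DataFrame, spec: ModelSpec, max_iter: int = 100,
                   tol_score: float = 1e-6) -> FitResult:
    """Fit the conditional-logistic SSF for one candidate structure.

    Requires every stratum to contain exactly one used row and at least one
    available row. Complete separation (a covariate that perfectly ranks the
    used step in every stratum) is detected by runaway coefficients; the fit
    is returned with ``converged=False`` and the offending terms listed in
    ``diverged_terms``.
    """
    X, names, y = design_matrix(rows, spec)
    order, starts = _stratum_structures(rows)
    X, y = X[order], y[order]
    used_per = np.add.reduceat(y, starts)
    if np.any(used_per != 1):
        raise ValueError(
            f"{int(np.sum(used_per != 1))} stratum(s) without exactly one used row")
    sizes = np.diff(np.r_[starts, len(y)])
    if np.any(sizes < 2):
        raise ValueError(f"{int(np.sum(sizes < 2))} stratum(s) without available rows")

    p = X.shape[1]
    n_strata = len(starts)
    groups = rows["animal_year_id"].to_numpy()[order]

    beta = np.zeros(p)
    ll, eta, lse, rep = clogit_loglik(X, y, starts, beta)
    converged = p == 0
    diverged = False
    for _ in range(max_iter if p else 0):
        pi = np.exp(eta - np.repeat(lse, rep))
        U = X.T @ (y - pi)
        if np.max(np.abs(U)) < tol_score:
            converged = True
            break
        Xw = X * pi[:, None]
        M = np.add.reduceat(Xw, starts, axis=0)          # per-stratum E[x]
        A = Xw.T @ X - M.T @ M                           # observed information
        try:
            step = np.linalg.solve(A, U)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(A, U, rcond=None)[0]
        t = 1.0
        for _ in range(30):
            cand = beta + t * step
            ll_c, eta_c, lse_c, _ = clogit_loglik(X, y, starts, cand)
            if ll_c >= ll - 1e-12:
                break
            t /= 2
        beta, eta, lse = cand, eta_c, lse_c
        if np.max(np.abs(beta)) > _DIVERGE_BOUND:
            diverged = True
            break
        ll = ll_c
    if p and np.max(np.abs(beta)) > _DIVERGE_BOUND:
        diverged = True

    pi = np.exp(eta - np.repeat(lse, rep))
    if p:
        Xw = X * pi[:, None]
        M = np.add.reduceat(Xw, starts, axis=0)
        A = Xw.T @ X - M.T @ M
        vcov = np.linalg.pinv(A)
        # stratum score contributions, summed within animal-year clusters
        resid = (y - pi)[:, None] * X
        u_strat = np.add.reduceat(resid, starts, axis=0)
        cl_codes, cl_idx = np.unique(groups[starts], return_inverse=True)
        Gc = len(cl_codes)
        Uc = np.zeros((Gc, p))
        np.add.at(Uc, cl_idx, u_strat)
        meat = Uc.T @ Uc * (Gc / max(Gc - 1, 1))
        robust_vcov = vcov @ meat @ vcov
        se = np.sqrt(np.clip(np.diag(vcov), 0, None))
        rse = np.sqrt(np.clip(np.diag(robust_vcov), 0, None))
        diverged_terms = tuple(np.array(names)[np.abs(beta) > _DIVERGE_BOUND]) \
            if diverged else ()
    else:
        A = vcov = robust_vcov = np.empty((0, 0))
        se = rse = np.empty(0)
        Gc = len(np.unique(groups))
        diverged_terms = ()

    return FitResult(
        spec=spec, coef=pd.Series(beta, index=names),
        se=pd.Series(se, index=names),
        robust_se=pd.Series(rse, index=names),
        loglik=ll, n_obs=len(y), k=p,
        converged=converged and not diverged,
        vcov=vcov, robust_vcov=robust_vcov,
        n_groups=Gc, n_strata=n_strata,
        diverged_terms=diverged_terms,
        extra={"information": A, "scale": "patch",
               "manifest": rows.attrs.get("manifest")},
    )
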