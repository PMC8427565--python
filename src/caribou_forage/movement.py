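"""Movement-rate response to insect harassment: linear mixed model.

Log-transformed step lengths are regressed on an insect activity index and
ordinal study day (day 1 = 1 June), with linear and quadratic terms and a
random intercept per animal-year. The variance ratio lambda = sigma_b^2 /
sigma_e^2 is profiled out of the (restricted) likelihood, leaving a 1-D
optimization; coefficients and variance components are reported from the
REML fit while AIC uses a maximum-likelihood refit so fixed-effect ladders
are comparable.

The harassment ratio summarizes a fit as the fold-change of median step
length between two index values at fixed ordinal day.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .model_specs import FitResult


@dataclass(frozen=True)
class MovementSpec:
    """Fixed-effect structure of one step-length candidate model."""

    index: str | None = None   # "mi" | "oi" | None
    index_quad: bool = False
    od_quad: bool = False

    @property
    def label(self) -> str:
        parts = []
        if self.index:
            parts.append(self.index.upper())
            if self.index_quad:
                parts.append(f"{self.index.upper()}^2")
        parts.append("OD")
        if self.od_quad:
            parts.append("OD^2")
        return " + ".join(parts)

    def terms(self) -> list[str]:
        cols = []
        if self.index:
            cols.append(self.index)
            if self.index_quad:
                cols.append(f"{self.index}2")
        cols.append("od")
        if self.od_quad:
            cols.append("od2")
        return cols


def movement_candidates(index: str) -> list[MovementSpec]:
    """The six-candidate ladder for one insect period.

    Ordinal day is in every candidate; the index enters not at all, linearly,
    or with its quadratic, crossed with a linear-or-quadratic day trend.
    """
    return [
        MovementSpec(index=index, index_quad=True, od_quad=True),
        MovementSpec(index=index, index_quad=False, od_quad=True),
        MovementSpec(index=index, index_quad=True, od_quad=False),
        MovementSpec(index=index, index_quad=False, od_quad=False),
        MovementSpec(index=None, od_quad=True),
        MovementSpec(index=None, od_quad=False),
    ]


def _movement_design(rows: pd.DataFrame, spec: MovementSpec):
    n = len(rows)
    cols = [np.ones(n)]
    names = ["intercept"]
    for t in spec.terms():
        if t.endswith("2"):
            v = rows[t[:-1]].to_numpy(dtype=float) ** 2
        else:
            v = rows[t].to_numpy(dtype=float)
        cols.append(v)
        names.append(t)
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(
            f"design for {spec.label!r} is rank deficient (constant predictor?)")
    return X, names


class _LMMProfile:
    """Profiled single-random-intercept Gaussian LMM sufficient statistics."""

    def __init__(self, X, y, gidx, n_groups):
        self.N, self.p = X.shape
        self.G = n_groups
        self.XtX = X.T @ X
        self.Xty = X.T @ y
        self.yty = float(y @ y)
        self.ng = np.bincount(gidx, minlength=n_groups).astype(float)
        self.Sx = np.zeros((n_groups, self.p))
        np.add.at(self.Sx, gidx, X)
        self.Sy = np.bincount(gidx, weights=y, minlength=n_groups)

    def _pieces(self, lam):
        c = lam / (1.0 + lam * self.ng)
        XtVX = self.XtX - (self.Sx * c[:, None]).T @ self.Sx
        XtVy = self.Xty - self.Sx.T @ (c * self.Sy)
        ytVy = self.yty - float(c @ (self.Sy ** 2))
        logdetV = float(np.sum(np.log1p(lam * self.ng)))
        beta = np.linalg.solve(XtVX, XtVy)
        qf = ytVy - float(beta @ XtVy)
        return beta, qf, XtVX, logdetV

    def neg_loglik(self, log_lam, reml=True):
        lam = np.exp(log_lam)
        beta, qf, XtVX, logdetV = self._pieces(lam)
        qf = max(qf, 1e-300)
        if reml:
            df = self.N - self.p
            s2 = qf / df
            _, ld_xvx = np.linalg.slogdet(XtVX)
            ll = -0.5 * (df * (1 + np.log(2 * np.pi * s2)) + logdetV + ld_xvx)
        else:
            s2 = qf / self.N
            ll = -0.5 * (self.N * (1 + np.log(2 * np.pi * s2)) + logdetV)
        return -ll

    def fit(self, reml=True):
        res = minimize_scalar(lambda t: self.neg_loglik(t, reml),
                              bounds=(-15.0, 10.0), method="bounded",
                              options={"xatol": 1e-10})
        lam = float(np.exp(res.x))
        beta, qf, XtVX, _ = self._pieces(lam)
        s2 = qf / ((self.N - self.p) if reml else self.N)
        return beta, lam, float(s2), -float(res.fun), XtVX


def fit_move_lmm(rows: pd.DataFrame, spec: MovementSpec,
                 response: str = "log_step_length") -> FitResult:
    """Fit one step-length candidate by REML (AIC from an ML refit).

    ``rows`` must carry positive-length steps already log-transformed into
    ``response``, standardized predictors, and ``animal_year_id``. Zero or
    negative step lengths are a caller error (the kernel-fitting floor
    handles exact zeros upstream).
    """
    y = rows[response].to_numpy(dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite log step lengths; drop zero-length steps first")
    groups = rows["animal_year_id"].to_numpy()
    gcodes, gidx = np.unique(groups, return_inverse=True)
    if len(gcodes) < 2:
        raise ValueError("need >= 2 animal-year groups")
    X, names = _movement_design(rows, spec)

    prob = _LMMProfile(X, y, gidx, len(gcodes))
    beta, lam, s2e, ll_reml, XtVX = prob.fit(reml=True)
    _, _, _, ll_ml, _ = prob.fit(reml=False)
    vcov = s2e * np.linalg.inv(XtVX)
    k = X.shape[1] + 2  # fixed effects + two variance components
    return FitResult(
        spec=spec, coef=pd.Series(beta, index=names),
        se=pd.Series(np.sqrt(np.diag(vcov)), index=names),
        loglik=ll_ml, n_obs=len(y), k=k, converged=True, vcov=vcov,
        re_var=float(lam * s2e), n_groups=len(gcodes),
        extra={"resid_var": s2e, "loglik_reml": ll_reml, "lambda": lam,
               "manifest": rows.attrs.get("manifest"),
               "index": spec.index},
    )


def harassment_ratio(fit: FitResult, index_low: float, index_high: float,
                     manifest: dict | None = None) -> float:
    """Fold-change of median step length between two raw index values.

    Ordinal day is held fixed (its terms cancel), so the ratio is
    exp(beta_I (z_hi - z_lo) + beta_I2 (z_hi^2 - z_lo^2)) with z the
    standardized index. Index values outside [0, 1] are rejected.
    """
    for v in (index_low, index_high):
        if not 0.0 <= v <= 1.0:
            raise ValueError("insect index values must lie in [0, 1]")
    spec = fit.spec
    idx = getattr(spec, "index", None)
    if idx is None:
        return 1.0
    manifest = manifest or fit.extra.get("manifest") or {}
    ms = manifest.get(idx, {"mean": 0.0, "sd": 1.0})
    z_lo = (index_low - ms["mean"]) / ms["sd"]
    z_hi = (index_high - ms["mean"]) / ms["sd"]
    delta = fit.coef.get(idx, 0.0) * (z_hi - z_lo)
    delta += fit.coef.get(f"{idx}2", 0.0) * (z_hi ** 2 - z_lo ** 2)
    return float(np.exp(delta))
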