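"""Mapping fitted coefficients back onto the generator's parameter scale.

The analysis standardizes covariates over each fitting table, while the
trajectory generator standardizes over the whole landscape, so coefficients
from the two live on different scales. Both parameterizations are affine
maps of the raw-unit polynomial coefficients: for a covariate x entering as
b_l z + b_q z^2 with z = (x - m)/s, the raw coefficients are

    on x:   b_l / s - 2 m b_q / s^2
    on x^2: b_q / s^2

Comparing truth and fit on the raw scale removes the scaling ambiguity; the
delta method (the map is linear in beta) carries covariances along.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def _mean_sd(entry):
    if isinstance(entry, dict):
        return float(entry["mean"]), float(entry["sd"])
    return float(entry[0]), float(entry[1])


def raw_scale_transform(term_names: list[str], manifest: dict) -> tuple[list[str], np.ndarray]:
    """(raw term names, matrix A) with beta_raw = A @ beta_standardized.

    Quadratic terms are recognized by the trailing ``2`` on a name whose stem
    is in the manifest; terms without a manifest entry (aspect dummies,
    interactions left standardized) pass through unchanged.
    """
    n = len(term_names)
    A = np.zeros((n, n))
    names = list(term_names)
    idx = {t: i for i, t in enumerate(term_names)}
    for i, t in enumerate(term_names):
        stem = t[:-1] if t.endswith("2") else t
        if stem not in manifest:
            A[i, i] = 1.0
            continue
        m, s = _mean_sd(manifest[stem])
        if t.endswith("2"):
            A[i, i] = 1.0 / s**2
        else:
            A[i, i] = 1.0 / s
            quad = t + "2"
            if quad in idx:
                A[i, idx[quad]] = -2.0 * m / s**2
    return names, A


def to_raw_scale(coef: pd.Series, manifest: dict,
                 vcov: np.ndarray | None = None
                 ) -> tuple[pd.Series, pd.Series | None]:
    """Raw-unit coefficients (and delta-method SEs) from a standardized fit."""
    names, A = raw_scale_transform(list(coef.index), manifest)
    raw = pd.Series(A @ coef.to_numpy(), index=names)
    if vcov is None:
        return raw, None
    se = pd.Series(np.sqrt(np.clip(np.diag(A @ vcov @ A.T), 0, None)), index=names)
    return raw, se


def truth_raw_scale(beta: dict[str, float], scaler: dict) -> pd.Series:
    """Generator truth mapped to raw units via the generator's scaler."""
    coef = pd.Series(beta, dtype=float)
    manifest = {k: {"mean": v[0], "sd": v[1]} for k, v in scaler.items()}
    raw, _ = to_raw_scale(coef, manifest)
    return raw
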