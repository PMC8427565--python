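"""Candidate ranking (AIC / QIC) and k-fold binned-Spearman validation.

AIC = -2 logLik + 2k ranks the landscape-scale mixed fits; the patch-scale
conditional fits use the quasi-likelihood independence criterion
QIC = -2 logLik + 2 trace(Omega_naive^{-1} V_robust), whose penalty reduces
to 2k when the robust and model-based covariances coincide and grows when
within-cluster correlation inflates the sandwich.

Cross-validation partitions animal-years (never rows) into k folds; each
fold's model is trained on the remaining animal-years, test scores are
ranked into equal-count bins over available rows, and the area-adjusted
frequency of used points per bin is Spearman-correlated with bin rank.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .design import standardize
from .model_specs import FitResult, ModelSpec
from .rsf import predict_relative_selection

log = logging.getLogger(__name__)


def aic(fit: FitResult) -> float:
    return -2.0 * fit.loglik + 2.0 * fit.k


def qic(fit: FitResult) -> float:
    """Quasi-likelihood independence criterion for a clustered clogit fit."""
    if fit.k == 0:
        return -2.0 * fit.loglik
    A = fit.extra.get("information")
    if A is None or fit.robust_vcov is None:
        raise ValueError("QIC needs the fit's information and sandwich matrices")
    if np.linalg.matrix_rank(A) < A.shape[0]:
        raise np.linalg.LinAlgError("singular information matrix in QIC")
    penalty = 2.0 * float(np.trace(A @ fit.robust_vcov))
    return -2.0 * fit.loglik + penalty


def delta_and_weights(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Delta to the best criterion value and the normalized Akaike weights."""
    values = np.asarray(values, dtype=float)
    delta = values - values.min()
    w = np.exp(-delta / 2.0)
    return delta, w / w.sum()


def selection_table(fits: list[FitResult], criterion: str = "aic") -> pd.DataFrame:
    """Rank candidates; non-converged fits are excluded with a logged note."""
    ok = []
    for f in fits:
        if f.converged:
            ok.append(f)
        else:
            log.warning("excluding non-converged candidate %s from the %s table",
                        f.spec.label, criterion.upper())
    crit_fn = {"aic": aic, "qic": qic}[criterion]
    vals = np.array([crit_fn(f) for f in ok])
    delta, w = delta_and_weights(vals)
    tab = pd.DataFrame({
        "model": [f.spec.label for f in ok],
        "loglik": [f.loglik for f in ok],
        "k": [f.k for f in ok],
        criterion: vals, f"delta_{criterion}": delta, "weight": w,
    }).sort_values(criterion, kind="stable").reset_index(drop=True)
    return tab


# ---------------------------------------------------------------------------
# binned Spearman cross-validation
# ---------------------------------------------------------------------------

def binned_spearman(scores: np.ndarray, used: np.ndarray, n_bins: int = 10) -> float:
    """Spearman r_s of area-adjusted used frequency against score-bin rank.

    Bins are equal-count over available rows; used rows are placed by the
    same bin edges; each bin's used fraction is divided by its available
    fraction (the area adjustment). Ties get average ranks.
    """
    scores = np.asarray(scores, dtype=float)
    used = np.asarray(used, dtype=bool)
    avail = scores[~used]
    if len(avail) < n_bins or used.sum() == 0:
        raise ValueError("need available rows >= bins and at least one used row")
    edges = np.quantile(avail, np.linspace(0, 1, n_bins + 1)[1:-1])
    bins = np.searchsorted(edges, scores, side="right")
    n_used = np.bincount(bins[used], minlength=n_bins).astype(float)
    n_avail = np.bincount(bins[~used], minlength=n_bins).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        adj = (n_used / used.sum()) / (n_avail / (~used).sum())
    adj[~np.isfinite(adj)] = 0.0
    r = stats.spearmanr(np.arange(1, n_bins + 1), adj).statistic
    return float(0.0 if np.isnan(r) else r)


@dataclass
class CVResult:
    """Per-repeat mean Spearman correlations and their overall mean."""

    per_repeat: list[float] = field(default_factory=list)
    fold_rs: list[list[float]] = field(default_factory=list)

    @property
    def mean_rs(self) -> float:
        return float(np.mean(self.per_repeat))


def kfold_cv(raw_rows: pd.DataFrame, spec: ModelSpec, fit_fn=None,
             k: int = 5, n_bins: int = 10, repeats: int = 10, seed: int = 0,
             permute_scores: bool = False) -> CVResult:
    """k-fold binned-Spearman validation of one candidate structure.

    ``raw_rows`` are unstandardized design rows; each fold standardizes its
    training animal-years, fits, applies the training manifest to the test
    rows, and scores them with the relative-selection function. Folds
    partition animal-years, never rows. A fold with no used (or too few
    available) test rows is skipped and logged. ``permute_scores`` shuffles
    the predicted scores within each test fold, the null reference.
    """
    if fit_fn is None:
        if spec.scale == "landscape":
            from .rsf import fit_rsf_mixed
            fit_fn = fit_rsf_mixed
        else:
            from .ssf import fit_ssf_clogit
            fit_fn = fit_ssf_clogit
    animals = np.array(sorted(raw_rows["animal_year_id"].unique()))
    if len(animals) < k:
        raise ValueError(f"need at least {k} animal-years for {k}-fold CV")
    rng = np.random.default_rng(seed)
    result = CVResult()
    for _ in range(repeats):
        perm = rng.permutation(animals)
        folds = np.array_split(perm, k)
        rs_folds = []
        for fold in folds:
            test_mask = raw_rows["animal_year_id"].isin(fold)
            train, manifest = standardize(raw_rows[~test_mask])
            fit = fit_fn(train, spec)
            test = raw_rows[test_mask]
            if test["used"].sum() == 0 or (~test["used"]).sum() < n_bins:
                log.warning("skipping CV fold without usable test rows")
                continue
            scores = predict_relative_selection(fit, test, manifest)
            if permute_scores:
                scores = rng.permutation(scores)
            rs_folds.append(binned_spearman(scores, test["used"].to_numpy(), n_bins))
        if rs_folds:
            result.fold_rs.append(rs_folds)
            result.per_repeat.append(float(np.mean(rs_folds)))
    return result
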