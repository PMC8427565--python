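"""Candidate model structures and design-matrix construction.

A candidate is the base habitat structure (aspect + elevation + elevation^2 +
snowmelt + snowmelt^2, plus step length at the patch scale) optionally
augmented with a forage subset (biomass linear or linear+quadratic, DN, DE),
an insect activity index, and insect-by-forage interactions. Quadratic terms
are squares of the standardized linear columns; the intercept exists only at
the landscape scale (the conditional likelihood absorbs it at the patch
scale). Flagged collinear pairs never co-occur in one candidate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .landscape import ASPECT_LEVELS

BASE_TERMS = ("aspect", "elevation", "elevation2", "snowmelt", "snowmelt2")
FORAGE_TERMS = ("biomass", "biomass2", "dn", "de")
ASPECT_DUMMIES = tuple(f"aspect_{a}" for a in ASPECT_LEVELS if a != "north")


@dataclass(frozen=True)
class ModelSpec:
    """One candidate covariate structure for an RSF or SSF fit."""

    scale: str                     # "landscape" | "patch"
    period: str = "all"
    base: bool = True
    forage: tuple[str, ...] = ()
    insect: str | None = None      # "mi" | "oi"
    interactions: tuple[str, ...] = ()  # forage terms interacted with the index

    def __post_init__(self):
        if self.scale not in ("landscape", "patch"):
            raise ValueError(f"unknown scale {self.scale!r}")
        if "biomass2" in self.forage and "biomass" not in self.forage:
            raise ValueError("biomass^2 requires the linear biomass term")
        if self.interactions and self.insect is None:
            raise ValueError("interactions require the insect main effect")
        for t in self.interactions:
            if t not in self.forage:
                raise ValueError(f"interaction with {t!r} requires its main effect")

    @property
    def label(self) -> str:
        if not self.base and not self.forage and self.insect is None:
            return "Null"
        parts = ["Base habitat"] if self.base else []
        names = {"biomass": "BM", "biomass2": "BM^2", "dn": "DN", "de": "DE"}
        parts += [names[t] for t in self.forage]
        if self.insect:
            ins = self.insect.upper()
            parts.append(ins)
            parts += [f"{ins}*{names[t]}" for t in self.interactions]
        return " + ".join(parts)

    def terms(self) -> list[str]:
        """Ordered design-matrix column names (excluding the intercept)."""
        cols: list[str] = []
        if self.base:
            cols += list(ASPECT_DUMMIES)
            cols += ["elevation", "elevation2", "snowmelt", "snowmelt2"]
            if self.scale == "patch":
                cols.append("step_length")
        cols += list(self.forage)
        if self.insect:
            cols.append(self.insect)
            cols += [f"{self.insect}:{t}" for t in self.interactions]
        return cols

    def violates(self, flagged_pairs) -> bool:
        """True if a flagged collinear pair co-occurs in this candidate.

        Base-habitat terms are fixed by design, so only pairs touching an
        optional term (forage or insect) can veto a candidate.
        """
        optional = {t.removesuffix("2") for t in self.forage}
        if self.insect:
            optional.add(self.insect)
        present = set(optional)
        if self.base:
            present |= {"elevation", "snowmelt"}
            if self.scale == "patch":
                present.add("step_length")
        return any(
            (a in optional or b in optional) and a in present and b in present
            for a, b, *_ in flagged_pairs
        )


def design_matrix(rows: pd.DataFrame, spec: ModelSpec,
                  intercept: bool | None = None):
    """Build (X, names, y) from a standardized design-row table.

    ``intercept`` defaults to True at the landscape scale and False at the
    patch scale. Raises on aspect levels outside the known five.
    """
    if intercept is None:
        intercept = spec.scale == "landscape"
    n = len(rows)
    cols: list[np.ndarray] = []
    names: list[str] = []
    if intercept:
        cols.append(np.ones(n))
        names.append("intercept")
    if spec.base:
        aspect = rows["aspect"].astype(str).to_numpy()
        bad = set(np.unique(aspect)) - set(ASPECT_LEVELS)
        if bad:
            raise ValueError(f"unseen aspect level(s): {sorted(bad)}")
        resp = rows["response"].to_numpy() if "response" in rows.columns else None
        for d in ASPECT_DUMMIES:
            col = (aspect == d.removeprefix("aspect_")).astype(float)
            # a level absent from the table, or present in only one response
            # class (a certain-separation column), folds into the reference
            keep = col.any()
            if keep and resp is not None:
                keep = col[resp == 1].any() and col[resp == 0].any()
            if keep:
                cols.append(col)
                names.append(d)

    def col(term):
        if term.endswith("2") and term[:-1] in rows.columns:
            return rows[term[:-1]].to_numpy(dtype=float) ** 2
        return rows[term].to_numpy(dtype=float)

    base_cont = ["elevation", "elevation2", "snowmelt", "snowmelt2"]
    if spec.base:
        for t in base_cont:
            cols.append(col(t))
            names.append(t)
        if spec.scale == "patch":
            cols.append(col("step_length"))
            names.append("step_length")
    for t in spec.forage:
        cols.append(col(t))
        names.append(t)
    if spec.insect:
        ins = col(spec.insect)
        cols.append(ins)
        names.append(spec.insect)
        for t in spec.interactions:
            cols.append(ins * col(t))
            names.append(f"{spec.insect}:{t}")
    X = np.column_stack(cols) if cols else np.empty((n, 0))
    y = rows["response"].to_numpy(dtype=float) if "response" in rows.columns else None
    return X, names, y


def build_candidate_set(period: str, scale: str,
                        flagged_pairs=(),
                        forage_vars=("biomass", "dn", "de")) -> list[ModelSpec]:
    """Null + base + base-with-every-forage-subset candidate list.

    Biomass enters linearly or with its quadratic; DN and DE linearly. With
    all three forage variables and no flags this yields 13 candidates; a
    flagged biomass-DE pair (the late-summer collinearity rule) reduces the
    set to 9 because no candidate may contain both.
    """
    specs = [ModelSpec(scale=scale, period=period, base=False)]
    bm_options = [(), ("biomass",), ("biomass", "biomass2")] if "biomass" in forage_vars else [()]
    dn_options = [(), ("dn",)] if "dn" in forage_vars else [()]
    de_options = [(), ("de",)] if "de" in forage_vars else [()]
    for bm in bm_options:
        for dn in dn_options:
            for de in de_options:
                spec = ModelSpec(scale=scale, period=period, base=True,
                                 forage=bm + dn + de)
                if not spec.violates(flagged_pairs):
                    specs.append(spec)
    return specs


def insect_candidate_set(forage_spec: ModelSpec, index: str) -> list[ModelSpec]:
    """Insect-stage candidates around a period's top forage model.

    The set is the forage model itself, then the forage model plus the index
    main effect combined with every subset of index-by-forage interaction
    blocks (the biomass block keeps its quadratic with it). Three forage
    blocks give 1 + 2^3 = 9 candidates.
    """
    blocks: list[tuple[str, ...]] = []
    if "biomass" in forage_spec.forage:
        blocks.append(tuple(t for t in ("biomass", "biomass2") if t in forage_spec.forage))
    for t in ("dn", "de"):
        if t in forage_spec.forage:
            blocks.append((t,))
    specs = [forage_spec]
    for mask in range(1 << len(blocks)):
        inter: tuple[str, ...] = ()
        for b, blk in enumerate(blocks):
            if mask >> b & 1:
                inter += blk
        specs.append(ModelSpec(scale=forage_spec.scale, period=forage_spec.period,
                               base=forage_spec.base, forage=forage_spec.forage,
                               insect=index, interactions=inter))
    return specs


@dataclass
class FitResult:
    """Fitted coefficients and diagnostics for one candidate model."""

    spec: ModelSpec
    coef: pd.Series
    se: pd.Series
    loglik: float
    n_obs: int
    k: int                       # parameter count entering AIC/QIC
    converged: bool
    robust_se: pd.Series | None = None
    vcov: np.ndarray | None = None
    robust_vcov: np.ndarray | None = None
    re_var: float | None = None  # random-intercept variance (landscape scale)
    n_groups: int | None = None
    n_strata: int | None = None
    diverged_terms: tuple[str, ...] = ()
    extra: dict = field(default_factory=dict)

    def _crit(self, robust: bool, level: float) -> float:
        from scipy.stats import norm, t

        # cluster-robust inference with few clusters uses t_{G-1} quantiles
        if robust and self.n_groups and self.n_groups > 1:
            return float(t.ppf(0.5 + level / 2, df=self.n_groups - 1))
        return float(norm.ppf(0.5 + level / 2))

    def ci(self, robust: bool = False, level: float = 0.95) -> pd.DataFrame:
        se = self.robust_se if robust and self.robust_se is not None else self.se
        q = self._crit(robust and self.robust_se is not None, level)
        return pd.DataFrame({
            "beta": self.coef, "se": se,
            "l95": self.coef - q * se, "u95": self.coef + q * se,
        })

    def table(self) -> pd.DataFrame:
        """Coefficient table in beta / SE / p / CI layout."""
        from scipy.stats import norm, t

        robust = self.robust_se is not None
        se = self.robust_se if robust else self.se
        z = (self.coef / se).to_numpy(dtype=float)
        tab = self.ci(robust=robust)
        if robust and self.n_groups and self.n_groups > 1:
            p = 2 * t.sf(np.abs(z), df=self.n_groups - 1)
        else:
            p = 2 * norm.sf(np.abs(z))
        tab.insert(2, "p", p)
        return tab
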