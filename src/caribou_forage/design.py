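"""Data hygiene and sampling constructions for the use-availability designs.

Covers the landscape scale (minimum-convex-polygon availability, 10:1
point sampling with matched timestamps) and the patch scale (2-h step
construction, period-specific gamma step-length kernels, available steps by
rejection against the ocean/prediction masks), plus covariate attribution
from the weekly forage grids, standardization with a reusable manifest, and
the pairwise collinearity screen.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from shapely import contains_xy
from shapely.geometry import MultiPoint

from .config import FIX_INTERVAL_S, PeriodCalendar, day_of_study, week_of_day
from .landscape import ASPECT_LEVELS, ForageStack

log = logging.getLogger(__name__)

#: continuous covariates standardized when present
CONTINUOUS_COVARIATES = (
    "biomass", "dn", "de", "elevation", "snowmelt", "step_length",
    "mi", "oi", "od", "log_step_length",
)


# ---------------------------------------------------------------------------
# periods
# ---------------------------------------------------------------------------

def assign_periods(points: pd.DataFrame, calendar: PeriodCalendar | None = None
                   ) -> pd.DataFrame:
    """Label each point with its period; drop points in calendar gaps.

    Adds ``day`` (study day), ``period``, and ``analysis_excluded`` (True for
    calving, whose selection is not assessed). Points in the 16-28 July and
    8-15 August gaps are removed.
    """
    calendar = calendar or PeriodCalendar()
    out = points.copy()
    out["day"] = [day_of_study(t) for t in pd.to_datetime(out["t"])]
    out["period"] = [calendar.period_of_day(d) for d in out["day"]]
    out = out[out["period"].notna()].copy()
    out["analysis_excluded"] = out["period"] == "calving"
    return out


# ---------------------------------------------------------------------------
# landscape availability
# ---------------------------------------------------------------------------

def mcp_available_area(points: pd.DataFrame, ocean=None):
    """100% minimum convex polygon of the points, minus the ocean polygon."""
    if len(points) < 3:
        raise ValueError("need at least 3 points for a convex polygon")
    hull = MultiPoint(list(zip(points["x"], points["y"]))).convex_hull
    if hull.geom_type != "Polygon":
        raise ValueError("points are collinear; availability polygon is degenerate")
    if ocean is not None and not ocean.is_empty:
        hull = hull.difference(ocean)
    if hull.is_empty:
        raise ValueError("availability polygon is empty after removing the ocean")
    return hull


def sample_available_landscape(used_points: pd.DataFrame, area,
                               stack: ForageStack, ratio: int = 10,
                               seed: int = 0) -> pd.DataFrame:
    """Draw ``ratio`` available points per used point, uniform over cells.

    Candidate cells are prediction-area cells whose centers fall inside the
    availability polygon; each available point is a uniform jitter within a
    uniformly drawn candidate cell and carries its used point's timestamp,
    animal-year and period labels.
    """
    if ratio < 0:
        raise ValueError("ratio must be non-negative")
    cols = [c for c in ("animal_year_id", "t", "period", "day") if c in used_points]
    if ratio == 0:
        return pd.DataFrame(columns=cols + ["x", "y", "used"])
    cells = np.argwhere(stack.prediction_area)
    cx, cy = stack.cell_center(cells[:, 0], cells[:, 1])
    inside = contains_xy(area, cx, cy)
    cells = cells[inside]
    if len(cells) == 0:
        raise ValueError("no sampleable prediction-area cells inside the polygon")
    rng = np.random.default_rng(seed)
    n = len(used_points) * ratio
    pick = rng.integers(0, len(cells), n)
    out = used_points.loc[used_points.index.repeat(ratio), cols].reset_index(drop=True)
    out["x"] = (cells[pick, 1] + rng.random(n)) * stack.cell_size
    out["y"] = (cells[pick, 0] + rng.random(n)) * stack.cell_size
    out["used"] = False
    return out


# ---------------------------------------------------------------------------
# steps
# ---------------------------------------------------------------------------

def _wrap_angle(a):
    """Wrap to (-pi, pi]."""
    w = (np.asarray(a) + np.pi) % (2 * np.pi) - np.pi
    return np.where(w == -np.pi, np.pi, w)


def build_steps(points: pd.DataFrame, stack: ForageStack | None = None,
                tolerance_s: float = 300.0) -> pd.DataFrame:
    """Pair consecutive fixes 2 h apart (within tolerance) into used steps.

    Pairs spanning larger gaps are skipped; if a stack is given, steps whose
    endpoint falls outside its prediction area are dropped. The turning angle
    is relative to the previous step's bearing and is missing for a track's
    first step (or after a gap).
    """
    frames = []
    for aid, grp in points.sort_values(["animal_year_id", "t"]).groupby(
            "animal_year_id", sort=True):
        t = pd.to_datetime(grp["t"]).to_numpy()
        x = grp["x"].to_numpy()
        y = grp["y"].to_numpy()
        dt = np.diff(t).astype("timedelta64[s]").astype(float)
        is_step = np.abs(dt - FIX_INTERVAL_S) <= tolerance_s
        if not is_step.any():
            continue
        i = np.flatnonzero(is_step)
        dx, dy = x[i + 1] - x[i], y[i + 1] - y[i]
        bearing = np.arctan2(dy, dx)
        length = np.hypot(dx, dy)
        # turning angle defined only when the previous pair is also a step
        prev_ok = np.zeros(len(i), dtype=bool)
        prev_ok[1:] = i[1:] == i[:-1] + 1
        turn = np.full(len(i), np.nan)
        turn[prev_ok] = _wrap_angle(bearing[prev_ok] - bearing[np.flatnonzero(prev_ok) - 1])
        frames.append(pd.DataFrame({
            "animal_year_id": aid,
            "t_start": t[i], "t_end": t[i + 1],
            "x_start": x[i], "y_start": y[i],
            "x_end": x[i + 1], "y_end": y[i + 1],
            "length": length, "turn_angle": turn,
        }))
    if not frames:
        return pd.DataFrame(columns=[
            "animal_year_id", "t_start", "t_end", "x_start", "y_start",
            "x_end", "y_end", "length", "turn_angle", "used", "stratum"])
    out = pd.concat(frames, ignore_index=True)
    if stack is not None:
        iy = np.floor(out["y_end"].to_numpy() / stack.cell_size).astype(int)
        ix = np.floor(out["x_end"].to_numpy() / stack.cell_size).astype(int)
        ny, nx = stack.shape
        ok = (ix >= 0) & (ix < nx) & (iy >= 0) & (iy < ny)
        ok[ok] &= stack.prediction_area[iy[ok], ix[ok]]
        out = out[ok].reset_index(drop=True)
    out["used"] = True
    out["stratum"] = [f"{a}_s{k}" for k, a in enumerate(out["animal_year_id"])]
    return out


def fit_step_kernel(steps: pd.DataFrame, period: str | None = None,
                    min_steps: int = 30) -> tuple[float, float]:
    """Maximum-likelihood gamma (shape, scale) of used step lengths.

    Zero lengths are replaced by half the minimum positive length before
    fitting (the gamma support excludes 0). Refuses fewer than ``min_steps``
    steps or zero-variance lengths.
    """
    lens = steps["length"]
    if period is not None:
        lens = lens[steps["period"] == period]
    lens = lens.to_numpy(dtype=float)
    if len(lens) < min_steps:
        raise ValueError(
            f"only {len(lens)} steps available; need at least {min_steps} "
            f"to fit a step-length kernel")
    if np.ptp(lens) == 0:
        raise ValueError("step lengths have zero variance; gamma MLE is undefined")
    pos = lens[lens > 0]
    lens = np.where(lens > 0, lens, pos.min() / 2.0)
    shape, _, scale = stats.gamma.fit(lens, floc=0)
    return float(shape), float(scale)


def sample_available_steps(used_steps: pd.DataFrame,
                           kernels: dict[str, tuple[float, float]] | tuple[float, float],
                           stack: ForageStack, ratio: int = 10, seed: int = 0,
                           max_tries: int = 100) -> pd.DataFrame:
    """Generate ``ratio`` available steps per used step (one stratum each).

    Available steps share the used step's start point; lengths come from the
    period's fitted gamma kernel and turning angles from uniform(-pi, pi].
    Endpoints landing in the ocean or outside the forage prediction area are
    redrawn up to ``max_tries`` times, after which the whole stratum is
    dropped with a logged warning. Returns used + available rows bound by
    ``stratum``.
    """
    rng = np.random.default_rng(seed)
    ny, nx = stack.shape
    ex, ey = stack.extent
    n = len(used_steps)
    if n == 0 or ratio == 0:
        return used_steps.assign(used=True)

    if isinstance(kernels, tuple):
        shp = np.full(n, kernels[0])
        scl = np.full(n, kernels[1])
    else:
        periods = used_steps["period"].to_numpy()
        shp = np.array([kernels[p][0] for p in periods])
        scl = np.array([kernels[p][1] for p in periods])

    x0 = np.repeat(used_steps["x_start"].to_numpy(), ratio)
    y0 = np.repeat(used_steps["y_start"].to_numpy(), ratio)
    shp_r = np.repeat(shp, ratio)
    scl_r = np.repeat(scl, ratio)
    m = n * ratio
    xe = np.empty(m)
    ye = np.empty(m)
    ln = np.empty(m)
    ang = np.empty(m)
    todo = np.ones(m, dtype=bool)
    for _ in range(max_tries):
        k = int(todo.sum())
        if k == 0:
            break
        L = rng.gamma(shp_r[todo], scl_r[todo])
        A = rng.uniform(-np.pi, np.pi, k)
        px = x0[todo] + L * np.cos(A)
        py = y0[todo] + L * np.sin(A)
        ix = np.floor(px / stack.cell_size).astype(int)
        iy = np.floor(py / stack.cell_size).astype(int)
        ok = (px >= 0) & (px < ex) & (py >= 0) & (py < ey)
        ok[ok] &= stack.prediction_area[iy[ok], ix[ok]]
        idx = np.flatnonzero(todo)[ok]
        xe[idx], ye[idx] = px[ok], py[ok]
        ln[idx], ang[idx] = L[ok], A[ok]
        todo[np.flatnonzero(todo)[ok]] = False
    stratum_bad = todo.reshape(n, ratio).any(axis=1)
    if stratum_bad.any():
        log.warning("dropping %d stratum(s): endpoint redraw cap (%d) exceeded",
                    int(stratum_bad.sum()), max_tries)

    keep = ~stratum_bad
    used = used_steps.loc[keep].copy()
    used["used"] = True
    rep = np.repeat(keep, ratio)
    cols = [c for c in ("animal_year_id", "stratum", "t_start", "t_end", "period", "day")
            if c in used_steps]
    avail = used_steps.loc[used_steps.index.repeat(ratio), cols].reset_index(drop=True)
    avail["x_start"], avail["y_start"] = x0, y0
    avail["x_end"], avail["y_end"] = xe, ye
    avail["length"], avail["turn_angle"] = ln, ang
    avail["used"] = False
    avail = avail[rep.astype(bool)]
    out = pd.concat([used, avail], ignore_index=True)
    return out.sort_values(["stratum", "used"], ascending=[True, False],
                           kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# covariate attribution
# ---------------------------------------------------------------------------

class AttributionError(ValueError):
    """Raised when rows fall outside the forage stack's extent."""


def attribute_covariates(rows: pd.DataFrame, stack: ForageStack,
                         calendar: PeriodCalendar | None = None
                         ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Attach forage + static habitat values at each row's endpoint cell-week.

    Works for point tables (columns x, y, t) and step tables (x_end, y_end,
    t_end; also emits ``step_length``). Forage comes from the weekly layer
    containing the timestamp; rows in masked cell-weeks are dropped and the
    dropped fraction reported per period. Static habitat (elevation, aspect,
    snowmelt date) is always attributed. For step tables, strata whose used
    row was masked are removed entirely.

    Returns ``(attributed_rows, missingness_report)``.
    """
    out = rows.copy()
    is_steps = "x_end" in out.columns
    xc, yc, tc = ("x_end", "y_end", "t_end") if is_steps else ("x", "y", "t")
    try:
        iy, ix = stack.cell_of(out[xc].to_numpy(), out[yc].to_numpy())
    except ValueError as e:
        raise AttributionError(str(e)) from e
    if "day" not in out.columns:
        out["day"] = [day_of_study(t) for t in pd.to_datetime(out[tc])]
    weeks = np.array([week_of_day(d, stack.n_weeks) for d in out["day"]])
    out["week"] = weeks
    wi = weeks - 1
    out["biomass"] = stack.biomass[wi, iy, ix]
    out["dn"] = stack.dn[wi, iy, ix]
    out["de"] = stack.de[wi, iy, ix]
    out["elevation"] = stack.elevation[iy, ix]
    out["aspect"] = pd.Categorical.from_codes(stack.aspect[iy, ix],
                                              categories=list(ASPECT_LEVELS))
    out["snowmelt"] = stack.snowmelt_date[iy, ix]
    if is_steps:
        out["step_length"] = out["length"]
    valid = stack.valid_mask[wi, iy, ix]
    out["_valid"] = valid

    if "period" not in out.columns:
        out["period"] = "all"
    used_flag = out["used"] if "used" in out.columns else pd.Series(True, index=out.index)
    by_period = out.groupby("period", observed=True)["_valid"]
    used_frac = (out[used_flag].groupby("period", observed=True)["_valid"]
                 .apply(lambda v: float(1 - v.mean())))
    report = pd.DataFrame({
        "n_rows": by_period.size(),
        "frac_dropped": by_period.apply(lambda v: float(1 - v.mean())),
    })
    report["frac_used_dropped"] = used_frac
    report = report.reset_index()

    kept = out[out["_valid"]].drop(columns=["_valid"])
    if is_steps and "stratum" in kept.columns and "used" in kept.columns:
        # a stratum is only informative with its used row and >=1 available row
        g = kept.groupby("stratum", observed=True)["used"]
        good = g.transform("any") & (g.transform("size") > g.transform("sum"))
        kept = kept[good]
    return kept.reset_index(drop=True), report


# ---------------------------------------------------------------------------
# standardization and screening
# ---------------------------------------------------------------------------

def standardize(rows: pd.DataFrame, cols: list[str] | None = None
                ) -> tuple[pd.DataFrame, dict[str, dict[str, float]]]:
    """Z-score continuous covariates over the full table (used + available).

    Uses the population standard deviation (ddof=0), so a two-point column
    {0, 2} maps to {-1, +1} and re-standardizing is an identity. Quadratic
    terms are built downstream from the standardized linear columns. Returns
    the table and a manifest {col: {mean, sd}} for prediction-time reuse.
    """
    if cols is None:
        cols = [c for c in CONTINUOUS_COVARIATES if c in rows.columns]
    out = rows.copy()
    manifest = {}
    for c in cols:
        v = out[c].to_numpy(dtype=float)
        m, s = float(v.mean()), float(v.std())
        if s == 0.0 or not np.isfinite(s):
            raise ValueError(f"covariate {c!r} has zero variance; cannot standardize")
        out[c] = (v - m) / s
        manifest[c] = {"mean": m, "sd": s}
    return out, manifest


def apply_standardization(rows: pd.DataFrame, manifest: dict) -> pd.DataFrame:
    """Apply a stored scaling manifest (training means/sds) to new rows."""
    out = rows.copy()
    for c, ms in manifest.items():
        if c in out.columns:
            out[c] = (out[c].to_numpy(dtype=float) - ms["mean"]) / ms["sd"]
    return out


def collinearity_screen(rows: pd.DataFrame, cols: list[str] | None = None,
                        threshold: float = 0.7) -> list[tuple[str, str, float]]:
    """Pearson |r| screen over continuous covariate pairs (strict > threshold).

    Flagged pairs are excluded from co-occurring in any candidate model; a
    pair at exactly the threshold is acceptable.
    """
    if cols is None:
        cols = [c for c in CONTINUOUS_COVARIATES if c in rows.columns]
    if len(rows) < 3:
        raise ValueError("need at least 3 rows to screen correlations")
    flagged = []
    arr = rows[cols].to_numpy(dtype=float)
    r = np.corrcoef(arr, rowvar=False)
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            if abs(r[i, j]) > threshold:
                flagged.append((cols[i], cols[j], float(r[i, j])))
    return flagged
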