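"""Synthetic caribou telemetry with known selection and movement truth.

``simulate_trajectories`` runs a step-selection process: at each 2-h fix it
proposes K candidate endpoints (gamma step lengths, uniform turning angles),
scores each by exp(beta' x) on generator-standardized endpoint covariates,
and picks one with probability proportional to its score. Insect activity
multiplies the step-length scale by exp(beta_move * index) during the
corresponding insect period, and a per-animal log-normal speed multiplier
plays the role of the movement model's random intercept.

``sample_rsf_points`` draws used locations directly from the landscape-scale
point process (cell probability proportional to exp(beta' x) within the
prediction area), giving an exact marginal-selection truth for calibrating
the use-availability estimator; the trajectory generator only realizes such
selection emergently.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import (FIX_INTERVAL_S, SEASON_START, PeriodCalendar, SimTruth,
                     week_of_day)
from .insects import mosquito_index, oestrid_index
from .landscape import ASPECT_LEVELS, ForageStack

#: covariate terms the generators can select on
GENERATOR_TERMS = (
    "biomass", "biomass2", "dn", "de", "elevation", "elevation2",
    "snowmelt", "snowmelt2",
    "aspect_east", "aspect_south", "aspect_west", "aspect_flat",
)


def generator_scaler(stack: ForageStack) -> dict[str, tuple[float, float]]:
    """Per-variable (mean, population sd) over prediction-area cell-weeks.

    The generator standardizes on the full true fields (masking is an
    observation effect); the manifest is recorded so fitted coefficients can
    be mapped back onto the generator's scale.
    """
    pa = stack.prediction_area
    out = {}
    for var in ("biomass", "dn", "de"):
        vals = getattr(stack, var)[:, pa]
        out[var] = (float(vals.mean()), float(vals.std()))
    for var, arr in (("elevation", stack.elevation), ("snowmelt", stack.snowmelt_date)):
        vals = arr[pa]
        out[var] = (float(vals.mean()), float(vals.std()))
    return out


def score_cube(stack: ForageStack, beta: dict[str, float],
               scaler: dict[str, tuple[float, float]] | None = None) -> np.ndarray:
    """(n_weeks, ny, nx) array of beta' x on standardized covariates."""
    if scaler is None:
        scaler = generator_scaler(stack)
    nw = stack.n_weeks
    ny, nx = stack.shape
    S = np.zeros((nw, ny, nx))

    def z(var, weekly):
        m, s = scaler[var]
        arr = getattr(stack, var if var != "snowmelt" else "snowmelt_date")
        zz = (arr - m) / s
        return zz if weekly else np.broadcast_to(zz, (nw, ny, nx))

    for term, b in beta.items():
        if b == 0:
            continue
        if term in ("biomass", "dn", "de"):
            S += b * z(term, True)
        elif term == "biomass2":
            S += b * z("biomass", True) ** 2
        elif term in ("elevation", "snowmelt"):
            S += b * z(term, False)
        elif term == "elevation2":
            S += b * z("elevation", False) ** 2
        elif term == "snowmelt2":
            S += b * z("snowmelt", False) ** 2
        elif term.startswith("aspect_"):
            level = ASPECT_LEVELS.index(term.removeprefix("aspect_"))
            S += b * (stack.aspect == level)
        else:
            raise KeyError(f"generator has no covariate for term {term!r}")
    return S


def simulate_trajectories(truth: SimTruth, stack: ForageStack, weather,
                          n_animal_years: int, fixes_per_animal: int,
                          seed: int, calendar: PeriodCalendar | None = None,
                          max_redraws: int = 50) -> pd.DataFrame:
    """Simulate 2-h telemetry tracks for ``n_animal_years`` animals.

    Returns a points table (animal_year_id, t, x, y, used=True) whose
    consecutive timestamps differ by exactly 7200 s. Raises ``RuntimeError``
    if no candidate endpoint can be placed inside the prediction area after
    ``max_redraws`` rounds of K proposals (a degenerate mask).
    """
    truth.validate()
    calendar = calendar or PeriodCalendar()
    rng = np.random.default_rng(seed)
    scaler = generator_scaler(stack)
    S = score_cube(stack, truth.beta_ssf, scaler)
    ny, nx = stack.shape
    ex, ey = stack.extent
    K = truth.n_candidates

    pa_cells = np.argwhere(stack.prediction_area)
    if len(pa_cells) == 0:
        raise RuntimeError("prediction area is empty")
    interior = pa_cells[
        (pa_cells[:, 0] > 1) & (pa_cells[:, 0] < ny - 2)
        & (pa_cells[:, 1] > 1) & (pa_cells[:, 1] < nx - 2)
    ]
    starts = interior if len(interior) else pa_cells

    b_mi = truth.beta_move.get("mi", 0.0)
    b_oi = truth.beta_move.get("oi", 0.0)
    move_re = (rng.normal(0.0, truth.move_re_sd, n_animal_years)
               if truth.move_re_sd > 0 else np.zeros(n_animal_years))

    records = []
    for a in range(n_animal_years):
        iy, ix = starts[rng.integers(len(starts))]
        x = (ix + rng.random()) * stack.cell_size
        y = (iy + rng.random()) * stack.cell_size
        xs = np.empty(fixes_per_animal)
        ys = np.empty(fixes_per_animal)
        xs[0], ys[0] = x, y
        for i in range(1, fixes_per_animal):
            day = (i * FIX_INTERVAL_S) // 86400 + 1
            hour = (i * FIX_INTERVAL_S) // 3600
            period = calendar.period_of_day(day)
            shape, scale = truth.kernel_for(period)
            mult = move_re[a]
            if period == "mosquito" and b_mi:
                t_c, w_c = weather.at(min(hour, weather.n_hours - 1), x, y)
                mult += b_mi * mosquito_index(t_c, w_c)
            elif period == "oestrid" and b_oi:
                t_c, w_c = weather.at(min(hour, weather.n_hours - 1), x, y)
                mult += b_oi * oestrid_index(t_c, w_c)
            scale_i = scale * np.exp(mult)
            week = week_of_day(day, stack.n_weeks)
            Sw = S[week - 1]
            for attempt in range(max_redraws + 1):
                lengths = rng.gamma(shape, scale_i, K)
                angles = rng.uniform(-np.pi, np.pi, K)
                cx = x + lengths * np.cos(angles)
                cy = y + lengths * np.sin(angles)
                cix = np.floor(cx / stack.cell_size).astype(int)
                ciy = np.floor(cy / stack.cell_size).astype(int)
                ok = (cx >= 0) & (cx < ex) & (cy >= 0) & (cy < ey)
                ok[ok] &= stack.prediction_area[ciy[ok], cix[ok]]
                if ok.any():
                    break
            else:
                raise RuntimeError(
                    f"could not place a candidate endpoint inside the prediction "
                    f"area after {max_redraws} redraws (animal {a}, fix {i})"
                )
            w = Sw[ciy[ok], cix[ok]]
            w = np.exp(w - w.max())
            j = rng.choice(np.flatnonzero(ok), p=w / w.sum())
            x, y = cx[j], cy[j]
            xs[i], ys[i] = x, y
        records.append(pd.DataFrame({
            "animal_year_id": f"ay{a:03d}",
            "t": pd.Timestamp(SEASON_START) + pd.to_timedelta(
                np.arange(fixes_per_animal) * FIX_INTERVAL_S, unit="s"),
            "x": xs, "y": ys,
        }))
    out = pd.concat(records, ignore_index=True)
    out["used"] = True
    return out


def sample_rsf_points(beta: dict[str, float], stack: ForageStack,
                      n_animal_years: int, n_per_animal: int, seed: int,
                      calendar: PeriodCalendar | None = None,
                      period: str | None = None,
                      intercept_sd: float = 0.0) -> pd.DataFrame:
    """Draw used locations from the landscape-scale selection process.

    Cell-weeks are drawn jointly with probability proportional to
    exp(beta' x) over all prediction-area cell-weeks of ``period`` (or the
    whole season); against the pooled uniform-availability design this is
    exactly the law the use-availability logistic model assumes, so the
    fitted coefficients estimate ``beta`` without per-week normalizer
    artifacts. Each point gets a uniform 2-h slot within a uniform day of
    its drawn week. ``intercept_sd`` perturbs per-animal sample sizes
    (Poisson thinning of ``n_per_animal``) to exercise the random-intercept
    machinery; it does not change the spatial law, which a per-animal
    additive intercept would not either.
    """
    calendar = calendar or PeriodCalendar()
    rng = np.random.default_rng(seed)
    scaler = generator_scaler(stack)
    S = score_cube(stack, beta, scaler)
    pa = stack.prediction_area
    cells = np.argwhere(pa)

    if period is None:
        lo, hi = 1, 92
    else:
        lo, hi = getattr(calendar, period)
    weeks_in = np.array(sorted({week_of_day(d, stack.n_weeks) for d in range(lo, hi + 1)}))
    days_by_week = {w: [d for d in range(lo, hi + 1)
                        if week_of_day(d, stack.n_weeks) == w] for w in weeks_in}
    flat = np.concatenate([S[w - 1][pa] for w in weeks_in])
    # weight weeks by their day counts so availability stays uniform in time
    day_w = np.concatenate([np.full(pa.sum(), len(days_by_week[w]))
                            for w in weeks_in])
    probs = np.exp(flat - flat.max()) * day_w
    probs /= probs.sum()
    n_cells = len(cells)

    frames = []
    for a in range(n_animal_years):
        n_a = n_per_animal
        if intercept_sd > 0:
            n_a = max(5, int(rng.poisson(n_per_animal * np.exp(
                rng.normal(-0.5 * intercept_sd ** 2, intercept_sd)))))
        pick = rng.choice(len(flat), size=n_a, p=probs)
        wk = weeks_in[pick // n_cells]
        cell = cells[pick % n_cells]
        days = np.array([days_by_week[w][rng.integers(len(days_by_week[w]))]
                         for w in wk])
        slots = rng.integers(0, 12, n_a)
        frames.append(pd.DataFrame({
            "animal_year_id": f"ay{a:03d}",
            "t": pd.Timestamp(SEASON_START)
            + pd.to_timedelta((days - 1) * 86400 + slots * FIX_INTERVAL_S, unit="s"),
            "x": (cell[:, 1] + rng.random(n_a)) * stack.cell_size,
            "y": (cell[:, 0] + rng.random(n_a)) * stack.cell_size,
        }))
    out = pd.concat(frames, ignore_index=True)
    out["used"] = True
    return out
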