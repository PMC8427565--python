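"""Run configuration, period calendar, and simulation ground truth.

Study days are 1-indexed with day 1 = 1 June; the season spans 1 June-31
August (days 1-92). All defaults encode the study conditions: a 250 m weekly
forage grid, 2-h telemetry, the five management periods, 10:1 availability
ratios, 5-fold / 10-bin / 10-repeat cross-validation, and the forage adequacy
thresholds of 1 g N/100 g DM (protein) and 9 kJ/g DM (energy).
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import hashlib
from dataclasses import dataclass, field

import yaml

SEASON_DAYS = 92
#: season origin (UTC); study day d corresponds to SEASON_START + (d-1) days
SEASON_START = _dt.datetime(2017, 6, 1, tzinfo=_dt.timezone.utc)
FIX_INTERVAL_S = 7200  # 2-h GPS fix rate

DN_ADEQUATE = 1.0  # g N / 100 g DM below which protein gain is impaired
DE_ADEQUATE = 9.0  # kJ / g DM below which energy gain is impaired


def day_of_study(ts) -> int:
    """1-indexed study day (day 1 = 1 June) of a UTC timestamp."""
    if hasattr(ts, "to_pydatetime"):
        ts = ts.to_pydatetime()
    if ts.tzinfo is None:
        ts = ts.replace(tzinfo=_dt.timezone.utc)
    return (ts.date() - SEASON_START.date()).days + 1


def week_of_day(day: int, n_weeks: int) -> int:
    """Map study day to the 1-indexed forage week, ceil(d/7), clamped to n_weeks.

    With 13 weekly layers day 92 falls past week 13 and is clamped onto the
    final layer.
    """
    return int(min(max(-(-day // 7), 1), n_weeks))


@dataclass(frozen=True)
class PeriodCalendar:
    """Named study-day intervals (inclusive) for the five summer periods.

    The gaps 16-28 July and 8-15 August belong to no period: days when the
    herd is transiting between habitat areas are excluded from all selection
    analyses. Calving locations are labeled but excluded from selection
    analyses (snow masking leaves too few attributable locations).
    """

    calving: tuple[int, int] = (1, 15)          # 1-15 Jun
    post_calving: tuple[int, int] = (16, 24)    # 16-24 Jun
    mosquito: tuple[int, int] = (25, 45)        # 25 Jun-15 Jul
    oestrid: tuple[int, int] = (59, 68)         # 29 Jul-7 Aug
    end_of_summer: tuple[int, int] = (77, 92)   # 16-31 Aug

    def intervals(self) -> dict[str, tuple[int, int]]:
        return {f.name: getattr(self, f.name) for f in dataclasses.fields(self)}

    def period_of_day(self, day: int) -> str | None:
        for name, (lo, hi) in self.intervals().items():
            if lo <= day <= hi:
                return name
        return None

    @property
    def early_summer(self) -> tuple[str, ...]:
        return ("calving", "post_calving", "mosquito")

    @property
    def late_summer(self) -> tuple[str, ...]:
        return ("oestrid", "end_of_summer")

    #: periods whose selection is analyzed (calving excluded)
    @property
    def analysis_periods(self) -> tuple[str, ...]:
        return ("post_calving", "mosquito", "oestrid", "end_of_summer")

    def insect_index_for(self, period: str) -> str | None:
        """Insect index attributed within its corresponding season."""
        return {"mosquito": "mi", "oestrid": "oi"}.get(period)

    def __post_init__(self):
        ivs = sorted(self.intervals().values())
        for (a0, a1), (b0, b1) in zip(ivs, ivs[1:]):
            if a1 >= b0:
                raise ValueError("calendar intervals must be disjoint")


DEFAULT_MISSINGNESS = (
    0.50, 0.42, 0.30, 0.15, 0.10, 0.06, 0.04, 0.04, 0.05, 0.08,
    0.12, 0.18, 0.24, 0.30,
)


@dataclass
class LandscapeConfig:
    """Geometry and seasonal-curve parameters of the synthetic forage grids.

    The seasonal curves emulate the observed trajectories: biomass rises to a
    peak near study day 65 (early August) and then declines; digestible
    nitrogen (DN) peaks very early and declines across the summer, crossing
    1 g/100 g DM near mid-July; digestible energy (DE) rises early then
    plateaus above 9 kJ/g DM. Phenology is delayed toward the coast edge.
    The missingness schedule emulates NDVI snow/cloud masking, heaviest in
    early June.
    """

    grid_nx: int = 40
    grid_ny: int = 40
    cell_size: float = 250.0   # m
    n_weeks: int = 14          # weekly layers over days 1-92
    coast_edge: str = "west"   # which grid edge borders the ocean
    ocean_width_cells: int = 3
    coast_delay_days: float = 9.0
    missingness_schedule: tuple[float, ...] = DEFAULT_MISSINGNESS
    smooth_sigma_cells: float = 3.0   # Gaussian bandwidth of spatial noise
    # biomass curve (g/m^2 DM): base + peak * asymmetric Gaussian around peak day
    biomass_base: float = 4.0
    biomass_peak: float = 55.0
    biomass_peak_day: float = 65.0
    biomass_rise_sd: float = 28.0
    biomass_fall_sd: float = 22.0
    biomass_noise_cv: float = 0.35
    # DN curve (g/100 g DM): early peak then exponential decline
    dn_peak: float = 2.6
    dn_peak_day: float = 5.0
    dn_decay: float = 0.024     # per day; crosses 1.0 near day 45 (mid-July)
    dn_noise_sd: float = 0.22
    # DE curve (kJ/g DM): rise to plateau
    de_start: float = 8.4
    de_plateau: float = 11.2
    de_rise_tau: float = 15.0   # days
    de_noise_sd: float = 0.35
    # static habitat
    elevation_max: float = 600.0
    elevation_noise: float = 60.0
    snowmelt_inland: float = 147.0   # ordinal day (27 May)
    snowmelt_coast: float = 157.0
    snowmelt_noise_sd: float = 4.5   # keeps |r(elevation, snowmelt)| below the 0.7 screen
    veg_hole_fraction: float = 0.15  # prediction-area gaps emulating unsampled vegetation
    seed: int = 0

    def validate(self) -> None:
        if self.grid_nx < 10 or self.grid_ny < 10:
            raise ValueError("grid must be at least 10 x 10 cells")
        if self.n_weeks < 13:
            raise ValueError("need at least 13 weekly layers to cover 92 days")
        if len(self.missingness_schedule) < self.n_weeks:
            raise ValueError("missingness schedule shorter than n_weeks")
        if any(not (0.0 <= f <= 1.0) for f in self.missingness_schedule):
            raise ValueError("missingness fractions must lie in [0, 1]")
        if self.coast_edge not in ("west", "east", "north", "south"):
            raise ValueError(f"unknown coast edge {self.coast_edge!r}")
        if self.biomass_base + self.biomass_peak <= 0 or self.dn_peak <= 0 or self.de_plateau <= 0:
            raise ValueError("seasonal curves would be non-positive everywhere")


@dataclass
class WeatherConfig:
    """Hourly coarse-grid weather over the simulated season.

    Temperature combines a seasonal cycle (warmest near mid-July), a diurnal
    cycle, and smooth noise; wind is truncated-normal around ``wind_mean``.
    Defaults give season-wide hourly temperatures spanning roughly -2 to
    26 deg C, so both insect indices traverse their full [0, 1] range.
    """

    coarse_nx: int = 3
    coarse_ny: int = 3
    extent_x: float = 10_000.0  # m; set from the landscape by the pipeline
    extent_y: float = 10_000.0
    n_days: int = SEASON_DAYS
    temp_base: float = 4.0       # deg C shoulder-season daily mean
    temp_seasonal_amp: float = 8.0
    temp_peak_day: float = 45.0
    temp_diurnal_amp: float = 5.0
    temp_noise_sd: float = 3.0
    coast_cooling: float = 3.0   # deg C cooler at the coast edge
    wind_mean: float = 4.0       # m/s
    wind_sd: float = 2.5
    heat_wave_week: int | None = None
    heat_wave_boost: float = 8.0

    def validate(self) -> None:
        if self.n_days < SEASON_DAYS:
            raise ValueError("weather must span the full season")
        if self.wind_mean < 0 or self.wind_sd < 0:
            raise ValueError("wind parameters must be non-negative")


#: default step-selection coefficients on generator-standardized covariates;
#: magnitudes follow the early-summer (mosquito-period) patch-scale estimates
DEFAULT_BETA_SSF = {
    "biomass": 0.48,
    "biomass2": -0.12,
    "dn": 0.42,
    "de": 0.16,
    "elevation": -0.49,
    "elevation2": 0.11,
}

#: default landscape-scale (point-process) coefficients; distinct magnitudes
#: so that rank order of |beta| is well defined
DEFAULT_BETA_RSF = {
    "biomass": 0.90,
    "biomass2": -0.60,
    "dn": 0.65,
    "de": 0.35,
    "elevation": -0.80,
    "elevation2": 0.20,
    "snowmelt": -0.40,
    "snowmelt2": 0.15,
    "aspect_east": 0.14,
    "aspect_south": -0.06,
    "aspect_west": -0.17,
    "aspect_flat": -0.40,
}


@dataclass
class SimTruth:
    """Ground-truth parameters of the telemetry generator.

    ``beta_ssf`` acts on generator-standardized endpoint covariates; the step
    kernel is gamma (shape, scale in metres) per period with an ``"all"``
    fallback for gap days; ``beta_move`` multiplies the kernel scale by
    exp(beta * index), so log step length responds linearly to the raw index.
    """

    beta_ssf: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_BETA_SSF))
    beta_rsf: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_BETA_RSF))
    step_kernel: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "all": (1.4, 380.0),
            "calving": (1.3, 300.0),
            "post_calving": (1.4, 420.0),
            "mosquito": (1.5, 520.0),
            "oestrid": (1.4, 430.0),
            "end_of_summer": (1.3, 330.0),
        }
    )
    beta_move: dict[str, float] = field(default_factory=lambda: {"mi": 0.92, "oi": 0.15})
    move_re_sd: float = 0.25   # sd of per-animal log speed multiplier
    n_candidates: int = 30     # proposals per step in the trajectory chooser
    seed: int = 0

    def validate(self) -> None:
        for period, (shape, scale) in self.step_kernel.items():
            if shape <= 0 or scale <= 0:
                raise ValueError(f"step kernel for {period!r} must be positive")
        if "all" not in self.step_kernel:
            raise ValueError("step kernel needs an 'all' fallback entry")

    def kernel_for(self, period: str | None) -> tuple[float, float]:
        if period is not None and period in self.step_kernel:
            return self.step_kernel[period]
        return self.step_kernel["all"]


@dataclass
class RunConfig:
    """End-to-end pipeline configuration; defaults are the study conditions."""

    seed: int = 0
    landscape: LandscapeConfig = field(default_factory=LandscapeConfig)
    weather: WeatherConfig = field(default_factory=WeatherConfig)
    truth: SimTruth = field(default_factory=SimTruth)
    calendar: PeriodCalendar = field(default_factory=PeriodCalendar)
    n_animal_years: int = 12
    fixes_per_animal: int = SEASON_DAYS * 12  # 2-h fixes over the season
    landscape_ratio: int = 10
    patch_ratio: int = 10
    cv_folds: int = 5
    cv_bins: int = 10
    cv_repeats: int = 10
    dn_adequate: float = DN_ADEQUATE
    de_adequate: float = DE_ADEQUATE
    collinearity_threshold: float = 0.7

    def validate(self) -> None:
        self.landscape.validate()
        self.weather.validate()
        self.truth.validate()
        if self.landscape_ratio < 0 or self.patch_ratio < 0:
            raise ValueError("availability ratios must be non-negative")

    def to_yaml(self) -> str:
        return yaml.safe_dump(_to_plain(self), sort_keys=True)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        raw = yaml.safe_load(text) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        kwargs = dict(raw)
        for key, sub in (
            ("landscape", LandscapeConfig),
            ("weather", WeatherConfig),
            ("truth", SimTruth),
            ("calendar", PeriodCalendar),
        ):
            if key in kwargs and isinstance(kwargs[key], dict):
                d = kwargs[key]
                if key == "truth" and "step_kernel" in d:
                    d["step_kernel"] = {k: tuple(v) for k, v in d["step_kernel"].items()}
                if key == "calendar":
                    d = {k: tuple(v) for k, v in d.items()}
                if key == "landscape" and "missingness_schedule" in d:
                    d["missingness_schedule"] = tuple(d["missingness_schedule"])
                kwargs[key] = sub(**d)
        return cls(**kwargs)


def _to_plain(obj):
    if dataclasses.is_dataclass(obj):
        return {f.name: _to_plain(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (tuple, list)):
        return [_to_plain(v) for v in obj]
    return obj
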