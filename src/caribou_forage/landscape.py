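"""Synthetic weekly forage grids with known seasonal and spatial structure.

The generator is a stand-in for the NDVI-driven forage prediction surfaces
the analysis consumes: weekly 250 m layers of forage biomass (g/m^2 DM),
digestible nitrogen (DN, g/100 g DM) and digestible energy (DE, kJ/g DM),
plus static elevation, aspect, snowmelt-date and prediction-area grids.
Spatial texture is smoothed Gaussian noise on top of deterministic
coast/elevation gradients; the coast edge delays phenology, and a per-week
validity mask reproduces a configured snow/cloud missingness schedule.

Grid registration is cell-center with half-open cell intervals: a point on a
shared edge belongs to the cell with the larger index.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter
from shapely.geometry import box

from .config import LandscapeConfig

ASPECT_LEVELS = ("north", "east", "south", "west", "flat")


@dataclass
class ForageStack:
    """Weekly forage layers plus static habitat grids.

    Forage arrays have shape (n_weeks, ny, nx); static grids (ny, nx).
    ``valid_mask`` marks cell-weeks with usable forage predictions; the
    underlying forage values are retained everywhere (masking is an
    observation effect, not a gap in the generative truth), but attribution
    never reads a masked cell. ``prediction_area`` excludes ocean cells and
    unsampled-vegetation holes.
    """

    biomass: np.ndarray
    dn: np.ndarray
    de: np.ndarray
    valid_mask: np.ndarray
    elevation: np.ndarray
    aspect: np.ndarray          # int codes into ASPECT_LEVELS
    snowmelt_date: np.ndarray
    prediction_area: np.ndarray
    ocean: np.ndarray
    cell_size: float
    config: LandscapeConfig | None = field(default=None, repr=False)

    @property
    def n_weeks(self) -> int:
        return self.biomass.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.elevation.shape

    @property
    def extent(self) -> tuple[float, float]:
        ny, nx = self.shape
        return nx * self.cell_size, ny * self.cell_size

    def cell_of(self, x, y):
        """(iy, ix) cell indices of planar coordinates; raises off-grid."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        ix = np.floor(x / self.cell_size).astype(int)
        iy = np.floor(y / self.cell_size).astype(int)
        ny, nx = self.shape
        bad = (ix < 0) | (ix >= nx) | (iy < 0) | (iy >= ny)
        if np.any(bad):
            raise ValueError(f"{int(np.sum(bad))} point(s) fall outside the grid extent")
        return iy, ix

    def cell_center(self, iy, ix):
        return (np.asarray(ix) + 0.5) * self.cell_size, (np.asarray(iy) + 0.5) * self.cell_size

    def ocean_polygon(self):
        """Shapely (multi)polygon of the ocean cells."""
        polys = [
            box(ix * self.cell_size, iy * self.cell_size,
                (ix + 1) * self.cell_size, (iy + 1) * self.cell_size)
            for iy, ix in zip(*np.nonzero(self.ocean))
        ]
        from shapely.ops import unary_union

        return unary_union(polys) if polys else box(0, 0, 0, 0)

    def spatial_mean(self, var: str, week: int) -> float:
        """Mean of a forage layer over valid prediction cells for one week."""
        arr = getattr(self, var)[week - 1]
        ok = self.valid_mask[week - 1] & self.prediction_area
        return float(arr[ok].mean())

    def save_npz(self, path) -> None:
        np.savez_compressed(
            path,
            biomass=self.biomass, dn=self.dn, de=self.de,
            valid_mask=self.valid_mask, elevation=self.elevation,
            aspect=self.aspect, snowmelt_date=self.snowmelt_date,
            prediction_area=self.prediction_area, ocean=self.ocean,
            cell_size=np.array(self.cell_size),
        )

    @classmethod
    def load_npz(cls, path) -> "ForageStack":
        z = np.load(path)
        return cls(
            biomass=z["biomass"], dn=z["dn"], de=z["de"],
            valid_mask=z["valid_mask"].astype(bool), elevation=z["elevation"],
            aspect=z["aspect"], snowmelt_date=z["snowmelt_date"],
            prediction_area=z["prediction_area"].astype(bool),
            ocean=z["ocean"].astype(bool), cell_size=float(z["cell_size"]),
        )


def _coast_distance_fraction(cfg: LandscapeConfig) -> np.ndarray:
    """0 at the coast edge rising to 1 at the opposite edge, shape (ny, nx)."""
    ny, nx = cfg.grid_ny, cfg.grid_nx
    xs = (np.arange(nx) + 0.5) / nx
    ys = (np.arange(ny) + 0.5) / ny
    if cfg.coast_edge == "west":
        d = np.tile(xs, (ny, 1))
    elif cfg.coast_edge == "east":
        d = np.tile(1 - xs, (ny, 1))
    elif cfg.coast_edge == "south":
        d = np.tile(ys[:, None], (1, nx))
    else:  # north
        d = np.tile(1 - ys[:, None], (1, nx))
    return d


def _smooth_noise(rng: np.random.Generator, shape, sigma: float) -> np.ndarray:
    """Unit-variance smoothed Gaussian field."""
    z = gaussian_filter(rng.standard_normal(shape), sigma, mode="reflect")
    sd = z.std()
    return z / sd if sd > 0 else z


def biomass_curve(day, cfg: LandscapeConfig):
    """Seasonal mean biomass: asymmetric Gaussian peaking near early August."""
    day = np.asarray(day, dtype=float)
    sd = np.where(day <= cfg.biomass_peak_day, cfg.biomass_rise_sd, cfg.biomass_fall_sd)
    return cfg.biomass_base + cfg.biomass_peak * np.exp(
        -0.5 * ((day - cfg.biomass_peak_day) / sd) ** 2
    )


def dn_curve(day, cfg: LandscapeConfig):
    """Seasonal mean DN: brief early rise then exponential decline.

    With defaults the curve crosses 1 g/100 g DM near study day 45 (mid-July).
    """
    day = np.asarray(day, dtype=float)
    rising = cfg.dn_peak * (0.92 + 0.08 * np.clip(day / cfg.dn_peak_day, 0, 1))
    falling = cfg.dn_peak * np.exp(-cfg.dn_decay * (day - cfg.dn_peak_day))
    return np.where(day <= cfg.dn_peak_day, rising, falling)


def de_curve(day, cfg: LandscapeConfig):
    """Seasonal mean DE: saturating rise to a plateau above 9 kJ/g DM."""
    day = np.asarray(day, dtype=float)
    return cfg.de_plateau - (cfg.de_plateau - cfg.de_start) * np.exp(
        -np.clip(day, 0, None) / cfg.de_rise_tau
    )


def generate_landscape(config: LandscapeConfig) -> ForageStack:
    """Generate the full synthetic forage stack for one summer.

    Weekly layers are the seasonal curves evaluated at each cell's
    phenology-delayed mid-week day, times/plus smoothed spatial noise, with
    any negative draw clamped to zero. The masked-cell count per week equals
    ``round(fraction * n_cells)`` exactly (spatially clustered blobs chosen
    by thresholding a smooth field at the matching quantile).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    ny, nx = config.grid_ny, config.grid_nx
    n_cells = ny * nx

    dist = _coast_distance_fraction(config)
    delay = config.coast_delay_days * (1.0 - dist)  # coast cells lag inland ones

    # static habitat: broad coastal-plain ramp + smooth hills + local relief
    # (the short-wavelength relief is what gives a 250 m DEM its mix of
    # aspect classes; without it every slope faces the coast)
    elevation = np.clip(
        config.elevation_max * dist ** 1.3
        + config.elevation_noise * _smooth_noise(rng, (ny, nx), config.smooth_sigma_cells)
        + 0.6 * config.elevation_noise * _smooth_noise(rng, (ny, nx), 1.2),
        0.0, None,
    )
    gy, gx = np.gradient(elevation)
    slope = np.hypot(gx, gy)
    bearing = np.arctan2(-gx, -gy)  # downslope direction, 0 = north
    aspect = np.full((ny, nx), ASPECT_LEVELS.index("flat"), dtype=np.int8)
    steep = slope > np.quantile(slope, 0.25)
    sector = ((bearing + np.pi / 4) % (2 * np.pi)) // (np.pi / 2)
    for code, name in enumerate(("north", "east", "south", "west")):
        aspect[steep & (sector == code)] = ASPECT_LEVELS.index(name)

    snowmelt = (
        config.snowmelt_inland
        + (config.snowmelt_coast - config.snowmelt_inland) * (1.0 - dist)
        + config.snowmelt_noise_sd * _smooth_noise(rng, (ny, nx), config.smooth_sigma_cells)
    )

    # ocean strip and prediction area --------------------------------------
    ocean = dist < (config.ocean_width_cells / max(nx, ny))
    holes = np.zeros((ny, nx), dtype=bool)
    if config.veg_hole_fraction > 0:
        f = _smooth_noise(rng, (ny, nx), config.smooth_sigma_cells)
        land = ~ocean
        k = int(round(config.veg_hole_fraction * land.sum()))
        if k > 0:
            cand = np.where(land.ravel())[0]
            order = np.argsort(f.ravel()[cand])
            holes.ravel()[cand[order[:k]]] = True
    prediction_area = (~ocean) & (~holes)

    # persistent spatial texture per forage variable ------------------------
    tex_bm = _smooth_noise(rng, (ny, nx), config.smooth_sigma_cells)
    tex_dn = _smooth_noise(rng, (ny, nx), config.smooth_sigma_cells)
    tex_de = _smooth_noise(rng, (ny, nx), config.smooth_sigma_cells)

    shp = (config.n_weeks, ny, nx)
    biomass = np.empty(shp)
    dn = np.empty(shp)
    de = np.empty(shp)
    valid = np.ones(shp, dtype=bool)
    for w in range(config.n_weeks):
        mid_day = min(7 * w + 4, 92)  # mid-week study day
        eff = mid_day - delay
        wk_bm = _smooth_noise(rng, (ny, nx), config.smooth_sigma_cells)
        wk_dn = _smooth_noise(rng, (ny, nx), config.smooth_sigma_cells)
        wk_de = _smooth_noise(rng, (ny, nx), config.smooth_sigma_cells)
        biomass[w] = biomass_curve(eff, config) * np.exp(
            config.biomass_noise_cv * (0.8 * tex_bm + 0.6 * wk_bm)
            - 0.5 * config.biomass_noise_cv ** 2
        )
        dn[w] = dn_curve(eff, config) + config.dn_noise_sd * (0.8 * tex_dn + 0.6 * wk_dn)
        de[w] = de_curve(eff, config) + config.de_noise_sd * (0.8 * tex_de + 0.6 * wk_de)

        frac = config.missingness_schedule[w]
        k = int(round(frac * n_cells))
        if k > 0:
            cloud = _smooth_noise(rng, (ny, nx), config.smooth_sigma_cells)
            cloud += 0.8 * (1.0 - dist)  # snow/cloud heaviest toward the coast
            order = np.argsort(-cloud.ravel())
            m = np.zeros(n_cells, dtype=bool)
            m[order[:k]] = True
            valid[w] = ~m.reshape(ny, nx)

    # clamping rule: negative predicted forage is assigned 0
    np.clip(biomass, 0.0, None, out=biomass)
    np.clip(dn, 0.0, None, out=dn)
    np.clip(de, 0.0, None, out=de)

    return ForageStack(
        biomass=biomass, dn=dn, de=de, valid_mask=valid,
        elevation=elevation, aspect=aspect, snowmelt_date=snowmelt,
        prediction_area=prediction_area, ocean=ocean,
        cell_size=config.cell_size, config=config,
    )
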