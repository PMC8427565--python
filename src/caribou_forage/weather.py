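"""Hourly coarse-grid temperature and wind fields for one summer season."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import WeatherConfig


@dataclass
class WeatherField:
    """Hourly temperature (deg C) and wind speed (m/s) on a coarse grid.

    Arrays have shape (n_hours, coarse_ny, coarse_nx); hour 0 is 00:00 UTC
    on 1 June. The coarse grid shares the landscape's planar extent, so a
    point's coarse cell is a simple floor division.
    """

    temperature: np.ndarray
    wind: np.ndarray
    extent_x: float
    extent_y: float

    @property
    def n_hours(self) -> int:
        return self.temperature.shape[0]

    @property
    def coarse_shape(self) -> tuple[int, int]:
        return self.temperature.shape[1:]

    def cell_of(self, x, y):
        ny, nx = self.coarse_shape
        ix = np.clip(np.floor(np.asarray(x) / (self.extent_x / nx)).astype(int), 0, nx - 1)
        iy = np.clip(np.floor(np.asarray(y) / (self.extent_y / ny)).astype(int), 0, ny - 1)
        return iy, ix

    def at(self, hour, x, y):
        """(temperature, wind) at the containing hour and nearest coarse cell."""
        hour = np.asarray(hour, dtype=int)
        bad = (hour < 0) | (hour >= self.n_hours)
        if np.any(bad):
            raise ValueError(f"{int(np.sum(bad))} lookup(s) outside the weather time axis")
        iy, ix = self.cell_of(x, y)
        return self.temperature[hour, iy, ix], self.wind[hour, iy, ix]

    def save_npz(self, path) -> None:
        np.savez_compressed(
            path, temperature=self.temperature, wind=self.wind,
            extent=np.array([self.extent_x, self.extent_y]),
        )

    @classmethod
    def load_npz(cls, path) -> "WeatherField":
        z = np.load(path)
        return cls(temperature=z["temperature"], wind=z["wind"],
                   extent_x=float(z["extent"][0]), extent_y=float(z["extent"][1]))


def generate_weather(config: WeatherConfig, seed: int) -> WeatherField:
    """Simulate the season's hourly weather, reproducibly under ``seed``.

    Temperature = seasonal cycle + diurnal cycle + temporally smoothed noise,
    cooler toward the west (coast) column of the coarse grid; wind is normal
    noise around the configured mean truncated at zero. A configured
    heat-wave week adds a constant boost to that week's temperatures.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    ny, nx = config.coarse_ny, config.coarse_nx
    hours = np.arange(config.n_days * 24)
    day = hours / 24.0 + 1.0
    seasonal = config.temp_base + config.temp_seasonal_amp * np.exp(
        -0.5 * ((day - config.temp_peak_day) / 30.0) ** 2
    )
    diurnal = config.temp_diurnal_amp * np.sin(2 * np.pi * (hours % 24 - 8) / 24.0)

    def smooth_series(sd):
        z = rng.standard_normal((len(hours) + 48, ny, nx))
        kernel = np.exp(-0.5 * (np.arange(-24, 25) / 8.0) ** 2)
        kernel /= kernel.sum()
        out = np.apply_along_axis(lambda s: np.convolve(s, kernel, mode="same"), 0, z)
        return sd * out[24:-24] / out[24:-24].std()

    cooling = config.coast_cooling * (1.0 - (np.arange(nx) + 0.5) / nx)  # west coldest
    temp = (
        seasonal[:, None, None]
        + diurnal[:, None, None]
        + smooth_series(config.temp_noise_sd)
        - cooling[None, None, :]
    )
    if config.heat_wave_week is not None:
        w = config.heat_wave_week
        sel = (day >= 7 * (w - 1) + 1) & (day < 7 * w + 1)
        temp[sel] += config.heat_wave_boost

    wind = np.clip(config.wind_mean + smooth_series(config.wind_sd), 0.0, None)

    return WeatherField(temperature=temp, wind=wind,
                        extent_x=config.extent_x, extent_y=config.extent_y)
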