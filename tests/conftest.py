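"""Shared fixtures: small seeded synthetic worlds reused across test modules."""

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import box

from caribou_forage import (LandscapeConfig, PeriodCalendar, WeatherConfig,
                            assign_periods, attribute_covariates,
                            generate_landscape, generate_weather,
                            sample_available_landscape, standardize)
from caribou_forage.trajectories import sample_rsf_points


@pytest.fixture(scope="session")
def calendar():
    return PeriodCalendar()


@pytest.fixture(scope="session")
def stack():
    """30x30 stack with the default missingness schedule."""
    return generate_landscape(LandscapeConfig(grid_nx=30, grid_ny=30, seed=42))


@pytest.fixture(scope="session")
def clean_stack():
    """30x30 stack with no masked cells (for sampling/recovery checks)."""
    cfg = LandscapeConfig(grid_nx=30, grid_ny=30, seed=42,
                          missingness_schedule=(0.0,) * 14)
    return generate_landscape(cfg)


@pytest.fixture(scope="session")
def weather(clean_stack):
    ex, ey = clean_stack.extent
    return generate_weather(WeatherConfig(extent_x=ex, extent_y=ey), 42)


def make_rsf_table(stack, beta, n_animals, n_per, seed, calendar,
                   period="mosquito", intercept_sd=0.3, ratio=10):
    """Used points from the landscape point process + matched availability,
    attributed and returned raw (unstandardized) with a response column."""
    used = sample_rsf_points(beta, stack, n_animals, n_per, seed,
                             calendar=calendar, period=period,
                             intercept_sd=intercept_sd)
    used = assign_periods(used, calendar)
    avail = sample_available_landscape(used, box(0, 0, *stack.extent), stack,
                                       ratio, seed + 1)
    rows, _ = attribute_covariates(
        pd.concat([used.assign(used=True), avail], ignore_index=True),
        stack, calendar)
    rows["response"] = rows["used"].astype(int)
    return rows


def standardized(rows, cols=None):
    out, manifest = standardize(rows, cols)
    out.attrs["manifest"] = manifest
    return out, manifest
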