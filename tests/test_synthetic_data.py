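"""Synthetic landscape, weather, and telemetry generators."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from caribou_forage import (LandscapeConfig, SimTruth, WeatherConfig,
                            generate_landscape, generate_weather,
                            simulate_trajectories)
from caribou_forage.landscape import ASPECT_LEVELS, biomass_curve, dn_curve
from caribou_forage.trajectories import generator_scaler


class TestLandscape:
    def test_seed_determinism(self):
        cfg = LandscapeConfig(grid_nx=12, grid_ny=12, seed=9)
        a, b = generate_landscape(cfg), generate_landscape(cfg)
        for f in ("biomass", "dn", "de", "valid_mask", "elevation",
                  "aspect", "snowmelt_date", "prediction_area"):
            np.testing.assert_array_equal(getattr(a, f), getattr(b, f))

    def test_forage_clamped_nonnegative(self, stack):
        assert stack.biomass.min() >= 0
        assert stack.dn.min() >= 0
        assert stack.de.min() >= 0

    def test_dn_declines_across_summer(self, stack):
        assert stack.spatial_mean("dn", 1) > stack.spatial_mean("dn", 13)

    def test_seasonal_shape_windows(self, stack):
        """Biomass peaks in late season; DN crosses 1 g/100 g DM mid-season."""
        bm = [stack.spatial_mean("biomass", w) for w in range(1, stack.n_weeks + 1)]
        assert 8 <= int(np.argmax(bm)) + 1 <= 11  # around study day 65
        dn = [stack.spatial_mean("dn", w) for w in range(1, stack.n_weeks + 1)]
        first_below = next(w for w, v in enumerate(dn, start=1) if v < 1.0)
        assert 6 <= first_below <= 8  # mid-July
        de = [stack.spatial_mean("de", w) for w in range(2, stack.n_weeks + 1)]
        assert min(de) > 9.0

    def test_coast_delays_phenology(self, stack):
        # mid-decline DN stays higher near the (west) coast: the coastal
        # phenology lag delays the nitrogen drop
        mid = stack.dn[4:7]  # weeks 5-7
        assert mid[:, :, 3:11].mean() > mid[:, :, 20:].mean()

    def test_missingness_matches_schedule_exactly(self):
        sched = (0.5, 0.3, 0.0, 0.25) + (0.1,) * 10
        cfg = LandscapeConfig(grid_nx=20, grid_ny=20, seed=3,
                              missingness_schedule=sched)
        st = generate_landscape(cfg)
        n = 400
        for w, frac in enumerate(st.config.missingness_schedule[:st.n_weeks]):
            masked = int((~st.valid_mask[w]).sum())
            assert abs(masked - round(frac * n)) <= 1

    def test_no_masking_configured(self, clean_stack):
        assert clean_stack.valid_mask.all()

    def test_aspect_has_five_levels(self, stack):
        assert len(ASPECT_LEVELS) == 5
        assert set(np.unique(stack.aspect)) <= set(range(5))

    @pytest.mark.parametrize("bad", [
        dict(grid_nx=5), dict(n_weeks=10),
        dict(missingness_schedule=(1.2,) * 14),
        dict(biomass_base=-10.0, biomass_peak=0.0),
    ])
    def test_invalid_configs_rejected(self, bad):
        with pytest.raises(ValueError):
            generate_landscape(LandscapeConfig(**bad))

    def test_curve_helpers_cross_where_configured(self):
        cfg = LandscapeConfig()
        days = np.arange(1, 93)
        bm = biomass_curve(days, cfg)
        assert abs(days[np.argmax(bm)] - cfg.biomass_peak_day) <= 1
        dn = dn_curve(days, cfg)
        assert 40 <= days[np.argmax(dn < 1.0)] <= 50

    def test_npz_roundtrip(self, stack, tmp_path):
        stack.save_npz(tmp_path / "s.npz")
        back = type(stack).load_npz(tmp_path / "s.npz")
        np.testing.assert_array_equal(back.biomass, stack.biomass)
        np.testing.assert_array_equal(back.prediction_area, stack.prediction_area)


class TestWeather:
    def test_seed_determinism(self):
        cfg = WeatherConfig(extent_x=5000, extent_y=5000)
        a, b = generate_weather(cfg, 5), generate_weather(cfg, 5)
        np.testing.assert_array_equal(a.temperature, b.temperature)
        np.testing.assert_array_equal(a.wind, b.wind)

    def test_season_spans_index_range(self, weather):
        assert weather.temperature.min() <= 0.0
        assert weather.temperature.max() >= 18.0  # reaches the MI=1 endpoint
        assert weather.wind.min() >= 0.0

    def test_heat_wave_week(self):
        cfg = WeatherConfig(extent_x=5000, extent_y=5000, heat_wave_week=3,
                            heat_wave_boost=10.0)
        wf = generate_weather(cfg, 1)
        hours = np.arange(wf.n_hours)
        wk3 = (hours // 24 >= 14) & (hours // 24 < 21)
        # boosted week's maximum clears the configured base + amplitudes
        assert wf.temperature[wk3].max() >= 18.0
        assert wf.temperature[wk3].mean() > wf.temperature[~wk3].mean()

    def test_zero_variance_constant_field(self):
        cfg = WeatherConfig(extent_x=1000, extent_y=1000, temp_base=7.5,
                            temp_seasonal_amp=0, temp_diurnal_amp=0,
                            temp_noise_sd=0, coast_cooling=0,
                            wind_mean=3.0, wind_sd=0)
        wf = generate_weather(cfg, 0)
        assert np.allclose(wf.temperature, 7.5)
        assert np.allclose(wf.wind, 3.0)


class TestTrajectories:
    def test_fix_spacing_exactly_two_hours(self, clean_stack, weather):
        pts = simulate_trajectories(SimTruth(), clean_stack, weather,
                                    n_animal_years=2, fixes_per_animal=50, seed=1)
        dt = pts.groupby("animal_year_id")["t"].diff().dropna().dt.total_seconds()
        assert set(dt.unique()) == {7200.0}

    def test_seed_determinism(self, clean_stack, weather):
        a = simulate_trajectories(SimTruth(), clean_stack, weather, 2, 30, seed=4)
        b = simulate_trajectories(SimTruth(), clean_stack, weather, 2, 30, seed=4)
        pd.testing.assert_frame_equal(a, b)

    def test_endpoints_stay_in_prediction_area(self, clean_stack, weather):
        pts = simulate_trajectories(SimTruth(), clean_stack, weather, 3, 120, seed=2)
        iy, ix = clean_stack.cell_of(pts["x"], pts["y"])
        assert clean_stack.prediction_area[iy, ix].all()

    def test_null_selection_matches_available_length_law(self, clean_stack,
                                                         weather):
        """With beta = 0 the chooser picks uniformly among valid candidates,
        so used step lengths follow exactly the law of mask-rejected kernel
        draws (what the available-step sampler produces); near boundaries
        both are tilted short of the raw kernel in the same way."""
        from caribou_forage import build_steps, sample_available_steps

        kern = (2.0, 250.0)
        truth = SimTruth(beta_ssf={}, step_kernel={"all": kern},
                         beta_move={}, move_re_sd=0.0)
        pts = simulate_trajectories(truth, clean_stack, weather, 8, 300, seed=6)
        steps = build_steps(pts, clean_stack)
        steps["period"] = "all"
        strata = sample_available_steps(steps, kern, clean_stack, ratio=10,
                                        seed=7)
        used = strata.loc[strata["used"], "length"].to_numpy()
        avail = strata.loc[~strata["used"], "length"].to_numpy()
        assert abs(np.median(used) - np.median(avail)) / np.median(avail) < 0.05
        assert abs(used.mean() - avail.mean()) / avail.mean() < 0.05
        # and the raw kernel mean is still the right scale (boundary tilt
        # shortens both laws by the same modest amount)
        assert abs(used.mean() - 2.0 * 250.0) / 500.0 < 0.15

    def test_positive_dn_selection_shifts_used_dn(self, clean_stack, weather):
        truth = SimTruth(beta_ssf={"dn": 2.0}, beta_move={}, move_re_sd=0.0)
        pts = simulate_trajectories(truth, clean_stack, weather, 10, 500, seed=7)
        null = SimTruth(beta_ssf={}, beta_move={}, move_re_sd=0.0)
        ref = simulate_trajectories(null, clean_stack, weather, 10, 500, seed=7)

        def mean_dn(df):
            iy, ix = clean_stack.cell_of(df["x"], df["y"])
            wk = np.minimum((pd.to_datetime(df["t"]).dt.dayofyear - 152) // 7, 13)
            return clean_stack.dn[wk, iy, ix].mean()

        assert mean_dn(pts) > mean_dn(ref) + 0.05

    def test_degenerate_mask_raises(self, weather):
        cfg = LandscapeConfig(grid_nx=12, grid_ny=12, seed=1,
                              veg_hole_fraction=0.0,
                              missingness_schedule=(0.0,) * 14)
        st = generate_landscape(cfg)
        st.prediction_area[:, :] = False
        st.prediction_area[6, 6] = True  # single island far smaller than steps
        truth = SimTruth(beta_ssf={}, step_kernel={"all": (20.0, 5000.0)},
                         beta_move={})
        with pytest.raises(RuntimeError):
            simulate_trajectories(truth, st, weather, 1, 30, seed=0,
                                  max_redraws=3)

    def test_generator_scaler_covers_covariates(self, clean_stack):
        sc = generator_scaler(clean_stack)
        assert set(sc) == {"biomass", "dn", "de", "elevation", "snowmelt"}
        assert all(s > 0 for _, s in sc.values())

    def test_null_selection_calibration(self, calendar):
        """With beta = 0, downstream step-selection fits see no selection:
        95% intervals cover 0 for >= 90% of covariates over 20 replicates.

        Each replicate walks its own default-size landscape; on grids much
        smaller than the spatial correlation range, cell reuse across
        animals correlates strata and the animal-clustered sandwich
        undercovers, so the calibration runs at the default 40x40 extent.
        """
        from caribou_forage import (ModelSpec, WeatherConfig,
                                    attribute_covariates, build_steps,
                                    fit_ssf_clogit, fit_step_kernel,
                                    generate_weather, sample_available_steps,
                                    standardize)

        truth = SimTruth(beta_ssf={}, beta_move={}, move_re_sd=0.0)
        spec = ModelSpec(scale="patch", period="all",
                         forage=("biomass", "biomass2", "dn", "de"))
        weather = generate_weather(
            WeatherConfig(extent_x=10_000, extent_y=10_000), 42)
        covered = total = 0
        for rep in range(20):
            stack = generate_landscape(LandscapeConfig(
                seed=800 + rep, missingness_schedule=(0.0,) * 14))
            pts = simulate_trajectories(truth, stack, weather, 12, 250,
                                        seed=900 + rep)
            steps = build_steps(pts, stack)
            steps["period"] = "all"
            kern = fit_step_kernel(steps)
            strata = sample_available_steps(steps, kern, stack, 10,
                                            seed=950 + rep)
            rows, _ = attribute_covariates(strata, stack, calendar)
            rows["response"] = rows["used"].astype(int)
            std, _ = standardize(rows)
            fit = fit_ssf_clogit(std, spec)
            ci = fit.ci(robust=True)
            for term in ("biomass", "biomass2", "dn", "de"):
                covered += ci.loc[term, "l95"] <= 0 <= ci.loc[term, "u95"]
                total += 1
        assert covered / total >= 0.9
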