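"""Sampling design: periods, MCP, availability, steps, kernels, screening."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from shapely.geometry import box

from caribou_forage import (PeriodCalendar, assign_periods,
                            attribute_covariates, build_steps,
                            collinearity_screen, fit_step_kernel,
                            mcp_available_area, sample_available_landscape,
                            sample_available_steps, standardize)
from caribou_forage.design import apply_standardization


def _pts(times, xy=None):
    n = len(times)
    xy = xy or [(100.0 * i, 50.0 * i) for i in range(n)]
    return pd.DataFrame({
        "animal_year_id": "a1",
        "t": pd.to_datetime(times, utc=True),
        "x": [p[0] for p in xy], "y": [p[1] for p in xy],
        "used": True,
    })


class TestPeriods:
    @pytest.mark.parametrize("ts,expected", [
        ("2017-06-05 10:00", "calving"),
        ("2017-06-20 10:00", "post_calving"),
        ("2017-06-25 00:00", "mosquito"),
        ("2017-07-15 23:59", "mosquito"),
        ("2017-07-29 00:00", "oestrid"),
        ("2017-08-31 23:59", "end_of_summer"),
    ])
    def test_labels(self, calendar, ts, expected):
        out = assign_periods(_pts([ts]), calendar)
        assert list(out["period"]) == [expected]

    @pytest.mark.parametrize("ts", ["2017-07-20 12:00", "2017-08-10 12:00"])
    def test_gap_days_dropped(self, calendar, ts):
        assert len(assign_periods(_pts([ts]), calendar)) == 0

    def test_calving_flagged_excluded(self, calendar):
        out = assign_periods(_pts(["2017-06-05", "2017-06-20"]), calendar)
        assert list(out["analysis_excluded"]) == [True, False]

    def test_intervals_disjoint_with_gaps(self, calendar):
        covered = sorted(d for lo, hi in calendar.intervals().values()
                         for d in range(lo, hi + 1))
        assert len(covered) == len(set(covered))
        gaps = set(range(1, 93)) - set(covered)
        assert gaps == set(range(46, 59)) | set(range(69, 77))


class TestWeekLookup:
    @pytest.mark.parametrize("day,week", [
        (1, 1), (7, 1), (8, 2), (45, 7), (91, 13), (92, 14),
    ])
    def test_ceil_mapping(self, day, week):
        from caribou_forage import week_of_day
        assert week_of_day(day, 14) == week

    def test_clamped_to_available_layers(self):
        from caribou_forage import week_of_day
        assert week_of_day(92, 13) == 13  # day 92 folds onto the last layer


class TestMCP:
    def test_unit_square_area(self):
        pts = _pts(["2017-06-10"] * 4, [(0, 0), (1, 0), (1, 1), (0, 1)])
        assert mcp_available_area(pts).area == pytest.approx(1.0)

    def test_ocean_removed(self):
        pts = _pts(["2017-06-10"] * 4, [(0, 0), (1, 0), (1, 1), (0, 1)])
        ocean = box(0, 0.5, 1, 1)
        assert mcp_available_area(pts, ocean).area == pytest.approx(0.5)

    def test_interior_point_does_not_change_hull(self):
        sq = [(0, 0), (1, 0), (1, 1), (0, 1)]
        a = mcp_available_area(_pts(["2017-06-10"] * 4, sq))
        b = mcp_available_area(_pts(["2017-06-10"] * 5, sq + [(0.5, 0.5)]))
        assert a.equals(b)

    def test_collinear_rejected(self):
        pts = _pts(["2017-06-10"] * 3, [(0, 0), (1, 1), (2, 2)])
        with pytest.raises(ValueError, match="collinear"):
            mcp_available_area(pts)


class TestLandscapeSampling:
    def test_ten_to_one_with_matched_timestamps(self, clean_stack, calendar):
        used = _pts([f"2017-07-0{d} 06:00" for d in range(1, 6)] * 20,
                    [(3000.0 + 17 * i, 3000.0 + 13 * i) for i in range(100)])
        used = assign_periods(used, calendar)
        area = box(0, 0, *clean_stack.extent)
        av = sample_available_landscape(used, area, clean_stack, 10, seed=1)
        assert len(av) == 1000
        assert not av["used"].any()
        counts = pd.concat([used, av])["t"].value_counts()
        assert set(counts) == {11 * 20}

    def test_ratio_zero_empty(self, clean_stack, calendar):
        used = assign_periods(_pts(["2017-07-01"]), calendar)
        av = sample_available_landscape(used, box(0, 0, *clean_stack.extent),
                                        clean_stack, 0, seed=1)
        assert len(av) == 0

    def test_seeded_reproducibility(self, clean_stack, calendar):
        used = assign_periods(_pts(["2017-07-01"] * 10), calendar)
        area = box(0, 0, *clean_stack.extent)
        a = sample_available_landscape(used, area, clean_stack, 10, seed=3)
        b = sample_available_landscape(used, area, clean_stack, 10, seed=3)
        pd.testing.assert_frame_equal(a, b)

    def test_empty_area_fails(self, clean_stack, calendar):
        used = assign_periods(_pts(["2017-07-01"]), calendar)
        with pytest.raises(ValueError, match="sampleable"):
            sample_available_landscape(used, box(-500, -500, -1, -1),
                                       clean_stack, 10, seed=1)

    def test_uniform_over_cells_chi2(self, clean_stack, calendar):
        """10^5 draws against the per-cell uniform expectation."""
        used = assign_periods(_pts(["2017-07-01"] * 10_000), calendar)
        area = box(0, 0, *clean_stack.extent)
        av = sample_available_landscape(used, area, clean_stack, 10, seed=9)
        iy, ix = clean_stack.cell_of(av["x"].to_numpy(), av["y"].to_numpy())
        n_cells = int(clean_stack.prediction_area.sum())
        counts = np.bincount(
            iy * clean_stack.shape[1] + ix,
            minlength=clean_stack.shape[0] * clean_stack.shape[1])
        counts = counts[clean_stack.prediction_area.ravel()]
        stat, p = stats.chisquare(counts)
        assert p > 0.01
        assert counts.sum() == 100_000 and len(counts) == n_cells


class TestSteps:
    def test_gap_pairs_skipped(self):
        pts = _pts(["2017-06-10 00:00", "2017-06-10 02:00", "2017-06-10 06:00"])
        steps = build_steps(pts)
        assert len(steps) == 1

    def test_three_four_five_length(self):
        pts = _pts(["2017-06-10 00:00", "2017-06-10 02:00"],
                   [(0.0, 0.0), (300.0, 400.0)])
        assert build_steps(pts)["length"].iloc[0] == pytest.approx(500.0)

    def test_collinear_fixes_zero_turn(self):
        pts = _pts(["2017-06-10 00:00", "2017-06-10 02:00", "2017-06-10 04:00"],
                   [(0, 0), (100, 100), (200, 200)])
        steps = build_steps(pts)
        assert np.isnan(steps["turn_angle"].iloc[0])  # first step undefined
        assert steps["turn_angle"].iloc[1] == pytest.approx(0.0)

    def test_steps_outside_prediction_area_dropped(self, clean_stack):
        ex, ey = clean_stack.extent
        ocean_x = 0.5 * clean_stack.cell_size  # west ocean strip
        pts = _pts(["2017-06-10 00:00", "2017-06-10 02:00", "2017-06-10 04:00"],
                   [(ex / 2, ey / 2), (ocean_x, ey / 2), (ex / 2, ey / 2)])
        steps = build_steps(pts, clean_stack)
        assert len(steps) == 1  # the step ending in the ocean is gone


class TestStepKernel:
    def test_gamma_mle_recovery(self):
        rng = np.random.default_rng(1)
        lens = rng.gamma(2.0, 300.0, 100_000)
        df = pd.DataFrame({"length": lens})
        shape, scale = fit_step_kernel(df)
        assert abs(shape - 2.0) / 2.0 < 0.05
        assert abs(shape * scale - 600.0) / 600.0 < 0.05

    def test_too_few_steps_refused(self):
        with pytest.raises(ValueError, match="at least 30"):
            fit_step_kernel(pd.DataFrame({"length": np.arange(10.0)}))

    def test_zero_variance_refused(self):
        with pytest.raises(ValueError, match="zero variance"):
            fit_step_kernel(pd.DataFrame({"length": np.full(50, 100.0)}))

    def test_period_stratification_independent(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame({
            "length": np.r_[rng.gamma(1.5, 200, 3000), rng.gamma(3.0, 500, 3000)],
            "period": ["a"] * 3000 + ["b"] * 3000,
        })
        ka = fit_step_kernel(df, "a")
        kb = fit_step_kernel(df, "b")
        assert abs(ka[0] - 1.5) < 0.15 and abs(kb[0] - 3.0) < 0.3


@pytest.fixture(scope="module")
def used_steps(clean_stack):
    rng = np.random.default_rng(3)
    n = 1000
    cells = np.argwhere(clean_stack.prediction_area)
    pick = cells[rng.integers(0, len(cells), n)]
    x0, y0 = clean_stack.cell_center(pick[:, 0], pick[:, 1])
    x0, y0 = np.asarray(x0, float), np.asarray(y0, float)
    return pd.DataFrame({
        "animal_year_id": np.repeat([f"a{i}" for i in range(10)], n // 10),
        "stratum": [f"s{i}" for i in range(n)],
        "t_start": pd.Timestamp("2017-07-01", tz="UTC"),
        "t_end": pd.Timestamp("2017-07-01 02:00", tz="UTC"),
        "x_start": x0, "y_start": y0,
        "x_end": x0 + 50, "y_end": y0 + 50,
        "length": np.hypot(50, 50), "turn_angle": 0.0,
        "used": True, "period": "mosquito",
    })


class TestAvailableSteps:
    def test_counts_and_mask(self, used_steps, clean_stack):
        out = sample_available_steps(used_steps, (1.5, 300.0), clean_stack,
                                     ratio=10, seed=4)
        kept = out["stratum"].nunique()
        assert kept >= 0.99 * used_steps["stratum"].nunique()
        assert len(out) == 11 * kept
        per = out.groupby("stratum")["used"].agg(["sum", "count"])
        assert (per["sum"] == 1).all() and (per["count"] == 11).all()
        av = out[~out["used"]]
        iy, ix = clean_stack.cell_of(av["x_end"], av["y_end"])
        assert clean_stack.prediction_area[iy, ix].all()
        # available steps share their used step's start point
        starts = out.groupby("stratum")[["x_start", "y_start"]].nunique()
        assert (starts == 1).all().all()

    def test_turning_angles_uniform(self, used_steps):
        # on an unconstrained mask (no ocean, no holes) the drawn angles are
        # exactly uniform; masks would tilt retained angles away from edges
        from caribou_forage import LandscapeConfig, generate_landscape
        open_stack = generate_landscape(LandscapeConfig(
            grid_nx=30, grid_ny=30, seed=8, ocean_width_cells=0,
            veg_hole_fraction=0.0, missingness_schedule=(0.0,) * 14))
        big = pd.concat([used_steps] * 10, ignore_index=True)
        big["stratum"] = [f"s{i}" for i in range(len(big))]
        ex, ey = open_stack.extent
        big["x_start"], big["y_start"] = ex / 2, ey / 2  # far from every edge
        out = sample_available_steps(big, (1.5, 300.0), open_stack,
                                     ratio=10, seed=5)
        ang = out.loc[~out["used"], "turn_angle"].to_numpy()
        assert len(ang) >= 99_000
        # Rayleigh test of circular uniformity
        n = len(ang)
        R = np.hypot(np.cos(ang).sum(), np.sin(ang).sum()) / n
        p = np.exp(-n * R ** 2)
        assert p > 0.01


class TestAttribution:
    def test_masked_rows_dropped_and_reported(self, stack, calendar):
        # week 1 has half its cells masked under the default schedule
        cells = np.argwhere(stack.prediction_area)
        cx, cy = stack.cell_center(cells[:, 0], cells[:, 1])
        pts = pd.DataFrame({
            "animal_year_id": "a1",
            "t": pd.Timestamp("2017-06-03", tz="UTC"),
            "x": cx, "y": cy, "used": True,
        })
        pts = assign_periods(pts, calendar)
        rows, report = attribute_covariates(pts, stack, calendar)
        frac = report.loc[report["period"] == "calving", "frac_dropped"].iloc[0]
        assert 0.3 < frac < 0.7
        assert len(rows) == round(len(pts) * (1 - frac))

    def test_all_valid_no_drops(self, clean_stack, calendar):
        pts = assign_periods(_pts(["2017-07-01"] * 5,
                                  [(3000 + 300 * i, 3000) for i in range(5)]),
                             calendar)
        rows, report = attribute_covariates(pts, clean_stack, calendar)
        assert (report["frac_dropped"] == 0).all()
        assert len(rows) == 5

    def test_lookup_value_passthrough(self, clean_stack, calendar):
        pts = assign_periods(_pts(["2017-07-01"], [(4000.0, 4000.0)]), calendar)
        rows, _ = attribute_covariates(pts, clean_stack, calendar)
        iy, ix = clean_stack.cell_of(4000.0, 4000.0)
        wk = rows["week"].iloc[0] - 1
        assert rows["dn"].iloc[0] == clean_stack.dn[wk, iy, ix]
        assert rows["elevation"].iloc[0] == clean_stack.elevation[iy, ix]

    def test_outside_extent_is_an_error(self, clean_stack, calendar):
        pts = assign_periods(_pts(["2017-07-01"], [(-10.0, 50.0)]), calendar)
        with pytest.raises(ValueError, match="outside"):
            attribute_covariates(pts, clean_stack, calendar)


class TestStandardize:
    def test_two_point_column(self):
        df = pd.DataFrame({"dn": [0.0, 2.0]})
        out, man = standardize(df, ["dn"])
        assert list(out["dn"]) == [-1.0, 1.0]
        assert man["dn"] == {"mean": 1.0, "sd": 1.0}

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({"dn": rng.normal(size=100)})
        once, _ = standardize(df, ["dn"])
        twice, _ = standardize(once, ["dn"])
        assert np.allclose(once["dn"], twice["dn"], atol=1e-12)

    def test_manifest_reused_for_prediction(self):
        train = pd.DataFrame({"dn": [0.0, 2.0, 4.0]})
        _, man = standardize(train, ["dn"])
        new = apply_standardization(pd.DataFrame({"dn": [6.0]}), man)
        # new data is scaled by the training moments, not recentered on itself
        assert new["dn"].iloc[0] == pytest.approx((6.0 - 2.0) / train["dn"].std(ddof=0))

    def test_zero_variance_refused(self):
        with pytest.raises(ValueError, match="zero variance"):
            standardize(pd.DataFrame({"dn": [1.0, 1.0]}), ["dn"])


class TestCollinearityScreen:
    def test_perfect_collinearity_flagged(self):
        x = np.arange(10.0)
        df = pd.DataFrame({"biomass": x, "de": 2 * x})
        out = collinearity_screen(df, ["biomass", "de"], 0.7)
        assert [(a, b) for a, b, _ in out] == [("biomass", "de")]

    def test_independent_not_flagged(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame({"biomass": rng.normal(size=5000),
                           "de": rng.normal(size=5000)})
        assert collinearity_screen(df, ["biomass", "de"], 0.7) == []

    def test_boundary_is_strict(self):
        # |r| equal to the threshold is acceptable; only strictly above flags
        rng = np.random.default_rng(2)
        x = rng.normal(size=200)
        y = 0.7 * x + 0.7 * rng.normal(size=200)
        df = pd.DataFrame({"biomass": x, "de": y})
        r = abs(np.corrcoef(x, y)[0, 1])
        assert collinearity_screen(df, ["biomass", "de"], r) == []
        assert len(collinearity_screen(df, ["biomass", "de"], r - 1e-9)) == 1
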