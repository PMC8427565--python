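"""End-to-end orchestration: simulate -> design -> fit -> select -> validate.

Each stage reads its inputs from and writes its outputs into a run
directory, so the stages can run in one call (``run_all``) or as separate
CLI invocations. All outputs are deterministic under the run seed: child
seeds are spawned from one ``SeedSequence`` and every table carries the
configuration hash.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import design as dz
from .config import RunConfig, _to_plain, day_of_study
from .insects import attribute_insects
from .landscape import ForageStack, generate_landscape
from .model_specs import ModelSpec, build_candidate_set, insect_candidate_set
from .movement import fit_move_lmm, harassment_ratio, movement_candidates
from .rsf import fit_rsf_mixed
from .selection import kfold_cv, selection_table
from .ssf import fit_ssf_clogit
from .trajectories import simulate_trajectories
from .weather import WeatherField, generate_weather

log = logging.getLogger(__name__)

CSV_FLOAT = "%.10g"


def adequacy_flags(rows: pd.DataFrame, dn_threshold: float = 1.0,
                   de_threshold: float = 9.0) -> pd.DataFrame:
    """Protein / energy adequacy flags per row.

    Forage below 1 g N/100 g DM or 9 kJ/g DM impairs female caribou (they
    cannot compensate with intake); the boundary value itself is adequate -
    strictly-below impairs.
    """
    if dn_threshold <= 0 or de_threshold <= 0:
        raise ValueError("adequacy thresholds must be positive")
    out = rows.copy()
    out["protein_adequate"] = out["dn"] >= dn_threshold
    out["energy_adequate"] = out["de"] >= de_threshold
    return out


def seasonal_adequacy_summary(stack: ForageStack, dn_threshold: float = 1.0,
                              de_threshold: float = 9.0) -> dict:
    """First week whose spatial-mean DN (DE) drops below its threshold."""
    first_dn = first_de = None
    for w in range(1, stack.n_weeks + 1):
        if first_dn is None and stack.spatial_mean("dn", w) < dn_threshold:
            first_dn = w
        if first_de is None and stack.spatial_mean("de", w) < de_threshold:
            first_de = w
    return {"first_week_dn_below": first_dn, "first_week_de_below": first_de}


def _write(df: pd.DataFrame, path: Path, cfg_hash: str) -> None:
    df = df.copy()
    df["config_hash"] = cfg_hash
    df.to_csv(path, index=False, float_format=CSV_FLOAT)


def _spec_yaml(spec: ModelSpec) -> dict:
    return _to_plain(spec)


def spec_from_dict(d: dict) -> ModelSpec:
    d = dict(d)
    d["forage"] = tuple(d.get("forage", ()))
    d["interactions"] = tuple(d.get("interactions", ()))
    return ModelSpec(**d)


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def simulate_stage(config: RunConfig, out: Path) -> dict:
    config.validate()
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(config.seed).spawn(3)
    seeds = [int(s.generate_state(1)[0] % 2**31) for s in ss]

    lcfg = dataclasses.replace(config.landscape, seed=seeds[0])
    stack = generate_landscape(lcfg)
    ex, ey = stack.extent
    wcfg = dataclasses.replace(config.weather, extent_x=ex, extent_y=ey)
    weather = generate_weather(wcfg, seeds[1])
    points = simulate_trajectories(
        config.truth, stack, weather, config.n_animal_years,
        config.fixes_per_animal, seeds[2], config.calendar)

    stack.save_npz(out / "forage_stack.npz")
    weather.save_npz(out / "weather.npz")
    (out / "forage_stack.meta.yaml").write_text(yaml.safe_dump({
        "cell_size_m": stack.cell_size, "n_weeks": stack.n_weeks,
        "grid": list(stack.shape), "origin": [0.0, 0.0],
        "variables": ["biomass g/m^2 DM", "dn g/100 g DM", "de kJ/g DM"],
        "config_hash": config.config_hash(),
    }))
    points.to_csv(out / "points_used.csv", index=False, float_format=CSV_FLOAT)
    (out / "config.yaml").write_text(config.to_yaml())
    (out / "truth.yaml").write_text(yaml.safe_dump(_to_plain(config.truth)))
    log.info("simulate: %d animal-years, %d fixes", config.n_animal_years, len(points))
    return {"stack": stack, "weather": weather, "points": points}


def _load_sim(out: Path) -> dict:
    return {
        "stack": ForageStack.load_npz(out / "forage_stack.npz"),
        "weather": WeatherField.load_npz(out / "weather.npz"),
        "points": pd.read_csv(out / "points_used.csv", parse_dates=["t"]),
    }


def design_stage(config: RunConfig, out: Path, sim: dict | None = None) -> dict:
    sim = sim or _load_sim(out)
    stack, weather, points = sim["stack"], sim["weather"], sim["points"]
    cal = config.calendar
    h = config.config_hash()
    ss = np.random.SeedSequence(config.seed + 1).spawn(2 * len(cal.analysis_periods))
    seeds = iter(int(s.generate_state(1)[0] % 2**31) for s in ss)

    mcp = dz.mcp_available_area(points, stack.ocean_polygon())
    labeled = dz.assign_periods(points, cal)
    reports = []

    rsf_rows: dict[str, pd.DataFrame] = {}
    for period in cal.analysis_periods:
        used = labeled[(labeled["period"] == period) & ~labeled["analysis_excluded"]]
        avail = dz.sample_available_landscape(
            used, mcp, stack, config.landscape_ratio, next(seeds))
        both = pd.concat([used.assign(used=True), avail], ignore_index=True)
        rows, rep = dz.attribute_covariates(both, stack, cal)
        rep["scale"] = "landscape"
        reports.append(rep)
        if cal.insect_index_for(period):
            rows = attribute_insects(rows, weather)
        rows = adequacy_flags(rows, config.dn_adequate, config.de_adequate)
        rows["response"] = rows["used"].astype(int)
        rsf_rows[period] = rows
        _write(rows, out / f"rsf_rows_{period}.csv", h)
        log.info("design landscape %s: %d used, %d available rows kept",
                 period, int(rows['used'].sum()), int((~rows['used']).sum()))

    steps = dz.build_steps(points, stack)
    steps["day"] = [day_of_study(t) for t in pd.to_datetime(steps["t_end"])]
    steps["period"] = [cal.period_of_day(d) for d in steps["day"]]
    steps = steps[steps["period"].isin(cal.analysis_periods)].reset_index(drop=True)

    kernels = {}
    ssf_rows: dict[str, pd.DataFrame] = {}
    for period in cal.analysis_periods:
        sub = steps[steps["period"] == period].reset_index(drop=True)
        kernels[period] = dz.fit_step_kernel(sub)
        strata = dz.sample_available_steps(
            sub, kernels[period], stack, config.patch_ratio, next(seeds))
        rows, rep = dz.attribute_covariates(strata, stack, cal)
        rep["scale"] = "patch"
        reports.append(rep)
        if cal.insect_index_for(period):
            rows = rows.rename(columns={"x_end": "x", "y_end": "y",
                                        "t_end": "t"})
            rows = attribute_insects(rows, weather)
            rows = rows.rename(columns={"x": "x_end", "y": "y_end",
                                        "t": "t_end"})
        rows["response"] = rows["used"].astype(int)
        ssf_rows[period] = rows
        _write(rows, out / f"ssf_rows_{period}.csv", h)
        log.info("design patch %s: %d strata kept", period, rows["stratum"].nunique())

    report = pd.concat(reports, ignore_index=True)
    _write(report, out / "missingness.csv", h)
    (out / "kernels.yaml").write_text(yaml.safe_dump(
        {p: [float(v) for v in k] for p, k in kernels.items()}))
    (out / "adequacy.yaml").write_text(yaml.safe_dump(
        seasonal_adequacy_summary(stack, config.dn_adequate, config.de_adequate)))
    return {"rsf_rows": rsf_rows, "ssf_rows": ssf_rows, "kernels": kernels,
            "missingness": report, **sim}


def _load_design(config: RunConfig, out: Path) -> dict:
    d = _load_sim(out)
    d["rsf_rows"] = {p: pd.read_csv(out / f"rsf_rows_{p}.csv", parse_dates=["t"])
                     for p in config.calendar.analysis_periods}
    d["ssf_rows"] = {p: pd.read_csv(out / f"ssf_rows_{p}.csv",
                                    parse_dates=["t_start", "t_end"])
                     for p in config.calendar.analysis_periods}
    return d


def _fit_scale(config: RunConfig, out: Path, data: dict, scale: str) -> dict:
    """Candidate fitting + criterion tables for one scale, all periods."""
    cal = config.calendar
    h = config.config_hash()
    rows_by_period = data["rsf_rows" if scale == "landscape" else "ssf_rows"]
    criterion = "aic" if scale == "landscape" else "qic"
    fit_fn = fit_rsf_mixed if scale == "landscape" else fit_ssf_clogit
    results = {}
    for period, raw in rows_by_period.items():
        insect = cal.insect_index_for(period)
        rows, manifest = dz.standardize(raw)
        rows.attrs["manifest"] = manifest
        cont = [c for c in ("biomass", "dn", "de", "elevation", "snowmelt")
                if c in rows.columns]
        flagged = dz.collinearity_screen(rows, cont, config.collinearity_threshold)
        cands = build_candidate_set(period, scale, flagged)
        fits = {s: fit_fn(rows, s) for s in cands}
        tab = selection_table(list(fits.values()), criterion)
        _write(tab, out / f"selection_{scale}_{period}.csv", h)
        top_label = tab.iloc[0]["model"]
        top_spec = next(s for s in fits if s.label == top_label)
        _write(fits[top_spec].table().reset_index(names="coefficient"),
               out / f"coef_{scale}_{period}.csv", h)

        entry = {"top_spec": top_spec, "fits": fits, "flagged": flagged,
                 "manifest": manifest, "table": tab}
        if insect and top_spec.forage:
            icands = insect_candidate_set(top_spec, insect)
            ifits = {s: fit_fn(rows, s) for s in icands}
            itab = selection_table(list(ifits.values()), criterion)
            _write(itab, out / f"selection_{scale}_{period}_{insect}.csv", h)
            itop = next(s for s in ifits
                        if s.label == itab.iloc[0]["model"])
            _write(ifits[itop].table().reset_index(names="coefficient"),
                   out / f"coef_{scale}_{period}_{insect}.csv", h)
            entry["insect_top_spec"] = itop
        (out / f"top_spec_{scale}_{period}.yaml").write_text(yaml.safe_dump({
            "top": _spec_yaml(top_spec),
            "insect_top": _spec_yaml(entry["insect_top_spec"])
            if "insect_top_spec" in entry else None,
            "flagged_pairs": [[a, b, float(r)] for a, b, r in flagged],
        }))
        results[period] = entry
        log.info("fit %s %s: top model %s", scale, period, top_label)
    return results


def fit_rsf_stage(config: RunConfig, out: Path, data: dict | None = None) -> dict:
    data = data or _load_design(config, out)
    return _fit_scale(config, out, data, "landscape")


def fit_ssf_stage(config: RunConfig, out: Path, data: dict | None = None) -> dict:
    data = data or _load_design(config, out)
    return _fit_scale(config, out, data, "patch")


def select_stage(config: RunConfig, out: Path) -> pd.DataFrame:
    """Aggregate the per-period selection tables into one summary."""
    frames = []
    for path in sorted(out.glob("selection_*.csv")):
        if path.name == "selection_summary.csv":
            continue
        df = pd.read_csv(path)
        parts = path.stem.split("_")
        df.insert(0, "scale", parts[1])
        df.insert(1, "period", "_".join(parts[2:]))
        frames.append(df)
    summary = pd.concat(frames, ignore_index=True)
    summary.to_csv(out / "selection_summary.csv", index=False)
    return summary


def cv_stage(config: RunConfig, out: Path, data: dict | None = None) -> pd.DataFrame:
    data = data or _load_design(config, out)
    cal = config.calendar
    h = config.config_hash()
    rng = np.random.SeedSequence(config.seed + 2)
    seeds = iter(int(s.generate_state(1)[0] % 2**31) for s in rng.spawn(32))
    records = []
    for scale, key in (("landscape", "rsf_rows"), ("patch", "ssf_rows")):
        for period, raw in data[key].items():
            spec_file = out / f"top_spec_{scale}_{period}.yaml"
            if not spec_file.exists():
                continue
            meta = yaml.safe_load(spec_file.read_text())
            for kind in ("top", "insect_top"):
                if meta.get(kind) is None:
                    continue
                spec = spec_from_dict(meta[kind])
                res = kfold_cv(raw, spec, k=config.cv_folds,
                               n_bins=config.cv_bins,
                               repeats=config.cv_repeats, seed=next(seeds))
                records.append({"scale": scale, "period": period, "model": kind,
                                "mean_rs": res.mean_rs,
                                "n_repeats": len(res.per_repeat)})
                log.info("cv %s %s %s: mean r_s = %.3f", scale, period, kind,
                         res.mean_rs)
    tab = pd.DataFrame(records)
    _write(tab, out / "cv_summary.csv", h)
    return tab


def movement_stage(config: RunConfig, out: Path, data: dict | None = None
                   ) -> pd.DataFrame:
    data = data or _load_design(config, out)
    h = config.config_hash()
    records = []
    for period, index in (("mosquito", "mi"), ("oestrid", "oi")):
        rows = data["ssf_rows"][period]
        used = rows[rows["used"] & (rows["length"] > 0)].copy()
        if index not in used.columns:
            pts = used.rename(columns={"x_start": "x", "y_start": "y",
                                       "t_start": "t"})
            used = attribute_insects(pts, data["weather"]).rename(
                columns={"x": "x_start", "y": "y_start", "t": "t_start"})
        used["log_step_length"] = np.log(used["length"])
        used["od"] = used["day"].astype(float)
        idx_raw = used[index].to_numpy()
        std, manifest = dz.standardize(used, [index, "od"])
        std.attrs["manifest"] = manifest
        fits = [fit_move_lmm(std, s) for s in movement_candidates(index)]
        tab = selection_table(fits, "aic")
        _write(tab, out / f"movement_selection_{period}.csv", h)
        top = fits[int(np.argmin([-2 * f.loglik + 2 * f.k for f in fits]))]
        _write(top.table().reset_index(names="coefficient"),
               out / f"movement_coef_{period}.csv", h)
        lo, hi = np.quantile(idx_raw, [0.05, 0.95])
        ratio = harassment_ratio(top, float(lo), float(hi), manifest)
        records.append({"period": period, "index": index,
                        "top_model": top.spec.label,
                        "index_low": float(lo), "index_high": float(hi),
                        "step_length_ratio": ratio})
        log.info("movement %s: top %s, fold-change %.2f",
                 period, top.spec.label, ratio)
    tab = pd.DataFrame(records)
    _write(tab, out / "movement_summary.csv", h)
    return tab


def run_all(config: RunConfig, out_dir) -> Path:
    """Run every stage into ``out_dir``; reproducible under ``config.seed``.

    Any stage failure halts the run with the stage name attached.
    """
    out = Path(out_dir)
    state: dict = {}
    stages = [
        ("simulate", lambda: simulate_stage(config, out)),
        ("design", lambda: design_stage(config, out, state["simulate"])),
        ("fit-rsf", lambda: fit_rsf_stage(config, out, state["design"])),
        ("fit-ssf", lambda: fit_ssf_stage(config, out, state["design"])),
        ("select", lambda: select_stage(config, out)),
        ("cv", lambda: cv_stage(config, out, state["design"])),
        ("movement", lambda: movement_stage(config, out, state["design"])),
    ]
    for name, fn in stages:
        try:
            state[name] = fn()
        except Exception as e:
            raise RuntimeError(f"pipeline stage {name!r} failed: {e}") from e
    return out
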