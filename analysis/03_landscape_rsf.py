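"""Landscape-scale resource selection: mixed-logit candidates ranked by AIC.

For each analyzed period, fits the null model, the base habitat model, and
the base model plus every forage subset (biomass linear or quadratic, DN,
DE), all with a random intercept per animal-year; then, for the insect
periods, tests whether adding the activity index and index-by-forage
interactions to the period's top forage model improves fit. Copies the AIC
tables and top-model coefficient tables into results/.

Run after 02_design_tables.py:  python analysis/03_landscape_rsf.py
"""

import argparse
import shutil
from pathlib import Path

import pandas as pd

from caribou_forage import RunConfig
from caribou_forage.pipeline import fit_rsf_stage

RESULTS = Path("results")


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--out", type=Path, default=Path("scratch/analysis_run"))
    args = ap.parse_args()

    cfg = RunConfig.from_yaml((args.out / "config.yaml").read_text())
    fits = fit_rsf_stage(cfg, args.out)

    RESULTS.mkdir(exist_ok=True)
    for f in sorted(args.out.glob("selection_landscape_*.csv")):
        shutil.copy(f, RESULTS / f.name)
    for f in sorted(args.out.glob("coef_landscape_*.csv")):
        shutil.copy(f, RESULTS / f.name)

    for period, entry in fits.items():
        top = entry["table"].iloc[0]
        print(f"{period:14s} top: {top['model']}  "
              f"(weight {top['weight']:.2f})")
    print(f"copied AIC and coefficient tables to {RESULTS}/")


if __name__ == "__main__":
    main()
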