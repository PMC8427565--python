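"""Patch-scale step selection: conditional-logit candidates ranked by QIC.

Each stratum pairs one observed 2-h step with its 10 kernel-drawn available
steps; candidates share the base habitat structure plus step length as a
nuisance covariate, and differ in their forage subset. Robust (animal-year
clustered sandwich) standard errors feed the QIC penalty. Insect-period
top models are re-tested with the activity index and interactions.

Run after 02_design_tables.py:  python analysis/04_patch_ssf.py
"""

import argparse
import shutil
from pathlib import Path

from caribou_forage import RunConfig
from caribou_forage.pipeline import fit_ssf_stage

RESULTS = Path("results")


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--out", type=Path, default=Path("scratch/analysis_run"))
    args = ap.parse_args()

    cfg = RunConfig.from_yaml((args.out / "config.yaml").read_text())
    fits = fit_ssf_stage(cfg, args.out)

    RESULTS.mkdir(exist_ok=True)
    for f in sorted(args.out.glob("selection_patch_*.csv")):
        shutil.copy(f, RESULTS / f.name)
    for f in sorted(args.out.glob("coef_patch_*.csv")):
        shutil.copy(f, RESULTS / f.name)

    for period, entry in fits.items():
        top = entry["table"].iloc[0]
        print(f"{period:14s} top: {top['model']}  (weight {top['weight']:.2f})")
    print(f"copied QIC and coefficient tables to {RESULTS}/")


if __name__ == "__main__":
    main()
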