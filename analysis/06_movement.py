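"""Movement-rate response to insect harassment.

Fits the six-candidate ladder of linear mixed models of log step length on
the period's insect activity index and ordinal study day (linear and
quadratic terms, random intercept per animal-year), ranks them by AIC from
an ML refit, and reports the fold-change of median step length between low
and high index values at fixed ordinal day.

Run after 02_design_tables.py:  python analysis/06_movement.py
"""

import argparse
import shutil
from pathlib import Path

from caribou_forage import RunConfig
from caribou_forage.pipeline import movement_stage

RESULTS = Path("results")


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--out", type=Path, default=Path("scratch/analysis_run"))
    args = ap.parse_args()

    cfg = RunConfig.from_yaml((args.out / "config.yaml").read_text())
    tab = movement_stage(cfg, args.out)

    RESULTS.mkdir(exist_ok=True)
    for name in ("movement_summary.csv", "movement_selection_mosquito.csv",
                 "movement_selection_oestrid.csv", "movement_coef_mosquito.csv",
                 "movement_coef_oestrid.csv"):
        shutil.copy(args.out / name, RESULTS / name)
    print(tab.to_string(index=False))
    print(f"copied movement tables to {RESULTS}/")


if __name__ == "__main__":
    main()
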