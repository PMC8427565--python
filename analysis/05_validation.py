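"""k-fold binned-Spearman validation of every period's top models.

Animal-years (never rows) are partitioned into 5 folds; each fold's model is
refit on the remaining animal-years and its relative-selection scores on the
held-out rows are ranked into 10 equal-count bins over available rows; the
area-adjusted used frequency per bin is Spearman-correlated with bin rank,
averaged over folds and 10 repeats.

Run after 03/04:  python analysis/05_validation.py
"""

import argparse
import shutil
from pathlib import Path

from caribou_forage import RunConfig
from caribou_forage.pipeline import cv_stage

RESULTS = Path("results")


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--out", type=Path, default=Path("scratch/analysis_run"))
    ap.add_argument("--repeats", type=int, default=None,
                    help="override the configured number of CV repeats")
    args = ap.parse_args()

    cfg = RunConfig.from_yaml((args.out / "config.yaml").read_text())
    if args.repeats:
        cfg.cv_repeats = args.repeats
    tab = cv_stage(cfg, args.out)

    RESULTS.mkdir(exist_ok=True)
    shutil.copy(args.out / "cv_summary.csv", RESULTS / "cv_summary.csv")
    print(tab.to_string(index=False))
    print(f"copied CV summary to {RESULTS}/")


if __name__ == "__main__":
    main()
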