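#!/usr/bin/env python
"""Compute the per-eyelid morphology metrics table for the simulated cohort.

Reads results/cohort/ (images + masks), measures gland height, width,
tortuosity, eyelid density and the vagueness contrast for every eyelid,
and writes results/metrics.csv.
"""

from pathlib import Path

from meibomorph.io_masks import write_metrics_table
from meibomorph.pipeline import cohort_dir_to_metrics

def main() -> None:
    cohort = Path("results") / "cohort"
    if not cohort.exists():
        raise SystemExit("run analysis/01_simulate_cohort.py first")
    metrics = cohort_dir_to_metrics(cohort)
    out = Path("results") / "metrics.csv"
    write_metrics_table(metrics, out)
    print(f"{len(metrics)} aggregate eyelid rows written to {out}")
    summary = metrics.groupby("eye_role")[["height_px", "width_px", "tortuosity", "density", "vagueness"]].mean()
    print("group means across eyelids:")
    print(summary.round(3).to_string())


if __name__ == "__main__":
    main()
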