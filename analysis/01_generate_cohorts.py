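#!/usr/bin/env python
"""Generate the study's synthetic cohorts and export them as CSV.

Three cohorts define the study conditions: a WT induction-withdrawal
(decay) cohort, a UBR5-knockout decay cohort with the early-G1 half-life
distribution doubled, and a Cdk-low-style cycling cohort with dilution
through G1.  Full trace tables are large, so they go to scratch/; the
resolved configs and a small per-cohort summary go to results/.
"""

import json
from pathlib import Path

from rbdyn.config import (
    dump_config,
    reference_cycling_config,
    reference_decay_config,
    ubr5_ko_decay_config,
)
from rbdyn.io import write_cohort_csv, write_truth_csv
from rbdyn.synthetic import generate_cycling_cohort, generate_decay_cohort

SEED = 1
ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "cohorts"
RESULTS = ROOT / "results"


def main() -> None:
    SCRATCH.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(exist_ok=True)
    summary = {}
    cohorts = {
        "decay_WT": (reference_decay_config(seed=SEED, n_cells=200), generate_decay_cohort),
        "decay_UBR5KO": (ubr5_ko_decay_config(seed=SEED + 1, n_cells=200), generate_decay_cohort),
        "cycling": (reference_cycling_config(seed=SEED + 2, n_cells=200), generate_cycling_cohort),
    }
    for name, (config, generate) in cohorts.items():
        cohort = generate(config)
        write_cohort_csv(cohort, SCRATCH / f"{name}.csv")
        write_truth_csv(cohort, SCRATCH / f"{name}_truth.csv")
        dump_config(config, RESULTS / f"{name}_config.yaml")
        summary[name] = {
            "n_cells": len(cohort),
            "n_frames_total": sum(t.n_frames for t in cohort),
            "condition": config.condition_label,
        }
        print(f"{name}: {len(cohort)} cells -> {SCRATCH / (name + '.csv')}")
    (RESULTS / "cohort_summary.json").write_text(json.dumps(summary, indent=2))


if __name__ == "__main__":
    main()
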