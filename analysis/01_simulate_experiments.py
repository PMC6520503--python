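"""Simulate synthetic cohorts for the three cursor-jump experiments.

Writes per-experiment trial, condition and subject tables under
results/sim/, plus channel-trial force traces for a small Experiment-3
cohort that the downstream extraction step (02) consumes.  Reports the
block compositions and the pooled standard-trial hit rate, which should sit
near the ~74% level the task staircasing targets.
"""

import sys
from pathlib import Path

import numpy as np

from reachgain import design_sim as ds

OUT = Path(__file__).resolve().parents[1] / "results" / "sim"
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1


def main():
    for experiment, n_subjects in ((1, 12), (2, 12), (3, 10)):
        cohort = ds.simulate_cohort(experiment, n_subjects=n_subjects,
                                    seed=SEED + experiment,
                                    traces=(experiment == 3 and n_subjects <= 10))
        outdir = OUT / f"exp{experiment}"
        outdir.mkdir(parents=True, exist_ok=True)
        for name, df in cohort.items():
            df.to_csv(outdir / f"{name}.csv", index=False)

        trials = cohort["trials"]
        per_block = trials.groupby(["subject_id", "block_id"]).size().unique()
        std = trials[(trials["trial_type"] == "standard")
                     & (trials["jump_direction"] != "none")
                     & (trials["phase"] == "main")]
        hit_rate = std["hit"].mean()
        print(f"Experiment {experiment}: {n_subjects} subjects, "
              f"block sizes {sorted(per_block)}, "
              f"standard-trial hit rate {100 * hit_rate:.1f}%")


if __name__ == "__main__":
    main()
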