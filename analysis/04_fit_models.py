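"""Hierarchical Bayesian fits of the four gain models.

Fits the probability, reward, risk-neutral value and risk-sensitive value
models to the Experiment-3 gain table from 02 (falling back to a directly
simulated table when 02 has not been run), at the reduced sampling profile.
Writes posterior summaries and posterior-predictive bands under
results/fits/, and prints the group-level estimates — in particular the
risk weight w, whose generating value is 0.68.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

from reachgain import design_sim as ds
from reachgain.compare import compute_waic
from reachgain.models import (MODEL_NAMES, ModelSpec, SamplerConfig,
                              fit_hierarchical, posterior_predict,
                              variance_explained)

ROOT = Path(__file__).resolve().parents[1] / "results"
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1


def load_gains():
    path = ROOT / "gains" / "gains.csv"
    if path.exists():
        return pd.read_csv(path)
    subjects = ds.sample_subject_params(n_subjects=10, seed=SEED)
    return ds.gain_table_to_frame(ds.simulate_gain_table(
        ds.experiment_conditions(3), subjects, 18, seed=SEED + 1))


def main():
    gains = load_gains()
    conditions = ds.experiment_conditions(3)
    outdir = ROOT / "fits"
    outdir.mkdir(parents=True, exist_ok=True)

    for name in MODEL_NAMES:
        config = SamplerConfig.reduced(seed=SEED)
        post = fit_hierarchical(gains, ModelSpec(name), config, conditions)
        post.summary().to_csv(outdir / f"summary_{name}.csv", index=False)
        np.save(outdir / f"loglik_{name}.npy", post.log_likelihood)
        posterior_predict(post, conditions).to_csv(
            outdir / f"predictive_{name}.csv", index=False)
        msg = (f"{name:>13}: WAIC {compute_waic(post.log_likelihood):8.1f}  "
               f"R^2 {variance_explained(post):.3f}  "
               f"max R-hat {post.max_rhat():.3f}")
        if name == "value_risk":
            w = post.flat("w_group_mean")
            lo, hi = np.quantile(w, [0.025, 0.975])
            msg += f"  w = {w.mean():.2f} [{lo:.2f}, {hi:.2f}]"
        print(msg)


if __name__ == "__main__":
    main()
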