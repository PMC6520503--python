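"""Model comparison and the hit-rate/gain relationship.

Turns the WAIC scores from 04 into a comparison table with pairwise Bayes
factors (K = exp(dWAIC/2)) and Kass-Raftery evidence labels, then regresses
per-condition outer/center hit-rate ratios (from the 01 trial tables) on
per-condition mean response gains — a negative slope: stronger corrections
toward the center target go with relatively fewer outer-target hits.

Writes results/comparison/comparison.csv and prints the table.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from reachgain.compare import (compute_waic, evidence_label,
                               hit_rate_gain_regression, hit_ratio_table,
                               waic_bayes_factor)
from reachgain.models import MODEL_NAMES

ROOT = Path(__file__).resolve().parents[1] / "results"


def main():
    fitdir = ROOT / "fits"
    waics = {name: compute_waic(np.load(fitdir / f"loglik_{name}.npy"))
             for name in MODEL_NAMES}
    best = min(waics, key=waics.get)
    rows = []
    for name, waic in sorted(waics.items(), key=lambda kv: kv[1]):
        k = waic_bayes_factor(waic, waics[best])
        rows.append({"model": name, "waic": waic, "k_vs_best": k,
                     "label": "best" if name == best else evidence_label(k)})
    table = pd.DataFrame(rows)
    outdir = ROOT / "comparison"
    outdir.mkdir(parents=True, exist_ok=True)
    table.to_csv(outdir / "comparison.csv", index=False)
    print(table.to_string(index=False))

    # hit-rate ratio vs gain across the 8 value conditions
    trials = pd.read_csv(ROOT / "sim" / "exp3" / "trials.csv")
    gains = pd.read_csv(ROOT / "gains" / "gains.csv")
    ratios = hit_ratio_table(trials)
    means = gains.groupby("condition_id")["gain"].mean().rename("gain")
    joined = ratios.merge(means, on="condition_id")
    res = hit_rate_gain_regression(joined["gain"], joined["hit_ratio"])
    print(f"\nhit-rate ratio vs response gain: slope {res.slope:+.3f}, "
          f"p = {res.p_value:.4f}, R^2 = {res.r_squared:.2f}")
    joined.to_csv(outdir / "hit_ratio_vs_gain.csv", index=False)

    _plot_predictive_fit(gains, outdir)


def _plot_predictive_fit(gains, outdir):
    """Risk-sensitive posterior-predictive bands with condition-mean gains."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    bands = pd.read_csv(ROOT / "fits" / "predictive_value_risk.csv")
    bands = bands.sort_values("x")
    means = (gains.merge(bands[["condition_id", "x"]], on="condition_id")
             .groupby("condition_id").agg(x=("x", "first"),
                                          gain=("gain", "mean")))
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.fill_between(bands["x"], bands["lo95"], bands["hi95"],
                    color="0.85", label="95% credible region")
    ax.fill_between(bands["x"], bands["lo50"], bands["hi50"],
                    color="0.7", label="50% credible region")
    ax.plot(bands["x"], bands["mean"], "k-", lw=1)
    ax.plot(means["x"], means["gain"], "o", color="C3",
            label="condition means")
    ax.set_xlabel("risk-weighted log relative value")
    ax.set_ylabel("response gain (N)")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(outdir / "predictive_fit_value_risk.png", dpi=150)
    print(f"wrote {outdir / 'predictive_fit_value_risk.png'}")


if __name__ == "__main__":
    main()
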