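#!/usr/bin/env python
"""Learning curves and criterion sessions from the simulated cohort.

Reads results/trial_scores.csv and results/session_summaries.csv (written
by 01_simulate_behavior.py), smooths the two per-trial performance metrics
with a Gaussian kernel (SD 50 trials) over each mouse's cumulative trial
history, finds the first session better than 2.5 ports poked per trial,
and plots the group curves.
"""

import argparse
from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from soundseek.poke_metrics import find_criterion, smooth_by_trial


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    args = ap.parse_args()
    trials = pd.read_csv(args.out_dir / "trial_scores.csv")
    sessions = pd.read_csv(args.out_dir / "session_summaries.csv")

    curve_rows = []
    for subject, df in trials.groupby("subject"):
        df = df.sort_values(["session_idx", "trial"])
        for metric in ("correct", "ports_poked"):
            sm = smooth_by_trial(df[metric].to_numpy(float), sd_trials=50)
            curve_rows.append(pd.DataFrame({
                "subject": subject, "group": df["group"].iloc[0],
                "cum_trial": np.arange(len(sm)),
                "metric": metric, "smoothed": sm}))
    curves = pd.concat(curve_rows, ignore_index=True)
    # thin the exported table (the smoothed curve is slow-varying by design)
    curves[curves["cum_trial"] % 5 == 0].to_csv(
        args.out_dir / "learning_curves.csv", index=False, float_format="%.5g")

    crit_rows = []
    for subject, df in sessions.groupby("subject"):
        df = df.sort_values("session_idx")
        learn = df[df["phase"] == "learning"]
        idx = find_criterion(learn["mean_ports_poked"].to_numpy())
        n_trials = (learn["n_trials"].iloc[:idx + 1].sum()
                    if idx is not None else np.nan)
        crit_rows.append({"subject": subject, "group": df["group"].iloc[0],
                          "criterion_session": idx,
                          "criterion_cum_trials": n_trials})
    crit = pd.DataFrame(crit_rows)
    crit.to_csv(args.out_dir / "criterion_sessions.csv", index=False)

    fig, axes = plt.subplots(1, 2, figsize=(9, 3.5))
    for metric, ax, chance in (("correct", axes[0], 1 / 7),
                               ("ports_poked", axes[1], 4.0)):
        for subject, df in curves[curves["metric"] == metric].groupby("subject"):
            ax.plot(df["cum_trial"], df["smoothed"], lw=0.8, alpha=0.7)
        ax.axhline(chance, ls="--", c="k", lw=0.8)
        ax.set_xlabel("cumulative trial")
        ax.set_ylabel(f"smoothed {metric}")
    fig.tight_layout()
    fig.savefig(args.out_dir / "learning_curves.png", dpi=120)

    print("criterion (first session better than 2.5 ports poked):")
    print(crit.to_string(index=False))
    print(f"\nmedian criterion session: {crit['criterion_session'].median():.1f}; "
          f"median cumulative trials: {crit['criterion_cum_trials'].median():.0f}")
    print(f"wrote {args.out_dir}/learning_curves.csv, criterion_sessions.csv, "
          f"learning_curves.png")


if __name__ == "__main__":
    main()
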