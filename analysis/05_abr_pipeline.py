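#!/usr/bin/env python
"""ABR preprocessing on synthetic epochs over a conductive-loss grid.

Generates two-channel click-evoked epoch sets (wave template x attenuation
+ speaker cross-talk + noise + injected artifacts) at attenuations from 0
to 55 dB — spanning the threshold elevation produced by malleus removal —
runs the full pipeline (cross-talk removal, 100 Hz high-pass, top-5%
outlier rejection, orientation-corrected averaging), and checks that the
recovered wave amplitude tracks 10^(-attenuation/20).
"""

import argparse
from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from soundseek.abr import ABRRecording, highpass, process_recording, \
    template_amplitude
from soundseek.config import substream
from soundseek.synth import synth_abr

ATTENUATIONS = (0.0, 15.0, 30.0, 40.0, 55.0)
N_EPOCHS = 750


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)
    rng = substream(args.seed, "abr")

    rows, averages = [], {}
    target = None
    for att in ATTENUATIONS:
        for side in ("left", "right"):
            s = synth_abr(N_EPOCHS, attenuation_db=att, leak_gain=0.3,
                          noise_sd=0.05, artifact_frac=0.03, side=side,
                          seed=int(rng.integers(2**31)))
            if target is None:
                target = highpass(s.true_template[None, :], fs=s.fs)[0]
            res = process_recording(ABRRecording(fs=s.fs, epochs=s.neural,
                                                 speaker=s.speaker, side=side))
            amp = template_amplitude(res["average"], target)
            rows.append({"attenuation_db": att, "side": side,
                         "recovered_amplitude": amp,
                         "expected_amplitude": 10 ** (-att / 20.0),
                         "n_averaged": res["n_averaged"],
                         "kept_fraction": res["rejection"]["kept_fraction"]})
            if side == "right":
                averages[att] = (np.arange(len(res["average"])) / s.fs * 1000,
                                 res["average"])

    df = pd.DataFrame(rows)
    df.to_csv(args.out_dir / "abr_recovery.csv", index=False)
    print("recovered vs expected wave amplitude (matched filter, both sides):")
    print(df.round(4).to_string(index=False))
    r = np.corrcoef(df["recovered_amplitude"], df["expected_amplitude"])[0, 1]
    print(f"\nlinearity of amplitude recovery over the 0-55 dB grid: r = {r:.5f}")

    fig, ax = plt.subplots(figsize=(6, 3.5))
    for att, (t_ms, avg) in averages.items():
        ax.plot(t_ms, avg, label=f"{att:.0f} dB")
    ax.set_xlabel("time (ms)")
    ax.set_ylabel("averaged voltage (a.u.)")
    ax.legend(fontsize=7, title="attenuation")
    fig.tight_layout()
    fig.savefig(args.out_dir / "abr_averages.png", dpi=120)
    print(f"wrote {args.out_dir}/abr_recovery.csv, abr_averages.png")


if __name__ == "__main__":
    main()
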