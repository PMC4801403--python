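#!/usr/bin/env python
"""Build the 1-minute probability histograms of echolocating and silent
phase durations that feed the g(0) simulation, and plot them."""

from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from strikewatch import tags as tg

OUT = Path(__file__).resolve().parents[1] / "results"


def main():
    phases = tg.PhaseDurationSet.from_csv(OUT / "phase_durations.csv")
    hists = tg.phase_histograms(phases, bin_min=1.0)

    rows = []
    for name, (edges, probs) in hists.items():
        for lo, p in zip(edges[:-1], probs):
            rows.append({"phase": name, "bin_lo_min": lo, "prob": p})
    pd.DataFrame(rows).to_csv(OUT / "phase_histograms.csv", index=False)

    fig, axes = plt.subplots(1, 2, figsize=(9, 3.2), sharey=False)
    for ax, name, color in zip(axes, ("echo", "silent"), ("k", "grey")):
        edges, probs = hists[name]
        ax.bar(edges[:-1], probs, width=1.0, align="edge", color=color)
        ax.set_xlabel("duration (min)")
        ax.set_title(f"{name} phases")
    axes[0].set_ylabel("probability")
    fig.tight_layout()
    fig.savefig(OUT / "phase_histograms.png", dpi=150)
    print(f"histogram mass: echo bins to {hists['echo'][0][-1]:.0f} min, "
          f"silent bins to {hists['silent'][0][-1]:.0f} min")
    print(f"wrote {OUT / 'phase_histograms.csv'} and .png")


if __name__ == "__main__":
    main()
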