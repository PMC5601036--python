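#!/usr/bin/env python
"""Condition-mean figure: SC scores per group and condition (tempo-averaged).

Writes: results/condition_means.png (bar chart with per-participant points).
Run 03_group_stats.py first.
"""
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    res = ROOT / "results"
    cm = pd.read_csv(res / "condition_means.csv")
    cells = pd.read_csv(res / "cell_means.csv")
    pmeans = (
        cells.groupby(["group", "condition", "participant_id"])["SC"].mean().reset_index()
    )
    order = [
        ("hearing", "auditory"), ("hearing", "muff"), ("hearing", "mask"),
        ("deaf", "muff"), ("deaf", "mask"),
    ]
    fig, ax = plt.subplots(figsize=(6, 4))
    for i, (g, c) in enumerate(order):
        row = cm[(cm["group"] == g) & (cm["condition"] == c)]
        if row.empty:
            continue
        ax.bar(i, row["mean_SC"].iloc[0], yerr=row["sd_SC"].iloc[0],
               color="tab:blue" if g == "hearing" else "tab:orange",
               alpha=0.7, capsize=4)
        pts = pmeans[(pmeans["group"] == g) & (pmeans["condition"] == c)]["SC"]
        ax.plot([i] * len(pts), pts, "k.", ms=4, alpha=0.6)
    ax.set_xticks(range(len(order)))
    ax.set_xticklabels([f"{g}\n{c}" for g, c in order])
    ax.set_ylabel("synchronization consistency (SC)")
    fig.tight_layout()
    out = res / "condition_means.png"
    fig.savefig(out, dpi=150)
    print(f"-> {out}")


if __name__ == "__main__":
    main()
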