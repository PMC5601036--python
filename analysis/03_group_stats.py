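#!/usr/bin/env python
"""Group-level statistics on the per-trial SC scores.

Applies the trial and participant exclusion rules, averages the two trials
per cell, runs the condition x tempo repeated-measures ANOVA within each
group (with Holm-adjusted paired post-hocs for the hearing group), and the
two between-group pooled t-tests (deaf mask+muff average vs hearing mask and
vs hearing muff).

Writes: results/cell_means.csv, results/condition_means.csv,
results/anova_{hearing,deaf}.csv, results/posthoc_*.csv, results/report.md.
Run 02_analyze_trials.py first.
"""
from pathlib import Path

import pandas as pd

from beatsync import workflow
from beatsync.config import PipelineConfig

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    trial_csv = ROOT / "results" / "trial_results.csv"
    if not trial_csv.exists():
        raise SystemExit("run analysis/02_analyze_trials.py first")
    results = pd.read_csv(trial_csv)
    analysis = workflow.group_analysis(results, PipelineConfig())
    workflow.write_analysis_outputs(analysis, ROOT / "results")
    for group, res in analysis["anova"].items():
        e = res["condition"]
        print(
            f"{group}: condition F({e.df_num},{e.df_den}) = {e.F:.2f}, "
            f"p = {e.p:.4g}, partial eta^2 = {e.partial_eta_sq:.2f}"
        )
    for cond, c in analysis["group_comparisons"].items():
        print(
            f"groups @ {cond}: t({c['df']}) = {c['t']:.2f}, p = {c['p']:.3f} "
            f"(hearing {c['mean_hearing']:.2f} vs deaf {c['mean_deaf']:.2f})"
        )
    print(f"-> {ROOT / 'results' / 'report.md'}")


if __name__ == "__main__":
    main()
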