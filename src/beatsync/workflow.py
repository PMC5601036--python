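"""End-to-end orchestration: manifests/cohorts -> trial table -> group report.

Everything here is a thin composition of the stage modules so that the
command-line tool, the analysis drivers and the test suite all run the exact
same code paths.
"""
from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from . import circstats, groupstats, mocap_io, synth
from .config import PipelineConfig

logger = logging.getLogger("beatsync")

__all__ = [
    "analyze_manifest",
    "analyze_cohort",
    "group_analysis",
    "render_report",
]

TRIAL_RESULT_COLUMNS = [
    "participant_id",
    "group",
    "condition",
    "tempo_bpm",
    "trial_index",
    "n",
    "R",
    "mean_angle",
    "Z",
    "p",
    "V",
    "SC",
    "phase_locked",
    "axis",
]


def _result_row(meta: dict, result: circstats.SyncResult) -> dict:
    row = {k: meta.get(k) for k in
           ("participant_id", "group", "condition", "tempo_bpm", "trial_index")}
    row.update(result.as_row())
    return row


def analyze_manifest(manifest_path, config: PipelineConfig | None = None) -> pd.DataFrame:
    """Run the per-trial pipeline on every analyzable manifest row.

    Spontaneous-condition rows have no stimulus to synchronize to and are
    skipped (they are a movement-regularity screen, not a synchronization
    trial). Unreadable or degenerate trials are skipped with a logged error;
    the run fails only if no usable trial remains.
    """
    cfg = config or PipelineConfig()
    manifest_path = Path(manifest_path)
    manifest = mocap_io.read_manifest(manifest_path)
    base = manifest_path.parent
    rows = []
    stim_cache: dict[str, object] = {}
    for _, mrow in manifest.iterrows():
        meta = mrow.to_dict()
        if meta["condition"] == "spontaneous":
            logger.info("skipping spontaneous screening trial %s", meta["trial_file"])
            continue
        try:
            sfile = str(meta["stimulus_file"])
            if sfile not in stim_cache:
                stim_cache[sfile] = mocap_io.read_stimulus_csv(
                    base / sfile, tempo_bpm=float(meta["tempo_bpm"])
                )
            stimulus = stim_cache[sfile]
            trial = mocap_io.read_trial_tsv(
                base / str(meta["trial_file"]),
                axis_map=cfg.axis_map,
                participant_id=str(meta["participant_id"]),
                group=str(meta["group"]),
                condition=str(meta["condition"]),
                tempo_bpm=float(meta["tempo_bpm"]),
            )
            result = circstats.analyze_trial(trial, stimulus, cfg)
        except Exception as exc:  # per-trial robustness: log and move on
            logger.error("trial %s skipped: %s", meta.get("trial_file"), exc)
            continue
        rows.append(_result_row(meta, result))
    if not rows:
        raise RuntimeError("no analyzable trials in manifest")
    return pd.DataFrame(rows)[
        [c for c in TRIAL_RESULT_COLUMNS if c in rows[0]]
    ]


def analyze_cohort(
    design: synth.CohortDesign, seed: int, config: PipelineConfig | None = None
) -> pd.DataFrame:
    """Simulate a cohort in memory and run the per-trial pipeline on it."""
    cfg = config or PipelineConfig()
    rows = []
    for mrow, trial, stimulus in synth.generate_cohort(design, seed):
        result = circstats.analyze_trial(trial, stimulus, cfg)
        rows.append(_result_row(mrow, result))
    return pd.DataFrame(rows, columns=TRIAL_RESULT_COLUMNS)


def group_analysis(
    trial_results: pd.DataFrame, config: PipelineConfig | None = None
) -> dict:
    """Exclusions, aggregation, per-group ANOVAs and between-group t-tests.

    Returns a dict with the kept/excluded tables, the per-cell means, one
    ANOVA (+ post-hoc for the 3-condition hearing design) per group, the
    condition-mean summary, and the two between-group comparisons (deaf
    mask+muff average vs hearing mask, and vs hearing muff).
    """
    cfg = config or PipelineConfig()
    kept_trials, excluded_trials = groupstats.apply_trial_exclusions(
        trial_results, alpha=cfg.alpha
    )
    kept_trials, kept_pids, reasons = groupstats.apply_participant_exclusions(
        trial_results,
        kept_trials,
        outlier_cells=[tuple(c) for c in cfg.outlier_cells],
    )
    cells = groupstats.aggregate_cells(kept_trials)
    tempi = sorted(cells["tempo_bpm"].unique())

    out: dict = {
        "trial_results": trial_results,
        "kept_trials": kept_trials,
        "excluded_trials": excluded_trials,
        "participant_exclusions": reasons,
        "cells": cells,
        "anova": {},
        "posthoc": {},
    }
    group_conditions = {
        "hearing": ("auditory", "mask", "muff"),
        "deaf": ("mask", "muff"),
    }
    for group, conditions in group_conditions.items():
        gcells = cells[cells["group"] == group]
        conds = [c for c in conditions if c in set(gcells["condition"])]
        if len(conds) < 2 or len(tempi) < 2:
            continue
        complete = groupstats.complete_cases(gcells, conds, tempi)
        if complete["participant_id"].nunique() < 2:
            continue
        out["anova"][group] = groupstats.rm_anova(complete)
        if len(conds) >= 2:
            out["posthoc"][group] = groupstats.paired_posthoc(complete)

    # between-group comparisons on tempo-averaged scores
    deaf_cells = cells[cells["group"] == "deaf"]
    hearing_cells = cells[cells["group"] == "hearing"]
    comparisons = {}
    if len(deaf_cells) and len(hearing_cells):
        deaf_combined = groupstats.average_mask_muff(deaf_cells)
        for cond in ("mask", "muff"):
            hc = (
                hearing_cells[hearing_cells["condition"] == cond]
                .groupby("participant_id")["SC"]
                .mean()
            )
            if len(deaf_combined) >= 2 and len(hc) >= 2:
                t, df, p = groupstats.two_sample_t(hc.to_numpy(), deaf_combined.to_numpy())
                comparisons[cond] = {
                    "t": t,
                    "df": df,
                    "p": p,
                    "mean_hearing": float(hc.mean()),
                    "mean_deaf": float(deaf_combined.mean()),
                }
    out["group_comparisons"] = comparisons

    # Figure-2-style summary: per group x condition mean +- SD of
    # tempo-averaged participant scores
    pmeans = (
        cells.groupby(["group", "condition", "participant_id"])["SC"]
        .mean()
        .reset_index()
    )
    out["condition_means"] = (
        pmeans.groupby(["group", "condition"])["SC"]
        .agg(mean_SC="mean", sd_SC=lambda v: v.std(ddof=1), n="size")
        .reset_index()
    )
    return out


def _anova_md(name: str, res) -> str:
    lines = [f"### {name} group: condition x tempo repeated-measures ANOVA", ""]
    lines.append("| effect | F | df | p | partial eta^2 |")
    lines.append("|---|---|---|---|---|")
    for e in res.effects:
        lines.append(
            f"| {e.name} | {e.F:.3f} | ({e.df_num}, {e.df_den}) | "
            f"{e.p:.4g} | {e.partial_eta_sq:.3f} |"
        )
    return "\n".join(lines) + "\n"


def render_report(analysis: dict) -> str:
    """Markdown report: exclusions, condition means, ANOVAs, group tests."""
    if analysis is None or len(analysis.get("trial_results", [])) == 0:
        return "# Synchronization report\n\nNo data.\n"
    parts = ["# Synchronization report", ""]
    tr = analysis["trial_results"]
    ex = analysis["excluded_trials"]
    parts.append(
        f"Analyzed {len(tr)} trials; {len(ex)} not phase-locked "
        f"(Rayleigh p >= alpha) and excluded."
    )
    pex = analysis["participant_exclusions"]
    if len(pex):
        for _, r in pex.iterrows():
            parts.append(f"- participant {r['participant_id']} excluded: {r['reason']}")
    else:
        parts.append("- no participants excluded")
    parts.append("")
    parts.append("## Condition means (SC, averaged across tempi)")
    parts.append("")
    parts.append("| group | condition | mean SC | SD | n |")
    parts.append("|---|---|---|---|---|")
    for _, r in analysis["condition_means"].iterrows():
        parts.append(
            f"| {r['group']} | {r['condition']} | {r['mean_SC']:.3f} | "
            f"{r['sd_SC']:.3f} | {int(r['n'])} |"
        )
    parts.append("")
    for group, res in analysis["anova"].items():
        parts.append(_anova_md(group, res))
        ph = analysis["posthoc"].get(group)
        if ph is not None and len(ph):
            parts.append(f"Post-hoc paired t-tests ({group}), Holm-adjusted:")
            parts.append("")
            parts.append("| pair | t | df | p (Holm) |")
            parts.append("|---|---|---|---|")
            for _, r in ph.iterrows():
                parts.append(
                    f"| {r['level_a']} vs {r['level_b']} | {r['t']:.3f} | "
                    f"{int(r['df'])} | {r['p_holm']:.4g} |"
                )
            parts.append("")
    if analysis["group_comparisons"]:
        parts.append("## Between-group comparisons (deaf mask+muff average)")
        parts.append("")
        parts.append("| hearing condition | t | df | p | mean hearing | mean deaf |")
        parts.append("|---|---|---|---|---|---|")
        for cond, c in analysis["group_comparisons"].items():
            parts.append(
                f"| {cond} | {c['t']:.3f} | {c['df']} | {c['p']:.4g} | "
                f"{c['mean_hearing']:.3f} | {c['mean_deaf']:.3f} |"
            )
        parts.append("")
    return "\n".join(parts)


def write_analysis_outputs(analysis: dict, out_dir) -> None:
    """Write the tidy CSV artifacts plus the markdown report."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    analysis["trial_results"].to_csv(out / "trial_results.csv", index=False)
    analysis["cells"].to_csv(out / "cell_means.csv", index=False)
    analysis["condition_means"].to_csv(out / "condition_means.csv", index=False)
    analysis["excluded_trials"].to_csv(out / "excluded_trials.csv", index=False)
    analysis["participant_exclusions"].to_csv(
        out / "participant_exclusions.csv", index=False
    )
    for group, res in analysis["anova"].items():
        res.to_frame().to_csv(out / f"anova_{group}.csv", index=False)
    for group, ph in analysis["posthoc"].items():
        ph.to_csv(out / f"posthoc_{group}.csv", index=False)
    (out / "report.md").write_text(render_report(analysis))
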