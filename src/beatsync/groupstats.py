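"""Exclusion rules, per-cell aggregation, and group-level inference.

Workflow on a table of per-trial synchronization results:

1. drop trials that were not phase-locked (Rayleigh p >= alpha);
2. drop participants who failed to lock on more than half of their trials,
   then participants whose mean SC in a designated cell (by default the
   hearing group's auditory condition) falls strictly below the group mean
   minus two SD;
3. average the (up to two) surviving trials per participant x condition x
   tempo cell;
4. two-way fully-within-subject repeated-measures ANOVA per group
   (condition x tempo) with partial eta squared, uncorrected degrees of
   freedom, and Holm-adjusted paired-t post-hocs;
5. between-group pooled-variance Student t-tests on tempo-averaged scores,
   with the deaf group's two vibrotactile conditions averaged.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .core import InvalidParameterError

__all__ = [
    "apply_trial_exclusions",
    "apply_participant_exclusions",
    "aggregate_cells",
    "rm_anova",
    "holm_posthoc",
    "paired_posthoc",
    "two_sample_t",
    "average_mask_muff",
    "AnovaResult",
]

REQUIRED_TRIAL_COLUMNS = (
    "participant_id",
    "group",
    "condition",
    "tempo_bpm",
    "SC",
    "p",
    "phase_locked",
)


def apply_trial_exclusions(
    results: pd.DataFrame, alpha: float = 0.001
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split trials into (kept, excluded) by the Rayleigh phase-locking rule."""
    if len(results) == 0:
        return results.copy(), results.copy()
    if "p" not in results.columns:
        raise InvalidParameterError("results table needs a Rayleigh 'p' column")
    locked = results["p"] < alpha
    kept = results[locked].copy()
    excluded = results[~locked].copy()
    excluded["exclusion_reason"] = "not_phase_locked"
    return kept, excluded


def apply_participant_exclusions(
    all_trials: pd.DataFrame,
    kept_trials: pd.DataFrame,
    outlier_cells: list | tuple = (("hearing", "auditory"),),
    sd_factor: float = 2.0,
) -> tuple[pd.DataFrame, list[str], pd.DataFrame]:
    """Apply the two participant-level exclusion rules.

    Rule 1 (on *all* trials): a participant whose non-phase-locked trials
    exceed half of their trials is removed entirely. Rule 2 (on the
    remainder): within each designated (group, condition) cell, a participant
    whose mean SC is strictly below the group mean minus ``sd_factor`` SD —
    the SD computed including the candidate — is removed. A cell with fewer
    than 3 participants skips rule 2 with a warning entry.

    Returns (kept trial rows, kept participant ids, reasons table).
    """
    reasons: list[dict] = []
    # rule 1: majority of trials unlocked
    per_pid = all_trials.groupby("participant_id")["phase_locked"].agg(["size", "sum"])
    rule1_out = per_pid[(per_pid["size"] - per_pid["sum"]) > per_pid["size"] / 2].index
    for pid in rule1_out:
        reasons.append({"participant_id": pid, "reason": "majority_unlocked"})
    kept = kept_trials[~kept_trials["participant_id"].isin(rule1_out)].copy()

    # rule 2: low-outlier mean SC in designated cells
    import warnings

    for group, condition in outlier_cells:
        cell = kept[(kept["group"] == group) & (kept["condition"] == condition)]
        means = cell.groupby("participant_id")["SC"].mean()
        if len(means) < 3:
            warnings.warn(
                f"outlier rule skipped for ({group}, {condition}): "
                f"only {len(means)} participants",
                RuntimeWarning,
                stacklevel=2,
            )
            continue
        cutoff = means.mean() - sd_factor * means.std(ddof=1)
        outliers = means[means < cutoff].index  # strictly below
        for pid in outliers:
            reasons.append(
                {
                    "participant_id": pid,
                    "reason": f"low_outlier_{group}_{condition}",
                }
            )
        kept = kept[~kept["participant_id"].isin(outliers)]
    kept_pids = sorted(set(kept["participant_id"]))
    reasons_df = pd.DataFrame(reasons, columns=["participant_id", "reason"])
    return kept, kept_pids, reasons_df


def aggregate_cells(kept_trials: pd.DataFrame) -> pd.DataFrame:
    """Mean SC per participant x condition x tempo cell over surviving trials.

    Cells that lost every trial simply do not appear; downstream balanced
    analyses apply listwise deletion via :func:`complete_cases`.
    """
    g = kept_trials.groupby(
        ["participant_id", "group", "condition", "tempo_bpm"], as_index=False
    ).agg(SC=("SC", "mean"), n_trials=("SC", "size"))
    return g


def complete_cases(cells: pd.DataFrame, conditions, tempi) -> pd.DataFrame:
    """Listwise deletion: keep participants with every condition x tempo cell."""
    need = len(conditions) * len(tempi)
    sub = cells[cells["condition"].isin(conditions) & cells["tempo_bpm"].isin(tempi)]
    counts = sub.groupby("participant_id")["SC"].size()
    full = counts[counts == need].index
    return sub[sub["participant_id"].isin(full)].copy()


@dataclass
class AnovaEffect:
    name: str
    ss: float
    df_num: int
    df_den: int
    ms: float
    ms_error: float
    F: float
    p: float
    partial_eta_sq: float


@dataclass
class AnovaResult:
    """Two-way fully-within-subject ANOVA table."""

    effects: list
    ss_subject: float
    ss_total: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "effect": e.name,
                    "F": e.F,
                    "df_num": e.df_num,
                    "df_den": e.df_den,
                    "p": e.p,
                    "partial_eta_sq": e.partial_eta_sq,
                }
                for e in self.effects
            ]
        )

    def __getitem__(self, name: str) -> AnovaEffect:
        for e in self.effects:
            if e.name == name:
                return e
        raise KeyError(name)


def rm_anova(
    data: pd.DataFrame,
    dv: str = "SC",
    subject: str = "participant_id",
    factors: tuple[str, str] = ("condition", "tempo_bpm"),
) -> AnovaResult:
    """Balanced two-way fully-within-subject repeated-measures ANOVA.

    Definitional sums-of-squares partition (subject, two main effects, their
    interaction, and one subject-by-effect error term per effect);
    ``F = MS_effect / MS_(effect x subject)``;
    ``partial eta^2 = SS_effect / (SS_effect + SS_error_effect)``.
    Sphericity is not corrected, so the degrees of freedom are the balanced-
    design values (e.g. a 3-level factor with 14 subjects gives df (2, 26)).
    Requires exactly one observation per subject x cell (aggregate and apply
    listwise deletion first).
    """
    fa, fb = factors
    for col in (dv, subject, fa, fb):
        if col not in data.columns:
            raise InvalidParameterError(f"missing column {col!r}")
    a_levels = sorted(data[fa].unique())
    b_levels = sorted(data[fb].unique())
    subjects = sorted(data[subject].unique())
    a, b, s = len(a_levels), len(b_levels), len(subjects)
    if a < 2 or b < 2:
        raise InvalidParameterError(
            f"both factors need >= 2 levels (got {a} x {b})"
        )
    counts = data.groupby([subject, fa, fb])[dv].size()
    if len(counts) != a * b * s or not (counts == 1).all():
        raise InvalidParameterError(
            "design must be balanced with exactly one observation per "
            "subject x cell; aggregate trials and apply listwise deletion first"
        )

    y = data.set_index([subject, fa, fb])[dv].astype(float)
    gm = y.mean()
    mean_s = y.groupby(level=0).mean()
    mean_a = y.groupby(level=1).mean()
    mean_b = y.groupby(level=2).mean()
    mean_ab = y.groupby(level=[1, 2]).mean()
    mean_sa = y.groupby(level=[0, 1]).mean()
    mean_sb = y.groupby(level=[0, 2]).mean()

    ss_total = float(((y - gm) ** 2).sum())
    ss_subject = float(a * b * ((mean_s - gm) ** 2).sum())
    ss_a = float(s * b * ((mean_a - gm) ** 2).sum())
    ss_b = float(s * a * ((mean_b - gm) ** 2).sum())
    dev_ab = mean_ab - gm
    dev_ab = dev_ab.sub(mean_a - gm, level=0).sub(mean_b - gm, level=1)
    ss_ab = float(s * (dev_ab**2).sum())
    dev_sa = mean_sa - gm
    dev_sa = dev_sa.sub(mean_s - gm, level=0).sub(mean_a - gm, level=1)
    ss_sa = float(b * (dev_sa**2).sum())
    dev_sb = mean_sb - gm
    dev_sb = dev_sb.sub(mean_s - gm, level=0).sub(mean_b - gm, level=1)
    ss_sb = float(a * (dev_sb**2).sum())
    ss_sab = ss_total - (ss_subject + ss_a + ss_b + ss_ab + ss_sa + ss_sb)
    ss_sab = max(ss_sab, 0.0)

    def effect(name, ss, dfn, ss_err, dfd) -> AnovaEffect:
        ms = ss / dfn
        mse = ss_err / dfd
        F = ms / mse if mse > 0 else (0.0 if ss == 0 else np.inf)
        p = float(scipy.stats.f.sf(F, dfn, dfd)) if np.isfinite(F) else 0.0
        eta = ss / (ss + ss_err) if (ss + ss_err) > 0 else 0.0
        return AnovaEffect(name, ss, dfn, dfd, ms, mse, F, p, eta)

    effects = [
        effect(fa, ss_a, a - 1, ss_sa, (a - 1) * (s - 1)),
        effect(fb, ss_b, b - 1, ss_sb, (b - 1) * (s - 1)),
        effect(
            f"{fa}*{fb}", ss_ab, (a - 1) * (b - 1), ss_sab, (a - 1) * (b - 1) * (s - 1)
        ),
    ]
    return AnovaResult(effects=effects, ss_subject=ss_subject, ss_total=ss_total)


def holm_posthoc(pairwise_p) -> np.ndarray:
    """Bonferroni-Holm step-down adjustment of raw p-values (capped at 1)."""
    p = np.asarray(pairwise_p, dtype=float).ravel()
    if p.size < 1:
        raise InvalidParameterError("need at least one p-value")
    if np.any((p < 0) | (p > 1)):
        raise InvalidParameterError("p-values must lie in [0, 1]")
    return multipletests(p, method="holm")[1]


def paired_posthoc(
    cells: pd.DataFrame,
    factor: str = "condition",
    dv: str = "SC",
    subject: str = "participant_id",
) -> pd.DataFrame:
    """Paired t-tests between all factor levels (averaged over the other
    factor per participant), Holm-adjusted."""
    means = cells.groupby([subject, factor])[dv].mean().unstack(factor)
    levels = list(means.columns)
    rows = []
    for i in range(len(levels)):
        for j in range(i + 1, len(levels)):
            x, y = means[levels[i]], means[levels[j]]
            t, p = scipy.stats.ttest_rel(x, y)
            rows.append(
                {
                    "level_a": levels[i],
                    "level_b": levels[j],
                    "mean_diff": float((x - y).mean()),
                    "t": float(t),
                    "df": len(x) - 1,
                    "p_raw": float(p),
                }
            )
    out = pd.DataFrame(rows)
    if len(out):
        out["p_holm"] = holm_posthoc(out["p_raw"].to_numpy())
    return out


def two_sample_t(group_a, group_b, pooled: bool = True) -> tuple[float, int, float]:
    """Pooled-variance Student t-test; df = n_a + n_b - 2.

    With 14 and 7 participants this gives df = 19. Two identical constant
    groups return t = 0, p = 1 by convention.
    """
    x = np.asarray(group_a, dtype=float)
    y = np.asarray(group_b, dtype=float)
    if x.size < 2 or y.size < 2:
        raise InvalidParameterError("each group needs n >= 2")
    df = x.size + y.size - 2
    if np.var(x, ddof=1) == 0 and np.var(y, ddof=1) == 0 and x.mean() == y.mean():
        return 0.0, df, 1.0
    t, p = scipy.stats.ttest_ind(x, y, equal_var=pooled)
    return float(t), df, float(p)


def average_mask_muff(
    cells: pd.DataFrame,
    conditions: tuple[str, str] = ("mask", "muff"),
    dv: str = "SC",
) -> pd.Series:
    """Per-participant mean over the two vibrotactile conditions and tempi.

    Participants missing either condition are dropped (flagged by omission).
    Used for the deaf group, whose mask/muff conditions do not differ and are
    therefore pooled before the between-group comparisons; the hearing group
    keeps its conditions separate.
    """
    sub = cells[cells["condition"].isin(conditions)]
    have_both = sub.groupby("participant_id")["condition"].nunique()
    full = have_both[have_both == len(conditions)].index
    sub = sub[sub["participant_id"].isin(full)]
    return sub.groupby("participant_id")[dv].mean()
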