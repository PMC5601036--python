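"""Calibration and verification experiments for the whole pipeline.

Each function runs one self-contained experiment — structural pipeline
numbers, oracle equivalence of the circular statistics, type-I calibration of
the phase-locking decision, generative-parameter recovery, ANOVA/t oracle
agreement, and end-to-end group-effect checks on simulated cohorts — and
returns plain dicts of numbers. They are used by the test suite and by
``scripts/acceptance.py``; nothing here asserts, so callers choose their own
tolerances.
"""
from __future__ import annotations

import math

import numpy as np
import pandas as pd
import scipy.stats

from . import groupstats, synth, workflow
from .circstats import mean_resultant, rayleigh_test, sc_score
from .config import PipelineConfig
from .core import wrap_angle
from .phase import passband_edges
from .synth import BounceParams, CohortDesign, generate_beat_onsets, simulate_bounce_trial


def structural_numbers() -> dict:
    """Desk-check numbers of the default pipeline configuration.

    Retained beats of a 128-beat trial after the default 10-lead/3-tail
    exclusion, the filter passband width relative to the beat frequency, and
    the marker count of a default full-body synthetic trial.
    """
    from .circstats import analyze_trial

    stim = generate_beat_onsets(120.0, 128)
    trial = simulate_bounce_trial(BounceParams(seed=0), stim)
    result = analyze_trial(trial, stim)
    low, high = passband_edges(stim.beat_freq_hz, PipelineConfig().rel_bandwidth)
    return {
        "retained_beats": result.n,
        "passband_width_over_beat_freq": (high - low) / stim.beat_freq_hz,
        "n_marker_trajectories": trial.n_markers,
    }


def _summation_oracle(phases: np.ndarray) -> tuple[float, float, float]:
    """R, V, Z by direct scalar trigonometric summation (independent route)."""
    c = s = 0.0
    for ph in phases:
        c += math.cos(ph)
        s += math.sin(ph)
    n = len(phases)
    R = math.hypot(c / n, s / n)
    return R, 1.0 - R, n * R * R


def circstats_oracle_diffs(n_sets: int = 1000, seed: int = 0) -> dict:
    """Max |difference| between the implementation and the summation oracle
    for R, V and Z over random phase sets of varying size and concentration."""
    rng = np.random.default_rng(seed)
    max_dr = max_dv = max_dz = 0.0
    for _ in range(n_sets):
        n = int(rng.integers(5, 200))
        kappa = float(rng.uniform(0.0, 8.0))
        phases = rng.vonmises(rng.uniform(-np.pi, np.pi), kappa, size=n)
        R0, V0, Z0 = _summation_oracle(phases)
        R, _ = mean_resultant(phases)
        Z, _, _ = rayleigh_test(phases)
        max_dr = max(max_dr, abs(R - R0))
        max_dv = max(max_dv, abs((1.0 - R) - V0))
        max_dz = max(max_dz, abs(Z - Z0))
    return {"max_dR": max_dr, "max_dV": max_dv, "max_dZ": max_dz}


def rayleigh_mc_comparison(
    n_values: tuple[int, ...] = (7, 20, 115),
    n_sim: int = 100_000,
    seed: int = 0,
) -> list[dict]:
    """Series-approximation p vs a Monte-Carlo uniform null, per sample size.

    The observed sample is drawn at moderate concentration so the true p is
    neither ~1 nor vanishingly small, where a 100k-draw null resolves it.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for n in n_values:
        kappa = {7: 1.0, 20: 0.6, 115: 0.25}.get(n, 0.5)
        phases = rng.vonmises(0.0, kappa, size=n)
        R, _ = mean_resultant(phases)
        _, p_approx, _ = rayleigh_test(phases)
        null = rng.uniform(-np.pi, np.pi, size=(n_sim, n))
        null_R = np.abs(np.mean(np.exp(1j * null), axis=1))
        p_mc = (1 + int(np.count_nonzero(null_R >= R))) / (n_sim + 1)
        se = math.sqrt(max(p_mc * (1 - p_mc), 1e-12) / n_sim)
        rows.append({"n": n, "p_approx": p_approx, "p_mc": p_mc, "mc_se": se})
    return rows


def type1_calibration(
    n: int = 115, reps: int = 10_000, alpha: float = 0.001, seed: int = 0
) -> dict:
    """Phase-locked rate under the uniform null, with the exact binomial 99%
    acceptance interval around alpha."""
    rng = np.random.default_rng(seed)
    phases = rng.uniform(-np.pi, np.pi, size=(reps, n))
    R = np.abs(np.mean(np.exp(1j * phases), axis=1))
    Rn = n * R
    p = np.exp(np.sqrt(1 + 4 * n + 4 * (n**2 - Rn**2)) - (1 + 2 * n))
    hits = int(np.count_nonzero(p < alpha))
    lo = int(scipy.stats.binom.ppf(0.005, reps, alpha))
    hi = int(scipy.stats.binom.ppf(0.995, reps, alpha))
    return {"reps": reps, "hits": hits, "rate": hits / reps, "ci_lo": lo, "ci_hi": hi}


def parameter_recovery(
    trials_per_level: int = 100,
    noise_levels: tuple[float, ...] = (0.0, 0.3, 0.8, 1.5),
    kappa: float = 4.0,
    mean_lag: float = 0.5,
    seed: int = 0,
) -> dict:
    """End-to-end generative-parameter recovery on full-length trials.

    Part 1: trials with per-beat von Mises jitter (concentration ``kappa``)
    and a known mean lag; reports the circular-mean recovery error of the
    mean angle across trials. Part 2: trials with random-walk phase noise at
    each SD in ``noise_levels``; reports the median SC (computed from the
    circular variance, which is defined for locked and unlocked trials alike)
    per level, plus the skewness of the SC distribution at the second level.
    """
    rng = np.random.default_rng(seed)
    stim = generate_beat_onsets(120.0, 128)
    from .circstats import analyze_trial

    errs = []
    for _ in range(trials_per_level):
        p = BounceParams(
            mean_lag_rad=mean_lag, phase_noise_sd=0.0, kappa=kappa,
            n_markers=1, seed=int(rng.integers(2**31 - 1)),
        )
        res = analyze_trial(simulate_bounce_trial(p, stim), stim)
        errs.append(wrap_angle(res.mean_angle_rad - mean_lag))
    recovery_err = abs(float(np.angle(np.mean(np.exp(1j * np.asarray(errs))))))

    median_sc = []
    skew_level = None
    for level_idx, sd in enumerate(noise_levels):
        scs = []
        for _ in range(trials_per_level):
            p = BounceParams(
                phase_noise_sd=sd, n_markers=1, seed=int(rng.integers(2**31 - 1))
            )
            res = analyze_trial(simulate_bounce_trial(p, stim), stim)
            scs.append(sc_score(max(res.circ_variance_V, 1e-300)))
        median_sc.append(float(np.median(scs)))
        if level_idx == 1:
            skew_level = float(scipy.stats.skew(np.asarray(scs)))
    return {
        "mean_angle_recovery_err_rad": recovery_err,
        "noise_levels": list(noise_levels),
        "median_sc_per_level": median_sc,
        "sc_skewness_mid_level": skew_level,
    }


def random_within_table(
    rng: np.random.Generator, n_subjects: int = 14, a: int = 3, b: int = 3
) -> pd.DataFrame:
    rows = []
    for s in range(n_subjects):
        subj_shift = rng.normal(0, 0.5)
        for i in range(a):
            for j in range(b):
                rows.append(
                    {
                        "participant_id": f"S{s:02d}",
                        "condition": f"c{i}",
                        "tempo_bpm": float(110 + 5 * j),
                        "SC": rng.normal(2.0 + subj_shift + 0.2 * i, 0.4),
                    }
                )
    return pd.DataFrame(rows)


def anova_oracle_check(n_tables: int = 50, seed: int = 0) -> dict:
    """Max |F| / |p| / |partial eta^2| discrepancy between the package ANOVA
    and an independent established implementation over random balanced
    tables, plus the design degrees of freedom and the pooled-t df."""
    from statsmodels.stats.anova import AnovaRM

    rng = np.random.default_rng(seed)
    max_df_f = max_df_p = max_d_eta = 0.0
    for _ in range(n_tables):
        table = random_within_table(rng)
        ours = groupstats.rm_anova(table)
        sm = AnovaRM(
            table, depvar="SC", subject="participant_id",
            within=["condition", "tempo_bpm"],
        ).fit().anova_table
        for effect, key in [
            ("condition", "condition"),
            ("tempo_bpm", "tempo_bpm"),
            ("condition*tempo_bpm", "condition:tempo_bpm"),
        ]:
            e = ours[effect]
            max_df_f = max(max_df_f, abs(e.F - sm.loc[key, "F Value"]))
            max_df_p = max(max_df_p, abs(e.p - sm.loc[key, "Pr > F"]))
            eta_from_f = e.F * e.df_num / (e.F * e.df_num + e.df_den)
            max_d_eta = max(max_d_eta, abs(e.partial_eta_sq - eta_from_f))
    res = groupstats.rm_anova(random_within_table(rng))
    _, t_df, _ = groupstats.two_sample_t(
        rng.normal(size=14), rng.normal(size=7)
    )
    return {
        "max_dF": max_df_f,
        "max_dp": max_df_p,
        "max_deta": max_d_eta,
        "condition_df": (res["condition"].df_num, res["condition"].df_den),
        "interaction_df": (
            res["condition*tempo_bpm"].df_num,
            res["condition*tempo_bpm"].df_den,
        ),
        "pooled_t_df_14_vs_7": t_df,
    }


def condition_ordering_check(seed: int = 0) -> dict:
    """One full default cohort: do the hearing-group condition means reproduce
    the planted auditory > muff > mask ordering?"""
    design = CohortDesign(n_markers=1)
    results = workflow.analyze_cohort(design, seed)
    analysis = workflow.group_analysis(results, PipelineConfig())
    cm = analysis["condition_means"]
    hearing = cm[cm["group"] == "hearing"].set_index("condition")["mean_SC"]
    return {
        "auditory": float(hearing["auditory"]),
        "muff": float(hearing["muff"]),
        "mask": float(hearing["mask"]),
        "ordering_ok": bool(
            hearing["auditory"] > hearing["muff"] > hearing["mask"]
        ),
        "analysis": analysis,
    }


def muff_detection_power(n_cohorts: int = 200, seed: int = 0) -> dict:
    """Detection rate of the planted deaf-vs-hearing muff difference.

    Each cohort simulates both groups' vibrotactile conditions at the default
    planted effect, runs the full pipeline and group analysis, and counts a
    detection when the muff between-group t-test is significant at 0.05 with
    the hearing group ahead. The mask comparison's false-detection rate (no
    planted difference there) is reported alongside.
    """
    rng = np.random.default_rng(seed)
    design = CohortDesign(
        n_markers=1,
        conditions={"deaf": ("mask", "muff"), "hearing": ("mask", "muff")},
    )
    cfg = PipelineConfig(outlier_cells=[])
    detected = 0
    mask_hits = 0
    usable = 0
    for _ in range(n_cohorts):
        cohort_seed = int(rng.integers(2**31 - 1))
        results = workflow.analyze_cohort(design, cohort_seed)
        analysis = workflow.group_analysis(results, cfg)
        comp = analysis["group_comparisons"]
        if "muff" not in comp:
            continue
        usable += 1
        muff = comp["muff"]
        if muff["p"] < 0.05 and muff["mean_hearing"] > muff["mean_deaf"]:
            detected += 1
        mask = comp.get("mask")
        if mask is not None and mask["p"] < 0.05:
            mask_hits += 1
    return {
        "n_cohorts": usable,
        "muff_detection_rate": detected / usable if usable else float("nan"),
        "mask_significance_rate": mask_hits / usable if usable else float("nan"),
    }
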