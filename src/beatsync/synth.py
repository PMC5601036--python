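"""Synthetic stimulus timelines and bouncing-movement motion-capture trials.

The generator emulates a participant bouncing (knee flexion) in time with an
isochronous beat: a dominant-axis sinusoidal displacement whose phase is
coupled to the stimulus with a controllable steady-state lag and a
controllable phase-noise process, plus secondary-axis harmonics, broadband
measurement noise, and a startup transient during which the mover converges
from their own spontaneous tempo onto the stimulus tempo.

Phase convention: the dominant-axis displacement is ``A*cos(phi(t))`` with
``phi(t) = stimulus_phase(t) + mean_lag + eps(t)`` after the startup
transient, so the Hilbert instantaneous phase sampled at beat onsets equals
the generative relative phase directly (at a beat the stimulus phase is 0
mod 2*pi).

Two phase-noise modes are available and may be combined:

* a Brownian random walk in phase with standard deviation ``phase_noise_sd``
  radians per sqrt(second) — slow wander of the relative phase, which is what
  gives circular variance its lognormal-like spread across trials;
* per-beat von Mises jitter with concentration ``kappa`` — fast,
  beat-to-beat timing scatter.

All randomness flows from one integer seed through a named
``numpy.random.Generator``; identical parameters and seed give bit-identical
trials.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (
    AXES,
    ConfigError,
    InvalidParameterError,
    StimulusTrack,
    TrialRecording,
)

__all__ = [
    "BounceParams",
    "CohortDesign",
    "DEFAULT_MARKERS",
    "generate_beat_onsets",
    "simulate_bounce_trial",
    "simulate_unsynced_trial",
    "generate_cohort",
    "write_cohort",
]

#: The 28-marker full-body set: hips (4), shoulders (4), elbows (2), hands (2),
#: knees (2), heels (2), toes (4), head (8).
DEFAULT_MARKERS: tuple[str, ...] = (
    "hip_LF", "hip_RF", "hip_LB", "hip_RB",
    "shoulder_LF", "shoulder_RF", "shoulder_LB", "shoulder_RB",
    "elbow_L", "elbow_R",
    "hand_L", "hand_R",
    "knee_L", "knee_R",
    "heel_L", "heel_R",
    "toe_L_in", "toe_L_out", "toe_R_in", "toe_R_out",
    "head_1", "head_2", "head_3", "head_4",
    "head_5", "head_6", "head_7", "head_8",
)

#: Marker that carries the analysis signal.
SIGNAL_MARKER = "knee_R"


def generate_beat_onsets(
    tempo_bpm: float, n_beats: int, start_offset_s: float = 0.0
) -> StimulusTrack:
    """Isochronous beat timeline: ``onsets[k] = start_offset_s + k*60/tempo``."""
    if tempo_bpm <= 0:
        raise InvalidParameterError(f"tempo_bpm must be > 0, got {tempo_bpm}")
    if n_beats < 1:
        raise InvalidParameterError(f"n_beats must be >= 1, got {n_beats}")
    onsets = start_offset_s + np.arange(n_beats) * (60.0 / tempo_bpm)
    return StimulusTrack(tempo_bpm=tempo_bpm, onsets=onsets)


@dataclass(frozen=True)
class BounceParams:
    """Generative parameters of one synthetic bouncing trial.

    Parameters
    ----------
    mean_lag_rad : float
        Intended steady-state relative phase between movement and beat.
    phase_noise_sd : float
        Random-walk phase jitter, radians per sqrt(second). 0 = perfect lock.
    kappa : float or None
        Optional von Mises concentration for per-beat jitter; None disables.
    own_tempo_bpm : float
        The mover's spontaneous tempo, used before lock and in unsynced trials.
    amplitude_mm : float
        Dominant-axis oscillation amplitude.
    dominant_axis : str
        One of "vertical", "anteroposterior", "mediolateral".
    startup_s : float
        Transient during which frequency ramps linearly from own tempo to the
        stimulus tempo.
    noise_mm : float
        Broadband Gaussian measurement noise SD on every coordinate.
    n_markers : int
        Markers emitted; "knee_R" always carries the full signal, the others
        are attenuated copies.
    seed : int
        Seed of the trial's private random generator.
    """

    mean_lag_rad: float = 0.0
    phase_noise_sd: float = 0.10
    kappa: float | None = None
    own_tempo_bpm: float = 100.0
    amplitude_mm: float = 40.0
    dominant_axis: str = "anteroposterior"
    startup_s: float = 5.0
    noise_mm: float = 1.0
    n_markers: int = 28
    seed: int = 0

    def __post_init__(self) -> None:
        if self.amplitude_mm <= 0:
            raise InvalidParameterError("amplitude_mm must be > 0")
        if self.startup_s < 0:
            raise InvalidParameterError("startup_s must be >= 0")
        if self.phase_noise_sd < 0:
            raise InvalidParameterError("phase_noise_sd must be >= 0")
        if self.noise_mm < 0:
            raise InvalidParameterError("noise_mm must be >= 0")
        if self.n_markers < 1:
            raise InvalidParameterError("n_markers must be >= 1")
        if self.dominant_axis not in AXES:
            raise InvalidParameterError(
                f"dominant_axis must be one of {AXES}, got {self.dominant_axis!r}"
            )
        if self.own_tempo_bpm <= 0:
            raise InvalidParameterError("own_tempo_bpm must be > 0")


def _marker_list(n_markers: int) -> tuple[str, ...]:
    """knee_R first, then the remaining full-body markers in canonical order."""
    others = [m for m in DEFAULT_MARKERS if m != SIGNAL_MARKER]
    if n_markers <= len(DEFAULT_MARKERS):
        return (SIGNAL_MARKER, *others[: n_markers - 1])
    extra = [f"aux_{i}" for i in range(n_markers - len(DEFAULT_MARKERS))]
    return (SIGNAL_MARKER, *others, *extra)


def _axis_signals(phi: np.ndarray, amplitude_mm: float, dominant_axis: str) -> np.ndarray:
    """Stack (n, 3) axis displacements in X/Y/Z order for a given total phase.

    The dominant axis carries the full-amplitude fundamental; one secondary
    axis carries a half-amplitude fundamental plus a second harmonic (the
    knee rises twice as sharply as it drops during a bounce); the remaining
    axis carries a small residual sway.
    """
    dominant = amplitude_mm * np.cos(phi)
    secondary = 0.5 * amplitude_mm * np.cos(phi - 0.4) + 0.12 * amplitude_mm * np.cos(2 * phi)
    tertiary = 0.05 * amplitude_mm * np.cos(phi + 1.1)
    # secondary axis: vertical unless vertical is dominant, then anteroposterior
    sec_axis = "vertical" if dominant_axis != "vertical" else "anteroposterior"
    out = np.empty((phi.size, 3))
    for i, ax in enumerate(AXES):
        if ax == dominant_axis:
            out[:, i] = dominant
        elif ax == sec_axis:
            out[:, i] = secondary
        else:
            out[:, i] = tertiary
    return out


def _assemble_trial(
    phi: np.ndarray,
    params: BounceParams,
    fs_hz: float,
    rng: np.random.Generator,
    **meta,
) -> TrialRecording:
    axes = _axis_signals(phi, params.amplitude_mm, params.dominant_axis)
    names = _marker_list(params.n_markers)
    n = phi.size
    positions = np.empty((n, params.n_markers, 3))
    # per-marker attenuation and static body-geometry offset
    gains = rng.uniform(0.2, 0.7, size=params.n_markers)
    gains[0] = 1.0  # knee_R carries the full signal
    offsets = np.column_stack(
        [
            rng.uniform(-400.0, 400.0, size=params.n_markers),
            rng.uniform(-400.0, 400.0, size=params.n_markers),
            rng.uniform(100.0, 1800.0, size=params.n_markers),
        ]
    )
    for m in range(params.n_markers):
        positions[:, m, :] = gains[m] * axes + offsets[m]
    if params.noise_mm > 0:
        positions += params.noise_mm * rng.standard_normal(positions.shape)
    return TrialRecording(
        positions=positions, fs_hz=fs_hz, marker_names=names, **meta
    )


def _phase_noise(
    params: BounceParams,
    t: np.ndarray,
    stimulus: StimulusTrack,
    rng: np.random.Generator,
) -> np.ndarray:
    """Brownian phase walk plus optional interpolated per-beat von Mises jitter."""
    n = t.size
    eps = np.zeros(n)
    if params.phase_noise_sd > 0:
        dt = t[1] - t[0] if n > 1 else 0.0
        steps = params.phase_noise_sd * np.sqrt(dt) * rng.standard_normal(n)
        steps[0] = 0.0
        eps = np.cumsum(steps)
    if params.kappa is not None:
        jitter = rng.vonmises(0.0, params.kappa, size=stimulus.n_beats)
        eps = eps + np.interp(t, stimulus.onsets, jitter)
    return eps


def _check_duration(duration_s: float | None, stimulus: StimulusTrack) -> float:
    min_needed = stimulus.onsets[-1] + 2.0
    if duration_s is None:
        return float(stimulus.onsets[-1] + 2.5)
    if duration_s < min_needed:
        raise InvalidParameterError(
            f"duration_s={duration_s} too short; stimulus needs >= {min_needed:.2f} s "
            "(last onset plus a 2 s tail)"
        )
    return float(duration_s)


def simulate_bounce_trial(
    params: BounceParams,
    stimulus: StimulusTrack,
    duration_s: float | None = None,
    fs_hz: float = 100.0,
    **meta,
) -> TrialRecording:
    """Simulate a beat-coupled bouncing trial.

    During ``startup_s`` the movement frequency ramps linearly from
    ``own_tempo_bpm`` to the stimulus tempo; from the end of the ramp the
    total phase equals the stimulus phase plus ``mean_lag_rad`` plus the
    configured phase-noise process.
    """
    duration_s = _check_duration(duration_s, stimulus)
    rng = np.random.default_rng(params.seed)
    n = int(round(duration_s * fs_hz)) + 1
    t = np.arange(n) / fs_hz

    f_beat = stimulus.beat_freq_hz
    f_own = params.own_tempo_bpm / 60.0
    if params.startup_s > 0:
        ramp = np.clip(t / params.startup_s, 0.0, 1.0)
        f_inst = f_own + (f_beat - f_own) * ramp
    else:
        f_inst = np.full(n, f_beat)
    dt = 1.0 / fs_hz
    phi_det = 2 * np.pi * np.concatenate(
        [[0.0], np.cumsum(0.5 * (f_inst[1:] + f_inst[:-1]) * dt)]
    )
    # anchor: at the end of the ramp, phase = stimulus phase + mean lag
    t_lock = params.startup_s
    stim_phase_lock = 2 * np.pi * f_beat * (t_lock - stimulus.onsets[0])
    phi_det_lock = np.interp(t_lock, t, phi_det)
    phi = phi_det + (stim_phase_lock + params.mean_lag_rad - phi_det_lock)
    phi = phi + _phase_noise(params, t, stimulus, rng)
    return _assemble_trial(phi, params, fs_hz, rng, tempo_bpm=stimulus.tempo_bpm, **meta)


def simulate_unsynced_trial(
    params: BounceParams,
    stimulus: StimulusTrack,
    duration_s: float | None = None,
    fs_hz: float = 100.0,
    freq_drift_sd: float = 0.02,
    **meta,
) -> TrialRecording:
    """Simulate bouncing at the mover's own tempo, uncoupled from the beat.

    The instantaneous frequency is ``own_tempo_bpm/60`` times a slowly
    drifting multiplier (random walk, SD ``freq_drift_sd`` per sqrt(second)),
    so relative phases at beat onsets drift across the circle whenever the own
    tempo differs from the stimulus tempo. Degenerate case: with
    ``own_tempo_bpm`` equal to the stimulus tempo and zero drift the trial is
    phase-locked despite being "unsynced" — the analysis cannot (and should
    not) tell identical tempi apart.
    """
    duration_s = _check_duration(duration_s, stimulus)
    rng = np.random.default_rng(params.seed)
    n = int(round(duration_s * fs_hz)) + 1
    t = np.arange(n) / fs_hz
    dt = 1.0 / fs_hz

    f_own = params.own_tempo_bpm / 60.0
    drift = np.cumsum(freq_drift_sd * np.sqrt(dt) * rng.standard_normal(n))
    drift[0] = 0.0
    f_inst = f_own * (1.0 + drift)
    phi = 2 * np.pi * np.concatenate(
        [[0.0], np.cumsum(0.5 * (f_inst[1:] + f_inst[:-1]) * dt)]
    )
    phi = phi + rng.uniform(0, 2 * np.pi)  # arbitrary starting posture
    phi = phi + _phase_noise(params, t, stimulus, rng)
    return _assemble_trial(phi, params, fs_hz, rng, tempo_bpm=stimulus.tempo_bpm, **meta)


# --------------------------------------------------------------------------
# cohort generation
# --------------------------------------------------------------------------

#: Per (group, condition) phase-noise SD (rad/sqrt(s)). Auditory synchronization
#: is tightest; the masked vibrotactile condition is noisiest; the deaf group
#: matches the hearing group's masked performance in both vibrotactile
#: conditions (so a deaf-vs-hearing gap exists for "muff" but not "mask").
DEFAULT_CONDITION_NOISE: dict[tuple[str, str], float] = {
    ("hearing", "auditory"): 0.06,
    ("hearing", "muff"): 0.10,
    ("hearing", "mask"): 0.14,
    ("deaf", "mask"): 0.14,
    ("deaf", "muff"): 0.14,
}


@dataclass(frozen=True)
class CohortDesign:
    """Experiment design for a synthetic cohort.

    Defaults mirror the study layout: 7 deaf and 14 hearing participants;
    deaf participants perform the two vibrotactile conditions (mask, muff),
    hearing participants additionally the auditory condition; three tempi
    (110, 115, 120 BPM) x two trials per condition-tempo cell, i.e. 12 trials
    per deaf and 18 per hearing participant.

    ``participant_sigma`` is the SD of a lognormal participant-ability
    multiplier applied to the condition phase-noise SD (individual
    differences in synchronization quality).
    """

    n_deaf: int = 7
    n_hearing: int = 14
    conditions: dict = field(
        default_factory=lambda: {
            "deaf": ("mask", "muff"),
            "hearing": ("mask", "muff", "auditory"),
        }
    )
    tempi_bpm: tuple[float, ...] = (110.0, 115.0, 120.0)
    trials_per_cell: int = 2
    n_beats: int = 128
    condition_noise_sd: dict = field(
        default_factory=lambda: dict(DEFAULT_CONDITION_NOISE)
    )
    participant_sigma: float = 0.18
    mean_lag_rad: float = 0.3
    lag_spread_rad: float = 0.25
    n_markers: int = 28
    fs_hz: float = 100.0

    def participants(self) -> list[tuple[str, str]]:
        deaf = [(f"D{i + 1:02d}", "deaf") for i in range(self.n_deaf)]
        hearing = [(f"H{i + 1:02d}", "hearing") for i in range(self.n_hearing)]
        return deaf + hearing

    def validate(self) -> None:
        for group in self.conditions:
            if group not in ("deaf", "hearing"):
                raise ConfigError(f"unknown group label {group!r}")
            for cond in self.conditions[group]:
                if cond not in ("auditory", "mask", "muff", "spontaneous"):
                    raise ConfigError(f"unknown condition label {cond!r}")
                if (group, cond) not in self.condition_noise_sd:
                    raise ConfigError(
                        f"no phase-noise SD configured for cell ({group}, {cond})"
                    )


def generate_cohort(design: CohortDesign, seed: int):
    """Yield ``(manifest_row, TrialRecording, StimulusTrack)`` for a cohort.

    Trials are yielded lazily (a full 28-marker cohort does not fit
    comfortably in memory). The manifest row is a dict with participant_id,
    group, condition, tempo_bpm, trial_index and the generative parameters
    actually used, so planted effects are fully auditable.
    """
    design.validate()
    master = np.random.default_rng(seed)
    stimuli = {
        bpm: generate_beat_onsets(bpm, design.n_beats) for bpm in design.tempi_bpm
    }
    for pid, group in design.participants():
        ability = float(np.exp(design.participant_sigma * master.standard_normal()))
        lag = float(
            design.mean_lag_rad + design.lag_spread_rad * master.standard_normal()
        )
        own_tempo = float(master.uniform(95.0, 125.0))
        for condition in design.conditions[group]:
            base_sd = design.condition_noise_sd[(group, condition)]
            for tempo in design.tempi_bpm:
                for trial_index in range(design.trials_per_cell):
                    trial_seed = int(master.integers(0, 2**31 - 1))
                    params = BounceParams(
                        mean_lag_rad=lag,
                        phase_noise_sd=base_sd * ability,
                        own_tempo_bpm=own_tempo,
                        n_markers=design.n_markers,
                        seed=trial_seed,
                    )
                    stimulus = stimuli[tempo]
                    trial = simulate_bounce_trial(
                        params,
                        stimulus,
                        fs_hz=design.fs_hz,
                        participant_id=pid,
                        group=group,
                        condition=condition,
                    )
                    row = {
                        "participant_id": pid,
                        "group": group,
                        "condition": condition,
                        "tempo_bpm": tempo,
                        "trial_index": trial_index,
                        "phase_noise_sd": base_sd * ability,
                        "mean_lag_rad": lag,
                        "seed": trial_seed,
                    }
                    yield row, trial, stimulus


def cohort_manifest(design: CohortDesign) -> pd.DataFrame:
    """Design arithmetic only: the manifest rows a cohort will contain."""
    design.validate()
    rows = []
    for pid, group in design.participants():
        for condition in design.conditions[group]:
            for tempo in design.tempi_bpm:
                for trial_index in range(design.trials_per_cell):
                    rows.append(
                        {
                            "participant_id": pid,
                            "group": group,
                            "condition": condition,
                            "tempo_bpm": tempo,
                            "trial_index": trial_index,
                        }
                    )
    return pd.DataFrame(
        rows,
        columns=["participant_id", "group", "condition", "tempo_bpm", "trial_index"],
    )


def write_cohort(design: CohortDesign, seed: int, out_dir) -> pd.DataFrame:
    """Generate a cohort and write trial TSVs, stimulus CSVs and manifest.csv.

    Returns the manifest DataFrame (also written to ``out_dir/manifest.csv``).
    """
    from pathlib import Path

    from . import mocap_io

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stim_files: dict[float, str] = {}
    rows = []
    for row, trial, stimulus in generate_cohort(design, seed):
        bpm = row["tempo_bpm"]
        if bpm not in stim_files:
            stim_path = out / f"stimulus_{int(round(bpm))}bpm.csv"
            mocap_io.write_stimulus_csv(stimulus, stim_path)
            stim_files[bpm] = stim_path.name
        fname = (
            f"{row['participant_id']}_{row['condition']}_"
            f"{int(round(bpm))}bpm_t{row['trial_index']}.tsv"
        )
        mocap_io.write_trial_tsv(trial, out / fname)
        rows.append({**row, "trial_file": fname, "stimulus_file": stim_files[bpm]})
    manifest = pd.DataFrame(
        rows,
        columns=[
            "participant_id",
            "group",
            "condition",
            "tempo_bpm",
            "trial_index",
            "phase_noise_sd",
            "mean_lag_rad",
            "seed",
            "trial_file",
            "stimulus_file",
        ],
    )
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest
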