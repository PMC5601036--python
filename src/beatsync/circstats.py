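"""Circular statistics of beat-sampled relative phases.

Phases are treated as unit vectors; the mean resultant length R measures
their concentration (1 = constant phase relation, 0 = uniform). The Rayleigh
test rejects circular uniformity when R is improbably large; circular
variance V = 1 - R quantifies dispersion; and the synchronization-consistency
score SC = -ln(V) maps the lognormal-shaped variance distribution onto an
approximately normal scale on which higher = better synchronization.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from . import phase as _phase
from .core import InvalidParameterError, StimulusTrack, TrialRecording, wrap_angle

__all__ = [
    "SyncResult",
    "mean_resultant",
    "rayleigh_test",
    "circular_variance",
    "sc_score",
    "analyze_trial",
]


def _as_phases(phases_rad) -> np.ndarray:
    x = np.asarray(phases_rad, dtype=float).ravel()
    if x.size == 0:
        raise InvalidParameterError("need at least one phase")
    return x


def mean_resultant(phases_rad) -> tuple[float, float]:
    """Mean resultant length R in [0, 1] and mean direction in (-pi, pi]."""
    x = _as_phases(phases_rad)
    z = np.mean(np.exp(1j * x))
    return float(np.abs(z)), float(np.angle(z))


def rayleigh_test(
    phases_rad,
    alpha: float = 0.001,
    method: str = "approx",
    n_sim: int = 100_000,
    rng: np.random.Generator | None = None,
) -> tuple[float, float, bool]:
    """Rayleigh test of circular uniformity.

    Returns ``(Z, p, significant)`` with ``Z = n*R**2``. ``method="approx"``
    uses the standard series approximation

        p = exp( sqrt(1 + 4n + 4(n^2 - Rn^2)) - (1 + 2n) ),   Rn = n*R,

    accurate for n >= 5; ``method="simulation"`` estimates p as the fraction
    of ``n_sim`` uniform null samples whose R is at least as large (an
    independent Monte-Carlo oracle, mostly for verification).
    """
    x = _as_phases(phases_rad)
    n = x.size
    if n < 5:
        raise InvalidParameterError(
            f"Rayleigh approximation needs n >= 5 phases, got {n}"
        )
    R, _ = mean_resultant(x)
    Z = n * R**2
    if method == "approx":
        Rn = n * R
        p = math.exp(math.sqrt(1 + 4 * n + 4 * (n**2 - Rn**2)) - (1 + 2 * n))
        p = min(p, 1.0)
    elif method == "simulation":
        rng = np.random.default_rng(0) if rng is None else rng
        null = rng.uniform(-np.pi, np.pi, size=(n_sim, n))
        null_R = np.abs(np.mean(np.exp(1j * null), axis=1))
        p = (1 + np.count_nonzero(null_R >= R)) / (n_sim + 1)
    else:
        raise InvalidParameterError(f"unknown method {method!r}")
    return float(Z), float(p), bool(p < alpha)


def circular_variance(phases_rad) -> float:
    """Circular variance V = 1 - R, in [0, 1]; 0 means a constant phase relation."""
    R, _ = mean_resultant(phases_rad)
    return 1.0 - R


def sc_score(V: float, base: float = math.e) -> float:
    """Synchronization-consistency score: the negated log of circular variance.

    ``SC = -log_base(V)`` is >= 0, strictly decreasing in V, and normalizes
    the lognormal-shaped variance distribution. V = 0 (a mathematically
    perfect phase lock) maps to +inf with a warning; values outside [0, 1]
    are domain errors.
    """
    if V < 0.0 or V > 1.0:
        raise InvalidParameterError(f"circular variance must lie in [0, 1], got {V}")
    if V == 0.0:
        warnings.warn(
            "circular variance is exactly 0 (perfect phase lock); SC score is infinite",
            RuntimeWarning,
            stacklevel=2,
        )
        return math.inf
    if base <= 0 or base == 1.0:
        raise InvalidParameterError(f"log base must be positive and != 1, got {base}")
    return -math.log(V) / math.log(base)


@dataclass
class SyncResult:
    """Per-trial synchronization outcome.

    ``sc_score`` is NaN unless the trial is phase-locked — consistency is
    only meaningful for trials that synchronized at all.
    """

    n: int
    mean_resultant_R: float
    mean_angle_rad: float
    rayleigh_Z: float
    rayleigh_p: float
    circ_variance_V: float
    sc_score: float
    phase_locked: bool
    axis_label: str = ""

    def as_row(self) -> dict:
        return {
            "n": self.n,
            "R": self.mean_resultant_R,
            "mean_angle": self.mean_angle_rad,
            "Z": self.rayleigh_Z,
            "p": self.rayleigh_p,
            "V": self.circ_variance_V,
            "SC": self.sc_score,
            "phase_locked": self.phase_locked,
            "axis": self.axis_label,
        }


def sync_stats(phases_rad, alpha: float = 0.001, sc_base: float = math.e) -> SyncResult:
    """Circular statistics of one set of beat phases (no signal processing)."""
    x = _as_phases(phases_rad)
    R, mean_angle = mean_resultant(x)
    Z, p, locked = rayleigh_test(x, alpha=alpha)
    V = 1.0 - R
    if locked:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            sc = sc_score(V, base=sc_base)
    else:
        sc = math.nan
    return SyncResult(
        n=x.size,
        mean_resultant_R=R,
        mean_angle_rad=mean_angle,
        rayleigh_Z=Z,
        rayleigh_p=p,
        circ_variance_V=V,
        sc_score=sc,
        phase_locked=locked,
    )


def analyze_trial(
    trial: TrialRecording,
    stimulus: StimulusTrack,
    config=None,
) -> SyncResult:
    """Full per-trial pipeline: marker -> filter -> phase -> beat phases -> stats.

    Stages: extract the analysis marker's three axes, band-pass each around
    the stimulus beat frequency, keep the maximal-amplitude component, take
    the Hilbert instantaneous phase, sample it at the retained beat onsets,
    and compute the circular statistics. Errors raised by a stage are
    re-raised annotated with the stage name.
    """
    from .config import PipelineConfig

    cfg = config or PipelineConfig()
    if (
        trial.tempo_bpm is not None
        and abs(trial.tempo_bpm - stimulus.tempo_bpm) > 1e-6
    ):
        raise InvalidParameterError(
            f"trial tempo {trial.tempo_bpm} BPM != stimulus tempo {stimulus.tempo_bpm} BPM"
        )
    stage = "component-selection"
    try:
        filtered = _phase.select_max_amplitude_component(
            trial,
            cfg.marker,
            stimulus.beat_freq_hz,
            rel_bandwidth=cfg.rel_bandwidth,
            order=cfg.filter_order,
        )
        stage = "instantaneous-phase"
        ps = _phase.instantaneous_phase(filtered, pad_s=cfg.pad_s)
        stage = "beat-sampling"
        beats = _phase.sample_phase_at_beats(
            ps,
            stimulus,
            n_lead_excluded=cfg.n_lead_excluded,
            n_tail_excluded=cfg.n_tail_excluded,
        )
        stage = "circular-statistics"
        result = sync_stats(beats.phases_rad, alpha=cfg.alpha, sc_base=cfg.sc_log_base)
    except Exception as exc:
        raise type(exc)(f"[stage: {stage}] {exc}") from exc
    result.axis_label = filtered.axis_label
    return result
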