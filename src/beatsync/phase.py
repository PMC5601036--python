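"""From raw displacement to beat-sampled relative phases.

Pipeline stages: (1) zero-phase Butterworth band-pass centred on the stimulus
beat frequency with a total passband width of 20% of that frequency;
(2) selection of the movement component (anatomical axis) with maximal
filtered amplitude; (3) Hilbert-transform instantaneous phase; (4) linear
interpolation of the unwrapped phase at stimulus beat onsets, discarding the
first 10 beats (time to find the beat) and the last 3 (end-of-trial margin).
Because the stimulus phase is zero at every beat onset, the sampled movement
phase *is* the movement-to-beat relative phase.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.signal

from .core import (
    AXES,
    AXIS_PRIORITY,
    DegenerateSignalError,
    InvalidParameterError,
    StimulusTrack,
    TooFewBeatsError,
    TrialRecording,
    wrap_angle,
)
from .mocap_io import extract_marker_axes

__all__ = [
    "FilteredSignal",
    "PhaseSeries",
    "BeatPhases",
    "bandpass_filter",
    "select_max_amplitude_component",
    "instantaneous_phase",
    "sample_phase_at_beats",
]


@dataclass
class FilteredSignal:
    """A band-pass-filtered, zero-mean displacement series."""

    samples: np.ndarray
    fs_hz: float
    center_freq_hz: float
    passband: tuple[float, float]
    axis_label: str = ""


@dataclass
class PhaseSeries:
    """Per-frame instantaneous phase: wrapped to (-pi, pi] and unwrapped."""

    phase_rad: np.ndarray
    unwrapped_rad: np.ndarray
    fs_hz: float

    @property
    def duration_s(self) -> float:
        return (self.phase_rad.size - 1) / self.fs_hz


@dataclass
class BeatPhases:
    """Relative phase at each retained stimulus beat."""

    phases_rad: np.ndarray
    retained_beat_indices: np.ndarray

    @property
    def n_retained(self) -> int:
        return int(self.phases_rad.size)


def passband_edges(center_freq_hz: float, rel_bandwidth: float = 0.20) -> tuple[float, float]:
    """Passband for a total relative width ``rel_bandwidth`` around the centre.

    The default 0.20 means a passband of f0*(1 - 0.1) .. f0*(1 + 0.1): the
    total width is 20% of the beat frequency.
    """
    half = 0.5 * rel_bandwidth
    return center_freq_hz * (1.0 - half), center_freq_hz * (1.0 + half)


def bandpass_filter(
    signal: np.ndarray,
    fs_hz: float,
    center_freq_hz: float,
    rel_bandwidth: float = 0.20,
    order: int = 2,
    axis_label: str = "",
) -> FilteredSignal:
    """Zero-phase Butterworth band-pass around the beat frequency.

    A second-order Butterworth is applied forward and backward
    (``sosfiltfilt``), so the output has no phase shift at any frequency —
    essential here because a lag would bias every relative phase.
    """
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1:
        raise InvalidParameterError("signal must be 1-D")
    if center_freq_hz <= 0:
        raise InvalidParameterError("center_freq_hz must be > 0")
    low, high = passband_edges(center_freq_hz, rel_bandwidth)
    nyq = fs_hz / 2.0
    if high >= nyq:
        raise InvalidParameterError(
            f"passband upper edge {high:.3f} Hz reaches Nyquist ({nyq:.3f} Hz)"
        )
    if fs_hz < 4 * center_freq_hz:
        raise InvalidParameterError(
            f"fs_hz={fs_hz} < 4x centre frequency {center_freq_hz}"
        )
    if x.size < 10 * fs_hz / center_freq_hz:
        raise InvalidParameterError(
            "signal shorter than 10 beat periods; too short to band-pass reliably"
        )
    sos = scipy.signal.butter(
        order, [low, high], btype="bandpass", fs=fs_hz, output="sos"
    )
    y = scipy.signal.sosfiltfilt(sos, x - x.mean())
    return FilteredSignal(
        samples=y,
        fs_hz=fs_hz,
        center_freq_hz=center_freq_hz,
        passband=(low, high),
        axis_label=axis_label,
    )


def select_max_amplitude_component(
    trial: TrialRecording,
    marker_name: str,
    center_freq_hz: float,
    rel_bandwidth: float = 0.20,
    order: int = 2,
) -> FilteredSignal:
    """Band-pass each axis of one marker and keep the largest-amplitude one.

    Amplitude is the RMS of the filtered signal (robust to single-sample
    spikes, unlike peak-to-peak). Exact ties break deterministically by the
    fixed axis priority vertical > anteroposterior > mediolateral.
    """
    axes = extract_marker_axes(trial, marker_name)
    raw = {ax: getattr(axes, ax) for ax in AXES}
    if all(np.ptp(v) == 0 for v in raw.values()):
        raise DegenerateSignalError(
            f"marker {marker_name!r}: all axes constant; no movement to analyze"
        )
    best: FilteredSignal | None = None
    best_rms = -np.inf
    for ax in AXIS_PRIORITY:
        filt = bandpass_filter(
            raw[ax], trial.fs_hz, center_freq_hz, rel_bandwidth, order, axis_label=ax
        )
        rms = float(np.sqrt(np.mean(filt.samples**2)))
        if rms > best_rms:  # strict: earlier (higher-priority) axis wins ties
            best, best_rms = filt, rms
    assert best is not None
    return best


def instantaneous_phase(
    filtered: FilteredSignal | np.ndarray,
    fs_hz: float | None = None,
    pad_s: float = 5.0,
) -> PhaseSeries:
    """Analytic-signal (Hilbert) phase of a band-limited oscillation.

    The signal is reflection-padded (mirrored) by ``pad_s`` seconds on each
    side before the transform and trimmed after, so the transform's circular
    edge distortion falls in the discarded margins; the residual junction
    artifact decays within a few cycles of each end. Combined with the
    downstream 10-lead/3-tail beat exclusion the retained phases stay well
    away from the edges.
    """
    if isinstance(filtered, FilteredSignal):
        x = filtered.samples
        fs = filtered.fs_hz
    else:
        x = np.asarray(filtered, dtype=float)
        if fs_hz is None:
            raise InvalidParameterError("fs_hz required when passing a bare array")
        fs = fs_hz
    if x.ndim != 1 or x.size < 2:
        raise InvalidParameterError("signal must be 1-D with at least 2 samples")
    if np.allclose(x, 0.0):
        raise DegenerateSignalError("all-zero signal has no phase")
    pad = int(round(pad_s * fs))
    pad = min(pad, x.size - 1)  # np.pad reflect limit
    if pad > 0:
        xp = np.pad(x, pad, mode="reflect")
    else:
        xp = x
    analytic = scipy.signal.hilbert(xp)
    phase = np.angle(analytic)
    if pad > 0:
        phase = phase[pad:-pad]
    unwrapped = np.unwrap(phase)
    return PhaseSeries(phase_rad=wrap_angle(unwrapped), unwrapped_rad=unwrapped, fs_hz=fs)


def sample_phase_at_beats(
    phase_series: PhaseSeries,
    stimulus: StimulusTrack,
    n_lead_excluded: int = 10,
    n_tail_excluded: int = 3,
) -> BeatPhases:
    """Sample the unwrapped phase at retained beat onsets and wrap.

    Beats 0..n_lead_excluded-1 are dropped (settling-in period, ~5 s at the
    study tempi) and the last ``n_tail_excluded`` beats are dropped
    (end-of-trial margin), leaving ``n_beats - lead - tail`` phases; with the
    128-beat stimuli and defaults that is 115. Phases are linearly
    interpolated on the *unwrapped* phase because onsets rarely coincide with
    frame times.
    """
    if n_lead_excluded < 0 or n_tail_excluded < 0:
        raise InvalidParameterError("exclusion counts must be >= 0")
    n_beats = stimulus.n_beats
    if n_beats <= n_lead_excluded + n_tail_excluded:
        raise TooFewBeatsError(
            f"{n_beats} beats cannot survive excluding {n_lead_excluded} lead "
            f"+ {n_tail_excluded} tail beats"
        )
    retained = np.arange(n_lead_excluded, n_beats - n_tail_excluded)
    t_onsets = stimulus.onsets[retained]
    duration = phase_series.duration_s
    if t_onsets[0] < 0 or t_onsets[-1] > duration:
        raise InvalidParameterError(
            f"retained onsets span [{t_onsets[0]:.3f}, {t_onsets[-1]:.3f}] s but the "
            f"recording lasts {duration:.3f} s"
        )
    t_grid = np.arange(phase_series.unwrapped_rad.size) / phase_series.fs_hz
    sampled = np.interp(t_onsets, t_grid, phase_series.unwrapped_rad)
    return BeatPhases(phases_rad=wrap_angle(sampled), retained_beat_indices=retained)
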