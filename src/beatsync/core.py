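"""Core containers and errors shared across the pipeline.

Axis convention (documented, remappable via :class:`beatsync.config.PipelineConfig`):
column order X, Y, Z maps to mediolateral, anteroposterior, vertical.
Coordinates are millimetres, time is seconds.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Fixed anatomical axis order used everywhere: index 0 = X, 1 = Y, 2 = Z.
AXES: tuple[str, str, str] = ("mediolateral", "anteroposterior", "vertical")

#: Tie-break priority when two axes have identical filtered amplitude.
AXIS_PRIORITY: tuple[str, str, str] = ("vertical", "anteroposterior", "mediolateral")


class BeatSyncError(Exception):
    """Base class for all pipeline errors."""


class InvalidParameterError(BeatSyncError, ValueError):
    """A parameter violates a documented precondition."""


class TrialFormatError(BeatSyncError, ValueError):
    """A trial/manifest file does not conform to the documented dialect."""


class DegenerateSignalError(BeatSyncError, ValueError):
    """The signal carries no usable oscillation (all-zero / constant)."""


class TooFewBeatsError(InvalidParameterError):
    """Not enough stimulus beats survive the lead/tail exclusions."""


class ConfigError(BeatSyncError, ValueError):
    """An experiment-design or pipeline configuration is inconsistent."""


@dataclass(frozen=True)
class StimulusTrack:
    """An isochronous beat timeline.

    Parameters
    ----------
    tempo_bpm : float
        Beat rate in beats per minute.
    onsets : np.ndarray
        Beat-onset times in seconds, strictly increasing, spaced 60/tempo.
    """

    tempo_bpm: float
    onsets: np.ndarray

    def __post_init__(self) -> None:
        onsets = np.asarray(self.onsets, dtype=float)
        object.__setattr__(self, "onsets", onsets)
        if self.tempo_bpm <= 0:
            raise InvalidParameterError(f"tempo_bpm must be > 0, got {self.tempo_bpm}")
        if onsets.ndim != 1 or onsets.size < 1:
            raise InvalidParameterError("onsets must be a non-empty 1-D array")
        if onsets.size > 1 and not np.all(np.diff(onsets) > 0):
            raise InvalidParameterError("onsets must be strictly increasing")

    @property
    def n_beats(self) -> int:
        return int(self.onsets.size)

    @property
    def beat_freq_hz(self) -> float:
        return self.tempo_bpm / 60.0

    @property
    def beat_period_s(self) -> float:
        return 60.0 / self.tempo_bpm


@dataclass
class TrialRecording:
    """One motion-capture trial: frames x markers x XYZ positions in mm.

    ``positions[t, m, :]`` is the (X, Y, Z) = (mediolateral, anteroposterior,
    vertical) coordinate of marker ``m`` at frame ``t``.
    """

    positions: np.ndarray
    fs_hz: float
    marker_names: tuple[str, ...]
    participant_id: str = "anon"
    group: str | None = None
    condition: str | None = None
    tempo_bpm: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.marker_names = tuple(self.marker_names)
        if self.positions.ndim != 3 or self.positions.shape[2] != 3:
            raise InvalidParameterError(
                f"positions must have shape (frames, markers, 3); got {self.positions.shape}"
            )
        if self.positions.shape[1] != len(self.marker_names):
            raise InvalidParameterError(
                f"{self.positions.shape[1]} marker columns but "
                f"{len(self.marker_names)} marker names"
            )
        if len(set(self.marker_names)) != len(self.marker_names):
            raise InvalidParameterError("marker names must be unique")
        if self.fs_hz <= 0:
            raise InvalidParameterError(f"fs_hz must be > 0, got {self.fs_hz}")
        if not np.isfinite(self.positions).all():
            raise InvalidParameterError("positions contain NaN/inf (missing frames?)")

    @property
    def n_frames(self) -> int:
        return int(self.positions.shape[0])

    @property
    def n_markers(self) -> int:
        return int(self.positions.shape[1])

    @property
    def duration_s(self) -> float:
        return (self.n_frames - 1) / self.fs_hz

    def marker_index(self, name: str) -> int:
        try:
            return self.marker_names.index(name)
        except ValueError:
            raise KeyError(
                f"marker {name!r} not present; available: {', '.join(self.marker_names)}"
            ) from None


def wrap_angle(theta: np.ndarray | float) -> np.ndarray | float:
    """Wrap angles to the interval (-pi, pi]."""
    return np.angle(np.exp(1j * np.asarray(theta, dtype=float)))
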