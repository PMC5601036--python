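"""Trial, stimulus and manifest file I/O.

Trial dialect (one documented TSV flavour, close to a motion-capture text
export): a single header line ``Frame\\tTime\\t<marker>_X\\t<marker>_Y\\t
<marker>_Z...``, then one row per frame. Coordinates are millimetres with six
decimals, time is seconds at the recording rate. Axis meaning defaults to
X = mediolateral, Y = anteroposterior, Z = vertical and can be overridden with
an ``axis_map`` when reading data exported under another convention.
"""
from __future__ import annotations

from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd

from .core import (
    AXES,
    ConfigError,
    StimulusTrack,
    TrialFormatError,
    TrialRecording,
)

SIGNAL_MARKER = "knee_R"

MANIFEST_COLUMNS = (
    "participant_id",
    "group",
    "condition",
    "tempo_bpm",
    "trial_file",
    "stimulus_file",
)


class MarkerAxes(NamedTuple):
    """Displacement of one marker split by anatomical axis (mm)."""

    mediolateral: np.ndarray
    anteroposterior: np.ndarray
    vertical: np.ndarray


def write_trial_tsv(trial: TrialRecording, path) -> None:
    """Serialize a trial in the documented TSV dialect, deterministically."""
    if trial.n_markers == 0 or len(trial.marker_names) == 0:
        raise TrialFormatError("cannot write a trial with no markers")
    path = Path(path)
    cols = ["Frame", "Time"]
    for name in trial.marker_names:
        cols += [f"{name}_X", f"{name}_Y", f"{name}_Z"]
    n = trial.n_frames
    flat = trial.positions.reshape(n, -1)
    with open(path, "w", newline="\n") as fh:
        fh.write("\t".join(cols) + "\n")
        for i in range(n):
            t = i / trial.fs_hz
            row = "\t".join(f"{v:.6f}" for v in flat[i])
            fh.write(f"{i}\t{t:.6f}\t{row}\n")


def read_trial_tsv(path, axis_map: dict | None = None, **meta) -> TrialRecording:
    """Parse a trial TSV back into a :class:`TrialRecording`.

    Parameters
    ----------
    axis_map : dict, optional
        Maps file suffixes "X"/"Y"/"Z" to anatomical axes, default
        ``{"X": "mediolateral", "Y": "anteroposterior", "Z": "vertical"}``.
    meta : participant_id, group, condition, tempo_bpm passed through.
    """
    path = Path(path)
    if not path.exists():
        raise TrialFormatError(f"trial file not found: {path}")
    try:
        df = pd.read_csv(path, sep="\t")
    except pd.errors.ParserError as exc:
        raise TrialFormatError(f"{path}: ragged or malformed TSV ({exc})") from exc
    if df.isna().any().any():
        bad = int(df[df.isna().any(axis=1)].index[0]) + 2  # +2: header, 1-based
        raise TrialFormatError(f"{path}: missing values at line {bad}")
    if list(df.columns[:2]) != ["Frame", "Time"]:
        raise TrialFormatError(f"{path}: header must start with 'Frame\\tTime'")
    coord_cols = list(df.columns[2:])
    if len(coord_cols) == 0 or len(coord_cols) % 3 != 0:
        raise TrialFormatError(
            f"{path}: coordinate columns must come in X/Y/Z triplets "
            f"(got {len(coord_cols)})"
        )

    axis_map = axis_map or {"X": "mediolateral", "Y": "anteroposterior", "Z": "vertical"}
    if sorted(axis_map.values()) != sorted(AXES):
        raise ConfigError(f"axis_map must cover {AXES} exactly, got {axis_map}")

    markers: list[str] = []
    for i in range(0, len(coord_cols), 3):
        triplet = coord_cols[i : i + 3]
        names = {c.rsplit("_", 1)[0] for c in triplet}
        suffixes = [c.rsplit("_", 1)[1] for c in triplet]
        if len(names) != 1 or sorted(suffixes) != ["X", "Y", "Z"]:
            raise TrialFormatError(
                f"{path}: columns {triplet} are not a <marker>_X/_Y/_Z triplet"
            )
        markers.append(names.pop())
    if SIGNAL_MARKER not in markers:
        raise TrialFormatError(
            f"{path}: required marker {SIGNAL_MARKER!r} missing "
            f"(found: {', '.join(markers)})"
        )

    time = df["Time"].to_numpy(dtype=float)
    if len(time) < 2:
        raise TrialFormatError(f"{path}: fewer than two frames")
    dts = np.diff(time)
    if dts.min() <= 0 or not np.allclose(dts, dts[0], atol=1e-6):
        bad = int(np.argmax(~np.isclose(dts, dts[0], atol=1e-6))) + 3
        raise TrialFormatError(f"{path}: non-uniform sampling near line {bad}")
    fs_hz = 1.0 / dts.mean()

    # reorder each triplet's file axes into the canonical X/Y/Z = ML/AP/vert order
    suffix_for_axis = {v: k for k, v in axis_map.items()}
    n = len(df)
    positions = np.empty((n, len(markers), 3))
    for m, name in enumerate(markers):
        for a, axis in enumerate(AXES):
            positions[:, m, a] = df[f"{name}_{suffix_for_axis[axis]}"].to_numpy(float)
    return TrialRecording(
        positions=positions,
        fs_hz=float(np.round(fs_hz, 6)),
        marker_names=tuple(markers),
        **meta,
    )


def extract_marker_axes(trial: TrialRecording, marker_name: str) -> MarkerAxes:
    """Return the three per-axis displacement series of one marker."""
    m = trial.marker_index(marker_name)  # raises KeyError listing markers
    return MarkerAxes(
        mediolateral=trial.positions[:, m, 0].copy(),
        anteroposterior=trial.positions[:, m, 1].copy(),
        vertical=trial.positions[:, m, 2].copy(),
    )


def write_stimulus_csv(stimulus: StimulusTrack, path) -> None:
    pd.DataFrame({"onset_s": stimulus.onsets}).to_csv(path, index=False, float_format="%.9f")


def read_stimulus_csv(path, tempo_bpm: float | None = None) -> StimulusTrack:
    """Read a beat-onset CSV; tempo is inferred from the spacing if not given."""
    df = pd.read_csv(path)
    if "onset_s" not in df.columns:
        raise TrialFormatError(f"{path}: stimulus CSV must have an 'onset_s' column")
    onsets = df["onset_s"].to_numpy(dtype=float)
    if tempo_bpm is None:
        if len(onsets) < 2:
            raise TrialFormatError(
                f"{path}: cannot infer tempo from a single onset; pass tempo_bpm"
            )
        tempo_bpm = 60.0 / float(np.median(np.diff(onsets)))
    return StimulusTrack(tempo_bpm=float(np.round(tempo_bpm, 6)), onsets=onsets)


def validate_manifest(manifest: pd.DataFrame) -> pd.DataFrame:
    """Check manifest structure and the design rule that only hearing
    participants have auditory trials."""
    missing = [c for c in MANIFEST_COLUMNS if c not in manifest.columns]
    if missing:
        raise TrialFormatError(f"manifest missing columns: {missing}")
    bad_group = set(manifest["group"]) - {"deaf", "hearing"}
    if bad_group:
        raise ConfigError(f"unknown group labels in manifest: {sorted(bad_group)}")
    bad_cond = set(manifest["condition"]) - {"auditory", "mask", "muff", "spontaneous"}
    if bad_cond:
        raise ConfigError(f"unknown condition labels in manifest: {sorted(bad_cond)}")
    offending = manifest[
        (manifest["group"] == "deaf") & (manifest["condition"] == "auditory")
    ]
    if len(offending):
        pids = sorted(set(offending["participant_id"]))
        raise ConfigError(
            f"auditory condition is only defined for the hearing group; "
            f"offending deaf participants: {pids}"
        )
    return manifest


def read_manifest(path) -> pd.DataFrame:
    return validate_manifest(pd.read_csv(path))


def write_manifest(manifest: pd.DataFrame, path) -> None:
    validate_manifest(manifest).to_csv(path, index=False)
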