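"""Pipeline configuration with the study's analysis constants as defaults."""
from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .core import AXES, ConfigError


@dataclass
class PipelineConfig:
    """All tunable analysis constants.

    Defaults: band-pass total width 20% of the beat frequency, 2nd-order
    zero-phase Butterworth, 5 s Hilbert reflection padding, first 10 beats
    and last 3 beats excluded, Rayleigh alpha 0.001, natural-log SC score,
    analysis marker "knee_R".
    """

    marker: str = "knee_R"
    rel_bandwidth: float = 0.20
    filter_order: int = 2
    pad_s: float = 5.0
    n_lead_excluded: int = 10
    n_tail_excluded: int = 3
    alpha: float = 0.001
    sc_log_base: float = math.e
    axis_map: dict = field(
        default_factory=lambda: {
            "X": "mediolateral",
            "Y": "anteroposterior",
            "Z": "vertical",
        }
    )
    # participant-outlier rule 2 is evaluated in these (group, condition) cells
    outlier_cells: list = field(default_factory=lambda: [["hearing", "auditory"]])

    def __post_init__(self) -> None:
        if not 0 < self.rel_bandwidth < 2:
            raise ConfigError("rel_bandwidth must be in (0, 2)")
        if not 0 < self.alpha < 1:
            raise ConfigError("alpha must be in (0, 1)")
        if self.n_lead_excluded < 0 or self.n_tail_excluded < 0:
            raise ConfigError("beat exclusion counts must be >= 0")
        if sorted(self.axis_map.values()) != sorted(AXES):
            raise ConfigError(f"axis_map must cover {AXES} exactly")

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)
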