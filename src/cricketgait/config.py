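"""Run configuration: calibration, thresholds and analysis settings."""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from .kinematics import CalibrationParams

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """All tunables for one analysis run.

    Defaults mirror the recording setup: 50 mm sphere radius, 120 fps video,
    50 Hz sensor log, 5 kHz EMG, pose-likelihood floor 0.9, significance
    level 0.005.
    """

    calibration: CalibrationParams = field(default_factory=CalibrationParams)
    body_length_mm: float = 20.0
    likelihood_floor: float = 0.9
    smooth_window: int = 5
    hysteresis_frac: float = 0.05
    segment_s: float = 1.2
    overlap: float = 0.5
    kde_kappa: float = 20.0
    coherence_floor: float = 0.3
    peak_band_hz: tuple = (1.0, 10.0)
    alpha: float = 0.005
    seed: int = 0

    def __post_init__(self):
        if isinstance(self.calibration, dict):
            self.calibration = CalibrationParams(**self.calibration)
        if self.body_length_mm <= 0:
            raise ValueError("body_length_mm must be positive")
        if not 0.0 <= self.likelihood_floor <= 1.0:
            raise ValueError("likelihood_floor must be in [0, 1]")
        if self.smooth_window < 1:
            raise ValueError("smooth_window must be >= 1")
        if not 0.0 <= self.hysteresis_frac < 1.0:
            raise ValueError("hysteresis_frac must be in [0, 1)")
        if not 0.0 <= self.overlap < 1.0:
            raise ValueError("overlap must be in [0, 1)")
        if self.kde_kappa <= 0:
            raise ValueError("kde_kappa must be positive")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        self.peak_band_hz = tuple(self.peak_band_hz)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        """Load from YAML, rejecting unknown keys."""
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {', '.join(sorted(unknown))}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        data = {f.name: getattr(self, f.name) for f in fields(self)}
        data["calibration"] = {
            f.name: getattr(self.calibration, f.name)
            for f in fields(CalibrationParams)
        }
        data["peak_band_hz"] = list(self.peak_band_hz)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))
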