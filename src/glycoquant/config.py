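"""Pipeline configuration with every threshold explicit.

Thresholds that come from the measurement protocol (S/N > 3, CV < 25%,
1.5 x IQR fences, the calibrant panel, the 700-3500 m/z window) default to
those values; tolerances the protocol leaves to vendor software (matching
ppm, calibration search window) are artifact defaults and are marked as
such in the run log.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .glycan_model import CALIBRANT_PANEL, DEFAULT_PANEL, MZ_WINDOW

#: config keys whose defaults are artifact choices, not protocol values
ARTIFACT_DEFAULTS = (
    "match_tol_ppm",
    "calib_search_da",
    "snr_exclude_da",
    "library_tol_ppm",
)


@dataclass
class PipelineConfig:
    panel: tuple[str, ...] = DEFAULT_PANEL
    calibrants: tuple[str, ...] = CALIBRANT_PANEL
    mz_window: tuple[float, float] = MZ_WINDOW
    library_tol_ppm: float = 10.0
    match_tol_ppm: float = 10.0
    calib_search_da: float = 0.3
    snr_threshold: float = 3.0
    snr_exclude_da: float = 0.5
    cv_threshold: float = 0.25
    iqr_k: float = 1.5
    strata: tuple[str, ...] = ("group", "week")
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "library_tol_ppm", "match_tol_ppm", "calib_search_da",
            "snr_threshold", "snr_exclude_da", "cv_threshold", "iqr_k",
        ):
            if getattr(self, name) <= 0 and name != "snr_threshold":
                raise ValueError(f"{name} must be positive")
        if self.snr_threshold < 0:
            raise ValueError("snr_threshold must be >= 0")
        lo, hi = self.mz_window
        if lo >= hi:
            raise ValueError("mz_window must be increasing")

    def to_dict(self) -> dict:
        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        for k in ("panel", "calibrants", "mz_window", "strata"):
            if k in d and isinstance(d[k], list):
                d[k] = tuple(d[k])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
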