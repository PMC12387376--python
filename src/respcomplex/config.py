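"""Pipeline configuration: every tunable, serializable, hashable.

Unknown keys are rejected so a stale or mistyped config fails loudly, and the
SHA-256 hash of the canonical JSON form is stamped onto every artifact so any
change to any tunable is visible downstream.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

from pydantic import BaseModel, ConfigDict, Field, model_validator


class PipelineConfig(BaseModel):
    """All tunables of the simulate -> preprocess -> breaths -> features -> stats chain."""

    model_config = ConfigDict(extra="forbid", validate_assignment=True)

    # simulation
    n_pc: int = Field(30, ge=1)
    n_nonpc: int = Field(30, ge=1)
    duration_s: float = Field(3600.0, ge=60.0)
    fs: float = Field(25.0, gt=0)
    seed: int = 0

    # night window / movement exclusion
    night_start: str = "23:00"
    night_end: str = "05:00"
    accel_window_s: float = Field(1.0, gt=0)
    accel_step_s: float = Field(0.5, gt=0)
    accel_threshold_g: float = Field(0.05, gt=0)
    pad_s: float = Field(2.0, ge=0)
    min_segment_s: float = Field(60.0, gt=0)

    # detrend / filter
    filter_order: int = Field(5, ge=1)
    cutoff_hz: float = Field(2.0, gt=0)
    single_pass_filter: bool = False

    # breath segmentation
    min_prominence: float | None = None  # None -> 20% of segment IQR
    min_peak_distance_s: float = Field(0.8, gt=0)
    bbi_min_s: float = Field(1.0, gt=0)
    bbi_max_s: float = Field(15.0, gt=0)
    ra_min_frac: float = Field(0.1, ge=0)

    # multiscale entropy
    m: int = Field(2, ge=1)
    r_factor: float = Field(0.2, gt=0)
    max_scale: int = Field(20, ge=1)
    quadrature: str = "trapezoid"

    # statistics
    normality_alpha: float = Field(0.05, gt=0, lt=1)
    bh_correction: bool = False

    outdir: str | None = None

    @model_validator(mode="after")
    def _check(self) -> "PipelineConfig":
        if self.cutoff_hz >= self.fs / 2:
            raise ValueError(
                f"cutoff_hz={self.cutoff_hz} must be below the Nyquist "
                f"frequency {self.fs / 2} Hz"
            )
        if self.bbi_max_s <= self.bbi_min_s:
            raise ValueError("bbi_max_s must exceed bbi_min_s")
        if self.quadrature not in ("trapezoid", "sum"):
            raise ValueError(f"unknown quadrature {self.quadrature!r}")
        for name in ("night_start", "night_end"):
            v = getattr(self, name)
            parts = v.split(":")
            if len(parts) != 2 or not all(p.isdigit() for p in parts):
                raise ValueError(f"{name} must be HH:MM, got {v!r}")
        return self

    def night_times(self):
        from datetime import time

        h0, m0 = map(int, self.night_start.split(":"))
        h1, m1 = map(int, self.night_end.split(":"))
        return time(h0, m0), time(h1, m1)

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.model_dump(), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "PipelineConfig":
        text = str(source)
        if not text.lstrip().startswith("{"):
            text = Path(source).read_text()
        return cls.model_validate(json.loads(text))
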