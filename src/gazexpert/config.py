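"""Pipeline configuration: every threshold in one serializable place."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields

import yaml


@dataclass
class PipelineConfig:
    """All tunable constants of the pipeline, YAML round-trippable.

    Defaults are the recording/analysis conventions the pipeline assumes:
    250 Hz sampling on a 3840x1920 equirectangular frame, a 40 deg/s saccade
    peak threshold, 50 ms minimum fixations, a 100 px pursuit dispersion
    split, a 75% tracking-ratio trial filter, 1000 deg/s and 1e5 deg/s^2
    physiological saccade bounds, and a k=50-fold SVM ensemble evaluated over
    1000 participant-wise runs.
    """

    frame: tuple = (3840, 1920)
    rate_hz: float = 250.0
    saccade_threshold: float = 40.0
    min_fixation_ms: float = 50.0
    pursuit_dispersion_px: float = 100.0
    min_saccade_samples: int = 3
    gap_min_samples: int = 25
    wrap_x: bool = False
    tracking_ratio_threshold: float = 0.75
    max_peak_velocity: float = 1000.0
    max_abs_acceleration: float = 100_000.0
    k_folds: int = 50
    n_runs: int = 1000
    n_train_per_class: int = 8
    n_eval_per_class: int = 2
    svm_c: float = 1.0
    alpha: float = 0.011
    top_m: int = 7
    seed: int = 0
    sim: dict = field(default_factory=dict)  # overrides for SimConfig

    def __post_init__(self):
        self.frame = tuple(self.frame)
        positive = (
            "rate_hz", "saccade_threshold", "min_fixation_ms",
            "pursuit_dispersion_px", "max_peak_velocity", "max_abs_acceleration",
        )
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.tracking_ratio_threshold <= 1:
            raise ValueError("tracking_ratio_threshold must lie in (0, 1]")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    def sim_config(self):
        from .simulate import SimConfig

        base = dict(
            rate_hz=self.rate_hz,
            frame=self.frame,
            saccade_threshold=self.saccade_threshold,
            seed=self.seed,
        )
        base.update(self.sim)
        return SimConfig(**base)
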