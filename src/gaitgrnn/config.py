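"""Run configuration: every tunable of the pipeline in one flat document.

Defaults follow the standard multi-source gait protocol: 20–500 Hz
Butterworth band-pass on 2000 Hz sEMG, 20-sample feature windows (100 Hz
feature clock), coif5 level-6 wavelet denoising, bandwidth search on
(1e-6, 0.2) with termination width 0.01, and a chronological 2/3–1/3
train/test split.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, fields, replace
from pathlib import Path

import yaml

from .grnn import GoldenSectionConfig
from .preprocessing import BandpassSpec

__all__ = ["RunConfig"]

ABLATIONS = ("angle_only", "angle_semg", "angle_semg_pressure")


@dataclass(frozen=True)
class RunConfig:
    # band-pass filter (sEMG)
    pass_lo: float = 20.0
    pass_hi: float = 500.0
    stop_lo: float = 10.0
    stop_hi: float = 570.0
    pass_atten_max: float = 3.0
    stop_atten_min: float = 20.0
    semg_rate: float = 2000.0
    # feature extraction
    window: int = 20
    feature_rate: float = 100.0
    fit_window: int = 20
    # wavelet denoising
    wavelet: str = "coif5"
    wavelet_levels: int = 6
    denoise_method: str = "threshold"  # threshold | lowpass | none
    threshold_mode: str = "hard"
    # bandwidth search
    gs_a: float = 1e-6
    gs_b: float = 0.2
    gs_epsilon: float = 0.01
    # evaluation
    train_fraction: float = 2.0 / 3.0
    ablation: str = "angle_semg_pressure"
    mre_floor_frac: float = 1e-6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ablation not in ABLATIONS:
            raise ValueError(f"ablation must be one of {ABLATIONS}, got {self.ablation!r}")
        if self.denoise_method not in ("threshold", "lowpass", "none"):
            raise ValueError(f"unknown denoise_method {self.denoise_method!r}")
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie in (0, 1)")
        if self.window < 1 or self.fit_window < 1:
            raise ValueError("window sizes must be >= 1")

    # -- views onto component configs ------------------------------------

    def bandpass_spec(self) -> BandpassSpec:
        return BandpassSpec(
            pass_lo=self.pass_lo,
            pass_hi=self.pass_hi,
            stop_lo=self.stop_lo,
            stop_hi=self.stop_hi,
            pass_atten_max=self.pass_atten_max,
            stop_atten_min=self.stop_atten_min,
            sample_rate=self.semg_rate,
        )

    def gs_config(self) -> GoldenSectionConfig:
        return GoldenSectionConfig(a=self.gs_a, b=self.gs_b, epsilon=self.gs_epsilon)

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        return asdict(self)

    def hash(self) -> str:
        """Short stable digest of the resolved configuration."""
        canonical = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:12]

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def with_overrides(self, **kwargs) -> "RunConfig":
        kwargs = {k: v for k, v in kwargs.items() if v is not None}
        return replace(self, **kwargs)
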