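"""Pipeline configuration: nested blocks with strict key validation.

A fully-defaulted config is valid; unknown keys raise immediately so typos
cannot silently fall back to defaults.  Configs load from YAML or JSON.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Optional, Tuple

import yaml


def _from_dict(cls, d: dict):
    if d is None:
        return cls()
    known = {f.name for f in fields(cls)}
    unknown = set(d) - known
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    kwargs = {}
    for f in fields(cls):
        if f.name in d:
            v = d[f.name]
            if isinstance(v, list):
                v = tuple(v)
            kwargs[f.name] = v
    return cls(**kwargs)


@dataclass
class PhantomBlock:
    grid_shape: Optional[Tuple[int, int, int]] = None
    spacing_mm: Optional[Tuple[float, float, float]] = None
    n_disks: int = 5
    cobb_like_angle_deg: float = 30.0
    disk_semi_axes_mm: Tuple[float, float, float] = (12.0, 14.0, 4.0)
    contrast_preset: str = "medic"
    blur_sigma_mm: float = 0.8
    noise_sigma: float = 0.05
    bright_nucleus: bool = False
    seed: int = 42


@dataclass
class SegmentationBlock:
    se_radius_px: int = 1
    smooth_radius_px: int = 2
    h_fraction: float = 0.10
    min_area_mm2: float = 30.0


@dataclass
class ClassificationBlock:
    k: int = 5
    hist_bins: int = 32
    angle_bin_deg: float = 5.0
    pad_to: int = 64
    energy_spectrum: bool = True
    n_train_per_class: int = 150
    train_seed: int = 7


@dataclass
class FusionBlock:
    enabled: bool = True
    iso_mm: float = 1.0
    max_dist_mm: float = 10.0
    min_voxels: int = 30


@dataclass
class EvaluationBlock:
    posterior_band_fraction: float = 0.25
    lateral_fraction: float = 0.10


@dataclass
class RobustnessBlock:
    M: int = 3
    k: int = 4
    p: int = 2
    blocks: int = 3
    alpha: float = 0.05


@dataclass
class PipelineConfig:
    phantom: PhantomBlock = field(default_factory=PhantomBlock)
    segmentation: SegmentationBlock = field(default_factory=SegmentationBlock)
    classification: ClassificationBlock = field(default_factory=ClassificationBlock)
    fusion: FusionBlock = field(default_factory=FusionBlock)
    evaluation: EvaluationBlock = field(default_factory=EvaluationBlock)
    robustness: RobustnessBlock = field(default_factory=RobustnessBlock)
    seed: int = 0
    output_dir: str = "."
    log_level: str = "INFO"

    @classmethod
    def from_dict(cls, d: Optional[dict]) -> "PipelineConfig":
        if d is None:
            return cls()
        blocks = {
            "phantom": PhantomBlock,
            "segmentation": SegmentationBlock,
            "classification": ClassificationBlock,
            "fusion": FusionBlock,
            "evaluation": EvaluationBlock,
            "robustness": RobustnessBlock,
        }
        known = set(blocks) | {"seed", "output_dir", "log_level"}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown PipelineConfig keys: {sorted(unknown)}")
        kwargs = {}
        for name, bcls in blocks.items():
            if name in d:
                kwargs[name] = _from_dict(bcls, d[name])
        for scalar in ("seed", "output_dir", "log_level"):
            if scalar in d:
                kwargs[scalar] = d[scalar]
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path) -> PipelineConfig:
    """Load a YAML or JSON config file (by extension)."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return PipelineConfig.from_dict(data)
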