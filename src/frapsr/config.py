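"""Pipeline configuration: serializable, documented defaults, strict keys."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields

import yaml

__all__ = ["PipelineConfig", "SegmentationConfig", "FrapConfig", "SubcompartmentConfig", "ImagingConfig"]


def _strict_build(cls, data: dict):
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    return cls(**data)


@dataclass
class ImagingConfig:
    pixel_size_nm: float = 24.0
    frame_interval_s: float = 5.0
    psf: str = "disim"  # widefield | sim | disim


@dataclass
class SegmentationConfig:
    intensity_threshold: float | None = None  # None -> Otsu within nucleus
    min_area_px: int = 12
    mean_intensity_min: float = 0.0
    max_jump_um: float = 1.0
    nucleus_smooth_sigma_px: float = 2.0


@dataclass
class FrapConfig:
    denom_tol: float = 1e-9
    t_start_s: float = 0.0


@dataclass
class SubcompartmentConfig:
    mode: str = "watershed_lag"
    cv_threshold: float = 0.3  # heterogeneity CV above which a focus is multi
    # contour thresholds calibrated on the phantom presets
    # (scripts/calibrate_thresholds.py)
    s_thr: float = 0.97  # mean sphericity below which contour is amorphous
    iou_thr: float = 0.96  # mean frame-to-frame IoU below which contour is amorphous
    lag_contrast_s: float = 5.0
    min_region_px: int = 20
    smooth_sigma_px: float = 2.0


@dataclass
class PipelineConfig:
    imaging: ImagingConfig = field(default_factory=ImagingConfig)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    frap: FrapConfig = field(default_factory=FrapConfig)
    subcompartments: SubcompartmentConfig = field(default_factory=SubcompartmentConfig)
    seed: int = 0

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        blocks = {
            "imaging": ImagingConfig,
            "segmentation": SegmentationConfig,
            "frap": FrapConfig,
            "subcompartments": SubcompartmentConfig,
        }
        kwargs = {}
        for name, bcls in blocks.items():
            kwargs[name] = _strict_build(bcls, data.pop(name, {}))
        kwargs["seed"] = data.pop("seed", 0)
        if data:
            raise ValueError(f"unknown config keys: {sorted(data)}")
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    def digest(self) -> str:
        return hashlib.sha256(json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]
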