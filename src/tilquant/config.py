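"""Pipeline configuration: one serializable record of every tunable constant.

Defaults are the workflow's reference settings: 0.252 um/px scanner
resolution, x16 downsampling for tumour segmentation, 1024 px tiles admitted
at >= 50% tumour, a 100 px^2 minimum cell area, Ruifrok-Johnston H-DAB stain
vectors, and seeded stochastic steps (k-means, bootstraps).  A config
round-trips through YAML unchanged, and its SHA-256 hash is embedded in
every output file for provenance.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .errors import ParameterError
from .image import DEFAULT_MPP


@dataclass
class PipelineConfig:
    mpp: float = DEFAULT_MPP
    downsample_factor: int = 16
    tile_size: int = 1024
    tumour_fraction_min: float = 0.5
    closing_radius: int = 2
    min_object_px: int = 64
    hue_range: tuple[float, float] | None = None
    n_superpixels: int = 200
    min_cell_area_px: int = 100
    max_cell_area_px: int = 5000
    stain_hematoxylin: tuple[float, float, float] = (0.650, 0.704, 0.286)
    stain_dab: tuple[float, float, float] = (0.268, 0.570, 0.776)
    bernsen_window_radius: int = 15
    bernsen_contrast_min: float = 0.08
    bernsen_mid_fixed: float = 0.15
    dust_threshold: float = 50.0
    min_peak_separation: int = 8
    maxstat_minprop: float = 0.1
    maxstat_maxprop: float = 0.9
    n_boot: int = 1000
    seed: int = 0

    def validate(self) -> None:
        if self.mpp <= 0:
            raise ParameterError("mpp must be positive")
        if self.downsample_factor < 1:
            raise ParameterError("downsample_factor must be >= 1")
        if self.tile_size < 1:
            raise ParameterError("tile_size must be >= 1")
        if not 0 <= self.tumour_fraction_min <= 1:
            raise ParameterError("tumour_fraction_min must be in [0, 1]")
        if not 0 <= self.dust_threshold <= 255:
            raise ParameterError("dust_threshold must be in [0, 255]")
        if self.min_cell_area_px < 0 or self.max_cell_area_px < self.min_cell_area_px:
            raise ParameterError("need 0 <= min_cell_area_px <= max_cell_area_px")
        if not 0 <= self.maxstat_minprop < self.maxstat_maxprop <= 1:
            raise ParameterError("need 0 <= minprop < maxprop <= 1")
        if self.n_boot < 1:
            raise ParameterError("n_boot must be >= 1")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["stain_hematoxylin"] = [float(x) for x in d["stain_hematoxylin"]]
        d["stain_dab"] = [float(x) for x in d["stain_dab"]]
        if d["hue_range"] is not None:
            d["hue_range"] = list(d["hue_range"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        for key in ("stain_hematoxylin", "stain_dab"):
            if key in d:
                d[key] = tuple(float(x) for x in d[key])
        if d.get("hue_range") is not None:
            d["hue_range"] = tuple(d["hue_range"])
        cfg = cls(**d)
        cfg.validate()
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]
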