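"""Pipeline configuration: a flat dataclass tree with lossless YAML round-trip."""

from __future__ import annotations

import os
from dataclasses import asdict, dataclass, field

import yaml


@dataclass
class GridConfig:
    rows: int = 15
    cols: int = 20
    tile_size: int = 512


@dataclass
class ROIConfig:
    threshold: float = 0.5


@dataclass
class DetectConfig:
    conf_thr: float = 0.75
    iou_thr: float = 0.5


@dataclass
class HCTConfig:
    min_tiles: int = 80
    tau: float = 1e-4
    patience: int = 5
    bm_me_in_distance: bool = True


@dataclass
class PipelineConfig:
    grid: GridConfig = field(default_factory=GridConfig)
    roi: ROIConfig = field(default_factory=ROIConfig)
    detect: DetectConfig = field(default_factory=DetectConfig)
    hct: HCTConfig = field(default_factory=HCTConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.roi.threshold <= 1.0:
            raise ValueError("roi.threshold must lie in [0, 1]")
        if not 0.0 <= self.detect.conf_thr <= 1.0:
            raise ValueError("detect.conf_thr must lie in [0, 1]")
        if not 0.0 < self.detect.iou_thr <= 1.0:
            raise ValueError("detect.iou_thr must lie in (0, 1]")
        if self.hct.tau <= 0:
            raise ValueError("hct.tau must be positive")
        if self.hct.patience < 1 or self.hct.min_tiles < 1:
            raise ValueError("hct.patience and hct.min_tiles must be >= 1")

    def to_yaml(self, path: str | os.PathLike | None = None) -> str:
        text = yaml.safe_dump(asdict(self), sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, source: str | os.PathLike) -> "PipelineConfig":
        if os.path.exists(str(source)):
            with open(source) as fh:
                data = yaml.safe_load(fh)
        else:
            data = yaml.safe_load(str(source))
        if not isinstance(data, dict):
            raise ValueError("config must be a YAML mapping")
        try:
            return cls(
                grid=GridConfig(**data.get("grid", {})),
                roi=ROIConfig(**data.get("roi", {})),
                detect=DetectConfig(**data.get("detect", {})),
                hct=HCTConfig(**data.get("hct", {})),
                seed=int(data.get("seed", 0)),
            )
        except TypeError as exc:
            raise ValueError(f"invalid config: {exc}") from exc
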