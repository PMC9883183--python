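"""Run configuration: one structured object, YAML round-trip, CLI overrides."""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """Everything a reproducible run needs, with the pipeline defaults.

    ``voxel_pitch_um`` is the isotropic physical voxel edge (7.8 µm for
    the tomography setup this pipeline targets); ``gamma_offset_px`` is
    the maximum inter-slice centroid offset for 3D stitching.
    """

    patch_size: int = 128
    train_stride: int = 64
    learning_rate: float = 1e-5
    weight_decay: float = 0.01
    batch_size: int = 16
    max_epochs: int = 500
    seed: int = 0
    binarize_threshold: float = 0.5
    gamma_offset_px: float = 5.0
    voxel_pitch_um: float = 7.8
    val_fraction: float = 0.2
    clahe_clip_limit: float = 0.01
    clahe_tile_grid: tuple = (8, 8)

    def __post_init__(self):
        if not 0.0 < self.binarize_threshold < 1.0:
            raise ValueError("binarize_threshold must lie strictly in (0, 1)")
        if self.patch_size % 16:
            raise ValueError("patch_size must be divisible by 16 (four poolings)")
        if self.voxel_pitch_um <= 0:
            raise ValueError("voxel_pitch_um must be positive")
        self.clahe_tile_grid = tuple(self.clahe_tile_grid)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["clahe_tile_grid"] = list(self.clahe_tile_grid)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    def replace(self, **overrides) -> "RunConfig":
        d = asdict(self)
        d.update({k: v for k, v in overrides.items() if v is not None})
        return RunConfig(**d)
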