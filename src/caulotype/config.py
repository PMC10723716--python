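"""Run configuration: optics, stage parameters, serialization.

All physical quantities are in micrometres (µm) unless stated otherwise.
Arrays are indexed ``[row, col]``; physical coordinates are
``index * pixel_size`` with the origin at the centre of the top-left pixel.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

U16_MAX = 65535

#: semantic pixel classes, in fixed model order
SEMANTIC_CLASSES = ("background", "cell_body", "stalk")
#: object-level cell classes
CELL_CLASSES = ("stalked", "swarmer", "debris")
#: stalk keep/remove statuses
STALK_STATUSES = ("keep", "remove")
#: final cell-type vocabulary (three-class scheme)
FINAL_TYPES = ("SW", "ST", "PD", "debris")


@dataclass(frozen=True)
class OpticsConfig:
    """Imaging model for the synthetic phase-contrast renderer.

    Defaults give a 2048 x 2048 frame at 0.065 µm/px, i.e. a
    133.12 x 133.12 µm field of view.
    """

    pixel_size: float = 0.065          # µm per pixel
    frame_shape: tuple[int, int] = (2048, 2048)
    psf_sigma: float = 0.09            # µm, in-focus blur
    halo_sigma: float = 0.40           # µm, bright-halo spread
    halo_amplitude: float = 0.55       # dimensionless, relative to cell contrast
    background_level: float = 30000.0  # 16-bit counts
    cell_contrast: float = 12000.0     # counts removed inside a cell body
    stalk_contrast_fraction: float = 0.55  # stalk darkness relative to body
    photon_noise_scale: float = 1.6    # sd = scale * sqrt(signal)
    read_noise_sd: float = 120.0       # counts
    illumination_gradient: float = 0.02  # fractional amplitude of shading

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if min(self.frame_shape) < 64:
            raise ValueError("frame dims must be >= 64 px")
        if not self.psf_sigma < self.halo_sigma:
            raise ValueError("psf_sigma must be smaller than halo_sigma")
        if not (0 <= self.background_level + abs(self.cell_contrast) <= U16_MAX):
            raise ValueError("background_level + |cell_contrast| outside 16-bit range")

    @property
    def field_size_um(self) -> tuple[float, float]:
        return (self.frame_shape[0] * self.pixel_size,
                self.frame_shape[1] * self.pixel_size)

    def to_px(self, um: float) -> float:
        return um / self.pixel_size


def default_optics(**overrides: Any) -> OpticsConfig:
    return OpticsConfig(**overrides)


@dataclass
class PixelTrainConfig:
    scales: tuple[float, ...] = (1.0, 2.0, 4.0, 8.0)  # filter sigmas, px
    n_trees: int = 100
    max_depth: int | None = None
    class_cap: int = 12000        # pixels sampled per class (pooled)
    seed: int = 0


@dataclass
class SegmentationConfig:
    body_prob_threshold: float = 0.5
    stalk_prob_threshold: float = 0.5
    min_cell_area_um2: float = 0.4
    min_stalk_length_um: float = 0.3
    max_stalk_mean_width_um: float = 0.35
    connectivity: int = 2                 # skimage connectivity (2 = 8-neighbour)
    exclude_border: bool = True
    watershed_min_separation_um: float = 0.8
    spur_fraction: float = 0.25           # prune skeleton spurs < this * length


@dataclass
class MorphoConfig:
    interior_fraction: float = 0.8        # central window for constriction search
    pd_threshold: float = 0.25            # constriction degree calling PD
    r_max_um: float = 0.5                 # stalk endpoint to pole attachment radius
    attach_dist_um: float = 0.25          # stalk endpoint to cell contour = "attached"


@dataclass
class RunConfig:
    """Resolved configuration written next to every run's outputs."""

    optics: OpticsConfig = field(default_factory=OpticsConfig)
    pixel_train: PixelTrainConfig = field(default_factory=PixelTrainConfig)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    morpho: MorphoConfig = field(default_factory=MorphoConfig)
    scheme: str = "three_class"           # or "two_class"
    seed: int = 0
    version: str = "0.1.0"

    def to_dict(self) -> dict[str, Any]:
        return _as_plain(dataclasses.asdict(self))

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RunConfig":
        d = dict(d)
        optics = d.pop("optics", {})
        if "frame_shape" in optics:
            optics["frame_shape"] = tuple(optics["frame_shape"])
        kwargs: dict[str, Any] = {
            "optics": OpticsConfig(**optics),
            "pixel_train": PixelTrainConfig(**_tupled(d.pop("pixel_train", {}), "scales")),
            "segmentation": SegmentationConfig(**d.pop("segmentation", {})),
            "morpho": MorphoConfig(**d.pop("morpho", {})),
        }
        kwargs.update(d)
        return cls(**kwargs)

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha1(blob).hexdigest()[:12]


def _tupled(d: dict[str, Any], key: str) -> dict[str, Any]:
    if key in d:
        d = dict(d)
        d[key] = tuple(d[key])
    return d


def _as_plain(obj: Any) -> Any:
    """Recursively convert tuples to lists so YAML stays plain."""
    if isinstance(obj, dict):
        return {k: _as_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_as_plain(v) for v in obj]
    return obj
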