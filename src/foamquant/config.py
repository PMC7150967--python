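"""Run configuration: YAML file plus command-line overrides."""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .phenotype import ClassifierThresholds
from .segment import SegmentationParams
from .synthgen import DEFAULT_PIXEL_SIZE
from .vacuoles import VacuoleParams

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    """Everything a pipeline run needs, validated up front."""

    images_dir: str | None = None
    layout_file: str | None = None
    output_dir: str = "out"
    pixel_size: float = DEFAULT_PIXEL_SIZE
    rng_seed: int = 0
    cells_per_field: int = 35
    field_size: int = 1024
    multipage: bool = False
    log_level: str = "INFO"
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    vacuoles: VacuoleParams = field(default_factory=VacuoleParams)
    thresholds: ClassifierThresholds = field(default_factory=ClassifierThresholds)

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        if self.field_size < 64:
            raise ValueError("field_size must be >= 64 px")
        if self.cells_per_field < 0:
            raise ValueError("cells_per_field must be >= 0")
        # propagate the shared calibration into the segmentation params
        self.segmentation.pixel_size = self.pixel_size

    def validate_paths(self, need_images: bool = False, need_layout: bool = False) -> None:
        if need_images and (self.images_dir is None or not Path(self.images_dir).is_dir()):
            raise FileNotFoundError(f"images dir not found: {self.images_dir}")
        if need_layout and (self.layout_file is None or not Path(self.layout_file).is_file()):
            raise FileNotFoundError(f"layout file not found: {self.layout_file}")

    def digest(self) -> str:
        """Stable hash of the full configuration, for provenance logging."""
        doc = yaml.safe_dump(asdict(self), sort_keys=True)
        return hashlib.sha256(doc.encode()).hexdigest()[:12]


def load_config(path=None, **overrides) -> RunConfig:
    """Build a :class:`RunConfig` from an optional YAML file plus overrides.

    Nested sections ``segmentation``, ``vacuoles`` and ``thresholds`` map to
    their parameter dataclasses; flat override keys win over file values.
    """
    doc: dict = {}
    if path is not None:
        doc = yaml.safe_load(Path(path).read_text()) or {}
    doc.update({k: v for k, v in overrides.items() if v is not None})
    seg = SegmentationParams(**doc.pop("segmentation", {}))
    vac = VacuoleParams(**doc.pop("vacuoles", {}))
    thr = ClassifierThresholds(**doc.pop("thresholds", {}))
    known = {f for f in RunConfig.__dataclass_fields__ if f not in
             ("segmentation", "vacuoles", "thresholds")}
    unknown = set(doc) - known
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    return RunConfig(segmentation=seg, vacuoles=vac, thresholds=thr, **doc)
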