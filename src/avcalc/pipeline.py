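"""End-to-end scoring workflow: landmarks -> annulus plane -> slab ROI ->
threshold segmentation -> manual edits -> Agatston score."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import yaml

from . import agatston, calcium_seg, geometry
from .agatston import AgatstonResult, ScoringConfig
from .ct_io import CTVolume, EditMask, LandmarkSet


@dataclass(frozen=True)
class RunConfig:
    """Full run configuration: scoring constants, slab offsets, connectivity
    and statistics options. Unknown keys in a config file are rejected."""

    scoring: ScoringConfig = ScoringConfig()
    lower_offset_mm: float = geometry.DEFAULT_LOWER_OFFSET_MM
    upper_offset_mm: float = geometry.DEFAULT_UPPER_OFFSET_MM
    connectivity_3d: int = 26
    icc_form: str = "icc2"
    discordance_thresholds_pct: tuple[float, ...] = (5.0, 10.0)
    log_level: str = "INFO"
    seed: int | None = None
    per_leaflet: bool = False

    def __post_init__(self) -> None:
        if not self.lower_offset_mm < self.upper_offset_mm:
            raise ValueError("lower_offset_mm must be < upper_offset_mm")
        if self.connectivity_3d not in (6, 26):
            raise ValueError("connectivity_3d must be 6 or 26")
        if self.icc_form not in {"icc1", "icc2", "icc3", "icc1k", "icc2k", "icc3k"}:
            raise ValueError(f"unknown icc_form {self.icc_form!r}")
        if self.log_level.upper() not in {"DEBUG", "INFO", "WARNING", "ERROR"}:
            raise ValueError(f"unknown log_level {self.log_level!r}")

    @classmethod
    def from_mapping(cls, data: Mapping) -> "RunConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs = dict(data)
        if "scoring" in kwargs and not isinstance(kwargs["scoring"], ScoringConfig):
            kwargs["scoring"] = ScoringConfig.from_mapping(kwargs["scoring"])
        if "discordance_thresholds_pct" in kwargs:
            kwargs["discordance_thresholds_pct"] = tuple(kwargs["discordance_thresholds_pct"])
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError("config YAML must be a mapping")
        return cls.from_mapping(data)


def score_study(
    volume: CTVolume,
    landmarks: LandmarkSet,
    edits: EditMask | None = None,
    config: RunConfig = RunConfig(),
) -> AgatstonResult:
    """Score one CT study with the annulus-referenced semiautomated workflow.

    Fits the annulus plane through the cusp nadirs, restricts to the slab
    from ``lower_offset_mm`` to ``upper_offset_mm`` along the plane normal,
    selects all voxels >= the calcium threshold, applies any manual edits,
    and computes the Agatston score.
    """
    plane = geometry.fit_annulus_plane(landmarks)
    slab = geometry.ROISlab(
        plane=plane,
        lower_offset_mm=config.lower_offset_mm,
        upper_offset_mm=config.upper_offset_mm,
    )
    roi = geometry.slab_mask(volume, slab)
    mask = calcium_seg.threshold_mask(volume, roi, threshold_hu=config.scoring.threshold_hu)
    if edits is not None:
        mask = calcium_seg.apply_edits(mask, edits, volume)
    result = agatston.score_volume(volume, mask, config.scoring)
    if config.per_leaflet and result.lesions:
        result = agatston.attach_per_leaflet(result, plane)
    return result
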