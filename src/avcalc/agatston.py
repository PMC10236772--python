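"""Agatston calcium scoring: density weight x area, summed over per-slice
lesions, plus the calcium volume score and an optional per-leaflet split.

Each per-slice lesion contributes ``area_mm2 * w(peak_hu) * thickness_factor``
where the density weight ``w`` is 1 for peak attenuation in [130, 200) HU,
2 for [200, 300), 3 for [300, 400) and 4 for >= 400 HU. A strict reading
of the traditional integer bin definitions (130-199, 200-299, 300-399,
>400) leaves exactly 400 HU unassigned; the classical >= 400 convention is
adopted and configurable (``hi_bin_inclusive``). The weight uses the
lesion's *peak* HU, the classical rule.

``thickness_factor = slice_thickness_mm / 3.0`` so 3 mm acquisitions — the
standard non-contrast calcium-scoring protocol — score with factor 1, and
thinner reconstructions remain comparable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .calcium_seg import CalciumMask, Lesion, label_lesions
from .ct_io import CTVolume, GeometryError
from .geometry import AnnulusPlane, signed_distance


@dataclass(frozen=True)
class ScoringConfig:
    """Tunable constants of the Agatston scorer.

    threshold_hu : calcium detection threshold, HU (classical 130).
    min_lesion_area_mm2 : lesions with smaller area are dropped before
        scoring (classical 1 mm^2 convention).
    weight_boundaries : lower edges of the density-weight bins, HU.
    hi_bin_inclusive : whether exactly 400 HU maps to weight 4 (classical)
        rather than falling into the published bins' gap.
    connectivity_2d : in-plane lesion connectivity, 4 or 8.
    thickness_reference_mm : slice thickness that scores with factor 1.
    """

    threshold_hu: float = 130.0
    min_lesion_area_mm2: float = 1.0
    weight_boundaries: tuple[float, float, float, float] = (130.0, 200.0, 300.0, 400.0)
    hi_bin_inclusive: bool = True
    connectivity_2d: int = 8
    thickness_reference_mm: float = 3.0

    def __post_init__(self) -> None:
        b = tuple(float(x) for x in self.weight_boundaries)
        if len(b) != 4 or any(b[i] >= b[i + 1] for i in range(3)):
            raise ValueError(f"weight_boundaries must be 4 increasing values, got {b}")
        object.__setattr__(self, "weight_boundaries", b)
        if self.connectivity_2d not in (4, 8):
            raise ValueError("connectivity_2d must be 4 or 8")
        if self.thickness_reference_mm <= 0:
            raise ValueError("thickness_reference_mm must be positive")

    @classmethod
    def from_mapping(cls, data: Mapping) -> "ScoringConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown scoring config keys: {sorted(unknown)}")
        kwargs = dict(data)
        if "weight_boundaries" in kwargs:
            kwargs["weight_boundaries"] = tuple(kwargs["weight_boundaries"])
        return cls(**kwargs)


DEFAULT_CONFIG = ScoringConfig()


@dataclass(frozen=True)
class LesionScore:
    """One scored per-slice lesion."""

    slice_index: int
    area_mm2: float
    peak_hu: float
    weight: int
    lesion_score: float
    centroid_mm: tuple[float, float, float]


@dataclass
class AgatstonResult:
    """Total Agatston score, per-lesion breakdown and calcium volume."""

    total_score: float
    lesions: list[LesionScore]
    volume_mm3: float
    thickness_factor: float
    per_leaflet: dict[str, float] | None = None

    def to_dict(self) -> dict:
        return {
            "total_score": self.total_score,
            "volume_mm3": self.volume_mm3,
            "thickness_factor": self.thickness_factor,
            "n_lesions": len(self.lesions),
            "lesions": [
                {
                    "slice_index": l.slice_index,
                    "area_mm2": l.area_mm2,
                    "peak_hu": l.peak_hu,
                    "weight": l.weight,
                    "lesion_score": l.lesion_score,
                    "centroid_mm": list(l.centroid_mm),
                }
                for l in self.lesions
            ],
            "per_leaflet": self.per_leaflet,
        }


def density_weight(peak_hu: float, config: ScoringConfig = DEFAULT_CONFIG) -> int:
    """Density weighting factor in {0, 1, 2, 3, 4} for a lesion's peak HU."""
    b = config.weight_boundaries
    if peak_hu < b[0]:
        return 0
    if peak_hu < b[1]:
        return 1
    if peak_hu < b[2]:
        return 2
    if peak_hu < b[3]:
        return 3
    if peak_hu > b[3] or config.hi_bin_inclusive:
        return 4
    return 3  # exactly at the top boundary with the strict >400 reading


def lesion_score(lesion: Lesion, thickness_factor: float = 1.0,
                 config: ScoringConfig = DEFAULT_CONFIG) -> float:
    """Agatston contribution of one lesion: area x density weight x factor."""
    return lesion.area_mm2 * density_weight(lesion.peak_hu, config) * thickness_factor


def thickness_factor_for(volume: CTVolume, config: ScoringConfig = DEFAULT_CONFIG) -> float:
    if volume.slice_thickness_mm <= 0:
        raise GeometryError("zero or negative slice thickness")
    return volume.slice_thickness_mm / config.thickness_reference_mm


def score_volume(
    volume: CTVolume,
    mask: CalciumMask,
    config: ScoringConfig = DEFAULT_CONFIG,
) -> AgatstonResult:
    """Score a calcium mask: label per-slice lesions, drop those below the
    minimum area, weight by peak HU and sum.

    ``volume_mm3`` counts every mask voxel (including sub-minimum lesions)
    times the voxel volume.
    """
    factor = thickness_factor_for(volume, config)
    raw = label_lesions(mask, volume, connectivity_2d=config.connectivity_2d)
    scored: list[LesionScore] = []
    for les in raw:
        if les.area_mm2 < config.min_lesion_area_mm2:
            continue
        w = density_weight(les.peak_hu, config)
        idx3 = np.column_stack(
            [les.voxel_indices, np.full(les.n_voxels, les.slice_index)]
        )
        centroid = volume.index_to_world(idx3).mean(axis=0)
        scored.append(
            LesionScore(
                slice_index=les.slice_index,
                area_mm2=les.area_mm2,
                peak_hu=les.peak_hu,
                weight=w,
                lesion_score=les.area_mm2 * w * factor,
                centroid_mm=tuple(float(c) for c in centroid),
            )
        )
    # fsum: exactly rounded, order-independent accumulation
    total = math.fsum(l.lesion_score for l in scored)
    volume_mm3 = float(mask.mask.sum()) * volume.voxel_volume_mm3
    return AgatstonResult(
        total_score=total,
        lesions=scored,
        volume_mm3=volume_mm3,
        thickness_factor=factor,
    )


class LeafletAssignmentError(ValueError):
    """A lesion centroid cannot be assigned to an angular sector."""


def per_leaflet_scores(
    result: AgatstonResult,
    plane: AnnulusPlane,
) -> dict[str, float]:
    """Split the total score over three leaflet sectors around the annulus.

    The three nadirs are projected onto the annulus plane; the directions
    from their in-plane centroid to each projected nadir divide the plane
    into three angular sectors (each sector lies between two adjacent nadir
    directions). Each lesion is assigned whole, by the projection of its
    centroid, to one sector. Sector scores sum to the total.
    """
    if plane.source_landmarks is None:
        raise LeafletAssignmentError("plane carries no source landmarks")
    nadirs = plane.source_landmarks.nadir_points
    n = plane.normal
    # orthonormal in-plane basis
    seed = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(seed, n)) > 0.9:
        seed = np.array([0.0, 1.0, 0.0])
    u = seed - np.dot(seed, n) * n
    u /= np.linalg.norm(u)
    v = np.cross(n, u)

    def project(p: np.ndarray) -> np.ndarray:
        rel = p - plane.point
        return np.array([np.dot(rel, u), np.dot(rel, v)])

    proj_nadirs = np.array([project(p) for p in nadirs])
    center = proj_nadirs.mean(axis=0)
    angles = np.arctan2(*(proj_nadirs - center).T[::-1])  # atan2(y, x)
    order = np.argsort(angles)
    sorted_angles = angles[order]

    ids = [f"leaflet_{i}" for i in range(3)]
    scores = {i: 0.0 for i in ids}
    for les in result.lesions:
        rel = project(np.asarray(les.centroid_mm)) - center
        if np.linalg.norm(rel) < 1e-12:
            raise LeafletAssignmentError(
                f"lesion centroid at slice {les.slice_index} projects onto the "
                "nadir centroid; sector angle undefined"
            )
        theta = float(np.arctan2(rel[1], rel[0]))
        # sector s spans [sorted_angles[s], sorted_angles[s+1]) cyclically
        sector = int(np.searchsorted(sorted_angles, theta, side="right") - 1) % 3
        scores[ids[sector]] += les.lesion_score
    return scores


def attach_per_leaflet(result: AgatstonResult, plane: AnnulusPlane) -> AgatstonResult:
    result.per_leaflet = per_leaflet_scores(result, plane)
    return result
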