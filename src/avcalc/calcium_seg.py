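"""Calcium candidate segmentation: thresholding, region growing, manual
edits and per-slice lesion labelling.

Calcium is defined by a fixed attenuation threshold of 130 HU (inclusive);
the automatic step selects every supra-threshold voxel inside the ROI.
Region growing expands a seed to its full connected supra-threshold
component and, when given an ROI, never crosses the ROI boundary — this is
how calcium that touches extra-valvular calcium (e.g. the mitral annulus)
across the slab face is kept out of the score; residual contact cases are
handled by manual exclude edits.

Scoring units are *per axial slice*: lesions are the maximal in-plane
8-connected components on each slice, because the Agatston score sums
density-weighted areas, a per-slice quantity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
from scipy import ndimage
from skimage import measure

from .ct_io import CTVolume, EditMask

DEFAULT_THRESHOLD_HU = 130.0

# provenance codes
PROV_NONE = 0
PROV_AUTO = 1
PROV_MANUAL_INCLUDE = 2
PROV_MANUAL_EXCLUDE_REMOVED = 3

PROVENANCE_NAMES = {
    PROV_NONE: "none",
    PROV_AUTO: "auto",
    PROV_MANUAL_INCLUDE: "manual_include",
    PROV_MANUAL_EXCLUDE_REMOVED: "manual_exclude_removed",
}


class AlignmentError(ValueError):
    """Mask/volume grids do not share a shape."""


@dataclass
class CalciumMask:
    """Boolean calcium mask aligned to a CT volume, with per-voxel provenance."""

    mask: np.ndarray
    provenance: np.ndarray  # uint8 codes, see PROVENANCE_NAMES
    threshold_hu: float = DEFAULT_THRESHOLD_HU

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        self.provenance = np.asarray(self.provenance, dtype=np.uint8)
        if self.mask.shape != self.provenance.shape:
            raise AlignmentError("mask and provenance grids must share a shape")
        if np.any(self.mask & (self.provenance == PROV_MANUAL_EXCLUDE_REMOVED)):
            raise ValueError("voxels tagged manual_exclude_removed cannot be in the mask")


@dataclass(frozen=True)
class Lesion:
    """A per-slice connected calcium region (the Agatston scoring unit)."""

    slice_index: int
    voxel_indices: np.ndarray  # (n, 2) in-plane (i, j) indices
    area_mm2: float
    peak_hu: float

    @property
    def n_voxels(self) -> int:
        return int(self.voxel_indices.shape[0])


def threshold_mask(
    volume: CTVolume,
    roi: np.ndarray,
    threshold_hu: float = DEFAULT_THRESHOLD_HU,
) -> CalciumMask:
    """All voxels inside the ROI with attenuation >= threshold (130 HU default)."""
    roi = np.asarray(roi, dtype=bool)
    if roi.shape != volume.shape:
        raise AlignmentError(
            f"ROI shape {roi.shape} does not match volume shape {volume.shape}"
        )
    mask = roi & (volume.voxels >= threshold_hu)
    prov = np.where(mask, PROV_AUTO, PROV_NONE).astype(np.uint8)
    return CalciumMask(mask=mask, provenance=prov, threshold_hu=threshold_hu)


def _structure_3d(connectivity: int) -> np.ndarray:
    if connectivity == 6:
        return ndimage.generate_binary_structure(3, 1)
    if connectivity == 26:
        return ndimage.generate_binary_structure(3, 3)
    raise ValueError(f"3D connectivity must be 6 or 26, got {connectivity}")


def region_grow(
    volume: CTVolume,
    seed: tuple[int, int, int],
    threshold_hu: float = DEFAULT_THRESHOLD_HU,
    connectivity: int = 26,
    roi: np.ndarray | None = None,
) -> set[tuple[int, int, int]]:
    """Maximal connected supra-threshold component containing the seed.

    With an ROI, growth is restricted to ROI voxels (the grown region never
    crosses the slab boundary). Returns the voxel index set.
    """
    seed = tuple(int(s) for s in seed)
    if volume.voxels[seed] < threshold_hu:
        raise ValueError(
            f"seed {seed} has attenuation {volume.voxels[seed]:.1f} HU, "
            f"below the {threshold_hu} HU threshold"
        )
    supra = volume.voxels >= threshold_hu
    if roi is not None:
        roi = np.asarray(roi, dtype=bool)
        if roi.shape != volume.shape:
            raise AlignmentError("ROI shape does not match volume shape")
        if not roi[seed]:
            raise ValueError(f"seed {seed} lies outside the ROI")
        supra &= roi
    labels, _ = ndimage.label(supra, structure=_structure_3d(connectivity))
    component = labels == labels[seed]
    return {tuple(int(v) for v in idx) for idx in np.argwhere(component)}


def apply_edits(mask: CalciumMask, edits: EditMask, volume: CTVolume) -> CalciumMask:
    """Apply manual include/exclude edits.

    Excluded voxels are removed regardless of attenuation. Included voxels
    are added only if supra-threshold: the attenuation requirement is never
    overridden. Idempotent.
    """
    if edits.include.shape != mask.mask.shape:
        raise AlignmentError("edit mask shape does not match calcium mask shape")
    if volume.shape != mask.mask.shape:
        raise AlignmentError("volume shape does not match calcium mask shape")
    supra = volume.voxels >= mask.threshold_hu
    add = edits.include & supra & ~mask.mask
    new_mask = (mask.mask | add) & ~edits.exclude
    prov = mask.provenance.copy()
    prov[add] = PROV_MANUAL_INCLUDE
    removed = edits.exclude & mask.mask
    prov[removed] = PROV_MANUAL_EXCLUDE_REMOVED
    return CalciumMask(mask=new_mask, provenance=prov, threshold_hu=mask.threshold_hu)


def label_lesions(
    mask: CalciumMask,
    volume: CTVolume,
    connectivity_2d: int = 8,
) -> list[Lesion]:
    """Partition the mask, slice by slice, into in-plane connected lesions.

    Each lesion carries its physical area (voxel count x in-plane pixel
    area) and peak attenuation. ``connectivity_2d`` is 4 or 8 (8 is the
    classical Agatston convention: diagonal contact joins a lesion).
    """
    if mask.mask.shape != volume.shape:
        raise AlignmentError("mask shape does not match volume shape")
    if connectivity_2d not in (4, 8):
        raise ValueError(f"in-plane connectivity must be 4 or 8, got {connectivity_2d}")
    skimage_conn = 1 if connectivity_2d == 4 else 2
    pixel_area = volume.pixel_area_mm2
    lesions: list[Lesion] = []
    for k in range(volume.shape[2]):
        plane = mask.mask[:, :, k]
        if not plane.any():
            continue
        labels = measure.label(plane, connectivity=skimage_conn)
        for lab in range(1, labels.max() + 1):
            idx = np.argwhere(labels == lab)
            hu = volume.voxels[idx[:, 0], idx[:, 1], k]
            lesions.append(
                Lesion(
                    slice_index=k,
                    voxel_indices=idx,
                    area_mm2=float(idx.shape[0] * pixel_area),
                    peak_hu=float(hu.max()),
                )
            )
    return lesions
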