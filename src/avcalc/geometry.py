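"""Annulus plane construction and the slab region of interest.

The aortic annulus plane is the plane through the nadirs (lowest insertion
points) of the three valve cusps; its normal is oriented toward the
ascending aorta using the aortic-side reference landmark. The region of
interest for automatic calcium selection is a slab bounded at fixed signed
distances along the plane normal, by default 5.0 mm below to 20 mm above
the annulus. Distances are true 3D point-plane distances (measured along
the normal), not scanner-axis offsets, so oblique annuli are handled
correctly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .ct_io import CTVolume, LandmarkSet

DEFAULT_LOWER_OFFSET_MM = -5.0
DEFAULT_UPPER_OFFSET_MM = 20.0


class DegenerateGeometryError(ValueError):
    pass


@dataclass(frozen=True)
class AnnulusPlane:
    """Plane through the three cusp nadirs, normal pointing to the aortic side."""

    point: np.ndarray  # (3,) mm, a point on the plane
    normal: np.ndarray  # (3,) unit vector, positive side = aortic side
    source_landmarks: LandmarkSet | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "point", np.asarray(self.point, dtype=float).reshape(3))
        n = np.asarray(self.normal, dtype=float).reshape(3)
        if abs(np.linalg.norm(n) - 1.0) > 1e-9:
            raise DegenerateGeometryError("plane normal must be unit length")
        object.__setattr__(self, "normal", n)


@dataclass(frozen=True)
class ROISlab:
    """Signed-distance slab around the annulus plane (closed interval, mm)."""

    plane: AnnulusPlane
    lower_offset_mm: float = DEFAULT_LOWER_OFFSET_MM
    upper_offset_mm: float = DEFAULT_UPPER_OFFSET_MM

    def __post_init__(self) -> None:
        if not self.lower_offset_mm < self.upper_offset_mm:
            raise ValueError(
                f"lower_offset_mm ({self.lower_offset_mm}) must be < "
                f"upper_offset_mm ({self.upper_offset_mm})"
            )


def fit_annulus_plane(landmarks: LandmarkSet) -> AnnulusPlane:
    """Fit the annulus plane through the three cusp nadirs.

    The normal is the unit cross product of two triangle edges, with its
    sign chosen so that the aortic reference landmark lies on the positive
    side ("above" the annulus).
    """
    nadirs = landmarks.nadir_points
    cross = np.cross(nadirs[1] - nadirs[0], nadirs[2] - nadirs[0])
    norm = np.linalg.norm(cross)
    if norm <= 2e-6:  # triangle area <= 1e-6 mm^2
        raise DegenerateGeometryError("nadir points are collinear")
    normal = cross / norm
    centroid = nadirs.mean(axis=0)
    if np.dot(landmarks.aortic_reference - centroid, normal) < 0:
        normal = -normal
    return AnnulusPlane(point=centroid, normal=normal, source_landmarks=landmarks)


def signed_distance(plane: AnnulusPlane, point: np.ndarray) -> float | np.ndarray:
    """Signed point-plane distance in mm; positive on the aortic side.

    Accepts a single point (shape ``(3,)``) or an array of points
    (shape ``(..., 3)``).
    """
    pts = np.asarray(point, dtype=float)
    d = (pts - plane.point) @ plane.normal
    return float(d) if pts.ndim == 1 else d


def slab_mask(volume: CTVolume, slab: ROISlab) -> np.ndarray:
    """Boolean mask of voxels whose *center* lies inside the slab.

    Membership is a closed interval on the signed distance:
    ``lower_offset_mm <= d <= upper_offset_mm``. Because the signed distance
    is affine in the voxel index, it is evaluated by broadcasting per-axis
    distance increments rather than materialising world coordinates.
    """
    n = slab.plane.normal
    # distance gradient per unit index step along each grid axis
    step = (volume.orientation * volume.spacing) .T @ n  # (3,)
    d0 = float(np.dot(volume.origin - slab.plane.point, n))
    ni, nj, nk = volume.shape
    di = d0 + step[0] * np.arange(ni)[:, None, None]
    dj = step[1] * np.arange(nj)[None, :, None]
    dk = step[2] * np.arange(nk)[None, None, :]
    d = di + dj + dk
    mask = (d >= slab.lower_offset_mm) & (d <= slab.upper_offset_mm)
    if not mask.any():
        warnings.warn(
            "ROI slab does not intersect the volume; the calcium mask will be empty",
            stacklevel=2,
        )
    return mask
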