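"""Reading and writing CT volumes, annulus landmarks, edit masks and reports.

Geometry convention
-------------------
All patient-space geometry is in millimetres, right-handed. Voxel indices
are 0-based and a voxel's position is its *center*:

    world = origin + orientation @ (spacing * index)

where ``orientation`` is a 3x3 matrix whose column ``a`` is the patient-space
direction of grid axis ``a``. Axis 2 of the voxel array is the slice axis
(the axis the per-slice Agatston lesions are defined on). Coordinates are
kept in the native patient frame of the source file (LPS for DICOM, RAS for
NIfTI); landmarks must be supplied in the same frame as the volume they
annotate.
"""

from __future__ import annotations

import csv
import json
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np


class GeometryError(ValueError):
    """Inconsistent or degenerate spatial metadata."""


class LandmarkValidationError(ValueError):
    """A landmark file violates the LandmarkSet invariants."""


_ORTHONORMAL_TOL = 1e-6


@dataclass
class CTVolume:
    """A 3D CT attenuation grid in Hounsfield units with patient-space geometry.

    Attributes
    ----------
    voxels : (ni, nj, nk) float array
        Attenuation in HU; axis 2 is the slice axis.
    spacing : (3,) float array
        Voxel size per grid axis in mm, strictly positive.
    origin : (3,) float array
        Patient-space position of the center of voxel (0, 0, 0), mm.
    orientation : (3, 3) float array
        Direction-cosine matrix; column a is the unit patient-space
        direction of grid axis a.
    """

    voxels: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray
    orientation: np.ndarray

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=float)
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.orientation = np.asarray(self.orientation, dtype=float).reshape(3, 3)
        if self.voxels.ndim != 3:
            raise GeometryError("voxel array must be 3-dimensional")
        if not np.all(self.spacing > 0):
            raise GeometryError(f"spacing must be strictly positive, got {self.spacing}")
        if not np.allclose(
            self.orientation.T @ self.orientation, np.eye(3), atol=_ORTHONORMAL_TOL
        ):
            raise GeometryError("orientation matrix is not orthonormal")
        if not np.all(np.isfinite(self.voxels)):
            raise GeometryError("voxel values must all be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def pixel_area_mm2(self) -> float:
        """In-plane pixel area (axes 0 and 1) in mm^2."""
        return float(self.spacing[0] * self.spacing[1])

    @property
    def slice_thickness_mm(self) -> float:
        return float(self.spacing[2])

    def index_to_world(self, index: np.ndarray) -> np.ndarray:
        """Patient-space position (mm) of voxel center(s); index shape (..., 3)."""
        idx = np.asarray(index, dtype=float)
        return self.origin + (idx * self.spacing) @ self.orientation.T

    @property
    def affine(self) -> np.ndarray:
        """4x4 index-to-world affine (homogeneous)."""
        aff = np.eye(4)
        aff[:3, :3] = self.orientation * self.spacing
        aff[:3, 3] = self.origin
        return aff


@dataclass(frozen=True)
class LandmarkSet:
    """Annulus landmarks: the three cusp-nadir points plus one point on the
    ascending-aorta side that fixes the 'above the annulus' direction.
    """

    nadir_points: np.ndarray  # (3, 3) mm
    aortic_reference: np.ndarray  # (3,) mm

    def __post_init__(self) -> None:
        nadirs = np.asarray(self.nadir_points, dtype=float)
        ref = np.asarray(self.aortic_reference, dtype=float).reshape(3)
        if nadirs.shape != (3, 3):
            raise LandmarkValidationError(
                f"exactly three 3D nadir points required, got shape {nadirs.shape}"
            )
        object.__setattr__(self, "nadir_points", nadirs)
        object.__setattr__(self, "aortic_reference", ref)
        for i in range(3):
            for j in range(i + 1, 3):
                if np.array_equal(nadirs[i], nadirs[j]):
                    raise LandmarkValidationError(
                        f"nadir points {i} and {j} coincide"
                    )
        cross = np.cross(nadirs[1] - nadirs[0], nadirs[2] - nadirs[0])
        area = 0.5 * float(np.linalg.norm(cross))
        if area <= 1e-6:
            raise LandmarkValidationError(
                f"nadir points are collinear (triangle area {area:.3g} mm^2)"
            )
        normal = cross / np.linalg.norm(cross)
        dist = float(np.dot(ref - nadirs[0], normal))
        if abs(dist) <= 1e-6:
            raise LandmarkValidationError(
                "aortic_reference lies on the nadir plane "
                f"(signed distance {dist:.3g} mm)"
            )


@dataclass
class EditMask:
    """Manual include/exclude edits to a calcium mask.

    ``include`` voxels are forced into the mask (only if supra-threshold,
    see :func:`avcalc.calcium_seg.apply_edits`); ``exclude`` voxels are
    forced out regardless of attenuation. Stored as boolean grids aligned
    to the CT volume.
    """

    include: np.ndarray
    exclude: np.ndarray

    def __post_init__(self) -> None:
        self.include = np.asarray(self.include, dtype=bool)
        self.exclude = np.asarray(self.exclude, dtype=bool)
        if self.include.shape != self.exclude.shape:
            raise ValueError("include and exclude grids must have the same shape")
        if np.any(self.include & self.exclude):
            raise ValueError("include and exclude voxel sets must be disjoint")

    @classmethod
    def empty(cls, shape: tuple[int, int, int]) -> "EditMask":
        z = np.zeros(shape, dtype=bool)
        return cls(include=z, exclude=z.copy())


# ---------------------------------------------------------------------------
# volume I/O


def read_volume(path: str | os.PathLike, format: str | None = None) -> CTVolume:
    """Read a CT volume from a DICOM series directory, NIfTI or NRRD file.

    Voxel values are calibrated Hounsfield units (DICOM rescale slope and
    intercept are applied). ``format`` is one of ``dicom-series``, ``nifti``,
    ``nrrd``; if omitted it is inferred from the path.
    """
    p = Path(path)
    if format is None:
        format = _infer_format(p)
    if not p.exists():
        raise IOError(f"volume path does not exist: {p}")
    if format == "dicom-series":
        return _read_dicom_series(p)
    if format == "nifti":
        return _read_nifti(p)
    if format == "nrrd":
        return _read_nrrd(p)
    raise ValueError(f"unknown volume format: {format!r}")


def write_volume(volume: CTVolume, path: str | os.PathLike) -> None:
    """Write a volume to NIfTI (.nii/.nii.gz) or NRRD (.nrrd) by extension."""
    p = Path(path)
    fmt = _infer_format(p)
    if fmt == "nifti":
        import nibabel as nib

        img = nib.Nifti1Image(volume.voxels.astype(np.float64), volume.affine)
        nib.save(img, str(p))
    elif fmt == "nrrd":
        import SimpleITK as sitk

        img = sitk.GetImageFromArray(np.ascontiguousarray(volume.voxels.T))
        img.SetSpacing(tuple(volume.spacing))
        img.SetOrigin(tuple(volume.origin))
        img.SetDirection(tuple(volume.orientation.flatten()))
        sitk.WriteImage(img, str(p))
    else:
        raise ValueError(f"cannot write volume format {fmt!r} (DICOM writing unsupported)")


def _infer_format(p: Path) -> str:
    if p.is_dir():
        return "dicom-series"
    name = p.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        return "nifti"
    if name.endswith(".nrrd"):
        return "nrrd"
    if name.endswith(".dcm"):
        return "dicom-series"
    raise ValueError(f"cannot infer volume format from path {p}")


def _read_nifti(p: Path) -> CTVolume:
    import nibabel as nib

    try:
        img = nib.load(str(p))
    except Exception as exc:  # nibabel raises several types for corrupt files
        raise IOError(f"failed to read NIfTI {p}: {exc}") from exc
    data = np.asarray(img.get_fdata(), dtype=float)
    if data.ndim != 3:
        raise GeometryError(f"expected a 3D NIfTI volume, got shape {data.shape}")
    aff = img.affine
    lin = aff[:3, :3]
    spacing = np.linalg.norm(lin, axis=0)
    if np.any(spacing <= 0):
        raise GeometryError(f"non-positive voxel spacing in {p}")
    orientation = lin / spacing
    return CTVolume(voxels=data, spacing=spacing, origin=aff[:3, 3], orientation=orientation)


def _read_nrrd(p: Path) -> CTVolume:
    import SimpleITK as sitk

    try:
        img = sitk.ReadImage(str(p))
    except RuntimeError as exc:
        raise IOError(f"failed to read NRRD {p}: {exc}") from exc
    data = sitk.GetArrayFromImage(img).T.astype(float)  # (z,y,x) -> (x,y,z)
    if data.ndim != 3:
        raise GeometryError(f"expected a 3D NRRD volume, got shape {data.shape}")
    orientation = np.asarray(img.GetDirection(), dtype=float).reshape(3, 3)
    return CTVolume(
        voxels=data,
        spacing=np.asarray(img.GetSpacing()),
        origin=np.asarray(img.GetOrigin()),
        orientation=orientation,
    )


def _read_dicom_series(p: Path) -> CTVolume:
    import pydicom

    paths = sorted(q for q in p.iterdir() if q.is_file())
    datasets = []
    for q in paths:
        try:
            ds = pydicom.dcmread(str(q))
        except Exception:
            continue  # skip non-DICOM files (e.g. DICOMDIR leftovers)
        if hasattr(ds, "PixelData"):
            datasets.append(ds)
    if not datasets:
        raise IOError(f"no DICOM image slices found under {p}")

    iop0 = np.asarray(datasets[0].ImageOrientationPatient, dtype=float)
    ps0 = np.asarray(datasets[0].PixelSpacing, dtype=float)
    for ds in datasets[1:]:
        if not np.allclose(np.asarray(ds.ImageOrientationPatient, dtype=float), iop0, atol=1e-6):
            raise GeometryError("DICOM slices do not share a common orientation")
        if not np.allclose(np.asarray(ds.PixelSpacing, dtype=float), ps0, atol=1e-6):
            raise GeometryError("DICOM slices do not share a common in-plane pixel spacing")

    col_dir = iop0[:3]  # direction of increasing column index
    row_dir = iop0[3:]  # direction of increasing row index
    normal = np.cross(col_dir, row_dir)
    # sort slices along the geometric normal, not by InstanceNumber
    positions = [float(np.dot(np.asarray(ds.ImagePositionPatient, dtype=float), normal)) for ds in datasets]
    order = np.argsort(positions)
    datasets = [datasets[i] for i in order]
    positions = [positions[i] for i in order]

    if len(datasets) > 1:
        steps = np.diff(positions)
        if np.any(steps <= 1e-9):
            raise GeometryError("DICOM slice positions are not strictly monotone along the normal")
        if not np.allclose(steps, steps[0], atol=1e-3):
            raise GeometryError("DICOM slice spacing is not uniform")
        slice_step = float(steps[0])
    else:
        slice_step = float(getattr(datasets[0], "SliceThickness", 1.0) or 1.0)

    slices = []
    for ds in datasets:
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        slices.append(ds.pixel_array.astype(float) * slope + intercept)
    voxels = np.stack(slices, axis=-1)  # (row, col, slice)

    orientation = np.column_stack([row_dir, col_dir, normal])
    spacing = np.array([ps0[0], ps0[1], slice_step])  # (row, col, slice) mm
    origin = np.asarray(datasets[0].ImagePositionPatient, dtype=float)
    return CTVolume(voxels=voxels, spacing=spacing, origin=origin, orientation=orientation)


# ---------------------------------------------------------------------------
# landmarks


def read_landmarks(path: str | os.PathLike) -> LandmarkSet:
    """Read a landmark JSON file.

    Dialect: ``{"nadir_points": [[x,y,z]*3], "aortic_reference": [x,y,z]}``,
    in mm, patient space (same frame as the volume).
    """
    p = Path(path)
    if not p.exists():
        raise IOError(f"landmark file does not exist: {p}")
    with open(p) as fh:
        try:
            payload = json.load(fh)
        except json.JSONDecodeError as exc:
            raise IOError(f"malformed landmark JSON {p}: {exc}") from exc
    if "nadir_points" not in payload:
        raise LandmarkValidationError("landmark file lacks 'nadir_points'")
    if "aortic_reference" not in payload:
        raise LandmarkValidationError("landmark file lacks 'aortic_reference'")
    nadirs = np.asarray(payload["nadir_points"], dtype=float)
    if nadirs.shape != (3, 3):
        raise LandmarkValidationError(
            f"'nadir_points' must be three 3D points, got shape {nadirs.shape}"
        )
    return LandmarkSet(nadir_points=nadirs, aortic_reference=np.asarray(payload["aortic_reference"], dtype=float))


def write_landmarks(landmarks: LandmarkSet, path: str | os.PathLike) -> None:
    payload = {
        "nadir_points": landmarks.nadir_points.tolist(),
        "aortic_reference": landmarks.aortic_reference.tolist(),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


# ---------------------------------------------------------------------------
# edit masks


def read_edit_mask(path: str | os.PathLike, volume: CTVolume) -> EditMask:
    """Read an edit mask from a NIfTI label volume aligned to the CT grid.

    Label 1 = force-include, 2 = force-exclude, 0 = untouched.
    """
    labels = read_volume(path, format="nifti")
    if labels.shape != volume.shape:
        raise GeometryError(
            f"edit mask shape {labels.shape} does not match volume shape {volume.shape}"
        )
    lab = np.rint(labels.voxels).astype(int)
    return EditMask(include=lab == 1, exclude=lab == 2)


# ---------------------------------------------------------------------------
# reports


def write_report(result: Any, path: str | os.PathLike, format: str = "json") -> None:
    """Write an AgatstonResult or AgreementReport to JSON (canonical) or CSV.

    JSON round-trips all numeric fields exactly (within 1e-9); the CSV is a
    flat table: one row per lesion plus one summary row for score reports,
    key/value rows for agreement reports.
    """
    p = Path(path)
    if not p.parent.exists():
        raise IOError(f"output directory does not exist: {p.parent}")
    payload = result.to_dict() if hasattr(result, "to_dict") else dict(result)
    if format == "json":
        with open(p, "w") as fh:
            json.dump(payload, fh, indent=2)
    elif format == "csv":
        _write_report_csv(payload, p)
    else:
        raise ValueError(f"unknown report format {format!r}")


def _write_report_csv(payload: Mapping[str, Any], p: Path) -> None:
    with open(p, "w", newline="") as fh:
        writer = csv.writer(fh)
        if "lesions" in payload:  # Agatston-style report
            writer.writerow(["row_type", "slice_index", "area_mm2", "peak_hu", "weight", "lesion_score"])
            for les in payload["lesions"]:
                writer.writerow(
                    ["lesion", les["slice_index"], repr(les["area_mm2"]),
                     repr(les["peak_hu"]), les["weight"], repr(les["lesion_score"])]
                )
            writer.writerow(["total", "", "", "", "", repr(payload["total_score"])])
            writer.writerow(["volume_mm3", "", "", "", "", repr(payload["volume_mm3"])])
        else:  # flat key/value rows
            writer.writerow(["key", "value"])
            for key, value in _flatten(payload):
                writer.writerow([key, value])


def _flatten(obj: Any, prefix: str = ""):
    if isinstance(obj, Mapping):
        for k, v in obj.items():
            yield from _flatten(v, f"{prefix}{k}." if not prefix else f"{prefix}{k}.")
    elif isinstance(obj, (list, tuple)):
        for i, v in enumerate(obj):
            yield from _flatten(v, f"{prefix}{i}.")
    else:
        yield prefix.rstrip("."), obj


def read_report(path: str | os.PathLike) -> dict:
    """Read back a JSON report written by :func:`write_report`."""
    with open(path) as fh:
        return json.load(fh)
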