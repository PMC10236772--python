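"""Volume, landmark and report I/O with HU calibration and geometry checks."""

import json

import numpy as np
import pytest

from avcalc.agatston import AgatstonResult, LesionScore
from avcalc.ct_io import (
    EditMask,
    GeometryError,
    LandmarkValidationError,
    read_edit_mask,
    read_landmarks,
    read_report,
    read_volume,
    write_landmarks,
    write_report,
    write_volume,
)

from conftest import make_volume


def write_dicom_series(dirpath, stored, slope=1.0, intercept=-1024.0,
                       spacing=(0.5, 0.6), positions=None, orientations=None):
    """Write a synthetic CT DICOM series; ``stored`` is (rows, cols, slices)
    of uint16 stored values."""
    import pydicom
    from pydicom.dataset import FileDataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, generate_uid

    stored = np.asarray(stored, dtype=np.uint16)
    rows, cols, n_slices = stored.shape
    series_uid = generate_uid()
    if positions is None:
        positions = [[0.0, 0.0, 3.0 * k] for k in range(n_slices)]
    if orientations is None:
        orientations = [[1, 0, 0, 0, 1, 0]] * n_slices
    for k in range(n_slices):
        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = pydicom.uid.CTImageStorage
        meta.MediaStorageSOPInstanceUID = generate_uid()
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds = FileDataset(None, {}, file_meta=meta, preamble=b"\0" * 128)
        ds.SOPClassUID = meta.MediaStorageSOPClassUID
        ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
        ds.SeriesInstanceUID = series_uid
        ds.Modality = "CT"
        ds.InstanceNumber = n_slices - k  # deliberately reversed
        ds.Rows, ds.Columns = rows, cols
        ds.PixelSpacing = [spacing[0], spacing[1]]
        ds.ImagePositionPatient = [float(x) for x in positions[k]]
        ds.ImageOrientationPatient = [float(x) for x in orientations[k]]
        ds.SliceThickness = 3.0
        ds.RescaleSlope = slope
        ds.RescaleIntercept = intercept
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 0
        ds.PixelData = np.ascontiguousarray(stored[:, :, k]).tobytes()
        ds.save_as(str(dirpath / f"slice_{k:03d}.dcm"), enforce_file_format=True)


class TestVolumeRoundTrip:
    @pytest.mark.parametrize("ext", ["nii", "nii.gz", "nrrd"])
    def test_write_read_identity(self, tmp_path, rng, ext):
        vol = make_volume(rng.uniform(-1000, 2000, size=(10, 10, 10)),
                          spacing=(0.5, 0.7, 3.0), origin=(-12.5, 4.0, 88.0))
        path = tmp_path / f"vol.{ext}"
        write_volume(vol, path)
        back = read_volume(path)
        assert np.allclose(back.voxels, vol.voxels, atol=1e-6)
        assert np.allclose(back.spacing, vol.spacing, atol=1e-6)
        assert np.allclose(back.origin, vol.origin, atol=1e-6)
        assert np.allclose(back.orientation, vol.orientation, atol=1e-6)

    def test_oblique_orientation_round_trip(self, tmp_path, rng):
        theta = 0.3
        rot = np.array([
            [np.cos(theta), -np.sin(theta), 0.0],
            [np.sin(theta), np.cos(theta), 0.0],
            [0.0, 0.0, 1.0],
        ])
        vol = make_volume(rng.uniform(-100, 500, size=(6, 7, 8)),
                          spacing=(0.6, 0.6, 2.5), orientation=rot)
        path = tmp_path / "vol.nrrd"
        write_volume(vol, path)
        back = read_volume(path)
        assert np.allclose(back.orientation, rot, atol=1e-6)
        # voxel centers map to the same patient coordinates
        idx = np.array([3, 4, 5])
        assert np.allclose(back.index_to_world(idx), vol.index_to_world(idx), atol=1e-6)

    def test_missing_file_raises_io_error(self, tmp_path):
        with pytest.raises(IOError):
            read_volume(tmp_path / "nope.nii")


class TestDicomSeries:
    def test_rescale_to_hu(self, tmp_path):
        # stored 1154 with slope 1, intercept -1024 -> exactly 130 HU
        stored = np.full((4, 4, 3), 100, dtype=np.uint16)
        stored[1, 2, 1] = 1154
        write_dicom_series(tmp_path, stored)
        vol = read_volume(tmp_path, format="dicom-series")
        assert vol.voxels[1, 2, 1] == pytest.approx(130.0)
        assert vol.voxels[0, 0, 0] == pytest.approx(100.0 - 1024.0)

    def test_nontrivial_slope(self, tmp_path):
        stored = np.full((4, 4, 2), 500, dtype=np.uint16)
        write_dicom_series(tmp_path, stored, slope=2.0, intercept=-1000.0)
        vol = read_volume(tmp_path)
        assert np.all(vol.voxels == 500 * 2.0 - 1000.0)

    def test_slices_sorted_by_position_not_instance_number(self, tmp_path):
        stored = np.zeros((4, 4, 3), dtype=np.uint16)
        for k in range(3):
            stored[:, :, k] = 1000 + k
        write_dicom_series(tmp_path, stored)  # InstanceNumber runs backwards
        vol = read_volume(tmp_path)
        assert vol.voxels[0, 0, 0] < vol.voxels[0, 0, 1] < vol.voxels[0, 0, 2]
        assert vol.spacing[2] == pytest.approx(3.0)

    def test_geometry_metadata(self, tmp_path):
        stored = np.zeros((6, 5, 3), dtype=np.uint16)
        write_dicom_series(tmp_path, stored, spacing=(0.5, 0.6))
        vol = read_volume(tmp_path)
        assert vol.shape == (6, 5, 3)
        assert np.allclose(vol.spacing, [0.5, 0.6, 3.0])

    def test_rotated_slice_rejected(self, tmp_path):
        stored = np.zeros((4, 4, 3), dtype=np.uint16)
        orientations = [[1, 0, 0, 0, 1, 0]] * 2 + [[0, 1, 0, 1, 0, 0]]
        write_dicom_series(tmp_path, stored, orientations=orientations)
        with pytest.raises(GeometryError, match="orientation"):
            read_volume(tmp_path)

    def test_duplicate_slice_position_rejected(self, tmp_path):
        stored = np.zeros((4, 4, 3), dtype=np.uint16)
        positions = [[0, 0, 0], [0, 0, 3.0], [0, 0, 3.0]]
        write_dicom_series(tmp_path, stored, positions=positions)
        with pytest.raises(GeometryError, match="monotone"):
            read_volume(tmp_path)


class TestLandmarks:
    def test_valid_file_round_trip(self, tmp_path):
        path = tmp_path / "lm.json"
        path.write_text(json.dumps({
            "nadir_points": [[0, 0, 0], [10, 0, 0], [0, 10, 0]],
            "aortic_reference": [0, 0, 20],
        }))
        lm = read_landmarks(path)
        assert lm.nadir_points.shape == (3, 3)
        out = tmp_path / "lm2.json"
        write_landmarks(lm, out)
        lm2 = read_landmarks(out)
        assert np.array_equal(lm2.nadir_points, lm.nadir_points)

    def test_collinear_nadirs_rejected(self, tmp_path):
        path = tmp_path / "lm.json"
        path.write_text(json.dumps({
            "nadir_points": [[0, 0, 0], [1, 1, 1], [2, 2, 2]],
            "aortic_reference": [0, 0, 20],
        }))
        with pytest.raises(LandmarkValidationError, match="collinear"):
            read_landmarks(path)

    def test_reference_on_plane_rejected(self, tmp_path):
        path = tmp_path / "lm.json"
        path.write_text(json.dumps({
            "nadir_points": [[0, 0, 0], [10, 0, 0], [0, 10, 0]],
            "aortic_reference": [3, 3, 0],
        }))
        with pytest.raises(LandmarkValidationError, match="plane"):
            read_landmarks(path)

    def test_missing_reference_rejected(self, tmp_path):
        path = tmp_path / "lm.json"
        path.write_text(json.dumps({"nadir_points": [[0, 0, 0], [10, 0, 0], [0, 10, 0]]}))
        with pytest.raises(LandmarkValidationError, match="aortic_reference"):
            read_landmarks(path)


class TestEditMaskIO:
    def test_label_volume_round_trip(self, tmp_path, rng):
        vol = make_volume(rng.uniform(-100, 500, size=(8, 8, 4)))
        labels = np.zeros(vol.shape)
        labels[1, 1, 1] = 1  # include
        labels[2, 2, 2] = 2  # exclude
        write_volume(make_volume(labels), tmp_path / "edits.nii.gz")
        edits = read_edit_mask(tmp_path / "edits.nii.gz", vol)
        assert edits.include.sum() == 1 and edits.include[1, 1, 1]
        assert edits.exclude.sum() == 1 and edits.exclude[2, 2, 2]

    def test_shape_mismatch_rejected(self, tmp_path, rng):
        vol = make_volume(rng.uniform(-100, 500, size=(8, 8, 4)))
        write_volume(make_volume(np.zeros((4, 4, 2))), tmp_path / "edits.nii.gz")
        with pytest.raises(GeometryError, match="shape"):
            read_edit_mask(tmp_path / "edits.nii.gz", vol)


def _agatston_result(total, lesions=()):
    return AgatstonResult(total_score=total, lesions=list(lesions),
                          volume_mm3=total, thickness_factor=1.0)


class TestReports:
    def test_zero_report_round_trip(self, tmp_path):
        path = tmp_path / "report.json"
        write_report(_agatston_result(0.0), path)
        assert read_report(path)["total_score"] == 0.0

    def test_numeric_fields_preserved(self, tmp_path):
        les = LesionScore(slice_index=3, area_mm2=4.5, peak_hu=512.0, weight=4,
                          lesion_score=18.0, centroid_mm=(1.0, 2.0, 3.0))
        path = tmp_path / "report.json"
        write_report(_agatston_result(3390.25, [les]), path)
        back = read_report(path)
        assert back["total_score"] == 3390.25
        assert back["lesions"][0]["lesion_score"] == 18.0

    def test_csv_round_trips_lesion_values(self, tmp_path):
        import csv as csvmod

        les = LesionScore(slice_index=3, area_mm2=4.5, peak_hu=512.0, weight=4,
                          lesion_score=18.0, centroid_mm=(1.0, 2.0, 3.0))
        path = tmp_path / "report.csv"
        write_report(_agatston_result(18.0, [les]), path, format="csv")
        with open(path) as fh:
            rows = list(csvmod.DictReader(fh))
        lesion_rows = [r for r in rows if r["row_type"] == "lesion"]
        assert float(lesion_rows[0]["lesion_score"]) == 18.0
        total_row = [r for r in rows if r["row_type"] == "total"][0]
        assert float(total_row["lesion_score"]) == 18.0

    def test_missing_directory_raises_io_error(self, tmp_path):
        with pytest.raises(IOError):
            write_report(_agatston_result(1.0), tmp_path / "absent" / "r.json")
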