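"""Volume I/O, resampling geometry, and SUV conversion contracts."""

import numpy as np
import pytest

from marrowmap import (
    SuvCalibration,
    VoxelGrid,
    compute_suv,
    read_volume,
    resample_to_grid,
    write_volume,
)
from marrowmap.grids import F18_HALF_LIFE_MIN


@pytest.fixture
def rng():
    return np.random.default_rng(42)


class TestVoxelGrid:
    def test_rejects_bad_geometry(self):
        with pytest.raises(ValueError, match="3-dimensional"):
            VoxelGrid(np.zeros((4, 4)), spacing=(1, 1, 1))
        with pytest.raises(ValueError, match="positive"):
            VoxelGrid(np.zeros((4, 4, 4)), spacing=(1, -1, 1))

    def test_voxel_volume(self):
        g = VoxelGrid(np.zeros((2, 2, 2)), spacing=(2.0, 2.0, 2.0))
        assert g.voxel_volume_ml == pytest.approx(8.0 / 1000.0)


class TestNiftiRoundTrip:
    @pytest.mark.parametrize("spacing", [(1.0, 1.0, 1.0), (1.0, 1.0, 3.0)])
    def test_data_spacing_origin_roundtrip(self, tmp_path, rng, spacing):
        grid = VoxelGrid(
            rng.normal(size=(7, 6, 5)),
            spacing=spacing,
            origin=(-12.5, 3.25, 40.0),
            role="CT",
        )
        path = tmp_path / "v.nii.gz"
        write_volume(grid, path)
        back = read_volume(path, role="CT")
        np.testing.assert_array_equal(back.data, grid.data)
        assert back.spacing == grid.spacing
        assert back.origin == pytest.approx(grid.origin)

    def test_bool_mask_stored_as_01_integers(self, tmp_path, rng):
        mask = rng.random((5, 5, 5)) > 0.5
        grid = VoxelGrid(mask, spacing=(1, 1, 1), role="mask")
        path = tmp_path / "m.nii.gz"
        write_volume(grid, path)
        back = read_volume(path, role="mask")
        assert back.data.dtype.kind in "ui"
        assert set(np.unique(back.data)) <= {0, 1}
        np.testing.assert_array_equal(back.data.astype(bool), mask)

    def test_missing_parent_directory_rejected(self, tmp_path, rng):
        grid = VoxelGrid(rng.normal(size=(3, 3, 3)), spacing=(1, 1, 1))
        with pytest.raises(ValueError, match="parent directory"):
            write_volume(grid, tmp_path / "nope" / "v.nii.gz")

    def test_non_3d_volume_rejected(self, tmp_path):
        import nibabel as nib

        img = nib.Nifti1Image(np.zeros((4, 4, 3, 2)), np.eye(4))
        nib.save(img, str(tmp_path / "4d.nii.gz"))
        with pytest.raises(ValueError, match="3-D"):
            read_volume(tmp_path / "4d.nii.gz")


def _write_dicom_slice(path, z, pixels, spacing=(1.5, 1.5)):
    import pydicom
    from pydicom.dataset import FileDataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, generate_uid

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = pydicom.uid.CTImageStorage
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = FileDataset(str(path), {}, file_meta=meta, preamble=b"\0" * 128)
    ds.SOPClassUID = meta.MediaStorageSOPClassUID
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "CT"
    ds.Rows, ds.Columns = pixels.shape
    ds.PixelSpacing = [spacing[0], spacing[1]]
    ds.ImagePositionPatient = [0.0, 0.0, float(z)]
    ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
    ds.SliceThickness = 2.0
    ds.RescaleSlope = 1.0
    ds.RescaleIntercept = -1024.0
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 0
    ds.PixelData = pixels.astype(np.uint16).tobytes()
    ds.save_as(str(path), enforce_file_format=True)


class TestDicomSeries:
    def test_series_assembles_sorted_with_rescale(self, tmp_path):
        for i, z in enumerate([4.0, 0.0, 2.0]):  # deliberately unsorted on disk
            pixels = np.full((4, 6), 1024 + 100 * z, dtype=np.uint16)
            _write_dicom_slice(tmp_path / f"s{i}.dcm", z, pixels)
        grid = read_volume(tmp_path, role="CT")
        assert grid.shape == (4, 6, 3)
        assert grid.spacing == pytest.approx((1.5, 1.5, 2.0))
        # rescale applied (HU = stored - 1024) and slices in spatial order
        np.testing.assert_allclose(grid.data[0, 0, :], [0.0, 200.0, 400.0])

    def test_missing_slice_rejected(self, tmp_path):
        for i, z in enumerate([0.0, 2.0, 6.0]):  # slice at z=4 missing
            pixels = np.zeros((4, 4), dtype=np.uint16)
            _write_dicom_slice(tmp_path / f"s{i}.dcm", z, pixels)
        with pytest.raises(ValueError, match="inconsistent slice spacing"):
            read_volume(tmp_path)


class TestResample:
    def test_identity_geometry_is_identity(self, rng):
        g = VoxelGrid(rng.normal(size=(6, 6, 6)), spacing=(2, 2, 2), origin=(1, 2, 3))
        for interp in ("nearest", "trilinear"):
            out = resample_to_grid(g, g, interp)
            np.testing.assert_array_equal(out.data, g.data)

    @pytest.mark.parametrize("interp", ["nearest", "trilinear"])
    def test_constant_volume_stays_constant(self, interp):
        moving = VoxelGrid(np.full((8, 8, 8), 7.0), spacing=(1, 1, 1))
        reference = VoxelGrid(np.zeros((4, 4, 4)), spacing=(1.5, 1.5, 1.5), origin=(1, 1, 1))
        out = resample_to_grid(moving, reference, interp)
        np.testing.assert_allclose(out.data, 7.0)

    def test_trilinear_matches_analytic_ramp(self):
        # f(x,y,z) = 2x + 3y - z in mm; trilinear interpolation is exact on it
        nx, ny, nz = 16, 16, 16
        idx = np.indices((nx, ny, nz), dtype=float)
        ramp = 2.0 * idx[0] + 3.0 * idx[1] - 1.0 * idx[2]  # spacing 1 mm
        moving = VoxelGrid(ramp, spacing=(1, 1, 1))
        reference = VoxelGrid(np.zeros((7, 7, 7)), spacing=(2, 2, 2), origin=(0.5, 0.5, 0.5))
        out = resample_to_grid(moving, reference, "trilinear")
        ridx = np.indices((7, 7, 7), dtype=float)
        expected = 2.0 * (0.5 + 2 * ridx[0]) + 3.0 * (0.5 + 2 * ridx[1]) - (0.5 + 2 * ridx[2])
        np.testing.assert_allclose(out.data, expected, atol=1e-6)

    def test_no_overlap_rejected(self):
        a = VoxelGrid(np.zeros((4, 4, 4)), spacing=(1, 1, 1), origin=(0, 0, 0))
        b = VoxelGrid(np.zeros((4, 4, 4)), spacing=(1, 1, 1), origin=(100, 100, 100))
        with pytest.raises(ValueError, match="overlap"):
            resample_to_grid(a, b)

    def test_nearest_preserves_label_values(self, rng):
        labels = rng.integers(0, 4, size=(8, 8, 8)).astype(float)
        moving = VoxelGrid(labels, spacing=(1, 1, 1), role="mask")
        reference = VoxelGrid(np.zeros((5, 5, 5)), spacing=(1.3, 1.3, 1.3), origin=(0.2, 0.2, 0.2))
        out = resample_to_grid(moving, reference, "nearest")
        assert set(np.unique(out.data)) <= set(np.unique(labels)) | {0.0}


class TestComputeSuv:
    def setup_method(self):
        self.cal = SuvCalibration(
            injected_activity_mbq=370.0,
            injection_to_scan_min=60.0,
            patient_weight_kg=74.0,
        )

    def test_unit_suv_case(self):
        # 370 MBq / 74 kg = 5000 Bq/g, so 5000 Bq/ml maps to SUV 1.0
        pet = VoxelGrid(np.full((4, 4, 4), 5000.0), spacing=(1, 1, 1), role="PET")
        out = compute_suv(pet, self.cal, decay_correct=False)
        np.testing.assert_allclose(out.data, 1.0)

    def test_doubling_dose_halves_suv(self, rng):
        pet = VoxelGrid(rng.uniform(0, 1e4, (4, 4, 4)), spacing=(1, 1, 1), role="PET")
        double = SuvCalibration(740.0, 60.0, 74.0)
        a = compute_suv(pet, self.cal, decay_correct=False)
        b = compute_suv(pet, double, decay_correct=False)
        np.testing.assert_allclose(b.data, a.data / 2.0)

    def test_decay_correction_one_half_life(self, rng):
        cal = SuvCalibration(370.0, F18_HALF_LIFE_MIN, 74.0)
        pet = VoxelGrid(rng.uniform(0, 1e4, (3, 3, 3)), spacing=(1, 1, 1), role="PET")
        corrected = compute_suv(pet, cal, decay_correct=True)
        uncorrected = compute_suv(pet, cal, decay_correct=False)
        np.testing.assert_allclose(corrected.data, 2.0 * uncorrected.data, rtol=1e-12)

    def test_homogeneous_degree_one_in_activity(self, rng):
        data = rng.uniform(0, 1e4, (3, 3, 3))
        pet = VoxelGrid(data, spacing=(1, 1, 1), role="PET")
        scaled = VoxelGrid(3.0 * data, spacing=(1, 1, 1), role="PET")
        np.testing.assert_allclose(
            compute_suv(scaled, self.cal).data, 3.0 * compute_suv(pet, self.cal).data
        )

    def test_invalid_calibration_rejected(self):
        with pytest.raises(ValueError, match="patient_weight_kg"):
            SuvCalibration(370.0, 60.0, 0.0)
        with pytest.raises(ValueError, match="injected_activity_mbq"):
            SuvCalibration(-1.0, 60.0, 74.0)

    def test_requires_pet_role(self):
        ct = VoxelGrid(np.zeros((3, 3, 3)), spacing=(1, 1, 1), role="CT")
        with pytest.raises(ValueError, match="PET"):
            compute_suv(ct, self.cal)
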