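import numpy as np
import pytest

import cinecompare as cc
from cinecompare.errors import (
    CorruptInputError,
    DuplicatePositionError,
    InconsistentSliceDimensionsError,
    LayoutError,
    SliceCountError,
)

from conftest import random_imageset


def test_axial_slice_validation():
    with pytest.raises(InconsistentSliceDimensionsError):
        cc.AxialSlice(np.ones((1, 5)))
    with pytest.raises(CorruptInputError):
        cc.AxialSlice(np.array([[1.0, np.nan], [0.0, 1.0]]))
    sl = cc.AxialSlice(np.ones((3, 4)), couch_index=2, slice_index=1)
    assert (sl.n_rows, sl.n_cols) == (3, 4)


def test_structural_counts():
    image_set = random_imageset(n_phases=10, n_couch=16, slices_per_couch=8, shape=(8, 8))
    assert image_set.n_slices == 1280
    assert all(v.n_transitions == 15 for v in image_set.volumes)


def test_non_uniform_slices_per_couch_rejected():
    blocks = [
        [cc.AxialSlice(np.ones((3, 3))) for _ in range(2)],
        [cc.AxialSlice(np.ones((3, 3)))],
    ]
    with pytest.raises(SliceCountError):
        cc.SortedPhaseVolume(0, blocks)


def test_phase_labels_must_increase():
    pixels = np.ones((2, 2, 2, 3, 3))
    with pytest.raises(ValueError):
        cc.imageset_from_array(pixels, [50, 50])


def test_unknown_layout(tmp_path):
    (tmp_path / "x").touch()
    with pytest.raises(LayoutError):
        cc.read_imageset(tmp_path / "x", layout="tarball")
    with pytest.raises(CorruptInputError):
        cc.read_imageset(tmp_path / "missing", layout="array-stack")


def test_array_stack_round_trip(tmp_path):
    image_set = random_imageset(times=True, seed=9)
    path = tmp_path / "set.npz"
    cc.write_imageset(image_set, path, "array-stack")
    back = cc.read_imageset(path, "array-stack")
    again = cc.read_imageset(path, "array-stack")
    px0, lab0, t0 = cc.imageset_to_array(image_set)
    px1, lab1, t1 = cc.imageset_to_array(back)
    px2, _, _ = cc.imageset_to_array(again)
    np.testing.assert_array_equal(px0, px1)
    np.testing.assert_array_equal(px1, px2)  # re-reading is deterministic
    np.testing.assert_array_equal(lab0, lab1)
    np.testing.assert_array_equal(t0, t1)


def test_nifti_round_trip(tmp_path, small_config):
    cine, _, peaks = cc.simulate_cine(small_config, seed=0)
    image_set = cc.phase_sort(cine, cc.PhaseAssignment(peaks), bin_labels=(0, 50))
    outdir = tmp_path / "nifti"
    cc.write_imageset(image_set, outdir, "nifti-per-phase")
    back = cc.read_imageset(outdir, "nifti-per-phase")
    np.testing.assert_array_equal(
        cc.imageset_to_array(image_set)[0], cc.imageset_to_array(back)[0]
    )
    assert back.phase_labels == [0, 50]


def test_nifti_slice_count_not_divisible(tmp_path):
    import nibabel as nib

    outdir = tmp_path / "bad"
    outdir.mkdir()
    data = np.zeros((4, 4, 129))
    nib.save(nib.Nifti1Image(data, np.eye(4)), str(outdir / "phase_00.nii"))
    with pytest.raises(SliceCountError, match="not divisible"):
        cc.read_imageset(outdir, "nifti-per-phase", slices_per_couch=8)


# --- DICOM fixtures -------------------------------------------------------

def _write_ct(path, pixels, z, t_seconds, slope=1.0, intercept=-1024.0):
    import pydicom
    from pydicom.dataset import Dataset, FileMetaDataset
    from pydicom.uid import CTImageStorage, ExplicitVRLittleEndian, generate_uid

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = CTImageStorage
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = Dataset()
    ds.file_meta = meta
    ds.SOPClassUID = meta.MediaStorageSOPClassUID
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "CT"
    ds.Rows, ds.Columns = pixels.shape
    ds.BitsAllocated = ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 1
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.RescaleSlope = slope
    ds.RescaleIntercept = intercept
    ds.ImagePositionPatient = [0.0, 0.0, float(z)]
    ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
    ds.AcquisitionTime = f"{t_seconds:010.3f}"
    ds.PixelData = pixels.astype(np.int16).tobytes()
    ds.save_as(path, enforce_file_format=True)


@pytest.fixture
def dicom_dir(tmp_path):
    rng = np.random.default_rng(4)
    root = tmp_path / "dicom"
    for b, label in enumerate((0, 50)):
        pdir = root / f"phase_{label:02d}"
        pdir.mkdir(parents=True)
        k = 0
        for n in range(2):  # couch blocks
            for s in range(2):  # slices per block, same acquisition time per block
                pixels = rng.integers(0, 3000, (8, 8))
                _write_ct(pdir / f"ct_{k:03d}.dcm", pixels, z=2.5 * k,
                          t_seconds=10.0 * b + 5.0 * n)
                k += 1
    return root


def test_dicom_read_by_position_and_time(dicom_dir):
    by_pos = cc.read_imageset(dicom_dir, "dicom-series", slices_per_couch=2)
    assert (by_pos.n_phases, by_pos.n_couch, by_pos.slices_per_couch) == (2, 2, 2)
    by_time = cc.read_imageset(dicom_dir, "dicom-series", slices_per_couch=2,
                               group_by="time")
    np.testing.assert_array_equal(
        cc.imageset_to_array(by_pos)[0], cc.imageset_to_array(by_time)[0]
    )
    # S derivable from equal-sized acquisition-time groups
    derived = cc.read_imageset(dicom_dir, "dicom-series")
    assert derived.slices_per_couch == 2


def test_dicom_hu_rescale(dicom_dir):
    import pydicom

    image_set = cc.read_imageset(dicom_dir, "dicom-series", slices_per_couch=2)
    f = sorted((dicom_dir / "phase_00").iterdir())[0]
    ds = pydicom.dcmread(str(f))
    expected = ds.pixel_array.astype(float) * 1.0 - 1024.0
    np.testing.assert_array_equal(image_set.volumes[0].slice_at(1, 1).pixels, expected)


def test_dicom_duplicate_positions(dicom_dir):
    rng = np.random.default_rng(1)
    _write_ct(dicom_dir / "phase_00" / "dup.dcm", rng.integers(0, 10, (8, 8)),
              z=0.0, t_seconds=0.0)
    with pytest.raises(DuplicatePositionError):
        cc.read_imageset(dicom_dir, "dicom-series", slices_per_couch=2)


def test_dicom_inconsistent_dimensions(dicom_dir):
    _write_ct(dicom_dir / "phase_00" / "odd.dcm", np.zeros((4, 4), dtype=np.int16),
              z=100.0, t_seconds=58.0)
    with pytest.raises((InconsistentSliceDimensionsError, SliceCountError)):
        cc.read_imageset(dicom_dir, "dicom-series", slices_per_couch=2)


def test_dicom_slice_count_error(dicom_dir):
    _write_ct(dicom_dir / "phase_00" / "extra.dcm",
              np.zeros((8, 8), dtype=np.int16), z=100.0, t_seconds=58.0)
    with pytest.raises(SliceCountError, match="not divisible"):
        cc.read_imageset(dicom_dir, "dicom-series", slices_per_couch=2)


# --- report output --------------------------------------------------------

def test_write_report_round_trip(tmp_path):
    rng = np.random.default_rng(8)
    delta = rng.normal(0, 0.01, (10, 15))
    report = cc.score(cc.ResidualMatrix(delta, list(range(0, 100, 10))))
    outdir = tmp_path / "report"
    cc.write_report(report, outdir)
    summary, delta_back = cc.read_report(outdir)
    assert summary["overall_score"] == report.overall_score
    assert delta_back.shape == (10, 15)
    np.testing.assert_array_equal(delta_back, delta)  # full-precision CSV
    assert summary["phase_signs"] == list(report.phase_signs)


def test_write_report_zero_score(tmp_path):
    report = cc.score(cc.ResidualMatrix(np.zeros((2, 3)), [0, 50]))
    cc.write_report(report, tmp_path / "r")
    summary, _ = cc.read_report(tmp_path / "r")
    assert summary["overall_score"] == 0
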