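"""Volume I/O, skull-strip fallback, ROI detection and MROI cropping."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from flairvol.preprocessing import (
    RoiBox,
    VolumeImage,
    crop,
    dataset_max_roi,
    load_volume,
    max_roi,
    normalize_volume,
    save_volume,
    slice_roi,
    strip_nonbrain,
    union_rois,
)


def brute_force_bbox(data):
    """Independent oracle: scan every non-zero coordinate for min/max."""
    coords = np.argwhere(data != 0)
    return (
        (coords[:, 0].min(), coords[:, 0].max()),
        (coords[:, 1].min(), coords[:, 1].max()),
    )


class TestRoiBox:
    def test_inclusive_extents(self):
        box = RoiBox((49, 207), (60, 200), (0, 65))
        assert box.extents == (159, 141, 66)

    def test_from_vertices_with_duplicates(self):
        """The clinical MROI vertices (one listed twice) give a 159x141 box."""
        box = RoiBox.from_vertices([(49, 60), (207, 200), (49, 200), (207, 200)], n_slices=66)
        assert box.row == (49, 207)
        assert box.col == (60, 200)
        assert box.extents == (159, 141, 66)

    def test_invalid_ranges_rejected(self):
        with pytest.raises(ValueError):
            RoiBox((5, 3), (0, 1), (0, 0))
        with pytest.raises(ValueError):
            RoiBox((-1, 3), (0, 1), (0, 0))


class TestSliceRoi:
    def test_single_voxel(self):
        sl = np.zeros((32, 32))
        sl[10, 20] = 1.0
        assert slice_roi(sl) == ((10, 10), (20, 20))

    def test_all_zero_is_empty(self):
        assert slice_roi(np.zeros((8, 8))) is None

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_matches_brute_force(self, seed):
        r = np.random.default_rng(seed)
        sl = (r.random((15, 17)) < 0.1).astype(float) * r.random((15, 17))
        res = slice_roi(sl)
        if not (sl != 0).any():
            assert res is None
        else:
            rows = np.argwhere((sl != 0).any(axis=1)).ravel()
            cols = np.argwhere((sl != 0).any(axis=0)).ravel()
            assert res == ((rows[0], rows[-1]), (cols[0], cols[-1]))


class TestMaxRoi:
    def test_single_voxel_degenerate_box(self):
        data = np.zeros((10, 10, 5))
        data[3, 7, 2] = 1.0
        box = max_roi(data)
        assert box.row == (3, 3) and box.col == (7, 7)
        assert box.slices == (0, 4)  # depth never cropped

    def test_all_zero_raises(self):
        with pytest.raises(ValueError):
            max_roi(np.zeros((5, 5, 5)))

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_oracle(self, seed):
        r = np.random.default_rng(seed)
        data = (r.random((12, 14, 6)) < 0.08).astype(float)
        if not data.any():
            data[0, 0, 0] = 1.0
        box = max_roi(data)
        row, col = brute_force_bbox(data)
        assert (box.row, box.col) == (tuple(row), tuple(col))

    def test_many_random_volumes_against_oracle(self):
        """Oracle equivalence on >= 100 random small volumes."""
        r = np.random.default_rng(123)
        for _ in range(100):
            data = (r.random((9, 11, 4)) < 0.1).astype(float)
            if not data.any():
                continue
            box = max_roi(data)
            row, col = brute_force_bbox(data)
            assert (box.row, box.col) == (tuple(row), tuple(col))

    def test_union_rois(self):
        a = RoiBox((2, 5), (3, 6), (0, 4))
        b = RoiBox((1, 4), (4, 9), (0, 4))
        u = union_rois([a, b])
        assert u == RoiBox((1, 5), (3, 9), (0, 4))


class TestCrop:
    def test_paper_geometry(self):
        """A 256x256x66 volume cropped to the clinical MROI is 159x141x66."""
        vol = VolumeImage(np.ones((256, 256, 66), dtype=np.float32))
        box = RoiBox.from_vertices([(49, 60), (207, 200), (49, 200), (207, 200)], 66)
        out = crop(vol, box)
        assert out.data.shape == (159, 141, 66)

    def test_full_box_is_identity(self, random_volume):
        m, n, l = random_volume.data.shape
        out = crop(random_volume, RoiBox((0, m - 1), (0, n - 1), (0, l - 1)))
        np.testing.assert_array_equal(out.data, random_volume.data)

    def test_crop_idempotent(self, random_volume):
        box = max_roi(random_volume)
        once = crop(random_volume, box)
        m, n, l = once.data.shape
        again = crop(once, RoiBox((0, m - 1), (0, n - 1), (0, l - 1)))
        np.testing.assert_array_equal(once.data, again.data)

    def test_out_of_bounds_box_rejected(self, random_volume):
        m, n, l = random_volume.data.shape
        with pytest.raises(ValueError):
            crop(random_volume, RoiBox((0, m), (0, n - 1), (0, l - 1)))

    def test_conservation_of_nonzero_values(self, random_volume):
        """crop(v, max_roi(v)) keeps exactly the multiset of non-zero values."""
        out = crop(random_volume, max_roi(random_volume))
        a = np.sort(random_volume.data[random_volume.data != 0])
        b = np.sort(out.data[out.data != 0])
        np.testing.assert_array_equal(a, b)

    def test_tightness(self, random_volume):
        """Shrinking the MROI by one index on any side drops a non-zero voxel."""
        box = max_roi(random_volume)
        n_nonzero = np.count_nonzero(random_volume.data)
        shrunk = []
        if box.row[0] < box.row[1]:
            shrunk.append(RoiBox((box.row[0] + 1, box.row[1]), box.col, box.slices))
            shrunk.append(RoiBox((box.row[0], box.row[1] - 1), box.col, box.slices))
        if box.col[0] < box.col[1]:
            shrunk.append(RoiBox(box.row, (box.col[0] + 1, box.col[1]), box.slices))
            shrunk.append(RoiBox(box.row, (box.col[0], box.col[1] - 1), box.slices))
        for sbox in shrunk:
            out = crop(random_volume, sbox)
            assert np.count_nonzero(out.data) < n_nonzero


class TestStripNonbrain:
    def test_phantom_interior_untouched(self, small_phantoms):
        """Already-stripped phantoms keep interior voxels exactly."""
        from flairvol.phantom import phantom_fields
        from scipy import ndimage

        lv = small_phantoms["VaMCI"]
        out = strip_nonbrain(VolumeImage(lv.data))
        fields = phantom_fields(lv.provenance)
        interior = ndimage.binary_erosion(fields["brain"], iterations=2)
        np.testing.assert_array_equal(out.data[interior], lv.data[interior])
        assert (out.data[~fields["brain"]] == 0).all()

    def test_constant_volume_single_component(self):
        vol = VolumeImage(np.full((10, 10, 10), 2.0, dtype=np.float32))
        out = strip_nonbrain(vol)
        # a constant positive volume is one component: everything retained
        assert (out.data > 0).all()

    def test_largest_component_oracle(self):
        """Retained mask equals the independent largest-component result."""
        from scipy import ndimage

        data = np.zeros((20, 20, 10), dtype=np.float32)
        data[2:12, 2:12, 2:8] = 1.0  # large blob
        data[16:19, 16:19, 1:3] = 1.0  # small distractor blob
        out = strip_nonbrain(VolumeImage(data))
        labels, _ = ndimage.label(data > 0)
        sizes = np.bincount(labels.ravel())[1:]
        keep = labels == (np.argmax(sizes) + 1)
        assert (out.data[~keep] == 0).all()
        assert (out.data[keep] > 0).any()

    def test_all_zero_raises(self):
        with pytest.raises(ValueError, match="no brain tissue"):
            strip_nonbrain(VolumeImage(np.zeros((8, 8, 8))))

    def test_negative_intensities_rejected(self):
        with pytest.raises(ValueError):
            strip_nonbrain(VolumeImage(np.full((5, 5, 5), -1.0)))


class TestLoadVolume:
    def test_nifti_round_trip(self, tmp_path, small_phantoms):
        lv = small_phantoms["HC"]
        p = tmp_path / "hc.nii.gz"
        save_volume(VolumeImage(lv.data, spacing=(1.0, 1.0, 2.0)), p)
        loaded = load_volume(p)
        np.testing.assert_array_equal(loaded.data, lv.data)
        assert loaded.spacing == (1.0, 1.0, 2.0)

    def test_4d_nifti_rejected(self, tmp_path):
        import nibabel as nib

        p = tmp_path / "bad.nii.gz"
        nib.save(nib.Nifti1Image(np.zeros((4, 4, 4, 2), dtype=np.float32), np.eye(4)), p)
        with pytest.raises(ValueError, match="3D"):
            load_volume(p)

    def _write_dicom_series(self, directory, data, series_uid, shuffle_order=None):
        import pydicom
        from pydicom.dataset import FileDataset, FileMetaDataset
        from pydicom.uid import ExplicitVRLittleEndian, generate_uid

        directory.mkdir(parents=True, exist_ok=True)
        n_slices = data.shape[2]
        order = shuffle_order if shuffle_order is not None else range(n_slices)
        for file_idx, z in enumerate(order):
            meta = FileMetaDataset()
            meta.MediaStorageSOPClassUID = pydicom.uid.MRImageStorage
            meta.MediaStorageSOPInstanceUID = generate_uid(entropy_srcs=[f"{z}"])
            meta.TransferSyntaxUID = ExplicitVRLittleEndian
            ds = FileDataset(None, {}, file_meta=meta, preamble=b"\0" * 128)
            ds.SOPClassUID = meta.MediaStorageSOPClassUID
            ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
            ds.SeriesInstanceUID = series_uid
            ds.Modality = "MR"
            ds.InstanceNumber = z + 1
            ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
            ds.ImagePositionPatient = [0.0, 0.0, float(z) * 2.0]
            ds.PixelSpacing = [1.0, 1.0]
            ds.SliceThickness = 2.0
            ds.Rows, ds.Columns = data.shape[:2]
            ds.BitsAllocated = 16
            ds.BitsStored = 16
            ds.HighBit = 15
            ds.PixelRepresentation = 0
            ds.SamplesPerPixel = 1
            ds.PhotometricInterpretation = "MONOCHROME2"
            ds.PixelData = data[:, :, z].astype(np.uint16).tobytes()
            ds.save_as(directory / f"slice_{file_idx:03d}.dcm", enforce_file_format=True)

    def test_dicom_shuffled_order_matches_sorted(self, tmp_path, rng):
        from pydicom.uid import generate_uid

        data = (rng.random((16, 16, 6)) * 100).astype(np.uint16)
        uid = generate_uid(entropy_srcs=["series"])
        self._write_dicom_series(tmp_path / "sorted", data, uid)
        shuffled = list(rng.permutation(6))
        self._write_dicom_series(tmp_path / "shuffled", data, uid, shuffle_order=shuffled)
        a = load_volume(tmp_path / "sorted")
        b = load_volume(tmp_path / "shuffled")
        np.testing.assert_array_equal(a.data, b.data)
        np.testing.assert_array_equal(a.data, data.astype(np.float32))

    def test_mixed_series_rejected(self, tmp_path, rng):
        from pydicom.uid import generate_uid

        data = (rng.random((8, 8, 2)) * 10).astype(np.uint16)
        d = tmp_path / "mixed"
        self._write_dicom_series(d, data[:, :, :1], generate_uid(entropy_srcs=["a"]))
        # second file from a different series
        import shutil

        self._write_dicom_series(tmp_path / "other", data[:, :, 1:], generate_uid(entropy_srcs=["b"]))
        shutil.copy(tmp_path / "other" / "slice_000.dcm", d / "slice_xxx.dcm")
        with pytest.raises(ValueError, match="series"):
            load_volume(d)


class TestNormalize:
    def test_unit_range_and_zero_background(self, small_phantoms):
        lv = small_phantoms["VaD"]
        out = normalize_volume(VolumeImage(lv.data))
        brain = lv.data != 0
        assert out.data[brain].min() == 0.0
        assert out.data[brain].max() == 1.0
        assert (out.data[~brain] == 0).all()

    def test_dataset_max_roi_covers_each_volume(self, tiny_cohort_arrays):
        x, _ = tiny_cohort_arrays
        boxes = [max_roi(v) for v in x]
        union = dataset_max_roi(list(x))
        for b in boxes:
            assert union.row[0] <= b.row[0] and union.row[1] >= b.row[1]
            assert union.col[0] <= b.col[0] and union.col[1] >= b.col[1]
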