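"""Preparation pipeline: kidney extraction, reorientation, resizing,
normalization, channel concatenation and I/O round-trips."""

import numpy as np
import pytest

from renalprog import preprocess as pre


def _block_mask(shape, lo, size, label=1):
    m = np.zeros(shape, dtype=np.int16)
    sl = tuple(slice(a, a + s) for a, s in zip(lo, size))
    m[sl] = label
    return m


class TestExtractKidneyRegion:
    def test_single_block_bounding_box(self):
        vol = pre.Volume3D(np.arange(64 ** 3, dtype=float).reshape(64, 64, 64))
        mask = pre.SegMask(_block_mask((64, 64, 64), (20, 20, 20), (10, 10, 10)))
        crops = pre.extract_kidney_region(vol, mask, "both-separately", margin=0)
        assert len(crops) == 1
        v, m = crops[0]
        assert v.shape == (10, 10, 10)
        assert (m.voxels == pre.KIDNEY_LABEL).all()
        assert np.array_equal(v.voxels, vol.voxels[20:30, 20:30, 20:30])

    def test_two_blobs_match_component_oracle(self):
        shape = (40, 40, 40)
        mask_arr = (_block_mask(shape, (2, 2, 2), (8, 9, 10))
                    + _block_mask(shape, (25, 20, 15), (6, 7, 8)))
        vol = pre.Volume3D(np.zeros(shape))
        crops = pre.extract_kidney_region(vol, pre.SegMask(mask_arr),
                                          "both-separately")
        assert len(crops) == 2
        # brute-force flood fill oracle: two components of known voxel counts
        sizes = sorted(int((m.voxels > 0).sum()) for _, m in crops)
        assert sizes == sorted([8 * 9 * 10, 6 * 7 * 8])
        shapes = sorted(tuple(v.shape) for v, _ in crops)
        assert shapes == sorted([(8, 9, 10), (6, 7, 8)])

    def test_left_right_policies_pick_by_first_axis(self):
        shape = (40, 40, 40)
        mask_arr = (_block_mask(shape, (2, 10, 10), (5, 5, 5))
                    + _block_mask(shape, (30, 10, 10), (5, 5, 5)))
        vol = pre.Volume3D(np.zeros(shape))
        (v_left, _), = pre.extract_kidney_region(vol, pre.SegMask(mask_arr), "left")
        (v_right, _), = pre.extract_kidney_region(vol, pre.SegMask(mask_arr), "right")
        assert v_left.shape == v_right.shape == (5, 5, 5)

    def test_with_tumor_policy_prefers_tumorous_kidney(self):
        shape = (40, 40, 40)
        mask_arr = _block_mask(shape, (2, 10, 10), (5, 5, 5))
        mask_arr += _block_mask(shape, (30, 10, 10), (6, 6, 6))
        mask_arr[31:33, 11:13, 11:13] = pre.TUMOR_LABEL
        vol = pre.Volume3D(np.zeros(shape))
        crops = pre.extract_kidney_region(vol, pre.SegMask(mask_arr), "with-tumor")
        assert len(crops) == 1
        assert (crops[0][1].voxels == pre.TUMOR_LABEL).any()

    def test_margin_expands_and_clamps(self):
        vol = pre.Volume3D(np.zeros((20, 20, 20)))
        mask = pre.SegMask(_block_mask((20, 20, 20), (0, 8, 8), (4, 4, 4)))
        (v, _), = pre.extract_kidney_region(vol, mask, "both-separately", margin=2)
        assert v.shape == (6, 8, 8)  # clamped at the low edge of axis 0

    def test_empty_mask_raises(self):
        vol = pre.Volume3D(np.zeros((8, 8, 8)))
        with pytest.raises(ValueError, match="empty segmentation"):
            pre.extract_kidney_region(vol, pre.SegMask(np.zeros((8, 8, 8), int)),
                                      "both-separately")

    def test_shape_mismatch_raises(self):
        vol = pre.Volume3D(np.zeros((8, 8, 8)))
        mask = pre.SegMask(np.ones((8, 8, 9), int))
        with pytest.raises(ValueError, match="mismatch"):
            pre.extract_kidney_region(vol, mask)


class TestReorient:
    def test_ras_is_identity(self, rng):
        v = pre.Volume3D(rng.normal(size=(4, 5, 6)), orientation="RAS")
        out = pre.reorient_to_ras(v)
        assert np.array_equal(out.voxels, v.voxels)

    def test_lps_round_trip_tracks_corner_voxel(self, rng):
        vox = rng.normal(size=(4, 5, 6))
        vox[0, 0, 0] = 99.0
        v = pre.Volume3D(vox, orientation="LPS")
        out = pre.reorient_to_ras(v)
        # L and P axes flip; S stays: the labeled corner moves to (-1, -1, 0)
        assert out.voxels[-1, -1, 0] == 99.0
        back, _ = pre._reorient(out.voxels, out.spacing, "RAS", "LPS")
        assert np.array_equal(back, vox)

    def test_axis_permutation_bookkeeping(self, rng):
        v = pre.Volume3D(rng.normal(size=(3, 4, 5)), spacing=(1.0, 2.0, 3.0),
                         orientation="ARS")
        out = pre.reorient_to_ras(v)
        # A(y-first) R(x-second) S: RAS order swaps the first two axes
        assert out.voxels.shape == (4, 3, 5)
        assert out.spacing == (2.0, 1.0, 3.0)

    def test_idempotent(self, rng):
        v = pre.Volume3D(rng.normal(size=(3, 4, 5)), orientation="PIL")
        once = pre.reorient_to_ras(v)
        twice = pre.reorient_to_ras(once)
        assert np.array_equal(once.voxels, twice.voxels)

    def test_invalid_code_rejected(self):
        with pytest.raises(ValueError, match="orientation"):
            pre.Volume3D(np.zeros((2, 2, 2)), orientation="RAX")
        with pytest.raises(ValueError, match="orientation"):
            pre.Volume3D(np.zeros((2, 2, 2)), orientation="RLS")


class TestResize:
    def test_constant_volume_stays_constant(self):
        v = pre.Volume3D(np.full((13, 9, 21), 7.25))
        out = pre.resize_volume(v, (16, 16, 16))
        assert out.shape == (16, 16, 16)
        assert np.allclose(out.voxels, 7.25)

    def test_mask_label_set_preserved(self, rng):
        m = pre.SegMask((rng.random((20, 20, 20)) > 0.5).astype(np.int16) * 2)
        out = pre.resize_mask(m, (31, 17, 9))
        assert set(np.unique(out.voxels)) <= {0, 2}

    def test_interpolation_stays_within_input_range(self):
        ramp = np.linspace(0, 1, 64 ** 3).reshape(64, 64, 64)
        out = pre.resize_volume(pre.Volume3D(ramp), (128, 128, 128))
        assert out.voxels.min() >= 0.0 - 1e-12
        assert out.voxels.max() <= 1.0 + 1e-12

    def test_nonpositive_target_rejected(self):
        with pytest.raises(ValueError):
            pre.resize_volume(pre.Volume3D(np.zeros((4, 4, 4))), (0, 4, 4))


class TestNormalize:
    def test_zscore_moments(self, rng):
        v = pre.Volume3D(rng.normal(5.0, 3.0, (16, 16, 16)))
        out = pre.normalize_intensity(v)
        assert abs(out.voxels.mean()) < 1e-10
        assert abs(out.voxels.std() - 1.0) < 1e-10

    def test_idempotent_on_standardized_input(self, rng):
        v = pre.normalize_intensity(pre.Volume3D(rng.normal(size=(8, 8, 8))))
        again = pre.normalize_intensity(v)
        assert np.allclose(again.voxels, v.voxels, atol=1e-10)

    def test_two_voxel_population_sd_convention(self):
        v = pre.Volume3D(np.array([0.0, 10.0]).reshape(2, 1, 1))
        out = pre.normalize_intensity(v)
        assert np.allclose(np.sort(out.voxels.ravel()), [-1.0, 1.0])

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            pre.normalize_intensity(pre.Volume3D(np.full((4, 4, 4), 3.0)))


class TestConcatenate:
    def test_empty_tumor_mask_gives_zero_channel(self, rng):
        img = pre.Volume3D(rng.normal(size=(8, 8, 8)))
        mask = pre.SegMask(np.full((8, 8, 8), pre.KIDNEY_LABEL, dtype=np.int16))
        s = pre.concatenate_tumor_channel(img, mask, grade=2)
        assert s.channels.shape == (2, 8, 8, 8)
        assert not s.channels[1].any()

    def test_tumor_label_selected_by_voxel_count(self, rng):
        img = pre.Volume3D(rng.normal(size=(8, 8, 8)))
        labels = rng.integers(0, 3, (8, 8, 8)).astype(np.int16)
        s = pre.concatenate_tumor_channel(img, pre.SegMask(labels), grade=1)
        assert int(s.channels[1].sum()) == int((labels == pre.TUMOR_LABEL).sum())

    def test_invalid_grade_rejected(self, rng):
        img = pre.Volume3D(rng.normal(size=(4, 4, 4)))
        mask = pre.SegMask(np.zeros((4, 4, 4), int))
        with pytest.raises(ValueError, match="grade"):
            pre.concatenate_tumor_channel(img, mask, grade=5)

    def test_shape_mismatch_rejected(self, rng):
        img = pre.Volume3D(rng.normal(size=(4, 4, 4)))
        with pytest.raises(ValueError, match="mismatch"):
            pre.concatenate_tumor_channel(img, pre.SegMask(np.zeros((4, 4, 5), int)), 1)


class TestPipeline:
    def test_prepare_is_deterministic_and_normalized(self, rng):
        vox = rng.normal(30.0, 20.0, (48, 48, 48))
        labels = _block_mask((48, 48, 48), (10, 12, 14), (14, 12, 10))
        labels[14:20, 14:20, 15:20] = pre.TUMOR_LABEL
        vol = pre.Volume3D(vox, orientation="LPS")
        mask = pre.SegMask(labels, orientation="LPS")
        a = pre.prepare_sample(vol, mask, 2, "p1", target=(24, 24, 24))
        b = pre.prepare_sample(vol, mask, 2, "p1", target=(24, 24, 24))
        assert len(a) == 1
        assert np.array_equal(a[0].channels, b[0].channels)
        assert abs(a[0].channels[0].mean()) < 1e-5
        assert abs(a[0].channels[0].std() - 1.0) < 1e-5
        assert set(np.unique(a[0].channels[1])) <= {0.0, 1.0}


class TestIO:
    def test_nifti_round_trip(self, tmp_path, rng):
        v = pre.Volume3D(rng.normal(size=(6, 7, 8)), spacing=(1.0, 1.5, 2.0),
                         orientation="LPS")
        pre.save_nifti(v, tmp_path / "v.nii.gz")
        back = pre.load_nifti_volume(tmp_path / "v.nii.gz")
        assert np.allclose(back.voxels, v.voxels, atol=1e-6)
        assert back.orientation == "LPS"
        assert np.allclose(back.spacing, v.spacing)

    def test_clinical_json_round_trip(self, tmp_path):
        import pandas as pd
        df = pd.DataFrame({"patient_id": ["a", "b"], "grade": [1, 4],
                           "event": [0, 1], "duration_days": [100.0, 2044.0]})
        pre.write_clinical(df, tmp_path / "c.json")
        back = pre.read_clinical(tmp_path / "c.json")
        pd.testing.assert_frame_equal(back, df)
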