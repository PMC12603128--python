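"""Deterministic slice preprocessing: selection, rescaling, resizing,
one-hot encoding and the on-disk cache."""

import numpy as np
import pytest

from spineseg.preprocess import (IDENTITY_4CLASS, LabelMap, VolumeRecord,
                                 build_dataset, central_slice, encode_masks,
                                 load_cache, nearest_resize_labels,
                                 rescale_to_8bit, resize_pair, save_cache,
                                 select_t1)


def make_record(depth=5, size=40, tag="t1", seed=0):
    r = np.random.default_rng(seed)
    voxels = r.random((depth, size, size)) * 1000
    labels = (r.random((depth, size, size)) < 0.3).astype(np.int64) * \
        r.integers(1, 4, (depth, size, size))
    return VolumeRecord(voxels, labels, series_tag=tag, source_id=f"vol{seed}")


def nn_resize_oracle(labels, out_shape):
    """Brute-force per-cell pixel-center index mapping."""
    h, w = labels.shape
    oh, ow = out_shape
    out = np.empty(out_shape, dtype=labels.dtype)
    for i in range(oh):
        for j in range(ow):
            si = min(int((i + 0.5) * h / oh), h - 1)
            sj = min(int((j + 0.5) * w / ow), w - 1)
            out[i, j] = labels[si, sj]
    return out


class TestSelectT1:
    def test_default_substring_pattern(self):
        recs = [make_record(tag=t, seed=i)
                for i, t in enumerate(["t1", "t2", "t1_space"])]
        kept = select_t1(recs)
        assert [r.series_tag for r in kept] == ["t1", "t1_space"]

    def test_no_match_warns_not_raises(self):
        with pytest.warns(UserWarning, match="T1"):
            assert select_t1([make_record(tag="t2")]) == []

    def test_anchored_pattern_is_exact(self):
        recs = [make_record(tag=t, seed=i)
                for i, t in enumerate(["t1", "t1_space"])]
        kept = select_t1(recs, pattern="^t1$")
        assert [r.series_tag for r in kept] == ["t1"]


class TestCentralSlice:
    @pytest.mark.parametrize("depth,expected", [(9, 4), (8, 4), (1, 0)])
    def test_floor_convention(self, depth, expected):
        rec = make_record(depth=depth)
        img, lab = central_slice(rec)
        np.testing.assert_array_equal(img, rec.voxels[expected])
        np.testing.assert_array_equal(lab, rec.labels[expected])

    def test_empty_volume_rejected(self):
        rec = VolumeRecord(np.empty((0, 4, 4)), np.empty((0, 4, 4), dtype=int))
        with pytest.raises(ValueError, match="empty"):
            central_slice(rec)


class TestRescaleTo8Bit:
    def test_three_values_round_half_up(self):
        out = rescale_to_8bit(np.array([[0.0, 0.5, 1.0]]))
        np.testing.assert_array_equal(out, [[0, 128, 255]])

    def test_constant_image_maps_to_zero(self):
        out = rescale_to_8bit(np.full((4, 4), 7.3))
        assert out.dtype == np.uint8
        assert (out == 0).all()

    def test_full_range_is_hit(self, rng):
        out = rescale_to_8bit(rng.normal(size=(32, 32)))
        assert out.min() == 0 and out.max() == 255

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError, match="NaN"):
            rescale_to_8bit(np.array([[np.nan, 1.0]]))


class TestResizePair:
    def test_labels_closed_under_resize(self, rng):
        labels = rng.choice([0, 1, 3], size=(50, 50))
        _, out = resize_pair(rng.integers(0, 256, (50, 50)), labels, 32)
        assert set(np.unique(out)) <= {0, 1, 3}

    def test_uniform_image_stays_uniform(self):
        img, _ = resize_pair(np.full((40, 40), 100.0), np.zeros((40, 40), int), 16)
        np.testing.assert_allclose(img, 100.0 / 255.0, atol=1e-12)
        assert img.shape == (16, 16)

    def test_checkerboard_matches_index_oracle(self):
        labels = (np.add.outer(np.arange(256), np.arange(256)) % 2)
        _, out = resize_pair(np.zeros((256, 256)), labels, 128)
        np.testing.assert_array_equal(out, nn_resize_oracle(labels, (128, 128)))

    @pytest.mark.parametrize("shape,out", [((37, 53), (16, 16)), ((128, 128), (8, 8))])
    def test_nearest_resize_matches_oracle(self, shape, out, rng):
        labels = rng.integers(0, 4, shape)
        np.testing.assert_array_equal(nearest_resize_labels(labels, out),
                                      nn_resize_oracle(labels, out))

    def test_image_lands_in_unit_interval(self, rng):
        img, _ = resize_pair(rng.integers(0, 256, (64, 64)),
                             np.zeros((64, 64), int), 32)
        assert img.min() >= 0.0 and img.max() <= 1.0


class TestEncodeMasks:
    def test_all_background_bottleneck(self):
        mask, bott = encode_masks(np.zeros((128, 128), int), LabelMap(), 2)
        assert bott.shape == (8, 8, 2)
        np.testing.assert_array_equal(bott[..., 0], 1.0)

    def test_nonzero_code_becomes_foreground(self):
        labels = np.zeros((16, 16), int)
        labels[3, 4] = 7
        mask, _ = encode_masks(labels, LabelMap(), 2, bottleneck_size=1)
        np.testing.assert_array_equal(mask[3, 4], [0.0, 1.0])

    def test_half_foreground_bottleneck_oracle(self):
        labels = np.zeros((128, 128), int)
        labels[64:, :] = 1
        _, bott = encode_masks(labels, LabelMap(), 2)
        ref = nn_resize_oracle(labels, (8, 8))
        np.testing.assert_array_equal(bott.argmax(axis=-1), ref)

    def test_one_hot_sums_everywhere(self, rng):
        labels = rng.integers(0, 4, (32, 32))
        mask, bott = encode_masks(labels, IDENTITY_4CLASS, 4, bottleneck_size=2)
        np.testing.assert_array_equal(mask.sum(axis=-1), 1.0)
        np.testing.assert_array_equal(bott.sum(axis=-1), 1.0)

    def test_unmapped_code_listed_in_error(self):
        labels = np.array([[0, 9]])
        with pytest.raises(ValueError, match="9"):
            encode_masks(labels, LabelMap({0: 0, 1: 1}), 4, bottleneck_size=1)

    def test_background_must_map_to_zero(self):
        with pytest.raises(ValueError, match="background"):
            LabelMap({0: 1})


class TestBuildDataset:
    def test_count_conservation_and_t1_filtering(self, tmp_path):
        recs = [make_record(tag="t1", seed=0), make_record(tag="t2", seed=1),
                make_record(tag="T1_tse", seed=2), make_record(tag="t1", seed=3)]
        pairs = build_dataset(recs, LabelMap(), n_classes=2, size=32,
                              cache_dir=tmp_path / "cache")
        assert len(pairs) == 3
        assert all(p.image.shape == (32, 32) for p in pairs)
        assert all(p.bottleneck_onehot.shape == (2, 2, 2) for p in pairs)

    def test_pipeline_is_deterministic(self):
        recs = [make_record(seed=4)]
        a = build_dataset(recs, LabelMap(), size=32)
        b = build_dataset(recs, LabelMap(), size=32)
        np.testing.assert_array_equal(a[0].image, b[0].image)
        np.testing.assert_array_equal(a[0].mask_onehot, b[0].mask_onehot)

    def test_binary_foreground_equals_nonzero_after_resize(self):
        rec = make_record(seed=5)
        pairs = build_dataset([rec], LabelMap(), size=32)
        _, lab = central_slice(rec)
        resized = nn_resize_oracle(lab, (32, 32))
        np.testing.assert_array_equal(pairs[0].labels, (resized > 0))

    def test_cache_round_trip_byte_identical(self, tmp_path):
        pairs = build_dataset([make_record(seed=6)], LabelMap(), size=32)
        save_cache(pairs, tmp_path / "c")
        loaded = load_cache(tmp_path / "c")
        np.testing.assert_array_equal(pairs[0].image, loaded[0].image)
        np.testing.assert_array_equal(pairs[0].mask_onehot, loaded[0].mask_onehot)
        np.testing.assert_array_equal(pairs[0].bottleneck_onehot,
                                      loaded[0].bottleneck_onehot)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="no input"):
            build_dataset([], LabelMap())


class TestVolumeIO:
    def test_metaimage_round_trip(self, tmp_path):
        import SimpleITK as sitk
        from spineseg.preprocess import read_volume
        r = np.random.default_rng(0)
        vox = r.random((4, 10, 10)).astype(np.float32)
        lab = r.integers(0, 3, (4, 10, 10)).astype(np.uint8)
        sitk.WriteImage(sitk.GetImageFromArray(vox), str(tmp_path / "case_t1.mha"))
        sitk.WriteImage(sitk.GetImageFromArray(lab), str(tmp_path / "case_t1_mask.mha"))
        rec = read_volume(tmp_path / "case_t1.mha", tmp_path / "case_t1_mask.mha")
        np.testing.assert_allclose(rec.voxels, vox)
        np.testing.assert_array_equal(rec.labels, lab)
        assert "t1" in rec.series_tag

    def test_nifti_reader(self, tmp_path):
        import nibabel as nib
        from spineseg.preprocess import read_volume
        r = np.random.default_rng(1)
        vox = r.random((6, 8, 4))
        lab = (vox > 0.5).astype(np.int16)
        nib.save(nib.Nifti1Image(vox, np.eye(4)), str(tmp_path / "s_t1.nii"))
        nib.save(nib.Nifti1Image(lab, np.eye(4)), str(tmp_path / "s_t1_m.nii"))
        rec = read_volume(tmp_path / "s_t1.nii", tmp_path / "s_t1_m.nii")
        assert rec.voxels.shape == (4, 8, 6)  # slice axis first
        np.testing.assert_allclose(np.transpose(rec.voxels, (2, 1, 0)), vox)
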