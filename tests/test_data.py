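"""Data plumbing: resizing oracle, augmentation group laws, splits, merging."""

import hashlib
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import leafcount as lc
from leafcount.data import ManifestRecord
from leafcount.errors import ValidationError
from leafcount.sim import EASY


def bilinear_oracle(img, th, tw):
    """Independent per-pixel bilinear interpolation at aligned pixel centers,
    clamped at the image border."""
    h, w = img.shape
    out = np.zeros((th, tw))
    for i in range(th):
        for j in range(tw):
            r = (i + 0.5) * h / th - 0.5
            c = (j + 0.5) * w / tw - 0.5
            r = min(max(r, 0.0), h - 1.0)
            c = min(max(c, 0.0), w - 1.0)
            r0, c0 = int(np.floor(r)), int(np.floor(c))
            r1, c1 = min(r0 + 1, h - 1), min(c0 + 1, w - 1)
            fr, fc = r - r0, c - c0
            out[i, j] = (img[r0, c0] * (1 - fr) * (1 - fc) + img[r0, c1] * (1 - fr) * fc
                         + img[r1, c0] * fr * (1 - fc) + img[r1, c1] * fr * fc)
    return out


def make_sample(rgb=None, mask=None, count=4):
    if rgb is None:
        rng = np.random.default_rng(0)
        rgb = rng.random((8, 8, 3), dtype=np.float32)
    return lc.ImageSample(rgb=rgb, mask=mask, count=count)


class TestResize:
    def test_identity_resize_returns_input(self):
        s = make_sample(mask=np.zeros((8, 8), np.uint8))
        out = lc.resize_bilinear(s, (8, 8))
        np.testing.assert_array_equal(out.rgb, s.rgb)
        np.testing.assert_array_equal(out.mask, s.mask)
        assert out.count == s.count

    def test_matches_independent_bilinear_oracle(self):
        grid = np.array([[0.0, 1.0], [1.0, 0.0]], dtype=np.float32)
        rgb = np.stack([grid] * 3, axis=2)
        out = lc.resize_bilinear(make_sample(rgb=rgb), (4, 4))
        expected = bilinear_oracle(grid, 4, 4)
        np.testing.assert_allclose(out.rgb[:, :, 0], expected, atol=1e-6)

    def test_oracle_agreement_on_random_image(self):
        rng = np.random.default_rng(1)
        grid = rng.random((5, 7), dtype=np.float32)
        rgb = np.stack([grid] * 3, axis=2)
        out = lc.resize_bilinear(make_sample(rgb=rgb), (11, 6))
        np.testing.assert_allclose(out.rgb[:, :, 0], bilinear_oracle(grid, 11, 6), atol=1e-5)

    def test_mask_resized_nearest_stays_binary(self):
        rng = np.random.default_rng(2)
        mask = (rng.random((8, 8)) > 0.5).astype(np.uint8)
        out = lc.resize_bilinear(make_sample(mask=mask), (19, 13))
        assert set(np.unique(out.mask)) <= {0, 1}

    def test_nonpositive_target_rejected(self):
        with pytest.raises(ValueError):
            lc.resize_bilinear(make_sample(), (0, 4))

    def test_mask_round_trip_stays_within_boundary_band(self):
        """Integer-scale up then back perturbs the mask only at its boundary."""
        from scipy.ndimage import binary_dilation, binary_erosion

        params = replace(EASY, seed=6)
        sample = lc.render_scene(lc.generate_scene(params, 0), params)
        up = lc.resize_bilinear(sample, (128, 128))
        back = lc.resize_bilinear(up, (64, 64))
        diff = sample.mask.astype(bool) ^ back.mask.astype(bool)
        boundary = sample.mask.astype(bool) ^ binary_erosion(sample.mask.astype(bool))
        band = binary_dilation(boundary, iterations=1)
        assert not np.any(diff & ~band)


class TestAugmentation:
    ops = lc.AugmentationOp

    def sample(self):
        rng = np.random.default_rng(3)
        rgb = rng.random((6, 6, 3), dtype=np.float32)
        mask = (rng.random((6, 6)) > 0.6).astype(np.uint8)
        return lc.ImageSample(rgb=rgb, mask=mask, count=5)

    def test_vflip_is_involution(self):
        s = self.sample()
        out = lc.apply_augmentation(lc.apply_augmentation(s, self.ops.VFLIP), self.ops.VFLIP)
        np.testing.assert_array_equal(out.rgb, s.rgb)
        np.testing.assert_array_equal(out.mask, s.mask)

    def test_rot90_cw_then_ccw_is_identity(self):
        s = self.sample()
        out = lc.apply_augmentation(lc.apply_augmentation(s, self.ops.ROT90CW),
                                    self.ops.ROT90CCW)
        np.testing.assert_array_equal(out.rgb, s.rgb)
        np.testing.assert_array_equal(out.mask, s.mask)

    def test_rot180_direction_independent(self):
        s = self.sample()
        via_cw = lc.apply_augmentation(lc.apply_augmentation(s, self.ops.ROT90CW),
                                       self.ops.ROT90CW)
        via_ccw = lc.apply_augmentation(lc.apply_augmentation(s, self.ops.ROT90CCW),
                                        self.ops.ROT90CCW)
        direct = lc.apply_augmentation(s, self.ops.ROT180)
        np.testing.assert_array_equal(via_cw.rgb, direct.rgb)
        np.testing.assert_array_equal(via_ccw.rgb, direct.rgb)

    @given(st.sampled_from(list(lc.AugmentationOp)))
    @settings(deadline=None, max_examples=8)
    def test_ops_preserve_count_and_binarity(self, op):
        s = self.sample()
        out = lc.apply_augmentation(s, op)
        assert out.count == s.count
        assert set(np.unique(out.mask)) <= {0, 1}
        assert out.rgb.shape == s.rgb.shape

    def test_unknown_op_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            lc.apply_augmentation(self.sample(), "flip")


class TestExpandWithAugmentation:
    def test_k_zero_leaves_manifest_unchanged(self, tiny_manifest):
        out = lc.expand_with_augmentation(tiny_manifest, 0, seed=1)
        assert out.records == tiny_manifest.records

    def test_cardinality_and_copied_counts(self, tmp_path):
        params = replace(EASY, n_images=5, canvas=(32, 32), leaf_length_range=(8.0, 12.0),
                         leaf_width_range=(3.0, 4.0), radial_offset_range=(2.0, 5.0), seed=1)
        manifest = lc.generate_dataset(params, tmp_path / "ds")
        out = lc.expand_with_augmentation(manifest, 2, seed=7)
        assert len(out) == 15
        by_stem = {r.image_path: r for r in out.records}
        for r in manifest.records:
            for j in range(2):
                aug = by_stem[r.image_path.replace(".png", f"_aug{j}.png")]
                assert aug.count == r.count
                assert (out.root / aug.image_path).exists()

    def test_same_seed_same_ops(self, tmp_path):
        params = replace(EASY, n_images=3, canvas=(32, 32), leaf_length_range=(8.0, 12.0),
                         leaf_width_range=(3.0, 4.0), radial_offset_range=(2.0, 5.0), seed=1)
        sums = []
        for name in ("a", "b"):
            manifest = lc.generate_dataset(params, tmp_path / name)
            out = lc.expand_with_augmentation(manifest, 2, seed=13)
            sums.append([hashlib.md5((out.root / r.image_path).read_bytes()).hexdigest()
                         for r in out.records])
        assert sums[0] == sums[1]

    def test_missing_file_raises_with_path(self, tmp_path):
        manifest = lc.DatasetManifest(tmp_path, [ManifestRecord("nope.png")])
        with pytest.raises(FileNotFoundError, match="nope.png"):
            lc.expand_with_augmentation(manifest, 1, seed=0)


def dummy_manifest(n, root="/tmp/x"):
    return lc.DatasetManifest(root, [ManifestRecord(f"img_{i}.png", count=3) for i in range(n)])


class TestSplit:
    def test_benchmark_sizes_1410_300_300(self):
        manifest = dummy_manifest(2010)
        spec = lc.SplitSpec(1410 / 2010, 300 / 2010, 300 / 2010, seed=0)
        out = lc.split_dataset(manifest, spec)
        sizes = {s: sum(r.split == s for r in out.records) for s in ("train", "val", "test")}
        assert sizes == {"train": 1410, "val": 300, "test": 300}

    def test_all_train(self):
        out = lc.split_dataset(dummy_manifest(10), lc.SplitSpec(1.0, 0.0, 0.0))
        assert all(r.split == "train" for r in out.records)

    def test_rounding_rule_70_15_15(self):
        out = lc.split_dataset(dummy_manifest(100), lc.SplitSpec(0.70, 0.15, 0.15))
        sizes = {s: sum(r.split == s for r in out.records) for s in ("train", "val", "test")}
        assert sizes == {"train": 70, "val": 15, "test": 15}

    def test_split_is_a_partition(self):
        out = lc.split_dataset(dummy_manifest(53), lc.SplitSpec(0.6, 0.2, 0.2, seed=5))
        assert all(r.split in ("train", "val", "test") for r in out.records)

    def test_empty_manifest_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            lc.split_dataset(dummy_manifest(0), lc.SplitSpec(1.0, 0.0, 0.0))

    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum"):
            lc.SplitSpec(0.5, 0.2, 0.2)

    def test_seeded_shuffle_reproducible(self):
        a = lc.split_dataset(dummy_manifest(40), lc.SplitSpec(0.5, 0.25, 0.25, seed=9))
        b = lc.split_dataset(dummy_manifest(40), lc.SplitSpec(0.5, 0.25, 0.25, seed=9))
        assert [r.split for r in a.records] == [r.split for r in b.records]


class TestMerge:
    def test_merge_with_empty_is_identity(self):
        a = dummy_manifest(4)
        out = lc.merge_manifests(a, lc.DatasetManifest("/tmp/x", []))
        assert out.records == a.records

    def test_merge_lengths_add(self):
        a = lc.DatasetManifest("/tmp/x/a", [ManifestRecord(f"a{i}.png") for i in range(810)])
        b = lc.DatasetManifest("/tmp/x/b", [ManifestRecord(f"b{i}.png") for i in range(1200)])
        out = lc.merge_manifests(a, b)
        assert len(out) == 2010
        sources = {r.image_path.split("/")[0] for r in out.records}
        assert sources == {"a", "b"}

    def test_duplicate_paths_rejected_and_listed(self):
        a = lc.DatasetManifest("/tmp/x", [ManifestRecord("same.png")])
        b = lc.DatasetManifest("/tmp/x", [ManifestRecord("same.png")])
        with pytest.raises(ValidationError, match="same.png"):
            lc.merge_manifests(a, b)


class TestManifestIO:
    def test_csv_round_trip(self, tmp_path):
        records = [ManifestRecord("i0.png", "m0.png", 4, "sim", "train"),
                   ManifestRecord("i1.png", None, None, "sim", "unassigned")]
        manifest = lc.DatasetManifest(tmp_path, records)
        manifest.to_csv(tmp_path / "m.csv")
        back = lc.DatasetManifest.from_csv(tmp_path / "m.csv")
        assert back.records == records

    def test_negative_count_rejected(self, tmp_path):
        with pytest.raises(ValidationError, match="negative"):
            lc.DatasetManifest(tmp_path, [ManifestRecord("x.png", count=-1)])

    def test_duplicate_paths_rejected(self, tmp_path):
        with pytest.raises(ValidationError, match="duplicate"):
            lc.DatasetManifest(tmp_path, [ManifestRecord("x.png"), ManifestRecord("x.png")])
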