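"""I/O layer: preprocessing, splits, batching, round-trips."""

import numpy as np
import pytest

from mpdc.data import (ImageBatch, PoolSampler, SlicePair, batch_from_pairs,
                       load_dataset, load_split, make_batch, normalize_intensity,
                       preprocess, read_mask, split_scans, write_dataset,
                       write_mask, write_mask_volume)
from mpdc.synthetic import FixtureSpec, generate, generate_arrays


def pairs_pool(n_scans=4, labeled=True, size=16, seed=0):
    rng = np.random.default_rng(seed)
    out = []
    for s in range(n_scans):
        for k in range(3):
            out.append(SlicePair(
                image=rng.random((size, size)).astype(np.float32),
                label=rng.integers(0, 2, (size, size)) if labeled else None,
                scan_id=f"s{s}", slice_index=k))
    return out


class TestPreprocess:
    def test_resize_to_configured_square(self):
        p = SlicePair(np.random.default_rng(0).random((40, 52)).astype(np.float32),
                      None, "a", 0)
        out = preprocess(p, 32)
        assert out.image.shape == (32, 32)

    def test_constant_slice_maps_to_zeros_without_nan(self):
        p = SlicePair(np.full((20, 20), 7.0, dtype=np.float32), None, "a", 0)
        out = preprocess(p, 16)
        assert not np.isnan(out.image).any()
        np.testing.assert_array_equal(out.image, 0.0)

    def test_nearest_resize_preserves_label_set(self):
        label = np.zeros((50, 50), dtype=np.int64)
        label[10:30, 10:30] = 2
        p = SlicePair(np.random.default_rng(1).random((50, 50)), label, "a", 0)
        out = preprocess(p, 32)
        assert set(np.unique(out.label)) <= {0, 2}
        assert 2 in out.label

    def test_idempotent_on_conforming_input(self):
        img = np.random.default_rng(2).random((16, 16)).astype(np.float32)
        p = preprocess(SlicePair(img, None, "a", 0), 16)
        q = preprocess(p, 16)
        np.testing.assert_allclose(p.image, q.image, atol=1e-6)

    def test_rgb_converted_to_luminance(self):
        rgb = np.random.default_rng(3).random((16, 16, 3)).astype(np.float32)
        out = preprocess(SlicePair(rgb, None, "a", 0), 16)
        assert out.image.ndim == 2

    def test_non_2d_rejected(self):
        with pytest.raises(ValueError):
            preprocess(SlicePair(np.zeros((2, 2, 2, 2)), None, "a", 0), 16)

    def test_normalization_range(self):
        x = np.random.default_rng(4).normal(500, 250, (8, 8))
        n = normalize_intensity(x)
        assert n.min() == 0.0 and n.max() == 1.0


class TestSplits:
    def test_ratio_arithmetic_7_1_2(self):
        groups = split_scans([f"s{i}" for i in range(10)], 1.0, 0.1, 0.2, seed=0)
        train = groups["labeled"] + groups["unlabeled"]
        assert (len(train), len(groups["val"]), len(groups["test"])) == (7, 1, 2)

    def test_ten_percent_of_seventy_training_scans(self):
        groups = split_scans([f"s{i}" for i in range(100)], 0.1, 0.1, 0.2, seed=0)
        assert len(groups["labeled"]) == 7
        assert len(groups["unlabeled"]) == 63

    def test_same_seed_identical_splits(self):
        ids = [f"s{i}" for i in range(20)]
        assert split_scans(ids, 0.2, 0.1, 0.2, 3) == split_scans(ids, 0.2, 0.1, 0.2, 3)

    def test_scan_disjointness_over_many_seeds(self):
        ids = [f"s{i}" for i in range(13)]
        for seed in range(50):
            g = split_scans(ids, 0.3, 0.2, 0.2, seed)
            buckets = [set(v) for v in g.values()]
            assert set().union(*buckets) == set(ids)
            assert sum(len(b) for b in buckets) == len(ids)

    def test_load_split_strips_unlabeled_and_checks_labels(self, tmp_path):
        generate(FixtureSpec(n_scans=6, slices_per_scan=2, image_size=16, seed=0),
                 tmp_path / "ds")
        split = {"labeled_fraction": 0.25, "val_fraction": 0.2, "test_fraction": 0.2,
                 "seed": 1}
        data = load_split(tmp_path / "ds", split)
        assert all(p.label is None for p in data.unlabeled)
        assert all(p.label is not None for p in data.labeled + data.val + data.test)
        scans = [set(p.scan_id for p in pool) for pool in
                 (data.labeled, data.unlabeled, data.val, data.test)]
        for i in range(4):
            for j in range(i + 1, 4):
                assert scans[i].isdisjoint(scans[j])

    def test_missing_label_for_labeled_scan_is_hard_error(self, tmp_path):
        root = tmp_path / "ds"
        generate(FixtureSpec(n_scans=3, slices_per_scan=2, image_size=16, seed=0), root)
        for f in (root / "labels").glob("scan000*"):
            f.unlink()
        with pytest.raises(ValueError, match="missing label"):
            load_split(root, {"labeled": ["scan000"], "unlabeled": ["scan001"],
                              "val": [], "test": ["scan002"]})


class TestBatching:
    def test_batch_composition(self, rng):
        b = make_batch(pairs_pool(), pairs_pool(labeled=False, seed=1), 8, 4, rng)
        assert b.images.shape == (8, 1, 16, 16)
        assert b.labeled_count == 4
        assert b.labels.shape == (4, 16, 16)

    def test_fully_supervised_boundary(self, rng):
        b = make_batch(pairs_pool(), [], 4, 4, rng)
        assert b.labeled_count == 4 and b.images.shape[0] == 4

    def test_identical_rng_state_gives_identical_batches(self):
        lab, unl = pairs_pool(), pairs_pool(labeled=False, seed=1)
        a = make_batch(lab, unl, 6, 3, np.random.default_rng(9))
        b = make_batch(lab, unl, 6, 3, np.random.default_rng(9))
        np.testing.assert_array_equal(a.images, b.images)
        assert a.metadata == b.metadata

    def test_empty_labeled_pool_rejected(self, rng):
        with pytest.raises(ValueError, match="labeled pool"):
            make_batch([], pairs_pool(labeled=False), 4, 2, rng)

    def test_labeled_overflow_rejected(self, rng):
        with pytest.raises(ValueError):
            make_batch(pairs_pool(), [], 4, 5, rng)

    def test_pool_sampler_cycles_with_reshuffle(self, rng):
        pool = pairs_pool(n_scans=2)  # 6 items
        sampler = PoolSampler(pool, rng)
        seen = sampler.draw(6)
        assert sorted(id(p) for p in seen) == sorted(id(p) for p in pool)
        assert len(sampler.draw(4)) == 4  # crosses the epoch boundary

    def test_labeled_item_without_label_rejected(self):
        pool = pairs_pool(labeled=False)
        with pytest.raises(ValueError):
            batch_from_pairs(pool[:2], labeled_count=2)


class TestRoundTrips:
    def test_mask_png_round_trip(self, tmp_path):
        mask = np.random.default_rng(0).integers(0, 4, (32, 32))
        write_mask(tmp_path / "m.png", mask)
        np.testing.assert_array_equal(read_mask(tmp_path / "m.png"), mask)

    def test_dataset_write_load_round_trip(self, tmp_path):
        pairs = generate_arrays(FixtureSpec(n_scans=2, slices_per_scan=2,
                                            image_size=16, seed=0))
        write_dataset(pairs, tmp_path / "ds")
        loaded = load_dataset(tmp_path / "ds")
        assert len(loaded) == len(pairs)
        by_key = {(p.scan_id, p.slice_index): p for p in loaded}
        for p in pairs:
            q = by_key[(p.scan_id, p.slice_index)]
            np.testing.assert_array_equal(q.label, p.label)
            # 16-bit quantisation on the [0,1] image
            np.testing.assert_allclose(q.image / 65535.0, p.image, atol=1e-4)

    def test_hdf5_archive_reader(self, tmp_path):
        import h5py
        with h5py.File(tmp_path / "scanA.h5", "w") as f:
            f["image_000"] = np.random.default_rng(0).random((16, 16))
            f["label_000"] = np.ones((16, 16), dtype=np.int64)
        loaded = load_dataset(tmp_path)
        assert len(loaded) == 1
        assert loaded[0].scan_id == "scanA"
        np.testing.assert_array_equal(loaded[0].label, 1)

    def test_nifti_volume_reader_and_mask_writer(self, tmp_path):
        import nibabel as nib
        root = tmp_path / "ds"
        (root / "images").mkdir(parents=True)
        (root / "labels").mkdir()
        vol = np.random.default_rng(1).random((16, 16, 3)).astype(np.float32)
        lab = (vol > 0.5).astype(np.int16)
        nib.save(nib.Nifti1Image(vol, np.eye(4)), root / "images" / "scanN.nii")
        nib.save(nib.Nifti1Image(lab, np.eye(4)), root / "labels" / "scanN.nii")
        loaded = load_dataset(root)
        assert len(loaded) == 3
        assert {p.slice_index for p in loaded} == {0, 1, 2}
        write_mask_volume(tmp_path / "pred.nii", np.stack([p.label for p in loaded]))
        back = np.asarray(nib.load(tmp_path / "pred.nii").dataobj)
        assert back.shape == (16, 16, 3)

    def test_missing_dataset_rejected(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            load_dataset(tmp_path / "nope")


class TestRgbHandling:
    def test_keep_mode_retains_three_channels_and_batches_channels_first(self):
        rgb = np.random.default_rng(5).random((20, 20, 3)).astype(np.float32)
        p = preprocess(SlicePair(rgb, np.zeros((20, 20), dtype=np.int64), "a", 0),
                       16, rgb="keep")
        assert p.image.shape == (16, 16, 3)
        batch = batch_from_pairs([p, p], labeled_count=2)
        assert batch.images.shape == (2, 3, 16, 16)
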