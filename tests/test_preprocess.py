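"""Slice augmentation, 8-bit normalization, equalization, and the split."""

import numpy as np
import pytest

from roscope import (ProcessedSlice, equalize_hist, generate_cell_stack,
                     largest_remainder, minmax_normalize, preprocess_slice,
                     slice_stack, split_dataset)


class TestSliceStack:
    def test_twenty_fold_augmentation(self, small_scene):
        import dataclasses

        params = dataclasses.replace(small_scene, n_slices=20)
        stack, _ = generate_cell_stack(params, seed=0)
        slices = slice_stack(stack)
        assert len(slices) == 20
        assert [s.z_index for s in slices] == list(range(20))

    def test_singleton_and_round_trip(self, small_scene):
        import dataclasses

        stack, _ = generate_cell_stack(
            dataclasses.replace(small_scene, n_slices=1), seed=0)
        assert len(slice_stack(stack)) == 1

        stack, _ = generate_cell_stack(small_scene, seed=1)
        rebuilt = np.stack([s.pixels for s in slice_stack(stack)])
        assert np.array_equal(rebuilt, stack.ros)

    def test_unknown_channel(self, small_scene):
        stack, _ = generate_cell_stack(small_scene, seed=0)
        with pytest.raises(ValueError):
            slice_stack(stack, channel="dapi")


class TestMinmaxNormalize:
    def test_full_range_input_unchanged(self, rng):
        img = rng.integers(0, 256, (16, 16)).astype(np.uint8)
        img[0, 0], img[0, 1] = 0, 255
        assert np.array_equal(minmax_normalize(img), img)

    def test_midpoint_rounds_half_to_even(self):
        img = np.array([[0, 510, 255]])
        out = minmax_normalize(img)
        assert out[0, 0] == 0 and out[0, 1] == 255
        assert out[0, 2] == 128  # 127.5 rounds to the even neighbour

    def test_range_contract(self, rng):
        for _ in range(20):
            img = rng.uniform(-50, 5000, (9, 13))
            out = minmax_normalize(img)
            assert out.min() == 0 and out.max() == 255

    def test_constant_image_is_zeroed(self):
        out = minmax_normalize(np.full((4, 4), 17.0))
        assert not out.any() and out.dtype == np.uint8

    def test_affine_invariance(self, rng):
        """Normalization cancels any positive affine rescaling of the input."""
        img = rng.uniform(0, 1000, (12, 12))
        for a, b in [(2.0, 5.0), (0.3, -40.0), (17.5, 1e4)]:
            assert np.array_equal(minmax_normalize(a * img + b),
                                  minmax_normalize(img))

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            minmax_normalize(np.array([[1.0, np.nan]]))


class TestEqualizeHist:
    def test_two_level_worked_example(self):
        """[[0,0],[255,255]] is a fixed point of the CDF remapping."""
        img = np.array([[0, 0], [255, 255]], dtype=np.uint8)
        assert np.array_equal(equalize_hist(img), img)

    def test_constant_image_unchanged(self):
        img = np.full((5, 5), 99, dtype=np.uint8)
        assert np.array_equal(equalize_hist(img), img)

    def test_hand_computed_cdf_mapping(self):
        """Direct evaluation of out(v) = round((cdf(v)-cdf_min)/(N-cdf_min)*255)."""
        img = np.array([[10, 10], [20, 200]], dtype=np.uint8)
        # cdf: 10 -> 2, 20 -> 3, 200 -> 4; cdf_min = 2, N = 4
        expected = np.rint((np.array([[2, 2], [3, 4]]) - 2) / 2 * 255).astype(np.uint8)
        assert np.array_equal(equalize_hist(img), expected)

    def test_flattens_skewed_histograms(self, rng):
        """The Kolmogorov distance of the intensity CDF to uniform does not
        increase (brute-force CDF comparison)."""
        def ks_to_uniform(img):
            cdf = np.cumsum(np.bincount(img.ravel(), minlength=256)) / img.size
            return np.abs(cdf - (np.arange(256) + 1) / 256).max()

        for _ in range(20):
            img = (rng.random((32, 32)) ** 3 * 255).astype(np.uint8)  # skewed
            assert ks_to_uniform(equalize_hist(img)) <= ks_to_uniform(img) + 0.01

    def test_idempotent_up_to_rounding(self, rng):
        img = (rng.random((32, 32)) ** 2 * 255).astype(np.uint8)
        once = equalize_hist(img)
        twice = equalize_hist(once)
        assert np.abs(twice.astype(int) - once.astype(int)).max() <= 1

    def test_rejects_non_8bit(self):
        with pytest.raises(ValueError):
            equalize_hist(np.zeros((4, 4), dtype=np.uint16))


class TestPreprocessSlice:
    def test_downscales_1024_to_256(self, rng):
        img = rng.integers(0, 4096, (1024, 1024)).astype(np.uint16)
        out = preprocess_slice(img)
        out.validate()
        assert out.pixels.shape == (256, 256)

    def test_identity_resize_path(self, rng):
        img = rng.integers(0, 256, (256, 256)).astype(np.uint8)
        out = preprocess_slice(img)
        assert out.pixels.shape == (256, 256)

    def test_non_integer_factor_resize(self, rng):
        img = rng.integers(0, 1000, (300, 300)).astype(np.uint16)
        assert preprocess_slice(img).pixels.shape == (256, 256)

    def test_rgb_input_collapses_to_gray(self, rng):
        img = rng.integers(0, 256, (256, 256, 3)).astype(np.uint8)
        assert preprocess_slice(img).pixels.ndim == 2

    def test_output_range_property(self, rng):
        for _ in range(20):
            img = rng.gamma(1.5, 300.0, (128, 128))
            out = preprocess_slice(img).pixels
            assert out.dtype == np.uint8
            assert out.min() >= 0 and out.max() <= 255


def _fake_slices(cells: dict[str, int], condition="LPS", treatment="control"):
    """cells: cell_id -> number of slices."""
    px = np.zeros((256, 256), dtype=np.uint8)
    out = []
    for cid, n in cells.items():
        for z in range(n):
            out.append(ProcessedSlice(pixels=px, treatment=treatment,
                                      condition=condition, cell_id=cid, z_index=z))
    return out


class TestSplitDataset:
    def test_largest_remainder_apportionment(self):
        assert largest_remainder(100, (0.72, 0.08, 0.20)) == [72, 8, 20]
        assert largest_remainder(10, (0.72, 0.08, 0.20)) == [7, 1, 2]

    def test_hundred_slices_split_72_8_20(self):
        slices = _fake_slices({f"c{i}": 1 for i in range(100)})
        split = split_dataset(slices, seed=0, grouping="by_slice")
        assert split.sizes() == {"train": 72, "val": 8, "test": 20}

    def test_by_cell_grouping_contract(self):
        slices = _fake_slices({f"c{i}": 10 for i in range(10)})
        split = split_dataset(slices, seed=3, grouping="by_cell")
        parts = {}
        for s, p in zip(slices, split.assignment):
            parts.setdefault(s.cell_id, set()).add(p)
        assert all(len(v) == 1 for v in parts.values())
        # cells are 10-slice atoms: partitions sit within one cell of target
        sizes = split.sizes()
        assert sum(sizes.values()) == 100
        for part, target in zip(("train", "val", "test"), (72, 8, 20)):
            assert abs(sizes[part] - target) < 10

    def test_disjoint_exhaustive_reproducible(self):
        slices = _fake_slices({f"c{i}": 7 for i in range(9)})
        s1 = split_dataset(slices, seed=5)
        s2 = split_dataset(slices, seed=5)
        assert s1.assignment == s2.assignment
        assert all(p in ("train", "val", "test") for p in s1.assignment)
        total = sum(s1.sizes().values())
        assert total == len(slices)

    def test_stratified_by_group(self):
        slices = (_fake_slices({f"a{i}": 1 for i in range(50)}, treatment="CBD")
                  + _fake_slices({f"b{i}": 1 for i in range(50)}, treatment="control"))
        split = split_dataset(slices, seed=1, grouping="by_slice")
        for treat in ("CBD", "control"):
            idx = [i for i, s in enumerate(slices) if s.treatment == treat]
            counts = {p: sum(split.assignment[i] == p for i in idx)
                      for p in ("train", "val", "test")}
            assert counts == {"train": 36, "val": 4, "test": 10}

    def test_oversized_cell_raises(self):
        slices = _fake_slices({"big": 10, "small": 2})
        with pytest.raises(ValueError, match="more slices than"):
            split_dataset(slices, fractions=(0.4, 0.3, 0.3), grouping="by_cell")

    def test_bad_fractions(self):
        slices = _fake_slices({"c": 3})
        with pytest.raises(ValueError):
            split_dataset(slices, fractions=(0.5, 0.5, 0.2))
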