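"""Segmentation, ImageJ-style measures, and the Welch statistics."""

import dataclasses

import numpy as np
import pytest
from scipy import stats

from roscope import (CellMask, NoCellFoundError, generate_cell_stack,
                     measure_cell, segment_cell, welch_test)
from roscope.quantify import compare_groups
import pandas as pd


def _full_mask(shape2d, n_slices=1, pixel_size=1.0):
    return CellMask.from_footprint(np.ones(shape2d, dtype=bool), n_slices, pixel_size)


class TestMeasureCell:
    def test_hand_example(self):
        """2x2 region [1,2,3,4] at 1 um pixels: mean 2.5, max 4, raw 10,
        area 4 um^2, IntDen 10."""
        ros = np.array([[1.0, 2.0], [3.0, 4.0]])
        m = measure_cell(ros, _full_mask((2, 2)))
        assert m.mean == 2.5
        assert m.max == 4.0
        assert m.raw_int_den == 10.0
        assert m.area_um2 == 4.0
        assert m.int_den == 10.0

    def test_constant_field(self):
        ros = np.full((5, 7), 3.25)
        m = measure_cell(ros, _full_mask((5, 7)))
        assert m.mean == 3.25 and m.max == 3.25
        assert m.raw_int_den == 3.25 * 35

    def test_identities_on_random_images(self, rng):
        """raw = mean x area_px and IntDen = mean x area_um2 to 1e-9 relative,
        and max >= mean, on 100 random masked images."""
        for _ in range(100):
            h, w = rng.integers(4, 40, 2)
            z = int(rng.integers(1, 6))
            ros = rng.gamma(2.0, 50.0, (z, h, w))
            fp = rng.random((h, w)) < 0.5
            fp[0, 0] = True  # never empty
            px = float(rng.uniform(0.1, 2.0))
            m = measure_cell(ros, CellMask.from_footprint(fp, z, px), pixel_size_um=px)
            assert m.raw_int_den == pytest.approx(m.mean * m.area_px, rel=1e-9)
            assert m.int_den == pytest.approx(m.mean * m.area_um2, rel=1e-9)
            assert m.max >= m.mean >= 0

    def test_mask_invariance(self, rng):
        """Pixels outside the mask contribute to no measure."""
        ros = rng.uniform(0, 100, (3, 20, 20))
        fp = np.zeros((20, 20), dtype=bool)
        fp[5:15, 5:15] = True
        mask = CellMask.from_footprint(fp, 3, 1.0)
        before = measure_cell(ros, mask)
        ros2 = ros.copy()
        ros2[:, ~fp] += 1e6
        after = measure_cell(ros2, mask)
        assert before.as_dict() == after.as_dict()

    def test_voxel_mode(self, rng):
        ros = rng.uniform(0, 10, (4, 8, 8))
        mask = _full_mask((8, 8), n_slices=4)
        m = measure_cell(ros, mask, mode="voxel")
        assert m.raw_int_den == pytest.approx(ros.sum(), rel=1e-12)
        assert m.max == ros.max()

    def test_empty_mask_error(self):
        with pytest.raises(ValueError):
            CellMask.from_footprint(np.zeros((4, 4), dtype=bool), 1, 1.0)


class TestSegmentCell:
    def test_recovers_ground_truth_footprint(self, small_scene):
        """Jaccard of the segmented footprint against the generator's mask
        footprint is at least 0.8 at the default noise level."""
        for seed in (1, 2, 3):
            stack, truth = generate_cell_stack(small_scene, seed=seed)
            cm = segment_cell(stack)
            true_fp = truth.mask.any(axis=0)
            jac = (cm.footprint & true_fp).sum() / (cm.footprint | true_fp).sum()
            assert jac >= 0.8

    def test_no_cell_found(self):
        with pytest.raises(NoCellFoundError):
            segment_cell(np.zeros((4, 32, 32), dtype=np.uint16))

    def test_disk_is_fixed_point(self):
        """A clean binary disk segments to exactly itself."""
        from skimage.morphology import disk

        img = np.zeros((41, 41), dtype=np.uint16)
        d = disk(12).astype(bool)
        img[8:8 + d.shape[0], 8:8 + d.shape[1]] = d * 1000
        cm = segment_cell(img)
        assert np.array_equal(cm.footprint, img > 0)

    def test_noiseless_raw_int_den_matches_ground_truth(self, clean_scene):
        """On a noiseless stack the measured RawIntDen equals the generator's
        recorded integrated ROS."""
        stack, truth = generate_cell_stack(clean_scene, seed=13)
        cm = segment_cell(stack)
        m = measure_cell(stack, cm)
        assert m.raw_int_den == pytest.approx(truth.true_integrated_ros, rel=1e-12)


class TestWelch:
    def test_identical_groups(self):
        c = welch_test([1, 2, 3], [1, 2, 3])
        assert c.t == 0.0 and c.p == 1.0

    def test_closed_form_toy(self):
        """a=[10,11,12] vs b=[1,2,3]: t = 9/sqrt(2/3), df = 4, p matches an
        independent t-CDF evaluation to 1e-10."""
        c = welch_test([10, 11, 12], [1, 2, 3])
        assert c.t == pytest.approx(9 / np.sqrt(2 / 3), rel=1e-12)
        assert c.df == pytest.approx(4.0, rel=1e-12)
        expected_p = 2 * (1 - stats.t.cdf(9 / np.sqrt(2 / 3), 4))
        assert c.p == pytest.approx(expected_p, abs=1e-10)
        assert c.stars == "***"

    def test_matches_reference_implementation(self, rng):
        """Agreement with scipy's Welch t-test to 1e-10 on 100 random datasets."""
        for _ in range(100):
            a = rng.normal(rng.uniform(-2, 2), rng.uniform(0.5, 3), rng.integers(3, 40))
            b = rng.normal(rng.uniform(-2, 2), rng.uniform(0.5, 3), rng.integers(3, 40))
            ours = welch_test(a, b)
            ref = stats.ttest_ind(a, b, equal_var=False)
            assert ours.t == pytest.approx(ref.statistic, abs=1e-10)
            assert ours.p == pytest.approx(ref.pvalue, abs=1e-10)
            assert ours.df == pytest.approx(ref.df, abs=1e-10)

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError):
            welch_test([1.0], [1, 2, 3])
        with pytest.raises(ValueError):
            welch_test([1, 2, np.inf], [1, 2, 3])
        same = welch_test([5, 5, 5], [5, 5])
        assert same.p == 1.0
        diff = welch_test([5, 5, 5], [4, 4])
        assert diff.p == 0.0 and diff.t > 0

    def test_type_one_error_calibration(self, rng):
        """Under the null (same normal population) the 5%-level rejection rate
        over 1000 replicates stays within [0.03, 0.07]."""
        rejections = 0
        for _ in range(1000):
            a = rng.normal(0, 1, 20)
            b = rng.normal(0, 1, 20)
            if welch_test(a, b).p < 0.05:
                rejections += 1
        assert 0.03 <= rejections / 1000 <= 0.07

    def test_sign_convention(self, rng):
        a = rng.normal(5, 1, 30)
        b = rng.normal(0, 1, 30)
        c = welch_test(a, b)
        assert np.sign(c.t) == np.sign(c.mean_a - c.mean_b) == 1


class TestCompareGroups:
    @staticmethod
    def _table(n=20, shift=0.0, rng=None):
        rng = rng or np.random.default_rng(0)
        rows = []
        for cond in ("LPS",):
            for treat, mu in (("CBD", 10 + shift), ("control", 10)):
                for i in range(n):
                    rows.append({"cell_id": f"{cond}_{treat}_{i}", "condition": cond,
                                 "treatment": treat,
                                 "raw_int_den": rng.normal(mu, 1)})
        return pd.DataFrame(rows)

    def test_detects_shift(self):
        comps, summary = compare_groups(self._table(shift=-3), "raw_int_den")
        assert comps["LPS"].p < 0.001
        assert comps["LPS"].mean_a < comps["LPS"].mean_b  # CBD below control
        assert set(summary.columns) >= {"condition", "t", "df", "p", "stars",
                                        "mean_cbd", "sem_cbd"}

    def test_missing_group_warns_and_skips(self):
        df = self._table()
        df = df[~((df.condition == "LPS") & (df.treatment == "control"))]
        with pytest.warns(UserWarning, match="missing or undersized"):
            comps, summary = compare_groups(df, "raw_int_den")
        assert not comps and summary.empty

    def test_unknown_measure(self):
        with pytest.raises(ValueError):
            compare_groups(self._table(), "bogus")
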