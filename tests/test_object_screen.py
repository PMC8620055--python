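import math

import numpy as np
import pytest
from scipy import ndimage

from conftest import voxelized_ball
from glom3d.object_screen import (
    ScreenedObjects,
    enclosing_ellipsoid_volume,
    minimum_volume_ellipsoid,
    ratio_distribution,
    screen_by_shape,
    screen_by_volume,
    shape_ratio,
    shape_table,
    volume_distribution,
)
from glom3d.segmentation import LabelStack

SPACING = (2.0, 0.5, 0.5)
ISO = (0.5, 0.5, 0.5)

# closed form for any box: V_box / V_mvee = 8 / (4/3·π·3^{3/2})
BOX_RATIO = 8.0 / (4.0 / 3.0 * math.pi * 3**1.5)


def labels_with_counts(counts, spacing=SPACING) -> LabelStack:
    """LabelStack of disjoint straight runs with the requested voxel counts."""
    total = sum(counts) + len(counts)
    arr = np.zeros((1, 1, total), np.int32)
    pos = 0
    for i, c in enumerate(counts, start=1):
        arr[0, 0, pos : pos + c] = i
        pos += c + 1
    return LabelStack(arr, len(counts), spacing)


class TestVolumeDistribution:
    def test_single_voxel_objects(self):
        labels = labels_with_counts([1, 1, 1])
        curve = volume_distribution(labels)
        assert curve.total == 3
        mean_volume = (curve.positions * curve.frequencies).sum() / curve.total
        assert mean_volume == pytest.approx(0.5, rel=0.05)

    def test_one_object_single_bin(self):
        curve = volume_distribution(labels_with_counts([10]))
        assert curve.total == 1
        assert np.count_nonzero(curve.frequencies) == 1

    def test_empty_rejected(self):
        labels = LabelStack(np.zeros((2, 2, 2), np.int32), 0, SPACING)
        with pytest.raises(ValueError):
            volume_distribution(labels)

    def test_two_scales_both_populated(self, default_phantom):
        _, _, truth = default_phantom
        # construction knowledge: tubule fragments sit ~1 decade below glomeruli
        from glom3d.segmentation import BinaryStack, label_components

        cm = truth.class_map
        mask = ((cm >= 2) & (cm <= 4)).astype(np.uint8)
        labels = label_components(BinaryStack(mask, SPACING))
        curve = volume_distribution(labels)
        small = curve.frequencies[curve.positions < 1000].sum()
        large = curve.frequencies[curve.positions > 2000].sum()
        assert small >= 10 and large >= 10


class TestScreenByVolume:
    def test_direct_predicate(self):
        labels = labels_with_counts([1, 1, 100000])  # 0.5, 0.5, 50000 µm³
        out = screen_by_volume(labels, min_volume=1000)
        np.testing.assert_array_equal(out.kept_labels, [3])
        assert out.stage == "volume"

    def test_zero_threshold_keeps_all(self):
        labels = labels_with_counts([1, 2, 3])
        out = screen_by_volume(labels, min_volume=0)
        assert out.kept_labels.size == 3

    def test_screen_removing_everything_warns(self):
        labels = labels_with_counts([1, 2])
        with pytest.warns(UserWarning, match="removed all"):
            out = screen_by_volume(labels, min_volume=1e9)
        assert out.kept_labels.size == 0

    def test_anti_monotone_in_threshold(self):
        labels = labels_with_counts([1, 5, 20, 100, 400])
        kept = [
            set(screen_by_volume(labels, min_volume=v).kept_labels.tolist())
            for v in (0.1, 1.0, 10.0, 100.0)
        ]
        for a, b in zip(kept, kept[1:]):
            assert b <= a


class TestEnclosingEllipsoid:
    def test_cube_corners_closed_form(self):
        pts = np.array(
            [[i, j, k] for i in (0.0, 2.0) for j in (0.0, 2.0) for k in (0.0, 2.0)]
        )
        vell = enclosing_ellipsoid_volume(pts, inflate="never")
        exact = 4.0 / 3.0 * math.pi * 3**1.5  # circumscribed sphere radius sqrt(3)
        assert vell == pytest.approx(exact, rel=0.005)

    def test_khachiyan_matches_exact_sphere(self):
        # points on a sphere of radius 5: MVEE is the sphere itself
        rng = np.random.default_rng(0)
        v = rng.standard_normal((500, 3))
        pts = 5.0 * v / np.linalg.norm(v, axis=1, keepdims=True)
        A, c = minimum_volume_ellipsoid(pts)
        vol = 4.0 / 3.0 * math.pi / math.sqrt(np.linalg.det(A))
        assert vol == pytest.approx(4.0 / 3.0 * math.pi * 125, rel=0.01)
        assert np.linalg.norm(c) < 0.05

    def test_voxelized_ball_within_10pct(self):
        mask = voxelized_ball(10.0, ISO)
        pts = np.argwhere(mask) * 0.5
        vell = enclosing_ellipsoid_volume(pts, ISO)
        assert vell == pytest.approx(4.0 / 3.0 * math.pi * 1000, rel=0.10)

    def test_single_voxel_inflated(self):
        vell = enclosing_ellipsoid_volume(np.array([[1.0, 1.0, 1.0]]), SPACING)
        # closed form: MVEE of a 2 × 0.5 × 0.5 box = 4/3·π·3^1.5·(1·0.25·0.25)
        exact = 4.0 / 3.0 * math.pi * 3**1.5 * 1.0 * 0.25 * 0.25
        assert vell == pytest.approx(exact, rel=0.01)

    def test_coplanar_inflated_positive(self):
        pts = np.array([[0.0, i, j] for i in range(3) for j in range(3)])
        assert enclosing_ellipsoid_volume(pts, (1, 1, 1)) > 0

    def test_degenerate_without_inflation_rejected(self):
        pts = np.array([[0.0, i, j] for i in range(3) for j in range(3)])
        with pytest.raises(ValueError):
            enclosing_ellipsoid_volume(pts, (1, 1, 1), inflate="never")

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            enclosing_ellipsoid_volume(np.empty((0, 3)), SPACING)


class TestShapeRatio:
    def test_ball_scores_high(self):
        mask = voxelized_ball(10.0, ISO)
        assert shape_ratio(mask, ISO) >= 0.85

    def test_thin_tube_scores_low(self):
        # 100 × 2 × 2 µm box at 0.5 µm: exact ratio is BOX_RATIO ≈ 0.368 for
        # any box (affine invariance of the minimum-volume enclosing ellipsoid)
        tube = np.ones((4, 4, 200), bool)
        ratio = shape_ratio(tube, ISO)
        assert ratio == pytest.approx(BOX_RATIO, rel=0.05)
        assert ratio < 0.45  # well separated from the ball's ≥ 0.85

    def test_ball_beats_tube(self):
        ball = voxelized_ball(10.0, ISO)
        tube = np.ones((4, 4, 200), bool)
        assert shape_ratio(ball, ISO) > 2 * shape_ratio(tube, ISO)

    def test_voxelized_ellipsoid_approaches_one(self):
        def ellipsoid_mask(h):
            a, b, c = 10.0, 6.0, 4.0
            n = int(2 * a / h) + 6
            ax = (np.arange(n) - n / 2 + 0.5) * h
            return (
                (ax[:, None, None] / a) ** 2
                + (ax[None, :, None] / b) ** 2
                + (ax[None, None, :] / c) ** 2
            ) <= 1

        coarse = shape_ratio(ellipsoid_mask(1.0), (1.0, 1.0, 1.0))
        fine = shape_ratio(ellipsoid_mask(0.5), ISO)
        assert fine > coarse  # converges toward 1 as resolution increases
        assert fine >= 0.8

    def test_in_unit_interval(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            mask = rng.random((6, 8, 8)) > 0.6
            if mask.sum() == 0:
                continue
            mask = ndimage.binary_dilation(mask)
            r = shape_ratio(mask, SPACING)
            assert 0 < r <= 1

    def test_dilation_grows_both_volumes(self):
        mask = voxelized_ball(4.0, ISO)
        grown = ndimage.binary_dilation(mask)
        v1, v2 = mask.sum() * 0.125, grown.sum() * 0.125
        e1 = enclosing_ellipsoid_volume(np.argwhere(mask) * 0.5, ISO, inflate="always")
        e2 = enclosing_ellipsoid_volume(np.argwhere(grown) * 0.5, ISO, inflate="always")
        assert v2 >= v1
        assert e2 >= e1 * 0.999  # set inclusion, modulo iteration tolerance


class TestShapeScreen:
    def _table(self, ratios):
        import pandas as pd

        return pd.DataFrame(
            {
                "voxel_count": 10,
                "volume_um3": 5.0,
                "vell_um3": 5.0 / np.asarray(ratios),
                "ratio": ratios,
            },
            index=pd.Index(range(1, len(ratios) + 1), name="label"),
        )

    def test_direct_predicate(self):
        out = screen_by_shape(self._table([0.1, 0.6, 0.7]), min_ratio=0.4)
        np.testing.assert_array_equal(out.kept_labels, [2, 3])
        assert out.stage == "shape"

    def test_zero_threshold_keeps_all(self):
        out = screen_by_shape(self._table([0.1, 0.6, 0.7]), min_ratio=0.0)
        assert out.kept_labels.size == 3

    def test_empty_result_warns(self):
        with pytest.warns(UserWarning, match="removed all"):
            screen_by_shape(self._table([0.1, 0.2]), min_ratio=0.9)

    def test_anti_monotone_in_threshold(self):
        table = self._table([0.1, 0.3, 0.5, 0.7, 0.9])
        kept = [
            set(screen_by_shape(table, min_ratio=r).kept_labels.tolist())
            for r in (0.05, 0.2, 0.4, 0.8)
        ]
        for a, b in zip(kept, kept[1:]):
            assert b <= a


class TestShapeTable:
    def test_table_consistency(self):
        mask = voxelized_ball(4.0, ISO).astype(np.int32)
        labels = LabelStack(mask, 1, ISO)
        table = shape_table(labels)
        row = table.loc[1]
        assert row["voxel_count"] == mask.sum()
        assert row["volume_um3"] == pytest.approx(mask.sum() * 0.125)
        assert row["ratio"] == pytest.approx(row["volume_um3"] / row["vell_um3"])

    def test_missing_label_rejected(self):
        labels = labels_with_counts([5])
        with pytest.raises((ValueError, IndexError)):
            shape_table(labels, np.array([7]))


def test_ratio_distribution_bins_span_unit_interval():
    curve = ratio_distribution(np.array([0.05, 0.5, 0.95]), n_bins=25)
    assert curve.positions[0] > 0 and curve.positions[-1] < 1
    assert curve.total == 3


def test_screened_objects_stage_validated():
    with pytest.raises(ValueError):
        ScreenedObjects(np.array([1]), 0.5, "colour")
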