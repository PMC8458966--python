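import numpy as np
import pytest
from scipy.ndimage import binary_erosion
from scipy.spatial.distance import cdist

from longimpute.errors import InputError, MetricUndefinedError
from longimpute.metrics import (
    BinaryMask,
    MetricRefs,
    asd,
    avd,
    border_voxels,
    dice,
    fused_score,
    per_structure_report,
    tanimoto_error,
)
from longimpute.volume_io import LabelMap


def brute_border(mask: np.ndarray) -> np.ndarray:
    """Independent border definition: 6-neighbour scan with padding."""
    padded = np.pad(mask, 1, constant_values=False)
    out = np.zeros_like(mask)
    idx = np.argwhere(mask)
    for z, y, x in idx:
        pz, py, px = z + 1, y + 1, x + 1
        neighbours = [padded[pz - 1, py, px], padded[pz + 1, py, px],
                      padded[pz, py - 1, px], padded[pz, py + 1, px],
                      padded[pz, py, px - 1], padded[pz, py, px + 1]]
        if not all(neighbours):
            out[z, y, x] = True
    return out


def brute_asd(m1: np.ndarray, m2: np.ndarray, spacing) -> float:
    """O(n^2) all-pairs surface distance oracle."""
    b1 = np.argwhere(brute_border(m1)) * np.asarray(spacing)
    b2 = np.argwhere(brute_border(m2)) * np.asarray(spacing)
    d = cdist(b1, b2)
    return (d.min(axis=1).sum() + d.min(axis=0).sum()) / (len(b1) + len(b2))


def _random_mask_pair(seed, shape=(12, 12, 12), p=0.3):
    rng = np.random.default_rng(seed)
    while True:
        m1 = rng.random(shape) < p
        m2 = rng.random(shape) < p
        if m1.any() and m2.any():
            return m1, m2


class TestAvd:
    def test_identical_masks_zero(self, rng):
        m = rng.random((6, 6, 6)) < 0.4
        m[0, 0, 0] = True
        assert avd(BinaryMask(m), BinaryMask(m)) == 0.0

    def test_eq9_arithmetic_and_asymmetry(self):
        m1 = np.zeros((10, 10, 10), bool)
        m2 = np.zeros((10, 10, 10), bool)
        m1.ravel()[:100] = True
        m2.ravel()[:80] = True
        assert avd(BinaryMask(m1), BinaryMask(m2)) == pytest.approx(20.0)
        assert avd(BinaryMask(m2), BinaryMask(m1)) == pytest.approx(25.0)

    def test_empty_reference_errors(self):
        empty = BinaryMask(np.zeros((4, 4, 4), bool))
        full = BinaryMask(np.ones((4, 4, 4), bool))
        with pytest.raises(MetricUndefinedError):
            avd(empty, full)


class TestBorder:
    def test_single_voxel_is_its_own_border(self):
        m = np.zeros((5, 5, 5), bool)
        m[2, 2, 2] = True
        assert np.array_equal(border_voxels(BinaryMask(m)).data, m)

    def test_solid_cube_border_count(self):
        m = np.zeros((9, 9, 9), bool)
        m[2:7, 2:7, 2:7] = True
        assert border_voxels(BinaryMask(m)).count == 5 ** 3 - 3 ** 3  # 98

    def test_one_voxel_thick_plane_is_all_border(self):
        m = np.zeros((7, 7, 7), bool)
        m[3, :, :] = True
        assert np.array_equal(border_voxels(BinaryMask(m)).data, m)

    def test_grid_edge_counts_as_background(self):
        m = np.ones((4, 4, 4), bool)
        assert border_voxels(BinaryMask(m)).count == 4 ** 3 - 2 ** 3


class TestAsd:
    def test_identical_masks_zero(self, rng):
        m = rng.random((8, 8, 8)) < 0.4
        m[3, 3, 3] = True
        assert asd(BinaryMask(m), BinaryMask(m)) == 0.0

    def test_two_voxels_three_apart(self):
        m1 = np.zeros((8, 8, 8), bool)
        m2 = np.zeros((8, 8, 8), bool)
        m1[2, 2, 2] = True
        m2[2, 2, 5] = True
        assert asd(BinaryMask(m1), BinaryMask(m2)) == pytest.approx(3.0)

    def test_spacing_scales_distances(self):
        m1 = np.zeros((8, 8, 8), bool)
        m2 = np.zeros((8, 8, 8), bool)
        m1[2, 2, 2] = True
        m2[2, 2, 4] = True
        sp = (1.0, 1.0, 2.5)
        assert asd(BinaryMask(m1, sp), BinaryMask(m2, sp)) == pytest.approx(5.0)

    def test_matches_brute_force_on_random_pairs(self):
        for seed in range(5):
            m1, m2 = _random_mask_pair(seed)
            got = asd(BinaryMask(m1), BinaryMask(m2))
            assert got == pytest.approx(brute_asd(m1, m2, (1, 1, 1)), abs=1e-9)

    def test_empty_mask_errors(self):
        m = np.zeros((4, 4, 4), bool)
        m2 = m.copy()
        m2[1, 1, 1] = True
        with pytest.raises(MetricUndefinedError):
            asd(BinaryMask(m), BinaryMask(m2))


class TestOverlap:
    def test_dice_constructed_half_overlap(self):
        m1 = np.zeros((6, 6, 6), bool)
        m2 = np.zeros((6, 6, 6), bool)
        m1[0:2, 0:2, 0:2] = True  # 8 voxels
        m2[0:2, 0:2, 1:3] = True  # 8 voxels, 4 shared
        assert dice(BinaryMask(m1), BinaryMask(m2)) == pytest.approx(0.5)

    def test_dice_extremes(self, rng):
        m = rng.random((6, 6, 6)) < 0.5
        m[0, 0, 0] = True
        assert dice(BinaryMask(m), BinaryMask(m)) == 1.0
        other = ~m
        assert dice(BinaryMask(m), BinaryMask(other)) == 0.0

    def test_tanimoto_constructed(self):
        m1 = np.zeros((4, 4, 4), bool)
        m2 = np.zeros((4, 4, 4), bool)
        m1.ravel()[:8] = True
        m2.ravel()[4:12] = True  # union 12, intersection 4
        assert tanimoto_error(BinaryMask(m1), BinaryMask(m2)) == pytest.approx(200.0 / 3)

    def test_tanimoto_extremes(self, rng):
        m = rng.random((5, 5, 5)) < 0.5
        m[0, 0, 0] = True
        assert tanimoto_error(BinaryMask(m), BinaryMask(m)) == 0.0
        assert tanimoto_error(BinaryMask(m), BinaryMask(~m)) == 100.0

    def test_symmetry_and_dice_tanimoto_identity(self):
        for seed in range(5):
            m1, m2 = _random_mask_pair(seed + 100)
            b1, b2 = BinaryMask(m1), BinaryMask(m2)
            assert dice(b1, b2) == dice(b2, b1)
            assert tanimoto_error(b1, b2) == tanimoto_error(b2, b1)
            assert asd(b1, b2) == pytest.approx(asd(b2, b1), abs=1e-12)
            d = dice(b1, b2)
            te = tanimoto_error(b1, b2)
            assert te / 100.0 == pytest.approx(1.0 - d / (2.0 - d), abs=1e-12)


class TestFusedScore:
    def test_reference_point_is_one(self):
        assert fused_score(5.6, 0.27, 15.8) == 1.0

    def test_zero_is_zero(self):
        assert fused_score(0.0, 0.0, 0.0) == 0.0

    def test_doubling_each_ratio_gives_two(self):
        assert fused_score(11.2, 0.54, 31.6) == pytest.approx(2.0)

    def test_negative_inputs_rejected(self):
        with pytest.raises(InputError):
            fused_score(-1.0, 0.1, 0.1)

    def test_refs_must_be_positive(self):
        with pytest.raises(InputError):
            MetricRefs(ref_avd=0.0)


class TestMonotoneDegradation:
    def test_eroding_one_mask_degrades_asd_and_dice(self):
        m = np.zeros((16, 16, 16), bool)
        z, y, x = np.ogrid[:16, :16, :16]
        m[((z - 8) ** 2 + (y - 8) ** 2 + (x - 8) ** 2) <= 36] = True
        ref = BinaryMask(m)
        prev_asd, prev_dice = 0.0, 1.0
        eroded = m
        for _ in range(3):
            eroded = binary_erosion(eroded)
            cur = BinaryMask(eroded)
            a = asd(ref, cur)
            d = dice(ref, cur)
            assert a >= prev_asd - 1e-12
            assert d <= prev_dice + 1e-12
            prev_asd, prev_dice = a, d


class TestReport:
    def _label_pair(self):
        gt = np.zeros((12, 12, 12), dtype=np.int16)
        gt[2:6, 2:6, 2:6] = 1
        gt[7:10, 7:10, 7:10] = 2
        pred = np.roll(gt, 1, axis=0)
        names = {1: "tissue_a", 2: "tissue_b"}
        return (LabelMap(pred, label_names=names), LabelMap(gt, label_names=names))

    def test_identical_maps_are_perfect(self):
        _, gt = self._label_pair()
        report = per_structure_report(gt, gt)
        assert np.allclose(report.table["dice"], 1.0)
        assert np.allclose(report.table[["avd", "asd", "tanimoto_error", "fused_score"]], 0.0)

    def test_shifted_map_matches_per_label_brute_force(self):
        pred, gt = self._label_pair()
        report = per_structure_report(pred, gt)
        for _, row in report.table.iterrows():
            m_ref = gt.data == row["label"]
            m_pred = pred.data == row["label"]
            assert row["dice"] == pytest.approx(
                2 * np.sum(m_ref & m_pred) / (m_ref.sum() + m_pred.sum()))
            assert row["asd"] == pytest.approx(brute_asd(m_ref, m_pred, (1, 1, 1)),
                                               abs=1e-9)

    def test_missing_structure_flagged_undefined(self):
        pred, gt = self._label_pair()
        pred.data[pred.data == 2] = 0
        report = per_structure_report(pred, gt)
        row = report.table[report.table["label"] == 2].iloc[0]
        assert not row["defined"]
        assert np.isnan(row["dice"])
        assert report.table[report.table["label"] == 1].iloc[0]["defined"]

    def test_vocabulary_mismatch_rejected(self):
        pred, gt = self._label_pair()
        bad = LabelMap(pred.data, label_names={1: "x", 2: "y"})
        with pytest.raises(InputError):
            per_structure_report(bad, gt)
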