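"""Evaluation metrics: DSC, slice partition, volumes, canal distance."""

import numpy as np
import pytest

from diskseg import (
    canal_boundary_distance,
    dsc,
    dsc_per_slice,
    partition_mid_lateral,
    variability_table,
    volume_discrepancy,
)

# (mid, lateral) slice-count pairs reported for the 27 clinical disk volumes
# across the three acquisition sequences; the ceil(0.10*n)-per-side rule must
# reproduce every one of them from n_total = mid + lateral.
PRINTED_PARTITIONS = [
    (28, 8), (30, 8), (32, 8), (40, 10), (26, 8), (33, 10), (22, 6), (23, 6), (25, 8),
    (9, 4), (9, 4), (13, 4), (12, 4), (11, 4), (14, 4), (9, 4), (8, 2), (9, 4),
    (29, 8), (28, 8), (31, 10), (36, 10), (32, 10), (32, 8), (26, 8), (28, 8), (24, 8),
]


def _set_dice_oracle(x, y):
    """Brute-force voxel counting with Python sets."""
    sx = {tuple(v) for v in np.argwhere(x)}
    sy = {tuple(v) for v in np.argwhere(y)}
    return 2.0 * len(sx & sy) / (len(sx) + len(sy))


class TestDSC:
    def test_identical_sets_score_one(self):
        m = np.zeros((6, 6, 6), dtype=bool)
        m[1:4, 1:4, 1:4] = True
        assert dsc(m, m).value == 1.0

    def test_disjoint_sets_score_zero(self):
        a = np.zeros((6, 6, 6), dtype=bool)
        b = np.zeros((6, 6, 6), dtype=bool)
        a[0:2], b[4:6] = True, True
        assert dsc(a, b).value == 0.0

    def test_worked_example_six_four_three(self):
        a = np.zeros((1, 1, 10), dtype=bool)
        b = np.zeros((1, 1, 10), dtype=bool)
        a[0, 0, 0:6] = True  # |X| = 6
        b[0, 0, 3:7] = True  # |Y| = 4, overlap 3
        res = dsc(a, b)
        assert (res.n_x, res.n_y, res.n_intersection) == (6, 4, 3)
        assert res.value == pytest.approx(0.6)

    def test_symmetry_and_oracle_on_random_masks(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a = rng.random((8, 8, 8)) > 0.6
            b = rng.random((8, 8, 8)) > 0.6
            if not (a.any() or b.any()):
                continue
            r = dsc(a, b)
            assert r.value == dsc(b, a).value
            assert abs(r.value - _set_dice_oracle(a, b)) < 1e-12

    def test_grid_mismatch_and_double_empty_rejected(self):
        with pytest.raises(ValueError):
            dsc(np.ones((3, 3, 3), dtype=bool), np.ones((3, 3, 4), dtype=bool))
        with pytest.raises(ValueError):
            dsc(np.zeros((3, 3, 3), dtype=bool), np.zeros((3, 3, 3), dtype=bool))


class TestDSCPerSlice:
    def test_identical_masks_score_one_everywhere(self):
        rng = np.random.default_rng(1)
        m = rng.random((6, 5, 5)) > 0.5
        results = dsc_per_slice(m, m)
        assert len(results) == sum(1 for i in range(6) if m[i].any())
        assert all(r.value == 1.0 for _, r in results)

    def test_disjoint_slice_ranges_all_zero(self):
        a = np.zeros((10, 4, 4), dtype=bool)
        b = np.zeros((10, 4, 4), dtype=bool)
        a[3:6] = True
        b[6:9] = True
        results = dsc_per_slice(a, b)
        assert [i for i, _ in results] == list(range(3, 9))
        assert all(r.value == 0.0 for _, r in results)

    def test_weighted_average_reproduces_global_dsc(self):
        rng = np.random.default_rng(2)
        a = rng.random((7, 6, 6)) > 0.5
        b = rng.random((7, 6, 6)) > 0.5
        results = dsc_per_slice(a, b)
        weights = np.array([r.n_x + r.n_y for _, r in results], dtype=float)
        values = np.array([r.value for _, r in results])
        pooled = (weights * values).sum() / weights.sum()
        assert pooled == pytest.approx(dsc(a, b).value, abs=1e-12)


class TestPartition:
    @pytest.mark.parametrize("mid,lateral", PRINTED_PARTITIONS)
    def test_reproduces_printed_pairs(self, mid, lateral):
        n = mid + lateral
        part = partition_mid_lateral(list(range(n)))
        assert len(part.mid_indices) == mid
        assert len(part.lateral_indices) == lateral

    def test_symmetric_split(self):
        part = partition_mid_lateral(list(range(13)))
        assert len(part.lateral_indices) == 4
        assert part.lateral_indices == (0, 1, 11, 12)
        assert part.mid_indices == tuple(range(2, 11))

    def test_union_covers_all_and_disjoint(self):
        for n in range(3, 60):
            part = partition_mid_lateral(list(range(n)))
            combined = sorted(part.mid_indices + part.lateral_indices)
            assert combined == list(range(n))

    def test_fewer_than_three_slices_rejected(self):
        with pytest.raises(ValueError):
            partition_mid_lateral([0, 1])


class TestVolumeDiscrepancy:
    def test_equal_sets_give_zero(self):
        m = np.zeros((4, 4, 4), dtype=bool)
        m[1:3] = True
        assert volume_discrepancy(m, m, (1, 1, 1)).relative == 0.0

    @pytest.mark.parametrize("n_auto,n_manual,expected", [(75, 100, -0.25), (130, 100, 0.30)])
    def test_signed_relative_difference(self, n_auto, n_manual, expected):
        a = np.zeros(200, dtype=bool)
        m = np.zeros(200, dtype=bool)
        a[:n_auto] = True
        m[:n_manual] = True
        res = volume_discrepancy(a.reshape(2, 10, 10), m.reshape(2, 10, 10), (1, 1, 1))
        assert res.relative == pytest.approx(expected)

    def test_empty_manual_rejected(self):
        with pytest.raises(ValueError):
            volume_discrepancy(
                np.ones((2, 2, 2), dtype=bool), np.zeros((2, 2, 2), dtype=bool), (1, 1, 1)
            )


class TestCanalBoundaryDistance:
    def _disk_pair(self, erode_posterior_px=0):
        # manual: a block; automatic: same block shortened on the posterior
        # (high-ap) side by erode_posterior_px rows
        manual = np.zeros((5, 40, 30), dtype=bool)
        manual[:, 10:30, 8:22] = True
        auto = manual.copy()
        if erode_posterior_px:
            auto[:, 30 - erode_posterior_px : 30, :] = False
        return auto, manual

    def test_identical_masks_give_zero(self):
        auto, manual = self._disk_pair(0)
        mean, std, n = canal_boundary_distance(auto, manual, [1, 2, 3], (1, 1, 1))
        assert mean == 0.0 and std == 0.0 and n > 0

    def test_posterior_erosion_measured_in_mm(self):
        auto, manual = self._disk_pair(2)
        mean, _, _ = canal_boundary_distance(auto, manual, [1, 2, 3], (1, 1, 1))
        assert mean == pytest.approx(2.0, abs=0.5)

    def test_distance_scales_with_spacing(self):
        auto, manual = self._disk_pair(2)
        m1, _, _ = canal_boundary_distance(auto, manual, [2], (1, 1, 1))
        m2, _, _ = canal_boundary_distance(auto, manual, [2], (1, 2, 2))
        assert m2 == pytest.approx(2 * m1)

    def test_empty_slice_list_rejected(self):
        auto, manual = self._disk_pair()
        with pytest.raises(ValueError):
            canal_boundary_distance(auto, manual, [], (1, 1, 1))


class TestVariabilityTable:
    def _mask(self, seed):
        return np.random.default_rng(seed).random((5, 5, 5)) > 0.5

    def test_identical_raters_score_one_with_zero_spread(self):
        m = {0: self._mask(1), 1: self._mask(2)}
        table = variability_table({"user1": m, "user2": m, "auto": m})
        assert len(table) == 3
        assert np.allclose(table["mean_dsc"], 1.0)
        assert np.allclose(table["std_pop"], 0.0)

    def test_hand_computed_pair_moments(self):
        # two disks with pairwise DSC 0.8 and 0.6
        a0 = np.zeros((1, 1, 10), dtype=bool); a0[0, 0, 0:5] = True
        b0 = np.zeros((1, 1, 10), dtype=bool); b0[0, 0, 1:6] = True  # dsc 0.8
        a1 = np.zeros((1, 1, 10), dtype=bool); a1[0, 0, 0:5] = True
        b1 = np.zeros((1, 1, 10), dtype=bool); b1[0, 0, 2:7] = True  # dsc 0.6
        table = variability_table({"u1": {0: a0, 1: a1}, "u2": {0: b0, 1: b1}})
        row = table.iloc[0]
        assert row["mean_dsc"] == pytest.approx(0.7)
        assert row["std_pop"] == pytest.approx(0.1)

    def test_order_of_names_does_not_change_values(self):
        m1 = {0: self._mask(3), 1: self._mask(4)}
        m2 = {0: self._mask(5), 1: self._mask(6)}
        t_ab = variability_table({"a": m1, "b": m2})
        t_ba = variability_table({"b": m2, "a": m1})
        assert t_ab["mean_dsc"].iloc[0] == pytest.approx(t_ba["mean_dsc"].iloc[0])

    def test_missing_disk_excluded_for_pair(self):
        m1 = {0: self._mask(7), 1: self._mask(8)}
        m2 = {0: self._mask(9)}
        table = variability_table({"a": m1, "b": m2})
        assert table["n_disks"].iloc[0] == 1
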