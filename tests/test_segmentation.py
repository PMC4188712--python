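"""Map segmentation tests: watershed clusters, 70% threshold semantics, COG
and overlap against brute-force oracles, bilinear barycenter weights,
COG shift and ratio arithmetic, and Wilcoxon calibration."""

from __future__ import annotations

import numpy as np
import pytest

import emgmap as eg
from emgmap.segmentation import (
    ActivityCluster,
    CoefficientMap,
    barycenter_weight,
    cog,
    cog_position_test,
    cog_shift,
    overlap,
    segment_map,
    weight_ratio,
)

GRID = eg.GridLayout()  # 14 x 8


def _gaussian_map(centers, sigmas=None, amps=None, grid=GRID):
    sigmas = sigmas or [1.0] * len(centers)
    amps = amps or [1.0] * len(centers)
    xs = np.arange(1, grid.n_cols + 1)[:, None]
    ys = np.arange(1, grid.n_rows + 1)[None, :]
    vals = np.zeros((grid.n_cols, grid.n_rows))
    for (cx, cy), s, a in zip(centers, sigmas, amps):
        vals += a * np.exp(-((xs - cx) ** 2 + (ys - cy) ** 2) / (2 * s**2))
    return CoefficientMap(values=vals, grid=grid)


def _cluster(electrodes, weights, grid=GRID):
    return ActivityCluster(electrodes=electrodes, weights=np.asarray(weights),
                           grid=grid)


class TestSegmentMap:
    def test_single_bump_single_cluster(self):
        cmap = _gaussian_map([(5.0, 4.0)])
        clusters = segment_map(cmap)
        assert len(clusters) == 1
        assert (5, 4) in clusters[0].electrode_set()

    def test_two_bumps_two_clusters(self):
        cmap = _gaussian_map([(4.0, 4.0), (10.0, 4.0)])
        clusters = segment_map(cmap)
        assert len(clusters) == 2
        sets = [c.electrode_set() for c in clusters]
        assert any((4, 4) in s for s in sets)
        assert any((10, 4) in s for s in sets)
        assert sets[0] & sets[1] == set()

    def test_seventy_percent_threshold_semantics(self):
        # uniform 100-region adjacent to 60s: only the 100-cells survive
        grid = eg.GridLayout(n_cols=6, n_rows=1)
        vals = np.array([[100.0], [100.0], [100.0], [60.0], [60.0], [60.0]])
        clusters = segment_map(CoefficientMap(values=vals, grid=grid))
        assert len(clusters) == 1
        assert clusters[0].electrode_set() == {(1, 1), (2, 1), (3, 1)}

    def test_noise_floor_regions_discarded(self):
        cmap = _gaussian_map([(4.0, 4.0), (11.0, 5.0)], amps=[1.0, 0.05])
        clusters = segment_map(cmap)
        assert len(clusters) == 1

    def test_all_zero_map_warns_empty(self):
        cmap = CoefficientMap(values=np.zeros((GRID.n_cols, GRID.n_rows)),
                              grid=GRID)
        with pytest.warns(UserWarning, match="all-zero"):
            assert segment_map(cmap) == []

    def test_clusters_disjoint_and_connected(self, rng):
        # watershed regions partition the grid: clusters never share cells
        for _ in range(10):
            vals = rng.random((GRID.n_cols, GRID.n_rows))
            clusters = segment_map(CoefficientMap(values=vals, grid=GRID))
            seen: set = set()
            for cl in clusters:
                s = cl.electrode_set()
                assert not (s & seen)
                seen |= s
                # 4-connectivity of each cluster
                if len(s) > 1:
                    from scipy.ndimage import label as nd_label

                    img = np.zeros((GRID.n_cols, GRID.n_rows), dtype=int)
                    for x, y in s:
                        img[x - 1, y - 1] = 1
                    _, n_comp = nd_label(img)
                    assert n_comp == 1

    def test_masked_cells_excluded(self):
        cmap = _gaussian_map([(5.0, 4.0)])
        cmap.mask[4, 3] = True  # mask the peak electrode
        clusters = segment_map(cmap)
        assert all((5, 4) not in c.electrode_set() for c in clusters)


class TestCog:
    def test_single_electrode(self):
        cl = _cluster([(5, 3)], [2.0])
        assert cl.cog == (5.0, 3.0)

    def test_hand_weighted_mean(self):
        cl = _cluster([(1, 1), (3, 1)], [1.0, 3.0])
        assert cl.cog == pytest.approx((2.5, 1.0))

    def test_symmetry_about_column(self):
        cl = _cluster([(6, 2), (8, 2)], [0.7, 0.7])
        assert cl.cog[0] == pytest.approx(7.0, abs=1e-12)

    def test_matches_bruteforce_oracle(self, rng):
        electrodes = [(int(x), int(y)) for x, y in
                      rng.integers(1, 9, size=(12, 2))]
        electrodes = list(dict.fromkeys(electrodes))
        weights = rng.random(len(electrodes)) + 0.01
        cl = _cluster(electrodes, weights)
        a = sum(weights)
        bx = sum(w * e[0] for w, e in zip(weights, electrodes)) / a
        by = sum(w * e[1] for w, e in zip(weights, electrodes)) / a
        assert cl.cog[0] == pytest.approx(bx, abs=1e-12)
        assert cl.cog[1] == pytest.approx(by, abs=1e-12)

    def test_zero_weight_rejected(self):
        with pytest.raises(ValueError, match="zero total weight"):
            ActivityCluster(electrodes=[(1, 1)], weights=np.array([0.0]),
                            grid=GRID)


class TestOverlap:
    def test_identical(self):
        a = _cluster([(1, 1), (2, 1)], [1, 1])
        assert overlap(a, a) == (100.0, 100.0)

    def test_disjoint(self):
        a = _cluster([(1, 1)], [1])
        b = _cluster([(5, 5)], [1])
        assert overlap(a, b) == (0.0, 0.0)

    def test_partial_arithmetic(self):
        a = _cluster([(1, 1), (2, 1), (3, 1), (4, 1)], [1] * 4)
        b = _cluster([(3, 1), (4, 1), (5, 1), (6, 1), (7, 1), (8, 1)], [1] * 6)
        sm, lg = overlap(a, b)
        assert sm == pytest.approx(50.0)
        assert lg == pytest.approx(100 * 2 / 6)

    def test_symmetric_and_ordered(self, rng):
        for _ in range(10):
            els_a = {(int(x), int(y)) for x, y in rng.integers(1, 8, (6, 2))}
            els_b = {(int(x), int(y)) for x, y in rng.integers(1, 8, (9, 2))}
            a = _cluster(sorted(els_a), np.ones(len(els_a)))
            b = _cluster(sorted(els_b), np.ones(len(els_b)))
            assert overlap(a, b) == overlap(b, a)
            sm, lg = overlap(a, b)
            assert lg <= sm <= 100.0


class TestShiftAndWeights:
    def test_zero_shift_identical(self):
        a = _cluster([(5, 3)], [1.0])
        assert cog_shift(a, a) == 0.0

    def test_x_shift_subtraction(self):
        a = _cluster([(5, 3)], [1.0])
        b = _cluster([(5, 3), (6, 3)], [0.2, 0.8])
        assert cog_shift(a, b, axis="x") == pytest.approx(0.8)
        assert cog_shift(a, b, axis="euclidean") == pytest.approx(0.8)

    def test_barycenter_on_electrode(self):
        cmap = _gaussian_map([(5.0, 4.0)])
        assert barycenter_weight(cmap, (5.0, 4.0)) == pytest.approx(
            cmap.values[4, 3]
        )

    def test_barycenter_midway_bilinear(self):
        grid = eg.GridLayout(n_cols=3, n_rows=2)
        vals = np.array([[40.0, 40.0], [60.0, 60.0], [60.0, 60.0]])
        cmap = CoefficientMap(values=vals, grid=grid)
        assert barycenter_weight(cmap, (1.5, 1.0)) == pytest.approx(50.0)

    def test_barycenter_constant_map(self):
        grid = eg.GridLayout(n_cols=4, n_rows=4)
        cmap = CoefficientMap(values=np.full((4, 4), 7.0), grid=grid)
        for xy in [(1.0, 1.0), (2.3, 3.7), (4.0, 4.0)]:
            assert barycenter_weight(cmap, xy) == pytest.approx(7.0)

    def test_barycenter_outside_grid_rejected(self):
        cmap = _gaussian_map([(5.0, 4.0)])
        with pytest.raises(ValueError, match="outside"):
            barycenter_weight(cmap, (0.5, 4.0))

    def test_weight_ratio_identity_and_guard(self):
        cmap = _gaussian_map([(5.0, 4.0)])
        assert weight_ratio(cmap, (5.0, 4.0), cmap, (5.0, 4.0)) == pytest.approx(1.0)
        zero = CoefficientMap(values=np.zeros((GRID.n_cols, GRID.n_rows)),
                              grid=GRID)
        with pytest.raises(ValueError, match="ratio"):
            weight_ratio(cmap, (5.0, 4.0), zero, (5.0, 4.0))


class TestCogPositionTest:
    def test_all_zero_diffs_p1(self):
        c = np.column_stack([np.arange(8.0), np.ones(8)])
        with pytest.warns(UserWarning, match="zero"):
            assert cog_position_test(c, c) == 1.0

    def test_eight_unit_shifts_exact_p(self):
        c1 = np.column_stack([np.arange(8.0), np.ones(8)])
        c2 = c1.copy()
        c2[:, 0] += 1.0
        # all 8 signed ranks positive: two-sided exact p = 2/2^8
        assert cog_position_test(c2, c1, axis="x") == pytest.approx(2 / 256)

    def test_type_i_error_calibrated(self):
        rng = np.random.default_rng(7)
        n_sim, alpha = 2000, 0.05
        rejections = 0
        for _ in range(n_sim):
            d = rng.standard_normal(10)
            c1 = np.column_stack([d, np.zeros(10)])
            c2 = np.zeros_like(c1)
            if cog_position_test(c1, c2, axis="x") < alpha:
                rejections += 1
        assert rejections / n_sim == pytest.approx(alpha, abs=0.02)

    def test_too_few_pairs_rejected(self):
        c = np.zeros((3, 2))
        with pytest.raises(ValueError):
            cog_position_test(c, c)
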