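"""Discretization, texture matrices and the 75-feature set.

Matrix builders are checked against the spec'd hand-worked examples and
against the independent brute-force oracle in ``oracle.py``.
"""

from __future__ import annotations

import numpy as np
import pytest

import oracle
from hetrad.texture import (
    FAMILY_SIZES,
    FEATURE_NAMES,
    ExtractionConfig,
    FeatureVector,
    compute_features,
    discretize,
)
from hetrad.texture import _features as F
from hetrad.texture import _matrices as M


def region_from_grid(make_region, grid, spread=25.0):
    """Lesion region whose discretized levels reproduce ``grid`` (0 = outside)."""
    grid = np.asarray(grid)
    coords = np.argwhere(grid > 0)
    intensities = (grid[tuple(coords.T)] - 1) * spread
    from hetrad.io import LesionRegion

    return LesionRegion(1, "p", intensities.astype(float), coords, 0.735)


class TestDiscretize:
    def test_edge_semantics_half_open_bins(self, make_region):
        d = discretize(make_region([0, 10, 24, 25]), bin_width=25)
        assert d.gray_levels.tolist() == [1, 1, 1, 2]
        assert d.n_levels == 2

    def test_constant_region_single_level(self, make_region):
        d = discretize(make_region([42.0, 42.0, 42.0]), bin_width=25)
        assert d.n_levels == 1 and set(d.gray_levels) == {1}

    def test_negative_minimum(self, make_region):
        d = discretize(make_region([-10.0, 40.0]), bin_width=25)
        assert d.gray_levels.tolist() == [1, 3]
        assert d.n_levels == 3
        assert d.bin_edges(1) == (-10.0, 15.0)

    def test_invalid_bin_width(self, make_region):
        with pytest.raises(ValueError):
            discretize(make_region([1.0, 2.0]), bin_width=0)


class TestGLCM:
    def test_two_by_two_inplane_example(self):
        grid = np.array([[1, 1], [1, 2]]).reshape(2, 2, 1)
        P = M.glcm_per_angle(grid, 2)
        a = M.DIRECTIONS_13.index((0, 1, 0))
        np.testing.assert_allclose(P[a], [[0.5, 0.25], [0.25, 0.0]])

    def test_constant_region_single_entry(self):
        grid = np.ones((3, 3, 3), dtype=int)
        P = M.glcm_per_angle(grid, 1)
        for a in range(13):
            np.testing.assert_allclose(P[a], [[1.0]])
        feats = F.glcm_features(P, 1)
        assert feats["JointEntropy"] == 0.0
        assert feats["Correlation"] == 1.0

    def test_symmetric_and_normalized(self):
        rng = np.random.default_rng(2)
        grid = rng.integers(0, 4, (5, 5, 4))
        ng = 3
        P = M.glcm_per_angle(grid, ng)
        for a in range(13):
            if P[a].sum() == 0:
                continue
            np.testing.assert_allclose(P[a], P[a].T, atol=1e-15)
            assert abs(P[a].sum() - 1.0) < 1e-12

    def test_gray_level_permutation_leaves_entropy(self):
        rng = np.random.default_rng(3)
        grid = rng.integers(1, 4, (4, 4, 4))
        perm = np.array([0, 3, 1, 2])  # permutation of levels 1..3
        permuted = perm[grid]
        e1 = F.glcm_features(M.glcm_per_angle(grid, 3), 3)["JointEntropy"]
        e2 = F.glcm_features(M.glcm_per_angle(permuted, 3), 3)["JointEntropy"]
        assert e1 == pytest.approx(e2, rel=1e-12)


class TestGLRLM:
    def test_run_enumeration_example(self):
        grid = np.array([1, 1, 2, 2]).reshape(1, 4, 1)
        R = M.glrlm_per_angle(grid, 2)
        a = M.DIRECTIONS_13.index((0, 1, 0))
        expected = np.zeros((2, 4))
        expected[0, 1] = 1  # level 1, run length 2
        expected[1, 1] = 1  # level 2, run length 2
        np.testing.assert_array_equal(R[a], expected)

    def test_constant_line_run_percentage(self):
        grid = np.ones((1, 5, 1), dtype=int)
        R = M.glrlm_per_angle(grid, 1)
        a = M.DIRECTIONS_13.index((0, 1, 0))
        assert R[a, 0, 4] == 1  # single run of length 5
        # along the line direction RP = 1 run / 5 voxels
        n_runs = R[a].sum()
        n_vox = (R[a] * np.arange(1, 6)).sum()
        assert n_runs / n_vox == pytest.approx(1 / 5)

    def test_alternating_levels_fragment_completely(self):
        grid = np.array([1, 2, 1, 2]).reshape(1, 4, 1)
        R = M.glrlm_per_angle(grid, 2)
        a = M.DIRECTIONS_13.index((0, 1, 0))
        assert R[a].sum() == 4 and R[a][:, 0].sum() == 4  # four runs of length 1
        assert R[a].sum() / 4 == pytest.approx(1.0)  # run percentage 1


class TestGLSZM:
    def test_diagonal_pair_is_one_zone(self):
        grid = np.zeros((2, 2, 2), dtype=int)
        grid[0, 0, 0] = grid[1, 1, 1] = 1
        Z = M.glszm(grid, 1)
        assert Z[0, 1] == 1 and Z.sum() == 1

    def test_constant_region_single_zone(self):
        grid = np.ones((3, 3, 2), dtype=int)
        Z = M.glszm(grid, 1)
        assert Z[0, 17] == 1 and Z.sum() == 1

    def test_checkerboard_two_zones_of_two(self):
        grid = np.array([[1, 2], [2, 1]]).reshape(2, 2, 1)
        Z = M.glszm(grid, 2)
        assert Z[0, 1] == 1 and Z[1, 1] == 1 and Z.sum() == 2


class TestGLDM:
    def test_isolated_voxel(self):
        grid = np.zeros((3, 3, 3), dtype=int)
        grid[1, 1, 1] = 2
        D = M.gldm(grid, 2)
        assert D[1, 0] == 1 and D.sum() == 1  # dependence 0 -> column 1

    def test_plane_center_dependence_eight(self):
        grid = np.ones((3, 3, 1), dtype=int)
        D = M.gldm(grid, 1)
        assert D[0, 8] == 1  # centre voxel: all 8 in-plane neighbours dependent

    def test_large_alpha_counts_all_neighbours(self):
        rng = np.random.default_rng(4)
        grid = rng.integers(1, 4, (4, 4, 2))
        D = M.gldm(grid, 3, alpha=3)
        # with all differences allowed, dependence == in-mask neighbour count
        nb = M._neighbour_stacks(grid)
        counts = (nb > 0).sum(axis=0)
        expected = np.bincount(counts.ravel(), minlength=D.shape[1])
        np.testing.assert_array_equal(D.sum(axis=0), expected[: D.shape[1]])


class TestNGTDM:
    def test_line_neighbour_means(self):
        # ends see only the centre (mean 2): |1 - 2| = 1 each; the centre
        # sees both ends (mean 1): |2 - 1| = 1
        grid = np.array([1, 2, 1]).reshape(1, 3, 1)
        n, p, s = M.ngtdm(grid, 2)
        np.testing.assert_allclose(n, [2, 1])
        np.testing.assert_allclose(s, [2.0, 1.0])

    def test_constant_region_flat(self):
        grid = np.ones((3, 3, 3), dtype=int)
        n, p, s = M.ngtdm(grid, 1)
        assert s.sum() == 0.0
        feats = F.ngtdm_features(n, p, s)
        assert feats["Coarseness"] == F.COARSENESS_CAP
        assert feats["Contrast"] == 0.0


class TestMassConservation:
    @pytest.mark.parametrize("seed", range(5))
    def test_counts_cover_all_voxels(self, seed):
        rng = np.random.default_rng(seed)
        grid = rng.integers(0, 5, (6, 5, 4))
        ng = 4
        n_vox = (grid > 0).sum()
        if n_vox == 0:
            return
        R = M.glrlm_per_angle(grid, ng)
        for a in range(13):
            assert (R[a] * np.arange(1, R.shape[2] + 1)).sum() == n_vox
        Z = M.glszm(grid, ng)
        assert (Z * np.arange(1, Z.shape[1] + 1)).sum() == n_vox
        assert M.gldm(grid, ng).sum() == n_vox


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(40))
    def test_all_matrices_match_brute_force(self, seed):
        rng = np.random.default_rng(seed + 1000)
        shape = tuple(rng.integers(1, 4, 3))
        ng = int(rng.integers(1, 4))
        grid = rng.integers(0, ng + 1, shape)
        if (grid > 0).sum() == 0:
            return
        P = M.glcm_per_angle(grid, ng)
        R = M.glrlm_per_angle(grid, ng)
        for a, d in enumerate(M.DIRECTIONS_13):
            np.testing.assert_allclose(P[a], oracle.naive_glcm(grid, ng, d), atol=1e-14)
            np.testing.assert_array_equal(R[a], oracle.naive_glrlm(grid, ng, d))
        np.testing.assert_array_equal(M.glszm(grid, ng), oracle.naive_glszm(grid, ng))
        D1, D2 = M.gldm(grid, ng), oracle.naive_gldm(grid, ng)
        nc = max(D1.shape[1], D2.shape[1])
        np.testing.assert_array_equal(np.pad(D1, ((0, 0), (0, nc - D1.shape[1]))),
                                      np.pad(D2, ((0, 0), (0, nc - D2.shape[1]))))
        for x, y in zip(M.ngtdm(grid, ng), oracle.naive_ngtdm(grid, ng)):
            np.testing.assert_allclose(x, y, atol=1e-12)


class TestComputeFeatures:
    def test_exactly_75_finite_values_with_family_counts(self, random_region):
        fv = compute_features(random_region)
        assert tuple(fv) == FEATURE_NAMES
        assert all(np.isfinite(v) for v in fv.values.values())
        for family, size in FAMILY_SIZES.items():
            assert sum(1 for k in fv if f"_{family}_" in k) == size

    def test_constant_region_zero_information(self, make_region):
        fv = compute_features(make_region([80.0] * 27, shape=(3, 3, 3)))
        assert fv["original_glcm_JointEntropy"] == 0.0
        assert fv["original_ngtdm_Contrast"] == 0.0
        assert fv["original_glszm_ZoneEntropy"] == 0.0
        assert fv["original_glcm_Correlation"] == 1.0
        assert fv["original_ngtdm_Coarseness"] == F.COARSENESS_CAP

    def test_intensity_shift_invariance(self, make_region):
        rng = np.random.default_rng(11)
        base = rng.integers(0, 120, size=64).astype(float)
        r1 = make_region(base, shape=(4, 4, 4))
        r2 = make_region(base + 3 * 25.0, shape=(4, 4, 4))
        fv1, fv2 = compute_features(r1), compute_features(r2)
        for k in fv1:
            assert fv1[k] == pytest.approx(fv2[k], rel=1e-12), k

    def test_axis_permutation_invariance_cubic_lesion(self, make_region):
        rng = np.random.default_rng(12)
        cube = rng.normal(90, 30, (5, 5, 5))
        fv1 = compute_features(make_region(cube.ravel(), shape=(5, 5, 5)))
        fv2 = compute_features(make_region(cube.transpose(2, 0, 1).ravel(), shape=(5, 5, 5)))
        for k in fv1:
            assert fv1[k] == pytest.approx(fv2[k], rel=1e-9, abs=1e-12), k

    def test_single_voxel_never_nan(self, make_region):
        fv = compute_features(make_region([77.0]))
        assert all(np.isfinite(v) for v in fv.values.values())

    def test_conformance_with_brute_force_on_random_lesions(self, make_region):
        rng = np.random.default_rng(13)
        for _ in range(3):
            shape = tuple(rng.integers(3, 6, 3))
            vals = rng.normal(90, 35, int(np.prod(shape)))
            region = make_region(vals, shape=shape)
            fv = compute_features(region)
            ref = oracle.naive_compute_features(region)
            for k in FEATURE_NAMES:
                assert fv[k] == pytest.approx(ref[k], rel=1e-9, abs=1e-12), k

    def test_feature_vector_validation(self):
        with pytest.raises(ValueError, match="canonical"):
            FeatureVector({"original_glcm_Contrast": 1.0})
        bad = dict.fromkeys(FEATURE_NAMES, 1.0)
        bad[FEATURE_NAMES[0]] = float("nan")
        with pytest.raises(ValueError, match="non-finite"):
            FeatureVector(bad)


class TestExtractionConfig:
    def test_file_roundtrip(self, tmp_path):
        cfg = ExtractionConfig(bin_width=10.0, distance=2, gldm_alpha=1.0)
        path = tmp_path / "cfg.txt"
        cfg.to_file(path)
        assert ExtractionConfig.from_file(path) == cfg

    def test_invalid_settings(self):
        with pytest.raises(ValueError):
            ExtractionConfig(bin_width=0)
        with pytest.raises(ValueError):
            ExtractionConfig(distance=0)
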