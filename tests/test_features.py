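"""Discretization and texture-feature examples, hand-derived values and
invariants.  Exhaustive oracle equivalence over random ROIs lives in
test_acceptance.py; here each family is pinned to small configurations
whose matrices can be enumerated by hand."""

import numpy as np
import pytest

from phantomrad import ExtractionParams, FEATURE_NAMES, extract_all
from phantomrad.phantom import ActivityVolume, ROIMask
from phantomrad.features import (DegenerateROIError, discretize_fbn,
                                 glcm_features, glcm_matrix, gldzm_features,
                                 gldzm_matrix, glrlm_features, glrlm_matrix,
                                 glszm_features, glszm_matrix, ngtdm_features,
                                 ngtdm_table)

AXIAL = ((0, 0, 1),)


class TestDiscretizeFBN:
    def test_two_point_range_split(self):
        data = np.array([5.0, 80.0]).reshape(1, 1, 2)
        mask = np.ones_like(data, dtype=bool)
        d = discretize_fbn(data, mask, ng=2)
        assert set(d.levels[mask]) == {1, 2}

    def test_constant_roi_flags_degenerate(self):
        data = np.full((1, 1, 4), 7.0)
        mask = np.ones_like(data, dtype=bool)
        d = discretize_fbn(data, mask, ng=8)
        assert d.degenerate
        assert np.all(d.levels[mask] == 1)

    def test_binning_formula_direct_evaluation(self):
        data = np.array([0.0, 1.0, 2.0, 3.0]).reshape(1, 1, 4)
        mask = np.ones_like(data, dtype=bool)
        d = discretize_fbn(data, mask, ng=4)
        assert list(d.levels[0, 0]) == [1, 2, 3, 4]

    def test_rejects_empty_mask_and_small_ng(self):
        data = np.zeros((2, 2, 2))
        with pytest.raises(ValueError):
            discretize_fbn(data, np.zeros_like(data, dtype=bool), 4)
        with pytest.raises(ValueError):
            discretize_fbn(data, np.ones_like(data, dtype=bool), 1)


class TestGLCM:
    def test_line_example_hand_enumerated(self, make_droi):
        """[1,1,2,2] along one axis: 6 symmetric pairs at distance 1."""
        d = make_droi([1, 1, 2, 2], ng=2)
        f = glcm_features(d, distance=1, directions=AXIAL)
        assert f["joint_maximum"] == pytest.approx(1 / 3)
        assert f["difference_average"] == pytest.approx(1 / 3)
        assert f["dissimilarity"] == pytest.approx(1 / 3)

    def test_constant_roi_single_cell_matrix(self, make_droi):
        d = make_droi([1, 1, 1, 1], ng=1)
        f = glcm_features(d, directions=AXIAL)
        assert f["joint_maximum"] == 1.0
        assert f["difference_average"] == 0.0
        assert f["contrast"] == 0.0

    def test_matrix_symmetric_and_normalized(self, make_droi):
        rng = np.random.default_rng(5)
        d = make_droi(rng.integers(1, 5, size=(4, 5, 3)), ng=4)
        m = glcm_matrix(d)
        np.testing.assert_allclose(m, m.T)
        assert (m / m.sum()).sum() == pytest.approx(1.0, abs=1e-9)

    def test_isolated_voxels_raise_degenerate(self, make_droi):
        lv = np.zeros((5, 5, 5), dtype=int)
        lv[0, 0, 0] = 1
        lv[4, 4, 0] = 2
        with pytest.raises(DegenerateROIError):
            glcm_matrix(make_droi(lv, ng=2))

    def test_rotation_invariance_of_merged_matrix(self, make_droi):
        rng = np.random.default_rng(17)
        lv = rng.integers(0, 5, size=(5, 5, 5))
        f0 = glcm_features(make_droi(lv, ng=4))
        f1 = glcm_features(make_droi(np.rot90(lv, axes=(0, 1)), ng=4))
        for k in f0:
            assert f0[k] == pytest.approx(f1[k], abs=1e-9), k


class TestGLRLM:
    def test_line_example_two_runs_of_two(self, make_droi):
        d = make_droi([1, 1, 2, 2], ng=2)
        f = glrlm_features(d, directions=AXIAL)
        assert f["short_runs_emphasis"] == pytest.approx(0.25)
        assert f["long_runs_emphasis"] == pytest.approx(4.0)
        assert f["run_percentage"] == pytest.approx(0.5)

    def test_constant_line_single_run(self, make_droi):
        d = make_droi([1, 1, 1, 1], ng=1)
        m = glrlm_matrix(d, directions=AXIAL)
        assert m.sum() == 1
        assert m[0, 3] == 1
        f = glrlm_features(d, directions=AXIAL)
        assert f["grey_level_non_uniformity_normalised"] == pytest.approx(1.0)

    def test_voxel_coverage_conservation(self, make_droi):
        rng = np.random.default_rng(3)
        lv = rng.integers(0, 4, size=(6, 4, 5))
        if (lv > 0).sum() < 2:
            lv[0, 0, :2] = 1
        d = make_droi(lv, ng=3)
        m = glrlm_matrix(d)
        lengths = np.arange(1, m.shape[1] + 1)
        assert (m.sum(axis=0) * lengths).sum() == (lv > 0).sum() * 13

    def test_rotation_invariance_of_merged_matrix(self, make_droi):
        rng = np.random.default_rng(23)
        lv = rng.integers(0, 4, size=(5, 5, 5))
        f0 = glrlm_features(make_droi(lv, ng=3))
        f1 = glrlm_features(make_droi(np.rot90(lv, axes=(1, 2)), ng=3))
        for k in f0:
            assert f0[k] == pytest.approx(f1[k], abs=1e-9), k


class TestGLSZM:
    def test_patch_example_two_zones(self, make_droi):
        d = make_droi([[1, 1], [2, 2]], ng=2)
        f = glszm_features(d)
        assert f["small_zone_emphasis"] == pytest.approx(0.25)
        assert f["zone_percentage"] == pytest.approx(0.5)

    def test_constant_roi_single_zone(self, make_droi):
        d = make_droi(np.ones((2, 3, 2), dtype=int), ng=1)
        f = glszm_features(d)
        assert f["zone_percentage"] == pytest.approx(1 / 12)

    def test_partition_conservation(self, make_droi):
        rng = np.random.default_rng(9)
        lv = rng.integers(0, 4, size=(5, 4, 6))
        d = make_droi(lv, ng=3)
        m = glszm_matrix(d)
        sizes = np.arange(1, m.shape[1] + 1)
        assert (m.sum(axis=0) * sizes).sum() == (lv > 0).sum()


class TestGLDZM:
    def test_single_voxel_zone_on_border(self, make_droi):
        lv = np.zeros((3, 3, 3), dtype=int)
        lv[1, 1, 1] = 1
        lv[1, 1, 0] = 1  # ROIMask-style contract needs >= 2 voxels
        d = make_droi(lv, ng=2)
        f = gldzm_features(d)
        assert f["small_distance_emphasis"] == pytest.approx(1.0)

    def test_cube_single_zone_distance_one(self, make_droi):
        d = make_droi(np.ones((3, 3, 3), dtype=int), ng=1)
        m = gldzm_matrix(d)
        assert m.shape[1] == 1 and m[0, 0] == 1  # zone touches the border

    def test_zone_counts_match_size_zone_matrix(self, make_droi):
        rng = np.random.default_rng(31)
        lv = rng.integers(0, 4, size=(5, 5, 4))
        d = make_droi(lv, ng=3)
        assert gldzm_matrix(d).sum() == glszm_matrix(d).sum()


class TestNGTDM:
    def test_line_example_hand_enumerated(self, make_droi):
        d = make_droi([1, 2, 1], ng=2)
        n_g, s_g, total = ngtdm_table(d)
        assert s_g[0] == pytest.approx(2.0)
        assert s_g[1] == pytest.approx(1.0)
        assert total == 3

    def test_constant_roi_conventions(self, make_droi):
        d = make_droi(np.ones((3, 3, 3), dtype=int), ng=2)
        f = ngtdm_features(d)
        assert f["contrast"] == 0.0
        assert f["busyness"] == 0.0
        assert f["complexity"] == 0.0
        assert f["strength"] == 0.0
        assert f["coarseness"] == 1e6

    def test_occurrence_distribution_normalized(self, make_droi):
        rng = np.random.default_rng(13)
        lv = rng.integers(0, 5, size=(4, 4, 4))
        d = make_droi(lv, ng=4)
        n_g, _, total = ngtdm_table(d)
        assert n_g.sum() == total


class TestExtractAll:
    def _phantom_roi(self, rng):
        data = rng.uniform(4.0, 80.0, size=(8, 8, 8))
        mask = np.zeros_like(data, dtype=bool)
        mask[1:7, 1:7, 1:7] = True
        vol = ActivityVolume(data, spacing=2.0)
        return vol, ROIMask(mask, spacing=2.0)

    def test_returns_78_features_in_canonical_order(self):
        vol, mask = self._phantom_roi(np.random.default_rng(0))
        feats = extract_all(vol, mask, ExtractionParams(ng=8))
        assert list(feats) == list(FEATURE_NAMES)
        assert all(np.isfinite(v) for v in feats.values())

    def test_deterministic(self):
        vol, mask = self._phantom_roi(np.random.default_rng(1))
        p = ExtractionParams(ng=8)
        assert extract_all(vol, mask, p) == extract_all(vol, mask, p)

    def test_affine_intensity_invariance(self):
        """Fixed-bin-number discretization cancels a·x+b rescaling."""
        vol, mask = self._phantom_roi(np.random.default_rng(2))
        p = ExtractionParams(ng=8)
        f0 = extract_all(vol, mask, p)
        rescaled = ActivityVolume(2.5 * vol.data + 10.0, vol.spacing)
        f1 = extract_all(rescaled, mask, p)
        for k in f0:
            assert f0[k] == pytest.approx(f1[k], abs=1e-9), k

    def test_mismatched_grids_rejected(self):
        vol, mask = self._phantom_roi(np.random.default_rng(3))
        bad = ROIMask(np.ones((4, 4, 4), dtype=bool), spacing=2.0)
        with pytest.raises(ValueError):
            extract_all(vol, bad)

    def test_resampling_path_preserves_catalogue(self):
        rng = np.random.default_rng(4)
        data = rng.uniform(4.0, 80.0, size=(10, 10, 10))
        mask = np.zeros_like(data, dtype=bool)
        mask[2:8, 2:8, 2:8] = True
        vol = ActivityVolume(data, spacing=3.0)
        feats = extract_all(vol, ROIMask(mask, spacing=3.0),
                            ExtractionParams(ng=8, spacing=2.0))
        assert list(feats) == list(FEATURE_NAMES)
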