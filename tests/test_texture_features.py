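"""Texture-matrix families against hand examples and brute-force oracles."""

import numpy as np
import pytest

from radiomap.features import (
    build_gldm,
    build_glszm,
    build_ngtdm,
    discretize_array,
    glcm_features,
    gldm_features,
    glrlm_features,
    glszm_features,
    ngtdm_features,
)
from radiomap.features.glcm import build_glcm
from radiomap.features.glrlm import _runs_one_direction
from radiomap.features.ngtdm import COARSENESS_CAP

from oracles import (
    glcm_features_oracle,
    gldm_features_oracle,
    glrlm_features_oracle,
    glszm_features_oracle,
    ngtdm_features_oracle,
)


def droi_from_levels(levels):
    levels = np.asarray(levels, dtype=float)
    return discretize_array(levels, levels > 0, 1.0)


ORACLES = {
    "glcm": (glcm_features, glcm_features_oracle),
    "glrlm": (glrlm_features, glrlm_features_oracle),
    "glszm": (glszm_features, glszm_features_oracle),
    "gldm": (gldm_features, gldm_features_oracle),
    "ngtdm": (ngtdm_features, ngtdm_features_oracle),
}


@pytest.mark.parametrize("family", sorted(ORACLES))
def test_matrix_features_match_bruteforce_oracle(family, random_droi_factory):
    impl, oracle = ORACLES[family]
    for _ in range(10):
        droi = random_droi_factory(shape=(5, 5, 5), n_raw_levels=5)
        got = impl(droi)
        want = oracle(droi.levels, droi.n_levels)
        for name, val in want.items():
            assert got[name] == pytest.approx(val, rel=1e-10, abs=1e-12), name


@pytest.mark.parametrize("family", sorted(ORACLES))
def test_oracle_agreement_on_irregular_masks(family, rng):
    """ROIs with holes exercise edge handling of every matrix builder."""
    impl, oracle = ORACLES[family]
    for _ in range(5):
        vals = rng.integers(0, 4, (4, 5, 3)).astype(float)
        mask = rng.random((4, 5, 3)) > 0.3
        mask.flat[0] = True  # never empty
        droi = discretize_array(vals, mask, 1.0)
        got = impl(droi)
        want = oracle(droi.levels, droi.n_levels)
        for name, val in want.items():
            assert got[name] == pytest.approx(val, rel=1e-10, abs=1e-12), name


class TestGlcm:
    def test_constant_roi_single_level(self):
        droi = droi_from_levels(np.ones((3, 3, 3)))
        f = glcm_features(droi)
        assert f["glcm_JointEntropy"] == 0
        assert f["glcm_Contrast"] == 0
        assert f["glcm_Id"] == 1
        assert f["glcm_MaximumProbability"] == 1
        assert f["glcm_Correlation"] == 1  # degenerate rule

    def test_two_row_example_symmetrized_counts(self):
        # levels [[1,1],[2,2]]: along the second axis the symmetrized
        # counts are {(1,1): 2, (2,2): 2} -> P(1,1) = P(2,2) = 0.5, contrast 0
        droi = droi_from_levels(np.array([[1, 1], [2, 2]]).reshape(2, 2, 1))
        stack = build_glcm(droi).entries
        along_y = None
        for mat in stack:
            if mat[0, 0] == 2 and mat[1, 1] == 2 and mat.sum() == 4:
                along_y = mat
        assert along_y is not None
        P = along_y / along_y.sum()
        assert P[0, 0] == 0.5 and P[1, 1] == 0.5
        assert (P * np.array([[0, 1], [1, 0]])).sum() == 0  # zero contrast

    def test_normalized_matrices_sum_to_one(self, random_droi_factory):
        droi = random_droi_factory()
        P = build_glcm(droi).normalize().entries
        np.testing.assert_allclose(P.sum(axis=(1, 2)), 1.0, atol=1e-12)
        assert (P >= 0).all() and (P <= 1).all()

    def test_symmetry(self, random_droi_factory):
        droi = random_droi_factory()
        M = build_glcm(droi).entries
        np.testing.assert_array_equal(M, np.transpose(M, (0, 2, 1)))


class TestGlrlm:
    def test_run_enumeration_1d(self):
        droi = droi_from_levels(np.array([1, 1, 1, 2]).reshape(1, 4, 1))
        runs = _runs_one_direction(droi.levels, droi.n_levels, (0, 1, 0))
        # (level 1, length 3) x1 and (level 2, length 1) x1
        assert runs[0, 2] == 1 and runs[1, 0] == 1
        assert runs.sum() == 2

    def test_constant_line_is_single_run(self):
        droi = droi_from_levels(np.ones((1, 6, 1)))
        runs = _runs_one_direction(droi.levels, 1, (0, 1, 0))
        assert runs.shape == (1, 6)
        assert runs[0, 5] == 1 and runs.sum() == 1


class TestGlszm:
    def test_zone_enumeration_example(self):
        droi = droi_from_levels(np.array([[1, 1], [1, 2]]).reshape(2, 2, 1))
        S = build_glszm(droi).entries
        assert S[0, 2] == 1  # level 1, size 3
        assert S[1, 0] == 1  # level 2, size 1
        assert S.sum() == 2

    def test_constant_roi_single_zone_zero_entropy(self):
        droi = droi_from_levels(np.ones((3, 4, 2)))
        f = glszm_features(droi)
        assert f["glszm_ZonePercentage"] == pytest.approx(1 / 24)
        assert f["glszm_ZoneEntropy"] == 0


class TestGldm:
    def test_constant_cube_neighbour_counts(self):
        droi = droi_from_levels(np.ones((3, 3, 3)))
        D = build_gldm(droi, alpha=0).entries
        # dependences: centre 26, corners 7 (stored at column = dependence)
        assert D[0, 26] == 1
        assert D[0, 7] == 8

    def test_single_voxel_has_zero_dependence(self):
        droi = droi_from_levels(np.ones((1, 1, 1)))
        D = build_gldm(droi).entries
        assert D.shape == (1, 1) and D[0, 0] == 1


class TestNgtdm:
    def test_constant_roi_degenerate_values(self):
        droi = droi_from_levels(np.ones((3, 3, 3)))
        f = ngtdm_features(droi)
        assert f["ngtdm_Coarseness"] == COARSENESS_CAP
        assert f["ngtdm_Complexity"] == 0
        assert f["ngtdm_Contrast"] == 0

    def test_hand_enumerable_s_values(self):
        # line (1,2,1): each end sees one neighbour, the middle sees two
        droi = droi_from_levels(np.array([1, 2, 1]).reshape(1, 3, 1))
        M = build_ngtdm(droi).entries
        n_i, s_i = M[:, 0], M[:, 1]
        assert n_i.tolist() == [2, 1]
        # each end voxel: sole neighbour has level 2 -> |1-2| = 1, so s_1 = 2;
        # middle voxel: neighbours (1,1) -> |2-1| = 1, so s_2 = 1
        assert s_i == pytest.approx([2.0, 1.0])


class TestLevelShiftInvariance:
    """Adding k*bin_width shifts levels uniformly: difference-type features
    are unchanged, level-magnitude features move."""

    def test_both_directions(self, rng):
        vals = rng.normal(300, 30, (5, 5, 3))
        mask = np.ones((5, 5, 3), bool)
        a = discretize_array(vals, mask, 25.0)
        b = discretize_array(vals + 3 * 25.0, mask, 25.0)
        fa, fb = glcm_features(a), glcm_features(b)
        for name in ("glcm_Contrast", "glcm_Id", "glcm_Idm", "glcm_InverseVariance",
                     "glcm_DifferenceEntropy"):
            assert fa[name] == pytest.approx(fb[name], rel=1e-12), name
        # level arrays are identical (min-anchored binning), so magnitude
        # features agree too; a genuine level shift must change them
        shifted = discretize_array(vals, mask, 25.0)
        shifted.levels[shifted.mask] += 2
        shifted.n_levels += 2
        fs = glcm_features(shifted)
        assert fs["glcm_Autocorrelation"] != pytest.approx(fa["glcm_Autocorrelation"])
        assert fs["glcm_Contrast"] == pytest.approx(fa["glcm_Contrast"], rel=1e-12)
        ga, gs = gldm_features(a), gldm_features(shifted)
        assert gs["gldm_HighGrayLevelEmphasis"] != pytest.approx(ga["gldm_HighGrayLevelEmphasis"])
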