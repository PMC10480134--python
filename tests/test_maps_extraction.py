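"""Block grids, parametric maps and the two extraction routes."""

import numpy as np
import pytest

from radiomap.extraction import MapCoverageError, conventional_extract, map_extract, map_support
from radiomap.features import FEATURE_NAMES, ExtractionSettings
from radiomap.geometry import ImageVolume, SphereVOI, VolumeGeometry
from radiomap.maps import compute_maps, plan_grid
from radiomap.voi import rasterize_sphere


def make_volume(values, spacing=(1.0, 1.0, 1.0)):
    values = np.asarray(values, dtype=float)
    return ImageVolume(values, VolumeGeometry(spacing=spacing, shape=values.shape))


class TestPlanGrid:
    def test_round_rule_on_scanner_geometry(self):
        geom = VolumeGeometry(spacing=(1.125, 1.125, 5.5), shape=(48, 48, 10))
        grid = plan_grid(geom, (5.0, 5.0, 5.5))
        assert grid.block_voxels == (4, 4, 1)  # round(5 / 1.125) = 4
        assert grid.n_blocks == (12, 12, 10)

    def test_exact_divisibility(self):
        geom = VolumeGeometry(spacing=(1, 1, 1), shape=(25, 25, 25))
        grid = plan_grid(geom, 5.0)
        assert grid.block_voxels == (5, 5, 5)
        assert grid.n_blocks == (5, 5, 5)
        assert grid.has_partial == (False, False, False)

    def test_partial_trailing_block_flagged(self):
        geom = VolumeGeometry(spacing=(1, 1, 1), shape=(23, 10, 10))
        grid = plan_grid(geom, (5.0, 5.0, 5.0))
        assert grid.n_blocks[0] == 4
        assert grid.has_partial[0] is True

    def test_block_smaller_than_voxel_rejected(self):
        geom = VolumeGeometry(spacing=(5, 5, 5), shape=(10, 10, 10))
        with pytest.raises(ValueError, match="smaller than one source voxel"):
            plan_grid(geom, 2.0)

    def test_map_geometry_spacing_is_block_extent(self):
        geom = VolumeGeometry(spacing=(1.125, 1.125, 5.5), shape=(48, 48, 10))
        grid = plan_grid(geom, (5.0, 5.0, 5.5))
        assert grid.map_geometry.spacing == pytest.approx((4.5, 4.5, 5.5))


class TestComputeMaps:
    def test_constant_volume_gives_constant_maps(self):
        vol = make_volume(np.full((10, 10, 5), 42.0))
        stack = compute_maps(vol, plan_grid(vol.geometry, 5.0),
                             features=("firstorder_Mean", "glcm_Id"))
        np.testing.assert_allclose(stack["firstorder_Mean"].values, 42.0)
        np.testing.assert_allclose(stack["glcm_Id"].values, 1.0)

    def test_identity_limit_single_voxel_blocks(self, rng):
        vals = rng.normal(300, 25, (6, 6, 3))
        vol = make_volume(vals)
        stack = compute_maps(vol, plan_grid(vol.geometry, 1.0), features=("firstorder_Mean",))
        np.testing.assert_array_equal(stack["firstorder_Mean"].values, vals)

    def test_blockwise_mean_worked_example(self):
        vals = np.arange(1, 17, dtype=float).reshape(4, 4, 1)
        vol = make_volume(vals)
        stack = compute_maps(vol, plan_grid(vol.geometry, (2.0, 2.0, 1.0)),
                             features=("firstorder_Mean",))
        np.testing.assert_allclose(
            stack["firstorder_Mean"].values[:, :, 0],
            [[3.5, 5.5], [11.5, 13.5]],
        )

    def test_partial_blocks_are_missing(self, rng):
        vol = make_volume(rng.normal(size=(7, 5, 5)))
        stack = compute_maps(vol, plan_grid(vol.geometry, 5.0), features=("firstorder_Mean",))
        assert stack["firstorder_Mean"].values.shape == (1, 1, 1)
        assert np.isfinite(stack["firstorder_Mean"].values).all()

    def test_tiling_conservation(self, rng):
        vals = rng.normal(100, 10, (10, 10, 10))
        vol = make_volume(vals)
        grid = plan_grid(vol.geometry, 5.0)
        stack = compute_maps(vol, grid, features=("firstorder_Mean",))
        block_n = np.prod(grid.block_voxels)
        total = (stack["firstorder_Mean"].values * block_n).sum()
        assert total == pytest.approx(vals.sum(), rel=1e-9)

    def test_determinism(self, rng):
        vals = rng.normal(300, 25, (10, 10, 2))
        vol = make_volume(vals)
        grid = plan_grid(vol.geometry, (5.0, 5.0, 1.0))
        a = compute_maps(vol, grid, features=("glszm_ZoneEntropy",))
        b = compute_maps(vol, grid, features=("glszm_ZoneEntropy",))
        np.testing.assert_array_equal(a["glszm_ZoneEntropy"].values,
                                      b["glszm_ZoneEntropy"].values)

    def test_unknown_feature_rejected(self):
        vol = make_volume(np.zeros((5, 5, 5)))
        with pytest.raises(KeyError, match="unknown features"):
            compute_maps(vol, plan_grid(vol.geometry, 5.0), features=("shape_Volume",))

    def test_stack_write_manifest(self, tmp_path, rng):
        vol = make_volume(rng.normal(size=(5, 5, 5)))
        stack = compute_maps(vol, plan_grid(vol.geometry, 5.0), features=("firstorder_Mean",))
        out = stack.write(tmp_path / "maps")
        assert (out / "manifest.json").exists()
        assert (out / "firstorder_Mean.nii.gz").exists()


# features whose degenerate value on a constant image does not depend on
# the ROI support, so conventional and map extraction agree exactly
SUPPORT_FREE_ON_CONSTANT = (
    [n for n in FEATURE_NAMES if n.startswith("firstorder")
     and n not in ("firstorder_Energy", "firstorder_TotalEnergy")]
    + [n for n in FEATURE_NAMES if n.startswith("glcm")]
    + ["gldm_LowGrayLevelEmphasis", "gldm_HighGrayLevelEmphasis",
       "glrlm_LowGrayLevelRunEmphasis", "glrlm_HighGrayLevelRunEmphasis",
       "glrlm_GrayLevelNonUniformityNormalized",
       "glszm_LowGrayLevelZoneEmphasis", "glszm_HighGrayLevelZoneEmphasis",
       "glszm_GrayLevelNonUniformityNormalized"]
    + [n for n in FEATURE_NAMES if n.startswith("ngtdm")]
)
SUPPORT_BOUND_ON_CONSTANT = (
    "firstorder_Energy", "firstorder_TotalEnergy",
    "glrlm_RunLengthNonUniformity", "glszm_LargeAreaEmphasis",
    "gldm_DependenceNonUniformity",
)


class TestExtractionRoutes:
    def _flat_case(self):
        geom = VolumeGeometry(spacing=(1.0, 1.0, 1.0), shape=(40, 40, 40))
        vol = ImageVolume(np.full(geom.shape, 250.0), geom)
        voi = SphereVOI((20.0, 20.0, 20.0), 20.0)
        stack = compute_maps(vol, plan_grid(vol.geometry, 5.0))
        return vol, voi, stack

    def test_method_agreement_in_the_flat_limit(self):
        vol, voi, stack = self._flat_case()
        conv = conventional_extract(vol, voi)
        mapped = map_extract(stack, voi)
        for name in SUPPORT_FREE_ON_CONSTANT:
            assert conv[name] == pytest.approx(mapped[name], abs=1e-12), name
        for name in SUPPORT_BOUND_ON_CONSTANT:
            assert conv[name] != pytest.approx(mapped[name]), name

    def test_constant_volume_identical_across_voi_sizes(self):
        vol, _, _ = self._flat_case()
        vecs = [conventional_extract(vol, SphereVOI((20.0, 20.0, 20.0), d))
                for d in (10, 20, 30)]
        for name in SUPPORT_FREE_ON_CONSTANT:
            assert len({round(v[name], 12) for v in vecs}) == 1, name

    def test_map_mean_matches_enumeration_oracle(self, rng):
        vals = rng.normal(300, 25, (20, 20, 20))
        vol = make_volume(vals)
        stack = compute_maps(vol, plan_grid(vol.geometry, 5.0), features=("firstorder_Mean",))
        # sphere centred on a map-voxel centre
        voi = SphereVOI((7.5, 7.5, 7.5), 10.0)
        got = map_extract(stack, voi)["firstorder_Mean"]
        mask = rasterize_sphere(voi, stack.grid.map_geometry).values
        want = stack["firstorder_Mean"].values[mask].mean()
        assert got == pytest.approx(want, rel=1e-12)

    def test_monotone_support_in_diameter(self):
        vol, _, stack = self._flat_case()
        supports = [map_support(stack, SphereVOI((20.0, 20.0, 20.0), d))
                    for d in (10, 20, 30)]
        assert supports == sorted(supports)
        assert supports[0] >= 1

    def test_sphere_missing_every_map_center_raises_named_error(self):
        vol, _, stack = self._flat_case()
        # a tiny sphere wedged between coarse voxel centres
        with pytest.raises(MapCoverageError):
            map_extract(stack, SphereVOI((5.0, 5.0, 5.0), 1.0))

    def test_conventional_mean_tracks_phantom_mean(self):
        from radiomap.phantom import ScannerPreset, SubjectParams, render_subject

        params = SubjectParams("s0", base_mean=300.0, texture_sd=20.0,
                               correlation_length=4.0, vessel_count=0)
        preset = ScannerPreset("p", 1.125, 5.5, noise_sd=5.0, global_gain=1.0)
        vol, _ = render_subject(params, preset, shape=(56, 56, 11), seed=2)
        center = tuple(e / 2 for e in vol.geometry.extent)
        mean = conventional_extract(vol, SphereVOI(center, 30.0),
                                    names=("firstorder_Mean",))["firstorder_Mean"]
        # correlated texture: ~2000 voxels but far fewer independent patches;
        # 3 standard errors with an effective-sample-size safety factor
        assert mean == pytest.approx(300.0, abs=3 * 20.0 / np.sqrt(2000 / 40))
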