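"""Phantom construction, settings enumeration and reconstruction surrogate."""

import numpy as np
import pytest

from phantomrad import (DEFAULT_SETTING, NECROTIC, InsertConfig, NoiseModel,
                        PhantomGeometry, build_activity_volume,
                        emulate_reconstruction, enumerate_settings,
                        make_roi_mask)
from phantomrad.phantom import ConfigError, GeometryError


class TestGeometry:
    def test_insert_volume_near_145_cm3(self, geometry):
        assert geometry.insert_volume_cm3() == pytest.approx(145.0, rel=0.01)

    def test_overlapping_syringes_rejected(self, geometry):
        import dataclasses
        fat = dataclasses.replace(geometry, syringe_radius=12.0,
                                  syringe_length=46.0)
        with pytest.raises(GeometryError, match="overlap"):
            fat.validate()

    def test_insert_outside_cylinder_rejected(self, geometry):
        import dataclasses
        bad = dataclasses.replace(geometry, insert_centers=((90.0, 0.0, 0.0),))
        with pytest.raises(GeometryError, match="cylinder"):
            bad.validate()


class TestInsertConfigs:
    def test_default_shapes_satisfy_contracts(self, insert_configs):
        assert [c.shape_id for c in insert_configs] == [1, 2, 3, 4]
        hot3 = [a for a in insert_configs[2].syringe_activities]
        assert set(hot3) == {20.0, 40.0, 80.0}
        assert max(hot3) / min(hot3) == 4.0
        assert insert_configs[1].syringe_activities.count(NECROTIC) == 1
        assert insert_configs[3].syringe_activities.count(NECROTIC) == 1

    @pytest.mark.parametrize("shape_id,acts", [
        (1, (40.0,) * 6 + (30.0,)),          # wrong homogeneous level
        (2, (40.0,) * 7),                     # missing necrotic syringe
        (3, (20.0,) * 7),                     # ratio not 4
        (3, (10.0, 40.0, 80.0) + (40.0,) * 4),  # level outside {20,40,80}
        (5, (40.0,) * 7),                     # unknown shape
    ])
    def test_invalid_configs_rejected(self, shape_id, acts):
        with pytest.raises(ConfigError):
            InsertConfig(shape_id, acts).validate()


class TestBuildActivityVolume:
    def test_homogeneous_insert_levels(self, geometry, insert_configs):
        vol = build_activity_volume(geometry, insert_configs[0])
        mask = make_roi_mask(geometry, 0)
        assert np.all(vol.data[mask.data] == 40.0)
        outside = ~mask.data & (vol.data > 0)
        assert np.all(vol.data[outside] == geometry.background_activity)

    def test_heterogeneous_insert_levels(self, geometry, insert_configs):
        vol = build_activity_volume(geometry, insert_configs[2])
        mask = make_roi_mask(geometry, 2)
        assert set(np.unique(vol.data[mask.data])) == {20.0, 40.0, 80.0}

    def test_necrotic_syringe_stays_at_background(self, geometry,
                                                  insert_configs):
        vol = build_activity_volume(geometry, insert_configs[1])
        mask = make_roi_mask(geometry, 1)
        vals = set(np.unique(vol.data[mask.data]))
        assert vals == {geometry.background_activity, 40.0}

    def test_background_only_config_is_constant_inside_cylinder(self, geometry):
        cfg = InsertConfig(1, (40.0,) * 7)
        vol = build_activity_volume(geometry, cfg)
        inside = vol.data > 0
        hot = vol.data == 40.0
        assert np.all(np.unique(vol.data[inside & ~hot])
                      == geometry.background_activity)
        assert np.all(vol.data[~inside] == 0.0)

    def test_activity_conservation(self, geometry, insert_configs):
        """Total activity matches 40×(insert vol) + 5×(water vol) within 10%."""
        vol = build_activity_volume(geometry, insert_configs[0])
        voxel_ml = geometry.voxel_spacing**3 / 1000.0
        total = vol.data.sum() * voxel_ml
        insert_ml = 145.0
        cyl_ml = (np.pi * geometry.cylinder_radius**2
                  * geometry.cylinder_length) / 1000.0
        expected = 40.0 * insert_ml + 5.0 * (cyl_ml - insert_ml)
        assert total == pytest.approx(expected, rel=0.10)


class TestROIMask:
    def test_mask_volume_near_145_cm3(self, geometry):
        mask = make_roi_mask(geometry, 0)
        assert mask.volume_cm3() == pytest.approx(145.0, rel=0.10)

    def test_translation_invariance_across_positions(self, geometry):
        counts = {make_roi_mask(geometry, i).voxel_count for i in range(4)}
        assert len(counts) == 1

    def test_mask_inside_cylinder(self, geometry, insert_configs):
        vol = build_activity_volume(geometry, insert_configs[0])
        mask = make_roi_mask(geometry, 0)
        assert np.all(vol.data[mask.data] > 0)

    def test_out_of_range_index(self, geometry):
        with pytest.raises(IndexError):
            make_roi_mask(geometry, 4)


class TestEnumerateSettings:
    def test_full_grid_yields_21_settings(self):
        settings = enumerate_settings()
        assert len(settings) == 21
        assert len({s.setting_id for s in settings}) == 21
        by_family = {}
        for s in settings:
            by_family.setdefault(s.family, []).append(s)
        assert {k: len(v) for k, v in by_family.items()} == {
            "subsets": 5, "iterations": 6, "filter": 8, "tof": 2}

    def test_singleton_lists_yield_one_per_family(self):
        settings = enumerate_settings(
            {"subsets": [24], "iterations": [2], "filter": [6.4],
             "tof": [True]})
        assert len(settings) == 4

    def test_empty_family_list_rejected(self):
        with pytest.raises(ConfigError):
            enumerate_settings({"subsets": [12, 16, 18, 24, 32],
                                "iterations": [], "filter": [],
                                "tof": []})

    def test_non_default_parameters_held_at_default(self):
        for s in enumerate_settings():
            if s.family != "filter":
                assert s.filter_fwhm == DEFAULT_SETTING.filter_fwhm


class TestEmulateReconstruction:
    def test_identity_when_all_degradations_off(self, geometry,
                                                insert_configs):
        vol = build_activity_volume(geometry, insert_configs[0])
        noiseless = NoiseModel(psf_fwhm=0.0, base_noise_sd=0.0)
        import dataclasses
        setting = dataclasses.replace(DEFAULT_SETTING, filter_fwhm=0.0)
        out = emulate_reconstruction(vol, setting, noiseless, seed=3)
        np.testing.assert_array_equal(out.data, vol.data)

    def test_determinism_bit_identical(self, geometry, insert_configs):
        vol = build_activity_volume(geometry, insert_configs[0])
        a = emulate_reconstruction(vol, DEFAULT_SETTING, seed=11)
        b = emulate_reconstruction(vol, DEFAULT_SETTING, seed=11)
        np.testing.assert_array_equal(a.data, b.data)

    def test_noise_grows_with_iteration_subset_product(self, geometry,
                                                       insert_configs):
        """Monte-Carlo check of the sqrt(iterations×subsets) noise law."""
        import dataclasses
        vol = build_activity_volume(geometry, insert_configs[0])
        mask = make_roi_mask(geometry, 0).data
        low = dataclasses.replace(DEFAULT_SETTING, iterations=2,
                                  filter_fwhm=0.0)
        high = dataclasses.replace(DEFAULT_SETTING, iterations=6,
                                   filter_fwhm=0.0)
        def in_roi_sd(setting):
            reps = [emulate_reconstruction(vol, setting, seed=s).data[mask]
                    for s in range(20)]
            return np.std(np.stack(reps), axis=0, ddof=1).mean()
        assert in_roi_sd(high) > in_roi_sd(low)

    def test_tof_reduces_noise(self):
        import dataclasses
        nm = NoiseModel()
        on = nm.noise_sd(DEFAULT_SETTING)
        off = nm.noise_sd(dataclasses.replace(DEFAULT_SETTING, tof=False))
        assert off == pytest.approx(on * nm.tof_gain)

    def test_smoothing_monotonically_reduces_in_roi_variance(
            self, geometry, insert_configs):
        import dataclasses
        vol = build_activity_volume(geometry, insert_configs[2])
        mask = make_roi_mask(geometry, 2).data
        noiseless = NoiseModel(psf_fwhm=5.0, base_noise_sd=0.0)
        variances = []
        for fwhm in (0.0, 2.0, 4.0, 6.0):
            s = dataclasses.replace(DEFAULT_SETTING, filter_fwhm=fwhm)
            out = emulate_reconstruction(vol, s, noiseless, seed=0)
            variances.append(out.data[mask].var())
        assert all(a > b for a, b in zip(variances, variances[1:]))

    def test_negative_fwhm_rejected(self, geometry, insert_configs):
        import dataclasses
        vol = build_activity_volume(geometry, insert_configs[0])
        bad = dataclasses.replace(DEFAULT_SETTING, filter_fwhm=-1.0)
        with pytest.raises(ValueError):
            emulate_reconstruction(vol, bad, seed=0)
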