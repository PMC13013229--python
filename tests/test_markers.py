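"""SUV statistics, composite markers and full-panel extraction."""

import numpy as np
import pytest

import dpdquant as dq
from dpdquant.errors import (
    DegenerateGeometryError,
    EmptyStructureError,
    InvalidReferenceError,
    MissingStructureError,
    UnitError,
)
from dpdquant.markers import sphere_mean_map, sphere_radius_mm
from dpdquant.phantom import _brute_sphere_peak


def _vol(values, spacing=(1.0, 1.0, 1.0), unit=dq.Unit.SUV):
    values = np.asarray(values, dtype=float)
    geom = dq.GridGeometry(shape=values.shape, spacing=spacing)
    return dq.Volume3D(values=values, geometry=geom, unit=unit)


class TestSuvMaxMean:
    def test_uniform_and_enumeration(self):
        vals = np.zeros((4, 4, 4))
        vals[0, 0, :4] = [1, 2, 3, 4]
        vals[1, 0, :4] = [5, 6, 7, 8]
        mask = vals > 0
        v = _vol(vals)
        assert dq.suv_max(v, mask) == 8.0
        assert dq.suv_mean(v, mask) == pytest.approx(4.5)
        uni = _vol(np.full((3, 3, 3), 2.5))
        m = np.ones((3, 3, 3), bool)
        assert dq.suv_max(uni, m) == 2.5
        assert dq.suv_mean(uni, m) == 2.5

    def test_homogeneity_and_order(self, rng):
        vals = rng.uniform(0, 10, size=(6, 6, 6))
        mask = rng.random((6, 6, 6)) < 0.4
        mask[0, 0, 0] = True
        v = _vol(vals)
        assert dq.suv_max(v.with_values(3 * vals), mask) == pytest.approx(
            3 * dq.suv_max(v, mask)
        )
        assert dq.suv_mean(v, mask) <= dq.suv_max(v, mask)

    def test_empty_mask_raises(self):
        v = _vol(np.ones((3, 3, 3)))
        with pytest.raises(EmptyStructureError):
            dq.suv_max(v, np.zeros((3, 3, 3), bool))
        with pytest.raises(EmptyStructureError):
            dq.suv_mean(v, np.zeros((3, 3, 3), bool))


class TestSuvPeak:
    def test_sphere_radius_1ml(self):
        assert sphere_radius_mm(1.0) == pytest.approx(6.2035, abs=1e-3)

    def test_uniform_volume(self):
        v = _vol(np.full((8, 8, 8), 3.0), spacing=(2, 2, 2))
        m = np.ones((8, 8, 8), bool)
        assert dq.suv_peak(v, m, 1.0) == pytest.approx(3.0)

    def test_hot_voxel_4mm_grid_19_member_sphere(self):
        # 4 mm isotropic: sphere holds 1+6+12 = 19 voxel centers
        # (distances 0, 4, 5.66 mm in; 6.93 mm corner out), so one voxel of
        # value 19 against zero background gives peak exactly 1.0
        vals = np.zeros((9, 9, 9))
        vals[4, 4, 4] = 19.0
        v = _vol(vals, spacing=(4, 4, 4))
        m = np.ones((9, 9, 9), bool)
        assert dq.suv_peak(v, m, 1.0) == pytest.approx(1.0)

    def test_matches_exhaustive_center_search(self, rng):
        for _ in range(5):
            shape = tuple(int(s) for s in rng.integers(6, 14, size=3))
            spacing = tuple(float(s) for s in rng.uniform(1.5, 4.0, size=3))
            vals = rng.uniform(0, 10, size=shape)
            mask = rng.random(shape) < 0.3
            mask[tuple(s // 2 for s in shape)] = True
            v = _vol(vals, spacing=spacing)
            expected = _brute_sphere_peak(vals, mask, spacing, 1.0)
            assert dq.suv_peak(v, mask, 1.0) == pytest.approx(expected, rel=1e-10)

    def test_order_property_when_sphere_fits(self, clean_phantom, clean_panel):
        for s in dq.CARDIAC_STRUCTURES:
            assert (
                clean_panel[f"SUVmean_{s}"]
                <= clean_panel[f"SUVpeak_{s}"] + 1e-9
            )
            assert clean_panel[f"SUVpeak_{s}"] <= clean_panel[f"SUVmax_{s}"] + 1e-9

    def test_degenerate_spacing_raises(self):
        v = _vol(np.ones((3, 3, 3)), spacing=(20, 20, 20))
        with pytest.raises(DegenerateGeometryError):
            dq.suv_peak(v, np.ones((3, 3, 3), bool), 1.0)


class TestAmyloidActivity:
    def test_uniform_region(self):
        # uniform SUV 2, expansion 0, 50 mL region -> 100 SUV*mL
        vals = np.full((10, 10, 10), 2.0)
        mask = np.zeros((10, 10, 10), bool)
        mask[:5, :10, :10] = True  # 500 voxels x 0.1 mL = 50 mL
        v = _vol(vals, spacing=(10, 5, 2))  # 100 mm3 voxels
        cfg = dq.ExtractionConfig(expansion_mm=0.0)
        assert dq.amyloid_activity(v, mask, cfg) == pytest.approx(100.0)

    def test_equals_voxel_sum_identity(self, rng):
        vals = rng.uniform(0, 5, size=(8, 8, 8))
        mask = rng.random((8, 8, 8)) < 0.1
        mask[4, 4, 4] = True
        v = _vol(vals, spacing=(2, 2, 2))
        cfg = dq.ExtractionConfig(expansion_mm=5.0)
        region = dq.dilate_mm(mask, v.geometry, 5.0)
        expected = vals[region].sum() * v.geometry.voxel_volume_ml
        assert dq.amyloid_activity(v, mask, cfg) == pytest.approx(expected)

    def test_single_1ml_voxel_no_expansion(self):
        vals = np.zeros((3, 3, 3))
        vals[1, 1, 1] = 5.0
        mask = vals > 0
        v = _vol(vals, spacing=(10, 10, 10))  # 1 mL voxels
        cfg = dq.ExtractionConfig(expansion_mm=0.0)
        assert dq.amyloid_activity(v, mask, cfg) == pytest.approx(5.0)


class TestTbrNormalize:
    def test_identity_reference_and_ratio(self):
        vals = np.full((4, 4, 4), 6.0)
        ivc = np.zeros((4, 4, 4), bool)
        ivc[0, 0, 0] = True
        vals[0, 0, 0] = 2.0
        v = _vol(vals)
        out = dq.tbr_normalize(v, ivc)
        assert out.unit is dq.Unit.TBR
        assert out.values[1, 1, 1] == pytest.approx(3.0)
        vals1 = vals.copy()
        vals1[0, 0, 0] = 1.0
        out1 = dq.tbr_normalize(v.with_values(vals1), ivc)
        np.testing.assert_allclose(out1.values, vals1)

    def test_scale_invariance(self, rng):
        vals = rng.uniform(0.5, 10, size=(5, 5, 5))
        ivc = rng.random((5, 5, 5)) < 0.2
        ivc[2, 2, 2] = True
        v = _vol(vals)
        a = dq.tbr_normalize(v, ivc).values
        b = dq.tbr_normalize(v.with_values(7.3 * vals), ivc).values
        np.testing.assert_allclose(a, b)

    def test_invalid_reference(self):
        v = _vol(np.zeros((3, 3, 3)))
        ivc = np.ones((3, 3, 3), bool)
        with pytest.raises(InvalidReferenceError):
            dq.tbr_normalize(v, ivc)  # zero mean
        with pytest.raises(InvalidReferenceError):
            dq.tbr_normalize(_vol(np.ones((3, 3, 3))), np.zeros((3, 3, 3), bool))


class TestAffectedVolume:
    def test_all_below_threshold(self):
        tbr = _vol(np.full((5, 5, 5), 0.5), unit=dq.Unit.TBR)
        mask = np.ones((5, 5, 5), bool)
        assert dq.affected_volume(tbr, mask, dq.ExtractionConfig(expansion_mm=0.0)) == 0.0

    def test_saturated_case(self):
        # 80 voxels at 0.5 mL/voxel, all TBR >= 1 -> 40 mL
        vals = np.full((5, 4, 4), 1.2)
        v = _vol(vals, spacing=(10, 10, 5), unit=dq.Unit.TBR)  # 0.5 mL voxels
        mask = np.ones(vals.shape, bool)
        assert dq.affected_volume(v, mask, dq.ExtractionConfig(expansion_mm=0.0)) == pytest.approx(
            40.0
        )

    def test_mixed_values_match_enumeration(self, rng):
        vals = rng.uniform(0, 2, size=(10, 10, 10))
        mask = rng.random((10, 10, 10)) < 0.2
        mask[5, 5, 5] = True
        v = _vol(vals, spacing=(2, 2, 2), unit=dq.Unit.TBR)
        cfg = dq.ExtractionConfig(expansion_mm=4.0)
        region = dq.dilate_mm(mask, v.geometry, 4.0)
        expected = sum(
            1 for idx in np.argwhere(region) if vals[tuple(idx)] >= 1.0
        ) * v.geometry.voxel_volume_ml
        assert dq.affected_volume(v, mask, cfg) == pytest.approx(expected)

    def test_inclusive_boundary(self):
        vals = np.full((4, 4, 4), 1.0)  # exactly at threshold
        v = _vol(vals, spacing=(5, 5, 5), unit=dq.Unit.TBR)
        mask = np.ones((4, 4, 4), bool)
        cfg = dq.ExtractionConfig(expansion_mm=0.0)
        assert dq.affected_volume(v, mask, cfg) == pytest.approx(64 * 0.125)

    def test_wrong_unit(self):
        v = _vol(np.ones((3, 3, 3)), unit=dq.Unit.SUV)
        with pytest.raises(UnitError):
            dq.affected_volume(v, np.ones((3, 3, 3), bool))


class TestRetentionIndex:
    def test_direct_formula_on_phantom(self, clean_phantom):
        vol, ss, truth = clean_phantom
        cfg = dq.ExtractionConfig()
        # myocardium 12, T9 5, paraspinal 1 with full spheres inside each
        assert dq.retention_index(vol, ss, cfg) == pytest.approx(12.0 / 5.0 * 1.0)

    def test_homogeneity_scales_linearly(self, clean_phantom):
        vol, ss, _ = clean_phantom
        cfg = dq.ExtractionConfig()
        base = dq.retention_index(vol, ss, cfg)
        scaled = dq.retention_index(vol.with_values(2.0 * vol.values), ss, cfg)
        # the ratio cancels one factor; the muscle term contributes one
        assert scaled == pytest.approx(2.0 * base)

    def test_zero_t9_peak_raises(self):
        geom = dq.GridGeometry(shape=(20, 20, 40), spacing=(4, 4, 4))
        vals = np.zeros(geom.shape)
        vals[4:8, 4:8, 10:20] = 5.0  # myocardium only
        masks = {
            "MYOCARDIUM": vals > 0,
            "T9": np.zeros(geom.shape, bool),
            "T7": np.zeros(geom.shape, bool),
            "T8": np.zeros(geom.shape, bool),
            "T10": np.zeros(geom.shape, bool),
            "T11": np.zeros(geom.shape, bool),
            "PARASPINAL_RIGHT": np.zeros(geom.shape, bool),
        }
        masks["T9"][14:16, 14:16, 14:18] = True
        masks["T7"][14:16, 14:16, 30:34] = True
        masks["T11"][14:16, 14:16, 2:6] = True
        masks["PARASPINAL_RIGHT"][17:19, 14:16, 2:36] = True
        ss = dq.StructureSet(geometry=geom, masks=masks)
        vol = dq.Volume3D(values=vals, geometry=geom, unit=dq.Unit.SUV)
        with pytest.raises(InvalidReferenceError):
            dq.retention_index(vol, ss)


class TestExtractPanel:
    def test_panel_has_exactly_26_markers(self, clean_panel):
        assert tuple(clean_panel.values) == dq.MARKER_NAMES
        assert len(clean_panel.values) == 26
        assert all(np.isfinite(v) for v in clean_panel.values.values())

    def test_missing_structure_named_in_error(self, clean_phantom):
        vol, ss, _ = clean_phantom
        masks = {k: v for k, v in ss.masks.items() if k != "LA"}
        broken = dq.StructureSet(geometry=ss.geometry, masks=masks)
        with pytest.raises(MissingStructureError, match="LA"):
            dq.extract_panel(vol, broken)

    def test_deterministic_repeat(self, clean_phantom):
        vol, ss, _ = clean_phantom
        p1 = dq.extract_panel(vol, ss)
        p2 = dq.extract_panel(vol, ss)
        assert p1.as_dict() == p2.as_dict()  # bitwise identical

    def test_homogeneity_of_panel(self, clean_phantom, clean_panel):
        vol, ss, _ = clean_phantom
        scaled = dq.extract_panel(vol.with_values(2.5 * vol.values), ss)
        for name in dq.MARKER_NAMES:
            if name.startswith(("SUV", "AMYLOID_ACTIVITY", "RETENTION")):
                assert scaled[name] == pytest.approx(2.5 * clean_panel[name], rel=1e-9)
            else:  # affected volume: TBR cancels the global scale
                assert scaled[name] == pytest.approx(clean_panel[name], rel=1e-12)

    def test_affected_volume_bounded_by_dilated_mask(self, clean_phantom, clean_panel):
        vol, ss, truth = clean_phantom
        for s in dq.CARDIAC_STRUCTURES:
            av = clean_panel[f"AFFECTED_VOLUME_{s}"]
            assert 0.0 <= av <= truth.dilated_volume_ml[s] + 1e-9

    def test_combined_chambers_flag(self, clean_phantom):
        vol, ss, _ = clean_phantom
        cfg = dq.ExtractionConfig(include_combined_chambers=True)
        panel = dq.extract_panel(vol, ss, cfg)
        assert len(panel.values) == 26  # panel itself stays at 26
        assert set(panel.extras) == {
            f"{m}_{g}" for m in ("SUVmax", "SUVmean", "SUVpeak") for g in ("VENTRICLES", "ATRIA")
        }

    def test_provenance_records_reference_and_counts(self, clean_panel):
        prov = clean_panel.provenance
        assert prov["ivc_mean_suv"] == pytest.approx(1.0)
        assert prov["structures"]["LV"]["voxels"] > 0
        assert prov["config_hash"]
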