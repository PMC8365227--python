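import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aneuflow.stent_model import (DEFAULT_CIRCUMFERENCE,
                                  DegeneratePatternError,
                                  IncompatibilityError, ResolutionError,
                                  UnsupportedOperationError, compact,
                                  compute_mcr, generate_pattern, load_presets,
                                  overlap, preset_pattern, solidity_profile)

NECK_RECT = (5.27e-3, math.pi * 4e-3)
# integer number of lattice periods: raster fraction equals the analytic
# coverage without window truncation effects
PERIODIC_RECT = (5e-3, 10e-3)


class TestGeneratePattern:
    def test_braided_coverage_matches_analytic_union(self):
        pat = generate_pattern("braided", dict(
            n_wires=16, braid_angle=75.0, wire_diameter=5e-5))
        spacing_y = DEFAULT_CIRCUMFERENCE / 8
        f = 5e-5 / (spacing_y * math.cos(math.radians(75.0)))
        analytic = 1.0 - (1.0 - f) ** 2
        raster = compute_mcr(pat, NECK_RECT).mcr
        assert raster == pytest.approx(analytic, rel=0.01)

    def test_laser_cut_coverage_approaches_one_as_width_fills_pitch(self):
        mcrs = []
        for frac in (0.5, 0.8, 0.95):
            theta = math.atan2(1e-3, 1e-3)
            p_perp = 1e-3 * math.cos(theta)
            pat = generate_pattern("laser_cut", dict(
                strut_width=frac * p_perp, axial_pitch=1e-3,
                circumferential_pitch=1e-3))
            mcrs.append(compute_mcr(pat, NECK_RECT,
                                    raster_spacing=2e-5).mcr)
        assert mcrs == sorted(mcrs)
        assert mcrs[-1] > 0.99

    def test_degenerate_width_rejected(self):
        with pytest.raises(DegeneratePatternError):
            generate_pattern("laser_cut", dict(
                strut_width=1e-3, axial_pitch=1e-3,
                circumferential_pitch=1e-3))

    def test_unknown_class_rejected(self):
        with pytest.raises(ValueError):
            generate_pattern("woven", {})


class TestPresets:
    @pytest.mark.parametrize("name,target", [
        ("enterprise", 0.070), ("lvis", 0.204), ("pipeline", 0.268)])
    def test_single_device_calibration(self, name, target):
        mcr = compute_mcr(preset_pattern(name), NECK_RECT).mcr
        assert mcr == pytest.approx(target, abs=0.005)

    @pytest.mark.parametrize("name,target", [
        ("lvis", 0.354), ("pipeline", 0.478)])
    def test_max_compaction_calibration(self, name, target):
        pat = preset_pattern(name, compaction="max")
        assert compute_mcr(pat, NECK_RECT).mcr == pytest.approx(
            target, abs=0.01)

    def test_registry_contents(self):
        presets = load_presets()
        assert set(presets) == {"enterprise", "lvis", "pipeline"}
        assert presets["enterprise"]["device_class"] == "laser_cut"

    def test_unknown_preset(self):
        with pytest.raises(KeyError):
            preset_pattern("silk")


class TestOverlap:
    def test_zero_offset_union_is_idempotent(self):
        pat = preset_pattern("lvis")
        double = overlap([pat, pat], offsets=[(0.0, 0.0), (0.0, 0.0)])
        m1 = compute_mcr(pat, NECK_RECT).mcr
        m2 = compute_mcr(double, NECK_RECT).mcr
        assert m2 == pytest.approx(m1, abs=1e-12)

    def test_default_offsets_give_constant_gap(self):
        pat = preset_pattern("enterprise")
        double = overlap([pat, pat])
        dx = [off[0] for off in double.layer_offsets]
        assert dx[1] - dx[0] == pytest.approx(pat.axial_pitch / 4)

    def test_union_bounds(self):
        p = preset_pattern("lvis")
        q = overlap([p, p])
        m1 = compute_mcr(p, NECK_RECT).mcr
        m2 = compute_mcr(q, NECK_RECT).mcr
        assert max(m1, m1) - 1e-9 <= m2 <= min(1.0, 2 * m1) + 1e-9

    def test_mismatched_frames_rejected(self):
        with pytest.raises(IncompatibilityError):
            overlap([preset_pattern("lvis"), preset_pattern("pipeline")])

    def test_independent_layers_expected_union(self):
        """Averaging the union over a grid of relative offsets approaches
        1 - (1 - m)^2 for two layers of single coverage m."""
        pat = generate_pattern("braided", dict(
            n_wires=16, braid_angle=65.0, wire_diameter=7e-5))
        m = compute_mcr(pat, PERIODIC_RECT, raster_spacing=pat.width / 4).mcr
        expected = 1.0 - (1.0 - m) ** 2
        x = (np.arange(250) + 0.5) * (PERIODIC_RECT[0] / 250)
        y = (np.arange(500) + 0.5) * (PERIODIC_RECT[1] / 500)
        base = pat.metal(x[:, None], y[None, :])
        unions = []
        for fx in np.linspace(0.1, 0.9, 5):
            for fy in np.linspace(0.1, 0.9, 5):
                shifted = pat.metal(x[:, None] - fx * pat.axial_pitch,
                                    y[None, :] - fy * pat.axial_pitch)
                unions.append(np.mean(base | shifted))
        assert np.mean(unions) == pytest.approx(expected, abs=0.01)

    @given(fx=st.floats(0.0, 1.0), fy=st.floats(0.0, 1.0))
    @settings(max_examples=15, deadline=None)
    def test_union_bounds_property(self, fx, fy):
        pat = generate_pattern("braided", dict(
            n_wires=16, braid_angle=65.0, wire_diameter=7e-5))
        x = (np.arange(150) + 0.5) * (PERIODIC_RECT[0] / 150)
        y = (np.arange(300) + 0.5) * (PERIODIC_RECT[1] / 300)
        base = pat.metal(x[:, None], y[None, :])
        shifted = pat.metal(x[:, None] - fx * pat.axial_pitch,
                            y[None, :] - fy * pat.axial_pitch)
        m1, m2 = np.mean(base), np.mean(shifted)
        mu = np.mean(base | shifted)
        assert mu >= max(m1, m2) - 1e-12
        assert mu <= min(1.0, m1 + m2) + 1e-12


class TestCompact:
    def test_identity_at_factor_one(self):
        pat = preset_pattern("lvis")
        assert compact(pat, 1.0) is pat

    def test_laser_cut_rejected(self):
        with pytest.raises(UnsupportedOperationError):
            compact(preset_pattern("enterprise"), 1.5)

    def test_subunit_factor_rejected(self):
        with pytest.raises(ValueError):
            compact(preset_pattern("lvis"), 0.9)

    def test_mcr_nondecreasing_in_factor(self):
        pat = preset_pattern("lvis")
        mcrs = [compute_mcr(compact(pat, f), NECK_RECT).mcr
                for f in (1.0, 1.25, 1.5, 1.75, 2.0)]
        assert all(b >= a for a, b in zip(mcrs, mcrs[1:]))
        assert mcrs[-1] > mcrs[0]

    def test_angle_steepens_with_factor(self):
        pat = preset_pattern("lvis")
        comp = compact(pat, 2.0)
        assert comp.braid_angle > pat.braid_angle
        assert comp.axial_pitch == pytest.approx(pat.axial_pitch / 2)


class TestComputeMCR:
    def test_empty_pattern_zero(self):
        res = compute_mcr(None, NECK_RECT)
        assert res.mcr == 0.0
        assert not res.metal_mask.any()

    def test_orthogonal_grid_inclusion_exclusion(self):
        pat = generate_pattern("laser_cut", dict(
            strut_width=1e-4, axial_pitch=1e-3, circumferential_pitch=1e-3,
            lattice="orthogonal"))
        res = compute_mcr(pat, PERIODIC_RECT)
        assert res.mcr == pytest.approx(1.0 - 0.9**2, abs=0.002)

    def test_solid_sheet_is_one(self):
        class Sheet:
            width = 1e-4

            def metal(self, x, y):
                return np.ones(np.broadcast(x, y).shape, dtype=bool)

        assert compute_mcr(Sheet(), NECK_RECT).mcr == 1.0

    def test_raster_too_coarse_rejected(self):
        pat = preset_pattern("lvis")
        with pytest.raises(ResolutionError):
            compute_mcr(pat, NECK_RECT, raster_spacing=pat.width)

    def test_refinement_convergence_half_point(self):
        pat = preset_pattern("pipeline")
        a = compute_mcr(pat, NECK_RECT, pat.width / 8).mcr
        b = compute_mcr(pat, NECK_RECT, pat.width / 16).mcr
        assert abs(a - b) * 100 < 0.5

    def test_determinism(self):
        pat = preset_pattern("lvis")
        a = compute_mcr(pat, NECK_RECT)
        b = compute_mcr(pat, NECK_RECT)
        assert np.array_equal(a.metal_mask, b.metal_mask)
        assert a.mcr == b.mcr


class TestSolidityProfile:
    def test_uniform_lattice_near_constant(self):
        prof = solidity_profile(preset_pattern("lvis"), NECK_RECT, 26)
        assert prof.std() / prof.mean() < 0.05

    def test_mean_matches_mcr(self):
        pat = preset_pattern("pipeline")
        prof = solidity_profile(pat, NECK_RECT, 26)
        mcr = compute_mcr(pat, NECK_RECT).mcr
        assert prof.mean() == pytest.approx(mcr, abs=0.005)

    def test_empty_pattern_all_zero(self):
        prof = solidity_profile(None, NECK_RECT, 26)
        assert np.all(prof == 0.0)
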