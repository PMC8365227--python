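import cmath
import math

import numpy as np
import pytest

from aneuflow.flow_solver import (BLOOD, VALIDATION_FLUID, FluidProperties,
                                  ProjectionSolver, PulsatileWaveform,
                                  ScreenModel, default_ica_waveform,
                                  run_cycles, womersley_inlet_profile)
from aneuflow.geometry import channel_grid


class TestFluidProperties:
    def test_presets(self):
        assert (BLOOD.density, BLOOD.viscosity) == (1055.0, 0.004)
        assert (VALIDATION_FLUID.density,
                VALIDATION_FLUID.viscosity) == (1200.0, 0.0038)

    def test_positive_required(self):
        with pytest.raises(ValueError):
            FluidProperties(density=-1.0, viscosity=0.004)


class TestWaveform:
    def test_womersley_number(self):
        wf = default_ica_waveform()
        alpha = wf.womersley_number(BLOOD, 4e-3)
        expected = 0.002 * math.sqrt(2 * math.pi * 1055 / (1.0 * 0.004))
        assert alpha == pytest.approx(expected, rel=1e-12)

    def test_default_stays_positive(self):
        wf = default_ica_waveform()
        t = np.linspace(0, 1, 1000)
        assert np.all(wf.mean_velocity_at(t) > 0)

    def test_negative_excursion_rejected(self):
        with pytest.raises(ValueError):
            PulsatileWaveform(period=1.0, mean_velocity=0.1,
                              harmonics=((0.2, 0.0),))

    def test_systolic_time_matches_argmax(self):
        wf = default_ica_waveform()
        ts = wf.systolic_time()
        t = np.linspace(0, 1, 100_000)
        assert abs(ts - t[np.argmax(wf.mean_velocity_at(t))]) < 1e-3


class TestWomersleyProfile:
    def test_zero_harmonics_is_parabola(self):
        wf = PulsatileWaveform(period=1.0, mean_velocity=0.25,
                               harmonics=((0.0, 0.0),))
        y = np.linspace(0, 4e-3, 81)
        prof = womersley_inlet_profile(wf, VALIDATION_FLUID, 4e-3, 0.3, y)
        assert prof[40] == pytest.approx(1.5 * 0.25, rel=1e-12)
        exact = 1.5 * 0.25 * (1 - (2 * y / 4e-3 - 1) ** 2)
        np.testing.assert_allclose(prof, exact, atol=1e-14)

    def test_quasi_steady_low_alpha_limit(self):
        """alpha -> 0: the harmonic profile degenerates to a parabolic
        modulation of the instantaneous mean."""
        period = 800.0  # alpha ~ 0.1 for the validation fluid
        wf = PulsatileWaveform(period=period, mean_velocity=0.25,
                               harmonics=((0.1, 0.0),))
        alpha = wf.womersley_number(VALIDATION_FLUID, 4e-3)
        assert alpha < 0.15
        y = np.linspace(1e-4, 3.9e-3, 64)
        for t in (0.0, 0.2 * period, 0.6 * period):
            prof = womersley_inlet_profile(wf, VALIDATION_FLUID, 4e-3, t, y)
            quasi = 1.5 * wf.mean_velocity_at(t) \
                * (1 - (2 * y / 4e-3 - 1) ** 2)
            assert np.max(np.abs(prof - quasi)) \
                < 0.01 * np.max(np.abs(quasi))

    def test_alpha_three_against_pointwise_oracle(self):
        """Independent scalar-cmath evaluation of the cosh-ratio closed
        form at 64 points, relative error < 1e-10."""
        height, mean, amp, phase = 4e-3, 0.25, 0.1, 0.4
        fluid = VALIDATION_FLUID
        nu = fluid.kinematic_viscosity
        # pick the period so alpha = 3 exactly
        alpha = 3.0
        omega = (alpha / (height / 2)) ** 2 * nu
        period = 2 * math.pi / omega
        wf = PulsatileWaveform(period=period, mean_velocity=mean,
                               harmonics=((amp, phase),))
        assert wf.womersley_number(fluid, height) == pytest.approx(3.0)
        y = np.linspace(0, height, 64)
        t = 0.37 * period
        prof = womersley_inlet_profile(wf, fluid, height, t, y)
        for yi, pi in zip(y, prof):
            xi = 2 * yi / height - 1
            lam = cmath.sqrt(1j * omega / nu)
            Lam = lam * height / 2
            shape = (1 - cmath.cosh(Lam * xi) / cmath.cosh(Lam)) \
                / (1 - cmath.tanh(Lam) / Lam)
            expect = 1.5 * mean * (1 - xi**2) + (
                amp * cmath.exp(1j * (omega * t + phase)) * shape).real
            assert pi == pytest.approx(expect, rel=1e-10, abs=1e-12)

    def test_section_average_equals_waveform_mean(self):
        wf = default_ica_waveform()
        y = (np.arange(4000) + 0.5) * (4e-3 / 4000)
        for t in (0.0, 0.13, 0.61):
            prof = womersley_inlet_profile(wf, BLOOD, 4e-3, t, y)
            assert prof.mean() == pytest.approx(
                wf.mean_velocity_at(t), rel=1e-6)


class TestScreenModel:
    def test_solidity_bounds(self):
        with pytest.raises(ValueError):
            ScreenModel(np.array([0.5, 1.0]))
        with pytest.raises(ValueError):
            ScreenModel(np.array([-0.1]))

    def test_loss_coefficient_increasing_and_finite(self):
        sc = ScreenModel.uniform(0.0, 4)
        s = np.linspace(0.0, 0.95, 50)
        k = sc.loss_coefficient(s)
        assert np.all(np.isfinite(k))
        assert np.all(np.diff(k) > 0)
        assert k[0] == 0.0

    def test_viscous_resistance_vanishes_at_zero(self):
        sc = ScreenModel.uniform(0.0, 4)
        assert sc.viscous_resistance(np.array([0.0]), 0.004)[0] == 0.0


class TestStep:
    def test_zero_forcing_stays_zero(self):
        grid = channel_grid(4e-3, 8e-3, 2e-4)
        solver = ProjectionSolver(grid, VALIDATION_FLUID, None)
        f = solver.initial_field(0.0, developed=False)
        for _ in range(20):
            f = solver.step(f)
        assert np.all(f.u == 0.0) and np.all(f.v == 0.0)

    def test_divergence_free_after_steps(self, womersley_run):
        solver, f = womersley_run["solver"], womersley_run["field"]
        div = solver.divergence(f)
        scale = np.abs(f.u).max() / solver.h
        assert np.abs(div).max() < 1e-8 * scale

    def test_noslip_on_solid_faces(self, trend_sweep):
        solver = trend_sweep["solvers"][0.0]
        f = trend_sweep["fields"][0.0]
        assert np.all(f.u[~solver.u_valued] == 0.0)
        assert np.all(f.v[~solver.v_unknown] == 0.0)

    def test_screen_drag_never_adds_energy(self, trend_sweep):
        """One step with and without the drag applied: screen faces only
        lose momentum magnitude."""
        solver = trend_sweep["solvers"][0.65]
        f = trend_sweep["fields"][0.65]
        sf = solver.screen_faces
        gamma = solver._gamma_lin[sf] + solver._gamma_quad[sf]
        assert np.all(gamma > 0)
        v = f.v[sf]
        damped = v / (1.0 + gamma * 1e-4)
        assert np.all(np.abs(damped) <= np.abs(v) + 1e-18)

    def test_zero_solidity_screen_identity(self):
        grid = channel_grid(4e-3, 8e-3, 2e-4)
        geom_grid = grid  # channel: no neck faces, screen must be empty
        wf = default_ica_waveform(period=0.5)
        from aneuflow.geometry import (build_sidewall_aneurysm, rasterize)
        geom = build_sidewall_aneurysm(4e-3, 5e-3, 5.27e-3, 20e-3)
        agrid = rasterize(geom, 2e-4)
        s0 = ScreenModel.uniform(0.0, agrid.neck_columns.size)
        sa = ProjectionSolver(agrid, BLOOD, wf, None)
        sb = ProjectionSolver(agrid, BLOOD, wf, s0)
        fa = sa.initial_field(0.0)
        fb = sb.initial_field(0.0)
        for _ in range(25):
            fa = sa.step(fa, 1e-4)
            fb = sb.step(fb, 1e-4)
        assert np.array_equal(fa.u, fb.u)
        assert np.array_equal(fa.v, fb.v)
        assert np.array_equal(fa.p, fb.p)


class TestChannelValidation:
    def test_poiseuille_profile_within_2pct(self, poiseuille_run):
        solver = poiseuille_run["solver"]
        grid = poiseuille_run["grid"]
        f = poiseuille_run["field"]
        y = solver.inlet_y
        exact = womersley_inlet_profile(
            poiseuille_run["waveform"], VALIDATION_FLUID, 4e-3, f.time, y)
        mid = f.u[grid.nx // 2, :]
        err = np.linalg.norm(mid - exact) / np.linalg.norm(exact)
        assert err < 0.02

    def test_womersley_third_cycle_within_5pct(self, womersley_run):
        errors = womersley_run["errors"]
        assert errors.size > 10
        assert errors.max() < 0.05

    def test_mass_conservation(self, womersley_run):
        solver, f = womersley_run["solver"], womersley_run["field"]
        qin, qout = solver.inlet_flux(f), solver.outlet_flux(f)
        assert abs(qin - qout) / abs(qin) < 1e-6


class TestRunCycles:
    def test_integrates_exactly_three_periods(self, trend_sweep):
        result = trend_sweep["results"][0.0]
        assert result.final_time == pytest.approx(3 * 0.5, abs=1e-9)

    def test_systole_in_third_cycle(self, trend_sweep):
        wf = default_ica_waveform(period=0.5)
        f = trend_sweep["fields"][0.0]
        assert 2 * 0.5 <= f.time <= 3 * 0.5
        phase = f.time - 2 * 0.5
        assert phase == pytest.approx(wf.systolic_time(), abs=5e-3)

    def test_cycle_periodicity_under_2pct(self, trend_sweep):
        c2, c3 = trend_sweep["control_cycles"][-2:]
        rel = np.linalg.norm(c3.u - c2.u) / np.linalg.norm(c3.u)
        assert rel < 0.02

    def test_aneurysm_mass_conservation_at_systole(self, trend_sweep):
        solver = trend_sweep["solvers"][0.0]
        f = trend_sweep["fields"][0.0]
        qin, qout = solver.inlet_flux(f), solver.outlet_flux(f)
        assert abs(qin - qout) / abs(qin) < 1e-6


class TestFlowDiversion:
    def test_inflow_monotone_nonincreasing_in_solidity(self, trend_sweep):
        summaries = trend_sweep["summaries"]
        solidities = sorted(summaries)
        inflows = [summaries[s].inflow_rate for s in solidities]
        vels = [summaries[s].avg_velocity for s in solidities]
        assert all(b <= a for a, b in zip(inflows, inflows[1:]))
        assert all(b <= a for a, b in zip(vels, vels[1:]))

    def test_grid_convergence_inflow(self):
        """Halving the spacing changes the systolic neck inflow by less
        than 10% (short-period configuration to stay fast)."""
        from aneuflow.geometry import (build_sidewall_aneurysm, place_planes,
                                       rasterize)
        from aneuflow.hemodynamic_metrics import neck_inflow_rate
        geom = build_sidewall_aneurysm(4e-3, 5e-3, 5.27e-3, 24e-3)
        wf = default_ica_waveform(period=0.3)
        rates = []
        for h in (2e-4, 1e-4):
            grid = place_planes(rasterize(geom, h), 4e-3, 4e-3)
            solver = ProjectionSolver(grid, BLOOD, wf)
            res = run_cycles(solver, 3)
            rates.append(neck_inflow_rate(res.systolic_field, grid))
        assert abs(rates[1] - rates[0]) / rates[0] < 0.10
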