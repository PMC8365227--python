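"""Shared fixtures.

The expensive solver runs (analytic channel validations, the uniform-
screen trend sweep) are session-scoped and reused by the unit,
property and acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from aneuflow.flow_solver import (BLOOD, VALIDATION_FLUID, ProjectionSolver,
                                  PulsatileWaveform, ScreenModel,
                                  default_ica_waveform, run_cycles,
                                  womersley_inlet_profile)
from aneuflow.geometry import (build_sidewall_aneurysm, channel_grid,
                               place_planes, rasterize)
from aneuflow.hemodynamic_metrics import summarize

#: solidity levels of the trend sweep; includes the three single-device
#: coverages (enterprise-, lvis-, pipeline-like) among six levels
TREND_SOLIDITIES = (0.0, 0.07, 0.204, 0.268, 0.45, 0.65)


@pytest.fixture(scope="session")
def paper_geometry():
    return build_sidewall_aneurysm(4e-3, 5e-3, 5.27e-3, 40e-3)


@pytest.fixture(scope="session")
def coarse_grid():
    """Fast aneurysm grid: 24 mm parent, 0.2 mm spacing, planes one
    parent diameter off the neck edges."""
    geom = build_sidewall_aneurysm(4e-3, 5e-3, 5.27e-3, 24e-3)
    grid = rasterize(geom, 2e-4)
    return place_planes(grid, 4e-3, 4e-3)


@pytest.fixture(scope="session")
def poiseuille_run():
    """Steady channel run: 40 cells across the lumen, integrated from
    rest to a viscous steady state."""
    wf = PulsatileWaveform(period=1.0, mean_velocity=0.25,
                           harmonics=((0.0, 0.0),))
    grid = channel_grid(4e-3, 12e-3, 1e-4)
    solver = ProjectionSolver(grid, VALIDATION_FLUID, wf)
    f = solver.initial_field(0.0, developed=False)
    while f.time < 2.0:
        f = solver.step(f)
    return dict(solver=solver, field=f, waveform=wf, grid=grid)


@pytest.fixture(scope="session")
def womersley_run():
    """Single-harmonic channel run over three cycles; records the
    relative L2 profile error against the closed form, sampled through
    the third cycle at mid-channel."""
    wf = PulsatileWaveform(period=1.0, mean_velocity=0.25,
                           harmonics=((0.1, 0.0),))
    grid = channel_grid(4e-3, 12e-3, 1e-4)
    solver = ProjectionSolver(grid, VALIDATION_FLUID, wf)
    f = solver.initial_field(0.0, developed=True)
    i_mid = grid.nx // 2
    y = solver.inlet_y
    errors = []
    n = 0
    while f.time < 3.0:
        f = solver.step(f)
        n += 1
        if f.time >= 2.0 and n % 40 == 0:
            exact = womersley_inlet_profile(wf, VALIDATION_FLUID, 4e-3,
                                            f.time, y)
            errors.append(np.linalg.norm(f.u[i_mid, :] - exact)
                          / np.linalg.norm(exact))
    return dict(solver=solver, field=f, errors=np.array(errors), grid=grid)


@pytest.fixture(scope="session")
def trend_sweep(coarse_grid):
    """Uniform-screen sweep over TREND_SOLIDITIES (s=0 is the control);
    three cycles of a 0.5 s period.  Returns per-level summaries plus
    the control run's per-cycle systolic fields."""
    grid = coarse_grid
    wf = default_ica_waveform(period=0.5)
    control_summary = None
    out = {"summaries": {}, "solvers": {}, "fields": {}}
    for s in TREND_SOLIDITIES:
        screen = (ScreenModel.uniform(s, grid.neck_columns.size)
                  if s > 0 else None)
        solver = ProjectionSolver(grid, BLOOD, wf, screen)
        result = run_cycles(solver, 3)
        summary = summarize(result.systolic_field, grid, BLOOD.density,
                            mcr=s, config_label=f"s={s}",
                            control=control_summary)
        if s == 0.0:
            control_summary = summary
            out["control_cycles"] = result.systolic_fields_per_cycle
        out["summaries"][s] = summary
        out["solvers"][s] = solver
        out["fields"][s] = result.systolic_field
        out.setdefault("results", {})[s] = result
    return out
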