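"""Hemodynamic parameters of a systolic flow field.

Three parameters are reported per configuration: the energy loss (EL)
between the parent-artery planes A and B, and the average velocity and
one-sided inflow rate through the neck plane C.  Reduction rates are
percent decreases relative to the unstented control.

Conventions: plane averages are area-weighted; the EL prefactor uses the
systolic section-mean inlet velocity; "inflow" counts only sac-directed
flux (net flux through a closed sac is ~0 by incompressibility, which
would make the metric degenerate).  All volumes and flow rates carry the
unit-depth scaling of the 2D reduction (depth = parent diameter).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .flow_solver import FlowField
from .geometry import ComputationalGrid

__all__ = [
    "PlaneSummary",
    "HemodynamicSummary",
    "plane_summary",
    "energy_loss",
    "neck_inflow_rate",
    "neck_average_velocity",
    "reduction_rate",
    "sac_to_neck_speed_ratio",
    "summarize",
]


@dataclass(frozen=True)
class PlaneSummary:
    """Area-averaged state on a measurement plane."""

    plane_id: str          # 'A' | 'B' | 'C'
    v_avg: float           # m/s, section-mean normal velocity
    p_avg: float           # Pa
    area: float            # m^2 (plane length x depth)


@dataclass(frozen=True)
class HemodynamicSummary:
    """One row of the study table."""

    config_label: str
    mcr: float                  # fraction
    energy_loss: float          # W/m^3
    avg_velocity: float         # m/s
    inflow_rate: float          # mm^3/s
    el_reduction_pct: float
    vel_reduction_pct: float
    inflow_reduction_pct: float


def plane_summary(field: FlowField, grid: ComputationalGrid,
                  plane_id: str) -> PlaneSummary:
    """Extract the section-mean normal velocity and pressure on plane A
    or B (vertical stations in the parent artery)."""
    i = {"A": grid.plane_a, "B": grid.plane_b}.get(plane_id)
    if i is None:
        raise ValueError(f"plane {plane_id!r} not placed on this grid")
    fl = grid.fluid
    rows = np.flatnonzero(fl[i - 1, :] & fl[i, :]) if 0 < i < grid.nx \
        else np.flatnonzero(fl[min(i, grid.nx - 1), :])
    v_avg = float(np.mean(field.u[i, rows]))
    if 0 < i < grid.nx:
        p_avg = float(np.mean(0.5 * (field.p[i - 1, rows]
                                     + field.p[i, rows])))
    else:
        p_avg = float(np.mean(field.p[min(i, grid.nx - 1), rows]))
    area = rows.size * grid.spacing * grid.depth
    return PlaneSummary(plane_id=plane_id, v_avg=v_avg, p_avg=p_avg,
                        area=area)


def energy_loss(inlet: PlaneSummary, outlet: PlaneSummary,
                rho: float, v_m: float) -> float:
    """Volumetric mechanical-energy loss rate between two planes (W/m^3):

        EL = v_in A [ (rho v_in^2 / 2 + P_in) - (rho v_out^2 / 2 + P_out) ] / V_m
    """
    if v_m <= 0:
        raise ValueError("inter-plane volume must be positive")
    if inlet.area <= 0:
        raise ValueError("inlet plane area must be positive")
    total_in = 0.5 * rho * inlet.v_avg**2 + inlet.p_avg
    total_out = 0.5 * rho * outlet.v_avg**2 + outlet.p_avg
    return inlet.v_avg * inlet.area * (total_in - total_out) / v_m


def _neck_faces(field: FlowField, grid: ComputationalGrid):
    cols = grid.neck_columns
    if cols.size == 0:
        raise ValueError("grid has no neck plane (plane C undefined)")
    jw = grid.j_wall
    vn = field.v[cols, jw]
    # tangential component interpolated to the face centers
    u_at = 0.25 * (field.u[cols, jw - 1] + field.u[cols + 1, jw - 1]
                   + field.u[cols, jw] + field.u[cols + 1, jw])
    return vn, u_at


def neck_inflow_rate(field: FlowField, grid: ComputationalGrid) -> float:
    """Sac-directed volume flux through plane C, in mm^3/s.

    Only faces with velocity into the sac contribute; outflow faces are
    excluded.  The per-depth flux is scaled by the unit-depth convention.
    """
    vn, _ = _neck_faces(field, grid)
    q = float(np.sum(np.maximum(vn, 0.0)) * grid.spacing * grid.depth)
    return q * 1e9  # m^3/s -> mm^3/s


def neck_average_velocity(field: FlowField, grid: ComputationalGrid) -> float:
    """Area-averaged magnitude of the plane-normal velocity over the
    plane C faces (m/s).

    The tangential component is deliberately excluded: on the screen
    line it is dominated by parent-jet slip, which measures the parent
    flow rather than trans-neck exchange.
    """
    vn, _ = _neck_faces(field, grid)
    return float(np.mean(np.abs(vn)))


def reduction_rate(control_value: float, device_value: float) -> float:
    """Percent decrease relative to the unstented control."""
    if control_value <= 0:
        raise ValueError("control value must be positive")
    return 100.0 * (control_value - device_value) / control_value


def sac_to_neck_speed_ratio(field: FlowField, grid: ComputationalGrid) -> float:
    """Mean sac-interior speed over mean neck-plane speed.

    A small ratio indicates hemodynamic separation of dome and neck (the
    qualitative 'silent vortex' regime); reported per row, not asserted.
    """
    from .geometry import FLUID_SAC
    speed = field.speed()
    sac = grid.cell_mask == FLUID_SAC
    neck_speed = neck_average_velocity(field, grid)
    if neck_speed == 0:
        return float("nan")
    return float(speed[sac].mean() / neck_speed)


def summarize(field: FlowField, grid: ComputationalGrid, rho: float,
              mcr: float, config_label: str,
              control: HemodynamicSummary | None = None) -> HemodynamicSummary:
    """Build one study-table row from a systolic field.

    ``control=None`` marks the row itself as the control (reductions 0
    by construction).
    """
    a = plane_summary(field, grid, "A")
    b = plane_summary(field, grid, "B")
    if grid.inter_plane_volume is None:
        raise ValueError("planes not placed: V_m unavailable")
    el = energy_loss(a, b, rho, grid.inter_plane_volume)
    vel = neck_average_velocity(field, grid)
    q = neck_inflow_rate(field, grid)
    if control is None:
        red = (0.0, 0.0, 0.0)
    else:
        red = (reduction_rate(control.energy_loss, el),
               reduction_rate(control.avg_velocity, vel),
               reduction_rate(control.inflow_rate, q))
    return HemodynamicSummary(
        config_label=config_label, mcr=mcr, energy_loss=el,
        avg_velocity=vel, inflow_rate=q,
        el_reduction_pct=red[0], vel_reduction_pct=red[1],
        inflow_reduction_pct=red[2])
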