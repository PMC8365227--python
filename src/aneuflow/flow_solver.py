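"""2D incompressible pulsatile flow through the (stented) aneurysm domain.

Staggered (MAC) grid, Chorin projection.  Per step: explicit
upwind-biased advection and explicit diffusion build a tentative
velocity; the stent screen applies an implicit local momentum sink on
the neck-interface faces; a pressure Poisson solve (5-point stencil,
prefactorized sparse LU, machine-precision residual) projects the field
to discrete divergence-free.  Boundary conditions: analytic oscillatory
channel (Womersley-type) velocity profile at the inlet, zero pressure at
the outlet, rigid no-slip walls (tangential ghost reflection, normal
face velocity exactly zero).

The device itself is not resolved: it enters only as a homogenized
screen whose per-face solidity comes from :mod:`aneuflow.stent_model`.
The screen imposes a pressure jump

    dp = -(1/2) * rho * K(s) * |u_n| * u_n  -  R_visc(s) * u_n

with the screen-drag loss law ``K(s) = c1 * s / (1 - s)^2`` and a
Kozeny-type viscous term ``R_visc = c2 * (mu / h) * s^2 / (1 - s)^3``,
both vanishing at s = 0 so an empty screen reproduces the unstented
field bit-for-bit.  In the projection the screen faces carry a reduced
conductivity ``1 - s`` (open-area fraction), kept constant over a run so
the Poisson operator can be factorized once.

The scheme is fully deterministic: no randomness anywhere, identical
configuration gives identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from .geometry import ComputationalGrid

__all__ = [
    "InstabilityError",
    "FluidProperties",
    "BLOOD",
    "VALIDATION_FLUID",
    "PulsatileWaveform",
    "default_ica_waveform",
    "ScreenModel",
    "FlowField",
    "womersley_inlet_profile",
    "ProjectionSolver",
    "CycleRunResult",
    "run_cycles",
]


class InstabilityError(RuntimeError):
    """The time integration produced NaN/Inf fields."""


@dataclass(frozen=True)
class FluidProperties:
    """Newtonian fluid: density (kg/m^3) and dynamic viscosity (Pa s)."""

    density: float
    viscosity: float

    def __post_init__(self) -> None:
        if self.density <= 0 or self.viscosity <= 0:
            raise ValueError("density and viscosity must be positive")

    @property
    def kinematic_viscosity(self) -> float:
        return self.viscosity / self.density


#: blood preset used for the stented runs
BLOOD = FluidProperties(density=1055.0, viscosity=0.004)
#: working-fluid preset of the process-validation experiment
VALIDATION_FLUID = FluidProperties(density=1200.0, viscosity=0.0038)


@dataclass(frozen=True)
class PulsatileWaveform:
    """Harmonic decomposition of the inlet section-mean velocity.

    mean_velocity_at(t) = mean * (1) + sum_k a_k cos(2 pi k t / T + phi_k)
    with ``harmonics`` = [(a_1, phi_1), ...] in m/s and radians.
    """

    period: float
    mean_velocity: float
    harmonics: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if self.period <= 0:
            raise ValueError("period must be positive")
        if self.mean_velocity <= 0:
            raise ValueError("mean velocity must be positive")
        if len(self.harmonics) < 1:
            raise ValueError("need at least one harmonic")
        t = np.linspace(0.0, self.period, 512, endpoint=False)
        if np.min(self.mean_velocity_at(t)) <= 0:
            raise ValueError("waveform must stay positive over the cycle")

    def mean_velocity_at(self, t: float | np.ndarray) -> float | np.ndarray:
        t = np.asarray(t, dtype=float)
        u = np.full(t.shape, self.mean_velocity)
        omega0 = 2.0 * math.pi / self.period
        for k, (amp, phase) in enumerate(self.harmonics, start=1):
            u = u + amp * np.cos(k * omega0 * t + phase)
        return float(u) if u.ndim == 0 else u

    def systolic_time(self, n_samples: int = 4096) -> float:
        """Phase of peak section-mean velocity within one period."""
        t = np.linspace(0.0, self.period, n_samples, endpoint=False)
        return float(t[np.argmax(self.mean_velocity_at(t))])

    def womersley_number(self, fluid: FluidProperties,
                         parent_diameter: float) -> float:
        """alpha = R sqrt(omega rho / mu) for the fundamental mode."""
        radius = 0.5 * parent_diameter
        return radius * math.sqrt(
            2.0 * math.pi * fluid.density / (self.period * fluid.viscosity))


def default_ica_waveform(period: float = 1.0,
                         mean_velocity: float = 0.25) -> PulsatileWaveform:
    """Carotid-like two-harmonic waveform (amplitudes 0.4 and 0.1 of the
    mean, phases 0 and pi/2).  The shape is a modeling choice, recorded
    in every run manifest; only relative comparisons depend on it."""
    return PulsatileWaveform(
        period=period,
        mean_velocity=mean_velocity,
        harmonics=((0.4 * mean_velocity, 0.0),
                   (0.1 * mean_velocity, 0.5 * math.pi)),
    )


@dataclass(frozen=True)
class ScreenModel:
    """Homogenized stent screen at the neck interface.

    ``solidity_profile`` holds one blocked-area fraction per open neck
    face (ordered along the chord).  ``loss_coefficient_scale`` (c1) and
    ``viscous_permeability_scale`` (c2) scale the inertial and viscous
    parts of the pressure-jump law.  ``feature_width`` is the metal
    feature size (wire diameter / strut width) setting the Kozeny
    permeability scale of the screen.
    """

    solidity_profile: np.ndarray
    loss_coefficient_scale: float = 1.0
    viscous_permeability_scale: float = 1.0
    feature_width: float = 5.0e-5

    def __post_init__(self) -> None:
        s = np.asarray(self.solidity_profile, dtype=float)
        if np.any(s < 0) or np.any(s >= 1):
            raise ValueError("solidities must lie in [0, 1)")
        object.__setattr__(self, "solidity_profile", s)

    @classmethod
    def uniform(cls, solidity: float, n_faces: int, **kw) -> "ScreenModel":
        return cls(np.full(n_faces, float(solidity)), **kw)

    def loss_coefficient(self, s: np.ndarray) -> np.ndarray:
        """Inertial screen-drag coefficient K(s) = c1 s / (1-s)^2."""
        s = np.asarray(s, dtype=float)
        return self.loss_coefficient_scale * s / (1.0 - s) ** 2

    def viscous_resistance(self, s: np.ndarray,
                           viscosity: float) -> np.ndarray:
        """Kozeny-type viscous resistance (Pa s / m) of the screen.

        Permeability ``k = d^2 (1-s)^3 / (180 s^2)`` (Kozeny-Carman with
        feature size d) over a screen thickness of two feature widths:
        R = 360 c2 mu s^2 / (d (1-s)^3).
        """
        s = np.asarray(s, dtype=float)
        return (360.0 * self.viscous_permeability_scale * viscosity
                / self.feature_width * s**2 / (1.0 - s) ** 3)


@dataclass
class FlowField:
    """Staggered velocity/pressure state at one time instant.

    ``u`` (nx+1, ny) on vertical faces, ``v`` (nx, ny+1) on horizontal
    faces, ``p`` (nx, ny) cell-centered.
    """

    u: np.ndarray
    v: np.ndarray
    p: np.ndarray
    time: float = 0.0
    cycle_index: int = 0

    def copy(self) -> "FlowField":
        return FlowField(self.u.copy(), self.v.copy(), self.p.copy(),
                         self.time, self.cycle_index)

    def speed(self) -> np.ndarray:
        """Cell-centered speed magnitude."""
        uc = 0.5 * (self.u[:-1, :] + self.u[1:, :])
        vc = 0.5 * (self.v[:, :-1] + self.v[:, 1:])
        return np.hypot(uc, vc)


def womersley_inlet_profile(waveform: PulsatileWaveform,
                            fluid: FluidProperties,
                            channel_height: float,
                            t: float,
                            y: np.ndarray) -> np.ndarray:
    """Exact oscillatory plane-channel velocity profile at time ``t``.

    ``y`` are cross-stream positions in (0, H).  The steady term is the
    plane-Poiseuille parabola with section mean ``mean_velocity``; each
    harmonic is the closed-form cosh-ratio solution normalized so its
    section mean equals the harmonic's instantaneous amplitude.  The
    continuum section average therefore equals ``mean_velocity_at(t)``.
    """
    y = np.asarray(y, dtype=float)
    xi = 2.0 * y / channel_height - 1.0
    prof = 1.5 * waveform.mean_velocity * (1.0 - xi**2)
    nu = fluid.kinematic_viscosity
    omega0 = 2.0 * math.pi / waveform.period
    half = 0.5 * channel_height
    for k, (amp, phase) in enumerate(waveform.harmonics, start=1):
        if amp == 0.0:
            continue
        omega = k * omega0
        lam = np.sqrt(1j * omega / nu)  # principal branch
        Lam = lam * half
        shape = (1.0 - np.cosh(Lam * xi) / np.cosh(Lam))
        shape /= (1.0 - np.tanh(Lam) / Lam)
        prof = prof + np.real(amp * np.exp(1j * (omega * t + phase)) * shape)
    return prof


class ProjectionSolver:
    """Pressure-projection integrator bound to one grid/fluid/screen.

    The Poisson operator (including the reduced conductivity of screen
    faces and the outlet Dirichlet closure) is assembled and LU-factorized
    once at construction.
    """

    def __init__(self, grid: ComputationalGrid, fluid: FluidProperties,
                 waveform: PulsatileWaveform | None,
                 screen: ScreenModel | None = None,
                 cfl: float = 0.4):
        self.grid = grid
        self.fluid = fluid
        self.waveform = waveform
        self.screen = screen
        self.cfl = cfl
        self.h = grid.spacing
        nx, ny = grid.nx, grid.ny
        fl = grid.fluid

        # --- face bookkeeping -------------------------------------------
        u_unknown = np.zeros((nx + 1, ny), dtype=bool)
        u_unknown[1:nx, :] = fl[:-1, :] & fl[1:, :]
        u_inlet = np.zeros((nx + 1, ny), dtype=bool)
        u_inlet[0, :] = fl[0, :]
        u_outlet = np.zeros((nx + 1, ny), dtype=bool)
        u_outlet[nx, :] = fl[nx - 1, :]
        self.u_unknown, self.u_inlet, self.u_outlet = u_unknown, u_inlet, u_outlet
        self.u_valued = u_unknown | u_inlet | u_outlet

        v_unknown = np.zeros((nx, ny + 1), dtype=bool)
        v_unknown[:, 1:ny] = fl[:, :-1] & fl[:, 1:]
        self.v_unknown = v_unknown

        # screen faces sit on the wall line across the open neck columns
        self.screen_faces = np.zeros((nx, ny + 1), dtype=bool)
        self.beta_v = np.ones((nx, ny + 1))
        self._gamma_lin = np.zeros((nx, ny + 1))   # viscous drag / (rho h)
        self._gamma_quad = np.zeros((nx, ny + 1))  # 0.5 K(s) / h
        if screen is not None:
            cols = grid.neck_columns
            s = np.asarray(screen.solidity_profile, dtype=float)
            if s.size != cols.size:
                raise ValueError(
                    f"screen profile has {s.size} faces, neck has {cols.size}")
            jw = grid.j_wall
            self.screen_faces[cols, jw] = v_unknown[cols, jw]
            rv = screen.viscous_resistance(s, fluid.viscosity)
            kk = screen.loss_coefficient(s)
            self._gamma_lin[cols, jw] = rv / (fluid.density * self.h)
            self._gamma_quad[cols, jw] = 0.5 * kk / self.h
            self.beta_v[cols, jw] = 1.0 - s

        # --- tangential ghost coefficients ------------------------------
        # eff_neighbor = m * value + q * self ; wall (m=0,q=-1),
        # zero-gradient open boundary (m=0,q=+1), fluid neighbor (1,0)
        def shift_valued(valued, axis, step):
            out = np.zeros_like(valued)
            if axis == 0:
                if step > 0:
                    out[:-1, :] = valued[1:, :]
                else:
                    out[1:, :] = valued[:-1, :]
            else:
                if step > 0:
                    out[:, :-1] = valued[:, 1:]
                else:
                    out[:, 1:] = valued[:, :-1]
            return out

        uv = self.u_valued
        self.u_mN = shift_valued(uv, 1, +1).astype(float)
        self.u_mS = shift_valued(uv, 1, -1).astype(float)
        self.u_qN = np.where(self.u_mN > 0, 0.0, -1.0)
        self.u_qS = np.where(self.u_mS > 0, 0.0, -1.0)

        vv = v_unknown
        self.v_mE = shift_valued(vv, 0, +1).astype(float)
        self.v_mW = shift_valued(vv, 0, -1).astype(float)
        self.v_qE = np.where(self.v_mE > 0, 0.0, -1.0)
        self.v_qW = np.where(self.v_mW > 0, 0.0, -1.0)
        # outlet column: zero-gradient for tangential v
        self.v_qE[nx - 1, :] = np.where(self.v_mE[nx - 1, :] > 0, 0.0, 1.0)

        # inlet profile sample points (v-face heights of open inlet rows)
        self.inlet_rows = np.flatnonzero(fl[0, :])
        self.inlet_y = (self.inlet_rows + 0.5) * self.h

        self._assemble_poisson()

    # -----------------------------------------------------------------
    def _assemble_poisson(self) -> None:
        grid, nx, ny = self.grid, self.grid.nx, self.grid.ny
        fl = grid.fluid
        idx = -np.ones((nx, ny), dtype=np.int64)
        cells = np.argwhere(fl)
        idx[fl] = np.arange(cells.shape[0])
        self._cell_index = idx
        self._cells = cells
        n = cells.shape[0]
        rows, cols_, vals = [], [], []
        diag = np.zeros(n)
        for c, (i, j) in enumerate(cells):
            # east
            if i + 1 < nx and fl[i + 1, j]:
                g = 1.0
                diag[c] -= g
                rows.append(c); cols_.append(idx[i + 1, j]); vals.append(g)
            elif i + 1 == nx:
                diag[c] -= 2.0  # outlet: p = 0 on the face
            # west (inlet face is prescribed velocity -> Neumann)
            if i - 1 >= 0 and fl[i - 1, j]:
                g = 1.0
                diag[c] -= g
                rows.append(c); cols_.append(idx[i - 1, j]); vals.append(g)
            # north
            if j + 1 < ny and fl[i, j + 1]:
                g = self.beta_v[i, j + 1]
                diag[c] -= g
                rows.append(c); cols_.append(idx[i, j + 1]); vals.append(g)
            # south
            if j - 1 >= 0 and fl[i, j - 1]:
                g = self.beta_v[i, j]
                diag[c] -= g
                rows.append(c); cols_.append(idx[i, j - 1]); vals.append(g)
        rows.extend(range(n)); cols_.extend(range(n)); vals.extend(diag)
        A = sp.csc_matrix(
            sp.coo_matrix((vals, (rows, cols_)), shape=(n, n)))
        self._lu = splu(A)

    # -----------------------------------------------------------------
    def initial_field(self, t: float = 0.0,
                      developed: bool = True) -> FlowField:
        """Zero field, or the analytic channel profile swept axially."""
        nx, ny = self.grid.nx, self.grid.ny
        f = FlowField(np.zeros((nx + 1, ny)), np.zeros((nx, ny + 1)),
                      np.zeros((nx, ny)), time=t)
        if developed:
            prof = self.inlet_profile(t)
            f.u[:, self.inlet_rows] = prof[None, :]
            f.u[~self.u_valued] = 0.0
        return f

    def inlet_profile(self, t: float) -> np.ndarray:
        if self.waveform is None:  # quiescent configuration
            return np.zeros(self.inlet_rows.size)
        return womersley_inlet_profile(
            self.waveform, self.fluid, self.grid.channel_height,
            t, self.inlet_y)

    def stable_dt(self, fieldv: FlowField) -> float:
        h, nu = self.h, self.fluid.kinematic_viscosity
        wf_scale = 1.5 * self.waveform.mean_velocity \
            if self.waveform is not None else 1e-9
        vmax = max(np.max(np.abs(fieldv.u)), np.max(np.abs(fieldv.v)),
                   wf_scale)
        dt_adv = h / vmax
        dt_diff = h * h / (4.0 * nu)
        return self.cfl * min(dt_adv, dt_diff)

    # -----------------------------------------------------------------
    def step(self, fieldv: FlowField, dt: float | None = None) -> FlowField:
        """Advance one projection step; returns a new FlowField."""
        if dt is None:
            dt = self.stable_dt(fieldv)
        h, nu, rho = self.h, self.fluid.kinematic_viscosity, self.fluid.density
        nx, ny = self.grid.nx, self.grid.ny
        u, v = fieldv.u, fieldv.v
        t_new = fieldv.time + dt

        # ---- tentative u ------------------------------------------------
        us = u[1:nx, :]  # interior faces (view)
        uE, uW = u[2:, :], u[:nx - 1, :]
        mN, qN = self.u_mN[1:nx, :], self.u_qN[1:nx, :]
        mS, qS = self.u_mS[1:nx, :], self.u_qS[1:nx, :]
        uN_full = np.zeros_like(us); uN_full[:, :-1] = u[1:nx, 1:]
        uS_full = np.zeros_like(us); uS_full[:, 1:] = u[1:nx, :-1]
        effN = mN * uN_full + qN * us
        effS = mS * uS_full + qS * us
        v_at_u = 0.25 * (v[:nx - 1, :ny] + v[:nx - 1, 1:]
                         + v[1:, :ny] + v[1:, 1:])
        dudx_b = (us - uW) / h
        dudx_f = (uE - us) / h
        dudy_b = (us - effS) / h
        dudy_f = (effN - us) / h
        adv_u = (np.where(us > 0, us * dudx_b, us * dudx_f)
                 + np.where(v_at_u > 0, v_at_u * dudy_b, v_at_u * dudy_f))
        lap_u = (uE + uW + effN + effS - 4.0 * us) / (h * h)
        u_star = u.copy()
        u_star[1:nx, :] = us + dt * (nu * lap_u - adv_u)
        u_star[~self.u_valued] = 0.0
        u_star[0, self.inlet_rows] = self.inlet_profile(t_new)
        u_star[nx, :] = 0.0
        u_star[nx, self.u_outlet[nx, :]] = u_star[nx - 1, self.u_outlet[nx, :]]

        # ---- tentative v ------------------------------------------------
        vs = v[:, 1:ny]
        vN, vS = v[:, 2:], v[:, :ny - 1]
        vE_full = np.zeros_like(vs); vE_full[:-1, :] = v[1:, 1:ny]
        vW_full = np.zeros_like(vs); vW_full[1:, :] = v[:-1, 1:ny]
        mE, qE = self.v_mE[:, 1:ny], self.v_qE[:, 1:ny]
        mW, qW = self.v_mW[:, 1:ny], self.v_qW[:, 1:ny]
        effE = mE * vE_full + qE * vs
        effW = mW * vW_full + qW * vs
        u_at_v = 0.25 * (u[:nx, :ny - 1] + u[:nx, 1:]
                         + u[1:, :ny - 1] + u[1:, 1:])
        dvdy_b = (vs - vS) / h
        dvdy_f = (vN - vs) / h
        dvdx_b = (vs - effW) / h
        dvdx_f = (effE - vs) / h
        adv_v = (np.where(u_at_v > 0, u_at_v * dvdx_b, u_at_v * dvdx_f)
                 + np.where(vs > 0, vs * dvdy_b, vs * dvdy_f))
        lap_v = (vN + vS + effE + effW - 4.0 * vs) / (h * h)
        v_star = v.copy()
        v_star[:, 1:ny] = vs + dt * (nu * lap_v - adv_v)
        v_star[~self.v_unknown] = 0.0

        # ---- screen momentum sink (implicit, local) --------------------
        if self.screen is not None:
            sf = self.screen_faces
            gamma = dt * (self._gamma_lin[sf]
                          + self._gamma_quad[sf] * np.abs(v_star[sf]))
            v_star[sf] = v_star[sf] / (1.0 + gamma)

        # ---- projection -------------------------------------------------
        fl = self.grid.fluid
        div = ((u_star[1:, :] - u_star[:-1, :])
               + (v_star[:, 1:] - v_star[:, :-1])) / h
        rhs = (rho * h * h / dt) * div[fl]
        phi_flat = self._lu.solve(rhs)
        phi = np.zeros((nx, ny))
        phi[fl] = phi_flat

        coef = dt / (rho * h)
        u_new = u_star
        interior = self.u_unknown[1:nx, :]
        dphi = phi[1:, :] - phi[:-1, :]
        u_new[1:nx, :][interior] -= coef * dphi[interior]
        out_rows = self.u_outlet[nx, :]
        u_new[nx, out_rows] -= coef * (-2.0 * phi[nx - 1, out_rows])

        v_new = v_star
        vint = self.v_unknown[:, 1:ny]
        dphi_y = (phi[:, 1:] - phi[:, :-1]) * self.beta_v[:, 1:ny]
        v_new[:, 1:ny][vint] -= coef * dphi_y[vint]

        if not (np.all(np.isfinite(u_new)) and np.all(np.isfinite(v_new))):
            raise InstabilityError(
                f"non-finite velocity at t={t_new:.6g} (dt={dt:.3g})")

        cyc = int(t_new / self.waveform.period) if self.waveform else 0
        return FlowField(u_new, v_new, phi, time=t_new, cycle_index=cyc)

    # -----------------------------------------------------------------
    def divergence(self, fieldv: FlowField) -> np.ndarray:
        div = ((fieldv.u[1:, :] - fieldv.u[:-1, :])
               + (fieldv.v[:, 1:] - fieldv.v[:, :-1])) / self.h
        return np.where(self.grid.fluid, div, 0.0)

    def inlet_flux(self, fieldv: FlowField) -> float:
        """Volume flux in through the inlet (m^3/s, with unit depth)."""
        return float(np.sum(fieldv.u[0, self.inlet_rows])
                     * self.h * self.grid.depth)

    def outlet_flux(self, fieldv: FlowField) -> float:
        """Volume flux out through the outlet (m^3/s, with unit depth)."""
        rows = self.u_outlet[self.grid.nx, :]
        return float(np.sum(fieldv.u[self.grid.nx, rows])
                     * self.h * self.grid.depth)


@dataclass
class CycleRunResult:
    """Outcome of a multi-cycle run."""

    systolic_field: FlowField
    systolic_fields_per_cycle: list[FlowField]
    snapshots: list[FlowField] = dc_field(default_factory=list)
    n_steps: int = 0
    final_time: float = 0.0

    @property
    def systolic_time(self) -> float:
        return self.systolic_field.time


def run_cycles(solver: ProjectionSolver, n_cycles: int = 3,
               snapshot_stride: int = 0,
               initial_field: FlowField | None = None) -> CycleRunResult:
    """Integrate ``n_cycles`` cardiac periods and capture the systolic
    snapshot of each cycle (field at the step of peak inlet section-mean
    velocity).  The returned ``systolic_field`` is the last cycle's.
    """
    T = solver.waveform.period
    t_end = n_cycles * T
    fieldv = initial_field if initial_field is not None \
        else solver.initial_field(0.0)
    per_cycle: list[FlowField | None] = [None] * n_cycles
    peak: list[float] = [-np.inf] * n_cycles
    snapshots: list[FlowField] = []
    n_steps = 0
    eps = 1e-12
    while fieldv.time < t_end - eps:
        dt = min(solver.stable_dt(fieldv), t_end - fieldv.time)
        fieldv = solver.step(fieldv, dt)
        n_steps += 1
        cyc = min(int((fieldv.time - eps) / T), n_cycles - 1)
        mean_now = solver.waveform.mean_velocity_at(fieldv.time)
        if mean_now > peak[cyc]:
            peak[cyc] = mean_now
            per_cycle[cyc] = fieldv.copy()
        if snapshot_stride and n_steps % snapshot_stride == 0:
            snapshots.append(fieldv.copy())
    per_cycle = [f for f in per_cycle if f is not None]
    return CycleRunResult(
        systolic_field=per_cycle[-1],
        systolic_fields_per_cycle=per_cycle,
        snapshots=snapshots,
        n_steps=n_steps,
        final_time=fieldv.time,
    )
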