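"""Synthetic inputs that make every other module testable offline.

Provides closed-form analytic flow cases (with matching solver
configurations where the solver supports the geometry), the packaged
study-table value fixture, and reduced study matrices for fast sweeps.

The process-validation experiment behind the original study compared CFD
against external PIV measurements; that dataset is not distributable, so
closed-form solutions substitute for it here.  The validation working
fluid (1200 kg/m^3, 0.0038 Pa s) is retained as a named preset in
:mod:`aneuflow.flow_solver`.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass
from importlib import resources
from typing import Callable

import numpy as np
import pandas as pd

from .flow_solver import (FluidProperties, PulsatileWaveform,
                          VALIDATION_FLUID, womersley_inlet_profile)

__all__ = [
    "AnalyticCase",
    "make_case",
    "table1_fixture",
    "TABLE1_SHA256",
    "reduced_matrix",
    "FixturePackagingError",
]

#: checksum of the packaged study-table CSV (exact printed digits)
TABLE1_SHA256 = "247a60994b906e734fe6771e26523e06802ff8e0555ffc1d869d79e17a339cfe"


class FixturePackagingError(RuntimeError):
    """The packaged fixture does not match its recorded checksum."""


@dataclass(frozen=True)
class AnalyticCase:
    """A closed-form flow with an exact evaluator.

    ``evaluate`` maps (y, t) to an axial-velocity profile for channel
    cases, or (x, y, t) to a (u, v) tuple for the periodic-box case.
    ``solver_config`` is a dict of keyword inputs (channel height,
    fluid, waveform, suggested spacing) for running the flow solver
    against the case, or ``None`` where the solver does not support the
    required boundary conditions (periodic box).
    """

    case_id: str
    parameters: dict
    evaluate: Callable
    solver_config: dict | None


def _poiseuille(params: dict) -> AnalyticCase:
    height = params.get("channel_height", 4e-3)
    mean = params.get("mean_velocity", 0.25)
    fluid = params.get("fluid", VALIDATION_FLUID)

    def evaluate(y, t=0.0):
        xi = 2.0 * np.asarray(y) / height - 1.0
        return 1.5 * mean * (1.0 - xi**2)

    waveform = PulsatileWaveform(period=params.get("period", 1.0),
                                 mean_velocity=mean,
                                 harmonics=((0.0, 0.0),))
    return AnalyticCase(
        "poiseuille", dict(params, channel_height=height, mean_velocity=mean),
        evaluate,
        dict(channel_height=height, channel_length=3.0 * height,
             fluid=fluid, waveform=waveform, spacing=height / 40.0))


def _womersley(params: dict) -> AnalyticCase:
    height = params.get("channel_height", 4e-3)
    mean = params.get("mean_velocity", 0.25)
    amp = params.get("amplitude", 0.1)
    phase = params.get("phase", 0.0)
    period = params.get("period", 1.0)
    fluid = params.get("fluid", VALIDATION_FLUID)
    waveform = PulsatileWaveform(period=period, mean_velocity=mean,
                                 harmonics=((amp, phase),))

    def evaluate(y, t):
        return womersley_inlet_profile(waveform, fluid, height, t,
                                       np.asarray(y))

    return AnalyticCase(
        "womersley_single_harmonic",
        dict(params, channel_height=height, mean_velocity=mean,
             amplitude=amp, period=period),
        evaluate,
        dict(channel_height=height, channel_length=3.0 * height,
             fluid=fluid, waveform=waveform, spacing=height / 40.0))


def _zero_flow(params: dict) -> AnalyticCase:
    def evaluate(y, t=0.0):
        return np.zeros_like(np.asarray(y, dtype=float))

    return AnalyticCase("zero_flow", dict(params), evaluate,
                        dict(channel_height=params.get("channel_height", 4e-3),
                             channel_length=12e-3,
                             fluid=params.get("fluid", VALIDATION_FLUID),
                             waveform=None, spacing=2e-4))


def _taylor_green(params: dict) -> AnalyticCase:
    """Decaying vortex array on a periodic box of side L.

    Kinetic energy decays as E(t) = E0 exp(-4 nu k^2 t), k = 2 pi / L.
    Evaluator only: the solver has no periodic boundaries, so this case
    validates analytic machinery, not the integrator.
    """
    L = params.get("box_size", 1e-2)
    u0 = params.get("amplitude", 0.1)
    fluid = params.get("fluid", VALIDATION_FLUID)
    k = 2.0 * math.pi / L
    nu = fluid.kinematic_viscosity

    def evaluate(x, y, t):
        decay = math.exp(-2.0 * nu * k * k * t)
        u = u0 * np.cos(k * np.asarray(x)) * np.sin(k * np.asarray(y)) * decay
        v = -u0 * np.sin(k * np.asarray(x)) * np.cos(k * np.asarray(y)) * decay
        return u, v

    return AnalyticCase("taylor_green",
                        dict(params, box_size=L, amplitude=u0), evaluate, None)


_CASES = {
    "poiseuille": _poiseuille,
    "womersley_single_harmonic": _womersley,
    "zero_flow": _zero_flow,
    "taylor_green": _taylor_green,
}


def make_case(case_id: str, params: dict | None = None) -> AnalyticCase:
    """Build an analytic case by id with optional parameter overrides."""
    if case_id not in _CASES:
        raise KeyError(f"unknown case {case_id!r}; have {sorted(_CASES)}")
    return _CASES[case_id](dict(params or {}))


def table1_fixture() -> pd.DataFrame:
    """The packaged 10-row study table (MCR %, EL, velocity, inflow and
    their printed reduction rates), with the exact printed significant
    digits.  Verified against a recorded checksum at load time."""
    data = (resources.files("aneuflow.data") / "table1.csv").read_bytes()
    digest = hashlib.sha256(data).hexdigest()
    if digest != TABLE1_SHA256:
        raise FixturePackagingError(
            f"table fixture checksum mismatch: {digest}")
    from io import BytesIO
    return pd.read_csv(BytesIO(data))


def reduced_matrix(n_levels: int):
    """Control plus ``n_levels`` uniform-solidity screens, evenly spaced
    in [0, 0.65], on the coarse fast preset (0.2 mm spacing, 3 cycles of
    a 0.5 s period).  Finishes in minutes on one CPU."""
    from .study_pipeline import StudyMatrix, StudyRow
    if not 2 <= n_levels <= 6:
        raise ValueError("n_levels must be between 2 and 6")
    solidities = np.linspace(0.0, 0.65, n_levels)
    rows = [StudyRow(label="Control")]
    rows += [StudyRow(label=f"screen s={s:.3f}", solidity=float(s))
             for s in solidities]
    return StudyMatrix(rows=rows, grid_spacing=2e-4, parent_length=24e-3,
                       period=0.5)
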