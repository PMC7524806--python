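"""Calcium-target master regulation, growth, and the open-loop comparison.

The controller is a per-channel integral feedback on the calcium error,

    tau_mu_i * dmu_i/dt = Ca_target - [Ca],
    tau_g   * dg_i/dt  = mu_i - g_i,

with transcription timescales chosen inversely proportional to the model's
own maximal conductances (tau_mu_i = constant / gbar_i), which makes the
reference conductance ratios a fixed direction of the controller: over any
interval the conductance increments obey dg_j/dg_i = tau_mu_i/tau_mu_j, so
all regulated motion lies along the ray through the model's conductance
vector.  Growth enters as linear area increase that dilutes conductance
densities (the thin-shell calcium volume scales with area, so the calcium
flux prefactor is size-invariant).

The timescale constant defaults to 2e6 ms: the inverse-conductance rule
fixes all timescale *ratios* (which carry the direction law); the constant
itself only sets the overall regulation speed and is calibrated so the
integral loop is slow compared with tau_g and the calcium dynamics (see
docs/methods.md).  The translation timescale tau_g defaults to 5 s.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import _kernel
from .model import (
    NeuronModel,
    NeuronState,
    SimulationDiverged,
    default_initial_state,
    simulate,
)

__all__ = [
    "TAU_MU_CONSTANT",
    "TAU_G_DEFAULT",
    "RegulationState",
    "GrowthParams",
    "RegulationTrajectory",
    "set_regulation_timescales",
    "integrate_closed_loop",
    "run_closed_loop_to_convergence",
    "integrate_open_loop",
]

TAU_MU_CONSTANT = 2.0e6  # ms * (uS/mm^2); see module docstring
TAU_G_DEFAULT = 5000.0  # ms


@dataclass
class RegulationState:
    """Controller state: per-channel mRNA levels and timescales."""

    mu: np.ndarray  # mRNA, same units as conductance density
    tau_mu: np.ndarray  # ms, per channel
    ca_target: float  # uM
    tau_g: float = TAU_G_DEFAULT  # ms

    def __post_init__(self):
        if np.any(self.tau_mu <= 0) or self.tau_g <= 0:
            raise ValueError("regulation timescales must be positive")


@dataclass(frozen=True)
class GrowthParams:
    """Growth/effector rates.

    ``k`` is the closed-loop linear area growth rate (mm^2/ms).  ``r`` and
    ``r_growth`` are the open-loop effector rates for absolute conductances
    (uS/ms per unit drive) and area (mm^2/ms per unit drive).
    """

    k: float = 0.0
    r: Optional[np.ndarray] = None
    r_growth: float = 0.0
    effector: float = 1.0

    def __post_init__(self):
        if self.k < 0:
            raise ValueError("growth rate k must be >= 0")


@dataclass
class RegulationTrajectory:
    t: np.ndarray  # ms
    gbar: np.ndarray  # (n, 8)
    area: np.ndarray  # mm^2
    Ca: np.ndarray  # uM, instantaneous at sample times
    end_model: NeuronModel
    end_regulation: Optional[RegulationState] = None
    diverged: bool = False


def set_regulation_timescales(model: NeuronModel,
                              ca_target: float,
                              constant: float = TAU_MU_CONSTANT,
                              tau_g: float = TAU_G_DEFAULT) -> RegulationState:
    """Controller tuned to a model: tau_mu_i = constant / gbar_i.

    With this choice the model's own conductance-ratio point is a fixed
    direction of the controller (g_j/g_i = tau_mu_i/tau_mu_j).
    """
    if np.any(model.gbar <= 0):
        raise ValueError("all regulated conductances must be positive "
                         "(zero conductance implies an infinite timescale)")
    tau_mu = constant / model.gbar
    return RegulationState(mu=model.gbar.copy(), tau_mu=tau_mu,
                           ca_target=ca_target, tau_g=tau_g)


def integrate_closed_loop(model: NeuronModel, reg: RegulationState,
                          growth: GrowthParams, t_total: float,
                          dt: float = 0.05, record_stride: int = 2000,
                          initial: Optional[NeuronState] = None,
                          burn_in: float = 5000.0,
                          v_limit: float = 500.0) -> RegulationTrajectory:
    """Co-integrate membrane, calcium, mRNA, conductances and area.

    The membrane is first burned in with the controller frozen (``burn_in``
    ms) so the controller engages on the established limit cycle rather
    than on the artificial initial condition.
    """
    if initial is None:
        initial = default_initial_state(model)
    ca = model.ca_params
    V0, Ca0, m0, h0 = initial.V, initial.Ca, initial.m, initial.h
    if burn_in > 0:
        n_burn = int(round(burn_in / dt))
        _, _, end, div = _kernel.integrate_fixed(
            model.gbar, model.c_flux, ca.tau_ca, ca.ca_inf, ca.ca_out,
            ca.rt_2f, model.cm, dt, n_burn, max(n_burn, 1),
            V0, Ca0, m0, h0, v_limit)
        if div:
            raise SimulationDiverged("divergence during regulation burn-in")
        V0, Ca0, m0, h0 = end[0], end[1], end[2:10], end[10:18]
    n_steps = int(round(t_total / dt))
    g_rec, A_rec, Ca_rec, end, div = _kernel.integrate_regulated(
        model.gbar, reg.mu, reg.tau_mu, reg.tau_g, reg.ca_target, growth.k,
        model.geometry.area, model.c_flux, ca.tau_ca, ca.ca_inf, ca.ca_out,
        ca.rt_2f, model.cm, dt, n_steps, record_stride,
        V0, Ca0, m0, h0, v_limit)
    t = (1 + np.arange(len(g_rec))) * dt * record_stride
    area_end = end[34]
    geo_factor = area_end / model.geometry.area
    end_model = NeuronModel(end[18:26].copy(),
                            geometry=model.geometry.scaled(geo_factor),
                            ca_params=model.ca_params, cm=model.cm)
    end_reg = RegulationState(mu=end[26:34].copy(), tau_mu=reg.tau_mu,
                              ca_target=reg.ca_target, tau_g=reg.tau_g)
    return RegulationTrajectory(t, g_rec, A_rec, Ca_rec, end_model,
                                end_reg, diverged=bool(div))


def run_closed_loop_to_convergence(model: NeuronModel, reg: RegulationState,
                                   dt: float = 0.05,
                                   chunk: float = 50_000.0,
                                   max_time: float = 500_000.0,
                                   tol: float = 0.005,
                                   growth: GrowthParams = GrowthParams(),
                                   burn_in: float = 5000.0):
    """Run the closed loop in chunks until conductances settle.

    Stops when the largest relative conductance change across one chunk is
    below ``tol`` (checked on densities above a small floor), or at
    ``max_time``.  Returns (end_model, converged, t_elapsed, trajectory of
    chunk endpoints).
    """
    current = model
    state = reg
    t_elapsed = 0.0
    prev = model.gbar.copy()
    snapshots = [model.gbar.copy()]
    converged = False
    first = True
    while t_elapsed < max_time:
        traj = integrate_closed_loop(current, state, growth, chunk, dt=dt,
                                     burn_in=burn_in if first else 0.0)
        first = False
        if traj.diverged:
            return traj.end_model, False, t_elapsed, np.array(snapshots)
        current = traj.end_model
        state = traj.end_regulation
        t_elapsed += chunk
        g = current.gbar
        snapshots.append(g.copy())
        floor = 1e-3 * max(g.max(), prev.max(), 1e-12)
        mask = (np.abs(g) > floor) | (np.abs(prev) > floor)
        denom = np.maximum(np.abs(prev), floor)
        if not mask.any() or np.max(np.abs(g - prev)[mask] / denom[mask]) < tol:
            converged = True
            break
        prev = g.copy()
    return current, converged, t_elapsed, np.array(snapshots)


def integrate_open_loop(model: NeuronModel, rates: GrowthParams,
                        t_total: float, n_record: int = 200
                        ) -> RegulationTrajectory:
    """Open-loop co-regulation: a constant effector drive E raises absolute
    conductances (dG_i/dt = r_i E) and area (dA/dt = r_growth E) with no
    calcium feedback.  The linear system is evaluated in closed form on a
    time grid; densities are G_i/A.
    """
    if rates.r is None:
        raise ValueError("open-loop integration requires per-channel rates r")
    r = np.asarray(rates.r, dtype=float)
    A0 = model.geometry.area
    G0 = model.gbar * A0  # absolute conductances, uS
    t = np.linspace(0.0, t_total, n_record)
    E = rates.effector
    area = A0 + rates.r_growth * E * t
    G = G0[None, :] + np.outer(t, r * E)
    gbar = G / area[:, None]
    end_model = NeuronModel(gbar[-1],
                            geometry=model.geometry.scaled(area[-1] / A0),
                            ca_params=model.ca_params, cm=model.cm)
    return RegulationTrajectory(t, gbar, area, np.full_like(t, np.nan),
                                end_model)


def tuned_open_loop_rates(model: NeuronModel, r_growth: float
                          ) -> GrowthParams:
    """Open-loop rates that preserve density exactly at drive E=1:
    r_i/r_growth = G_i0/A0."""
    return GrowthParams(r=model.gbar * r_growth, r_growth=r_growth)
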