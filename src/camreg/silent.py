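"""Analytical prediction of homeostatically trapped silent states.

A regulated neuron can satisfy its calcium set-point while silent if a
steady window current through the calcium channels supplies exactly the
influx that balances buffering at the target concentration.  Such a state
requires simultaneous zeros of the calcium ODE and the voltage ODE under
steady-state gating:

- ``V_Ca``: voltage where the steady calcium current equals the influx
  required to hold [Ca] at the target (depends only on the calcium-channel
  conductances);
- ``V_V``:  voltage where the total steady-state membrane current vanishes
  (with [Ca] frozen at the target for KCa activation and E_Ca).

Points in conductance space where some ``V_V`` coincides with some ``V_Ca``
are candidate silent states; their actual stability is checked by direct
simulation, since the quiescent state can destabilise into subthreshold
oscillations or spiking along the solution curve.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
from scipy.optimize import brentq

from .channels import CHANNEL_ORDER, CHANNELS
from .model import (NeuronModel, NeuronState, nernst_eca, simulate,
                    steady_state_gating)

__all__ = ["SilentSolution", "required_calcium_current",
           "steady_calcium_current", "steady_membrane_current",
           "solve_V_Ca", "solve_V_V", "marginal_stability", "silent_set",
           "validate_branch_by_simulation"]

V_RANGE = (-80.0, 0.0)
_GRID_STEP = 0.5  # mV pre-scan for root bracketing
_ROOT_TOL = 1e-12  # mV


@dataclass
class SilentSolution:
    x: float  # plane coordinates of the solution point
    y: float
    V_V: float  # mV, zero of the voltage ODE
    V_Ca: float  # mV, zero of the calcium ODE (paired root)
    marginal_stability: float  # d(dV/dt)/dV at V_V, 1/ms
    branch: Optional[str] = None  # "stable"/"unstable" by simulation


def required_calcium_current(model: NeuronModel, ca_target: float) -> float:
    """Steady calcium current density (nA/mm^2, negative = inward) that
    holds [Ca] at the target against buffering."""
    ca = model.ca_params
    return -(ca_target - ca.ca_inf) / (ca.tau_ca * model.c_flux)


def steady_calcium_current(model: NeuronModel, V: float,
                           ca_target: float) -> float:
    """i_Ca at steady-state gating with E_Ca evaluated at the target."""
    eca = nernst_eca(model, ca_target)
    ica = 0.0
    for i, name in enumerate(CHANNEL_ORDER):
        spec = CHANNELS[name]
        if not spec.carries_calcium:
            continue
        gate = spec.m_inf(V, ca_target) ** spec.p
        if spec.q:
            gate *= spec.h_inf(V)
        ica += model.gbar[i] * gate * (V - eca)
    return ica


def steady_membrane_current(model: NeuronModel, V: float,
                            ca_target: float) -> float:
    """Total steady-state current density Sum g m_inf^p h_inf^q (V - E)."""
    total = 0.0
    for i, name in enumerate(CHANNEL_ORDER):
        spec = CHANNELS[name]
        gate = spec.m_inf(V, ca_target) ** spec.p
        if spec.q:
            gate *= spec.h_inf(V)
        e = nernst_eca(model, ca_target) if spec.carries_calcium else spec.E
        total += model.gbar[i] * gate * (V - e)
    return total


def _bracketed_roots(f, v_range: Tuple[float, float]) -> List[float]:
    grid = np.arange(v_range[0], v_range[1] + _GRID_STEP / 2, _GRID_STEP)
    vals = np.array([f(v) for v in grid])
    roots = []
    for a, b, fa, fb in zip(grid[:-1], grid[1:], vals[:-1], vals[1:]):
        if fa == 0.0:
            roots.append(float(a))
        elif fa * fb < 0:
            roots.append(float(brentq(f, a, b, xtol=_ROOT_TOL)))
    if len(vals) and vals[-1] == 0.0:
        roots.append(float(grid[-1]))
    return roots


def solve_V_Ca(model: NeuronModel, ca_target: float,
               v_range: Tuple[float, float] = V_RANGE) -> List[float]:
    """Voltages where the calcium ODE is quenched at the target level.

    Empty when the required influx is unattainable — silent trapping is
    impossible below a critical calcium-channel conductance density.
    """
    i_req = required_calcium_current(model, ca_target)

    def f(v):
        return steady_calcium_current(model, v, ca_target) - i_req

    return _bracketed_roots(f, v_range)


def solve_V_V(model: NeuronModel, ca_target: float,
              v_range: Tuple[float, float] = V_RANGE) -> List[float]:
    """Voltages where the steady-state membrane current vanishes."""

    def f(v):
        return steady_membrane_current(model, v, ca_target)

    return _bracketed_roots(f, v_range)


def marginal_stability(model: NeuronModel, V: float, ca_target: float,
                       dv: float = 1e-4) -> float:
    """d(dV/dt)/dV of the steady-state voltage ODE at V (1/ms).

    Positive values mean the voltage fixed point repels perturbations.
    """
    fp = steady_membrane_current(model, V + dv, ca_target)
    fm = steady_membrane_current(model, V - dv, ca_target)
    return -(fp - fm) / (2 * dv) / model.cm


def _mismatch(model: NeuronModel, ca_target: float):
    """Signed V_V - V_Ca for the closest root pair; NaN if either empty."""
    roots_v = solve_V_V(model, ca_target)
    roots_ca = solve_V_Ca(model, ca_target)
    if not roots_v or not roots_ca:
        return np.nan, None, None
    best = None
    for a in roots_v:
        for b in roots_ca:
            if best is None or abs(a - b) < abs(best[0]):
                best = (a - b, a, b)
    return best


def silent_set(plane, ca_target: float, n_x: int = 40, n_y: int = 60,
               match_tol: float = 0.05,
               x_range: Optional[Tuple[float, float]] = None,
               y_range: Optional[Tuple[float, float]] = None
               ) -> List[SilentSolution]:
    """Curve of analytic silent solutions in a 2-D conductance plane.

    For each x on a grid, the signed mismatch ``V_V - V_Ca`` is scanned
    along y and its sign changes refined by bisection until the two
    voltages agree to ``match_tol`` mV.  Regions without calcium-ODE roots
    contribute nothing.  ``plane`` is a :class:`camreg.plane.PlaneDef`.
    """
    x_range = x_range or plane.x_range
    y_range = y_range or plane.y_range
    xs = np.linspace(x_range[0], x_range[1], n_x)
    ys = np.linspace(y_range[0], y_range[1], n_y)
    out: List[SilentSolution] = []
    for x in xs:
        vals = np.array([
            _mismatch(plane.model_at(x, y), ca_target)[0] for y in ys])
        for a, b, fa, fb in zip(ys[:-1], ys[1:], vals[:-1], vals[1:]):
            if not (np.isfinite(fa) and np.isfinite(fb)) or fa * fb > 0:
                continue
            lo, hi, flo = a, b, fa
            for _ in range(40):
                mid = 0.5 * (lo + hi)
                fm = _mismatch(plane.model_at(x, mid), ca_target)[0]
                if not np.isfinite(fm):
                    break
                if abs(fm) < match_tol:
                    lo = hi = mid
                    break
                if np.sign(fm) == np.sign(flo):
                    lo, flo = mid, fm
                else:
                    hi = mid
            y_star = 0.5 * (lo + hi)
            m = plane.model_at(x, y_star)
            diff, vv, vca = _mismatch(m, ca_target)
            if diff is None or not np.isfinite(diff) or abs(diff) > match_tol:
                continue
            out.append(SilentSolution(
                x=float(x), y=float(y_star), V_V=vv, V_Ca=vca,
                marginal_stability=marginal_stability(m, vv, ca_target)))
    return out


def validate_branch_by_simulation(model: NeuronModel, solution: SilentSolution,
                                  ca_target: float, t_sim: float = 20_000.0,
                                  band: float = 2.0, dt: float = 0.05) -> str:
    """Label a silent solution by direct simulation from the fixed point.

    The full model is initialised at (V_V, steady gating, Ca_target) and
    integrated; the state is ``stable`` if the voltage stays within
    ``band`` mV and spike-free, else ``unstable`` (including divergence).
    """
    m, h = steady_state_gating(solution.V_V, ca_target)
    init = NeuronState(V=solution.V_V, Ca=ca_target, m=m, h=h)
    try:
        res = simulate(model, t_sim, dt=dt, initial=init,
                       raise_on_divergence=False)
    except Exception:
        return "unstable"
    if len(res.V) == 0:
        return "unstable"
    if np.max(np.abs(res.V - solution.V_V)) <= band:
        label = "stable"
    else:
        label = "unstable"
    solution.branch = label
    return label
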