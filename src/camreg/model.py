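"""Single-compartment neuron model: types, simulation, calcium readout.

The membrane follows

    C_m dV/dt = -sum_i gbar_i m_i^p h_i^q (V - E_i)

in conductance-density form (uS/mm^2), so the voltage dynamics depend on
cell geometry only through the calcium equation

    d[Ca]/dt = -phi * i_Ca * A / (2 F eta) - ([Ca] - Ca_inf) / tau_Ca,

where ``eta`` is the thin-shell volume accessible to calcium.  Under the
thin-shell assumption ``eta`` scales with the membrane area ``A``, so the
prefactor — and hence the whole dynamical system — is invariant under a pure
size change at fixed densities.  That invariance is the premise of the
growth-compensation analysis and is asserted by the test suite.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Union

import numpy as np

from . import _kernel
from .channels import (
    CHANNEL_ORDER,
    CHANNELS,
    FARADAY,
    RT_2F,
    ChannelSpec,
)

__all__ = [
    "Geometry",
    "CalciumParams",
    "NeuronModel",
    "NeuronState",
    "SimResult",
    "SimulationDiverged",
    "reference_model",
    "REFERENCE_GBAR",
    "steady_state",
    "nernst_eca",
    "total_calcium_current_density",
    "steady_state_gating",
    "default_initial_state",
    "simulate",
    "mean_calcium",
]

#: Reference maximal conductance densities, uS/mm^2.
REFERENCE_GBAR = {
    "A": 379.0,
    "CaS": 165.0,
    "CaT": 2.35,
    "H": 0.72,
    "KCa": 297.0,
    "Kd": 1713.0,
    "Leak": 0.46,
    "NaV": 1370.0,
}


class SimulationDiverged(RuntimeError):
    """Raised when the membrane potential leaves the sanity bound."""


@dataclass(frozen=True)
class Geometry:
    """Cell geometry: membrane area and thin-shell calcium volume.

    Defaults give a 0.0628 mm^2 cell with a ~1.1 um calcium shell, chosen so
    the calcium flux prefactor matches the classic 14.96 uM/nA factor of the
    lineage this model descends from.
    """

    area: float = 0.0628  # mm^2
    eta: float = 0.0628 * 1.1029e-3  # mm^3

    def __post_init__(self):
        if self.area <= 0 or self.eta <= 0:
            raise ValueError("area and eta must be positive")

    def scaled(self, factor: float) -> "Geometry":
        """Grow or shrink the cell, preserving the thin-shell ratio A/eta."""
        return Geometry(self.area * factor, self.eta * factor)


@dataclass(frozen=True)
class CalciumParams:
    phi: float = 0.5  # dimensionless flux scaling
    tau_ca: float = 200.0  # ms
    ca_inf: float = 0.05  # uM
    ca_out: float = 3000.0  # uM, fixed extracellular concentration
    rt_2f: float = RT_2F  # mV, Nernst slope for a divalent ion
    faraday: float = FARADAY

    def __post_init__(self):
        if min(self.phi, self.tau_ca, self.ca_inf, self.ca_out) <= 0:
            raise ValueError("calcium parameters must be strictly positive")


@dataclass(frozen=True)
class NeuronModel:
    """A point in conductance-density space plus geometry and calcium rules."""

    gbar: np.ndarray  # length 8, CHANNEL_ORDER, uS/mm^2
    geometry: Geometry = field(default_factory=Geometry)
    ca_params: CalciumParams = field(default_factory=CalciumParams)
    cm: float = 10.0  # nF/mm^2

    def __post_init__(self):
        g = np.asarray(self.gbar, dtype=float)
        if g.shape != (8,):
            raise ValueError("gbar must be a length-8 vector")
        if np.any(g < 0) or not np.all(np.isfinite(g)):
            raise ValueError("gbar values must be finite and >= 0")
        object.__setattr__(self, "gbar", g)

    @classmethod
    def from_dict(cls, gbar: Mapping[str, float], **kw) -> "NeuronModel":
        vec = np.array([float(gbar[name]) for name in CHANNEL_ORDER])
        return cls(vec, **kw)

    @property
    def gbar_dict(self) -> dict:
        return dict(zip(CHANNEL_ORDER, self.gbar))

    @property
    def c_flux(self) -> float:
        """Calcium prefactor phi*A/(2*F*eta) in uM/ms per nA/mm^2."""
        geo, ca = self.geometry, self.ca_params
        return ca.phi * geo.area * _kernel._NA_TO_UM / geo.eta

    def scaled(self, factor: Union[float, np.ndarray]) -> "NeuronModel":
        """Scale all conductance densities (uniform factor = size change)."""
        return replace(self, gbar=self.gbar * factor)

    def with_gbar(self, gbar) -> "NeuronModel":
        return replace(self, gbar=np.asarray(gbar, dtype=float))


@dataclass
class NeuronState:
    V: float  # mV
    Ca: float  # uM
    m: np.ndarray  # length 8, in [0, 1]
    h: np.ndarray  # length 8, in [0, 1]


@dataclass
class SimResult:
    """Recorded traces after the burn-in window."""

    t: np.ndarray  # ms, relative to start of recording
    V: np.ndarray  # mV
    Ca: np.ndarray  # uM
    dt: float  # ms (recording resolution = dt * record_stride)
    burn_in: float  # ms of model time discarded before recording
    end_state: NeuronState = None

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"t_ms": self.t, "V_mV": self.V, "Ca_uM": self.Ca})


def reference_model() -> NeuronModel:
    """The canonical bursting model used as regulation target everywhere."""
    return NeuronModel.from_dict(REFERENCE_GBAR)


def steady_state(spec: ChannelSpec, V: float, Ca: float) -> tuple:
    """Steady-state activation and inactivation (m_inf, h_inf) at (V, Ca)."""
    if not (np.isfinite(V) and np.isfinite(Ca)) or Ca <= 0:
        raise ValueError("V must be finite and Ca positive")
    return spec.m_inf(V, Ca), spec.h_inf(V)


def nernst_eca(model: NeuronModel, Ca: float) -> float:
    ca = model.ca_params
    return ca.rt_2f * np.log(ca.ca_out / Ca)


def total_calcium_current_density(model: NeuronModel,
                                  state: NeuronState) -> float:
    """Total calcium current density i_Ca (nA/mm^2), negative = inward.

    Sums gbar*m^p*h^q*(V - E_Ca) over the two calcium-fluxing channels with
    E_Ca from the Nernst equation at the state's calcium level.
    """
    eca = nernst_eca(model, state.Ca)
    ica = 0.0
    for i, name in enumerate(CHANNEL_ORDER):
        spec = CHANNELS[name]
        if not spec.carries_calcium:
            continue
        gate = state.m[i] ** spec.p
        if spec.q:
            gate *= state.h[i]
        ica += model.gbar[i] * gate * (state.V - eca)
    return ica


def steady_state_gating(V: float, Ca: float) -> tuple:
    """(m, h) vectors with every gate at its steady state for (V, Ca)."""
    m = np.empty(8)
    h = np.empty(8)
    for i, name in enumerate(CHANNEL_ORDER):
        spec = CHANNELS[name]
        m[i], h[i] = steady_state(spec, V, Ca)
    return m, h


def default_initial_state(model: NeuronModel, V: float = -60.0) -> NeuronState:
    m, h = steady_state_gating(V, model.ca_params.ca_inf)
    return NeuronState(V=V, Ca=model.ca_params.ca_inf, m=m, h=h)


def _unpack_end_state(vec) -> NeuronState:
    return NeuronState(V=vec[0], Ca=vec[1], m=vec[2:10].copy(),
                       h=vec[10:18].copy())


def simulate(model: NeuronModel, t_total: float, dt: float = 0.05,
             initial: Optional[NeuronState] = None, burn_in: float = 0.0,
             record_stride: int = 1, v_limit: float = 500.0,
             raise_on_divergence: bool = True) -> SimResult:
    """Exponential-Euler integration for ``t_total`` ms of model time.

    ``burn_in`` ms are integrated without recording and discarded; the
    returned traces cover the remaining window at resolution
    ``dt * record_stride``.  Deterministic given (model, dt, initial).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if t_total <= burn_in:
        raise ValueError("t_total must exceed burn_in")
    if initial is None:
        initial = default_initial_state(model)
    ca = model.ca_params
    args = (model.gbar, model.c_flux, ca.tau_ca, ca.ca_inf, ca.ca_out,
            ca.rt_2f, model.cm, dt)
    V0, Ca0, m0, h0 = initial.V, initial.Ca, initial.m, initial.h
    diverged = False
    if burn_in > 0:
        n_burn = int(round(burn_in / dt))
        _, _, end, diverged = _kernel.integrate_fixed(
            *args, n_burn, max(n_burn, 1), V0, Ca0, m0, h0, v_limit)
        V0, Ca0, m0, h0 = end[0], end[1], end[2:10], end[10:18]
    if diverged:
        if raise_on_divergence:
            raise SimulationDiverged("membrane potential diverged in burn-in")
        return SimResult(np.empty(0), np.empty(0), np.empty(0), dt, burn_in,
                         _unpack_end_state(end))
    n_steps = int(round((t_total - burn_in) / dt))
    V_rec, Ca_rec, end, diverged = _kernel.integrate_fixed(
        *args, n_steps, record_stride, V0, Ca0, m0, h0, v_limit)
    if diverged and raise_on_divergence:
        raise SimulationDiverged("membrane potential diverged")
    t = (1 + np.arange(len(V_rec))) * dt * record_stride
    return SimResult(t, V_rec, Ca_rec, dt, burn_in, _unpack_end_state(end))


def mean_calcium(result: SimResult, min_window: float = 1000.0) -> float:
    """Time-averaged intracellular calcium over the recorded window (uM)."""
    if len(result.t) == 0 or result.t[-1] < min_window:
        raise ValueError("recorded window too short for a calcium average")
    return float(result.Ca.mean())
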