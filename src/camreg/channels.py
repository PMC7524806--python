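"""Ion-channel kinetics for the 8-conductance crustacean pacemaker model.

The model carries the classic stomatogastric-ganglion complement of
voltage-gated conductances: a transient potassium current (A), slow and
transient calcium currents (CaS, CaT), a hyperpolarisation-activated inward
current (H), a calcium-activated potassium current (KCa), a delayed-rectifier
potassium current (Kd), a passive leak, and a fast sodium current (NaV).
Gating follows first-order kinetics

    tau_x(V) * dx/dt = x_inf(V) - x,

with each current contributing ``gbar * m**p * h**q * (V - E)`` to the
membrane current density.  Steady states are Boltzmann sigmoids and the time
constants are sigmoid or double-exponential functions of voltage; KCa
activation additionally carries a Michaelis factor ``Ca / (Ca + 3 uM)`` so
the current only flows when intracellular calcium is elevated.  CaS and CaT
are the only calcium-fluxing conductances and their reversal potential is
computed from the Nernst equation at each step.

Every gating function is a scalar ``numba.njit`` function, used unchanged by
both the Python-level API (:func:`camreg.model.steady_state`) and the
compiled integrator (:mod:`camreg._kernel`), so there is a single source of
truth for the kinetics.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
from numba import njit

__all__ = [
    "CHANNEL_ORDER",
    "CHANNELS",
    "ChannelSpec",
    "A_IDX",
    "CAS_IDX",
    "CAT_IDX",
    "P_EXP",
    "Q_EXP",
    "E_FIXED",
    "CARRIES_CA",
    "gating_all",
    "FARADAY",
    "RT_2F",
]

#: Canonical channel ordering used for every length-8 conductance vector.
CHANNEL_ORDER = ("A", "CaS", "CaT", "H", "KCa", "Kd", "Leak", "NaV")

A_IDX = CHANNEL_ORDER.index("A")
CAS_IDX = CHANNEL_ORDER.index("CaS")
CAT_IDX = CHANNEL_ORDER.index("CaT")

#: activation exponents p
P_EXP = np.array([3, 3, 3, 1, 4, 4, 0, 3], dtype=np.int64)
#: inactivation exponents q (0 = no inactivation gate)
Q_EXP = np.array([1, 1, 1, 0, 0, 0, 0, 1], dtype=np.int64)
#: fixed reversal potentials, mV; calcium entries are placeholders (Nernst)
E_FIXED = np.array([-80.0, 0.0, 0.0, -20.0, -80.0, -80.0, -50.0, 50.0])
#: which channels flux calcium into the shell
CARRIES_CA = np.array(
    [False, True, True, False, False, False, False, False]
)

FARADAY = 96485.0  # C/mol
#: RT/2F at 10 degrees C, mV — the divalent Nernst slope for E_Ca.
RT_2F = 12.1983


# --- scalar gating functions (V in mV, Ca in uM, tau in ms) ---------------

@njit(cache=True)
def _minf_A(V):
    return 1.0 / (1.0 + math.exp(-(V + 27.2) / 8.7))


@njit(cache=True)
def _hinf_A(V):
    return 1.0 / (1.0 + math.exp((V + 56.9) / 4.9))


@njit(cache=True)
def _taum_A(V):
    return 23.2 - 20.8 / (1.0 + math.exp(-(V + 32.9) / 15.2))


@njit(cache=True)
def _tauh_A(V):
    return 77.2 - 58.4 / (1.0 + math.exp(-(V + 38.9) / 26.5))


@njit(cache=True)
def _minf_CaS(V):
    return 1.0 / (1.0 + math.exp(-(V + 33.0) / 8.1))


@njit(cache=True)
def _hinf_CaS(V):
    return 1.0 / (1.0 + math.exp((V + 60.0) / 6.2))


@njit(cache=True)
def _taum_CaS(V):
    return 2.8 + 14.0 / (
        math.exp((V + 27.0) / 10.0) + math.exp(-(V + 70.0) / 13.0)
    )


@njit(cache=True)
def _tauh_CaS(V):
    return 120.0 + 300.0 / (
        math.exp((V + 55.0) / 9.0) + math.exp(-(V + 65.0) / 16.0)
    )


@njit(cache=True)
def _minf_CaT(V):
    return 1.0 / (1.0 + math.exp(-(V + 27.1) / 7.2))


@njit(cache=True)
def _hinf_CaT(V):
    return 1.0 / (1.0 + math.exp((V + 32.1) / 5.5))


@njit(cache=True)
def _taum_CaT(V):
    return 43.4 - 42.6 / (1.0 + math.exp(-(V + 68.1) / 20.5))


@njit(cache=True)
def _tauh_CaT(V):
    return 210.0 - 179.6 / (1.0 + math.exp(-(V + 55.0) / 16.9))


@njit(cache=True)
def _minf_H(V):
    return 1.0 / (1.0 + math.exp((V + 75.0) / 5.5))


@njit(cache=True)
def _taum_H(V):
    return 2.0 / (
        math.exp(-(V + 169.7) / 11.6) + math.exp((V - 26.7) / 14.3)
    )


@njit(cache=True)
def _minf_KCa(V, Ca):
    return (Ca / (Ca + 3.0)) / (1.0 + math.exp(-(V + 28.3) / 12.6))


@njit(cache=True)
def _taum_KCa(V):
    return 180.6 - 150.2 / (1.0 + math.exp(-(V + 46.0) / 22.7))


@njit(cache=True)
def _minf_Kd(V):
    return 1.0 / (1.0 + math.exp(-(V + 12.3) / 11.8))


@njit(cache=True)
def _taum_Kd(V):
    return 14.4 - 12.8 / (1.0 + math.exp(-(V + 28.3) / 19.2))


@njit(cache=True)
def _minf_NaV(V):
    return 1.0 / (1.0 + math.exp(-(V + 25.5) / 5.29))


@njit(cache=True)
def _hinf_NaV(V):
    return 1.0 / (1.0 + math.exp((V + 48.9) / 5.18))


@njit(cache=True)
def _taum_NaV(V):
    return 2.64 - 2.52 / (1.0 + math.exp(-(V + 120.0) / 25.0))


@njit(cache=True)
def _tauh_NaV(V):
    return (1.34 / (1.0 + math.exp(-(V + 62.9) / 10.0))) * (
        1.5 + 1.0 / (1.0 + math.exp((V + 34.9) / 3.6))
    )


@njit(cache=True)
def gating_all(V, Ca, minf, hinf, taum, tauh):
    """Fill length-8 work arrays with steady states and time constants.

    Channels without a gate get (1, 1 ms) so the integrator update is a
    no-op for them.  Order follows :data:`CHANNEL_ORDER`.
    """
    minf[0] = _minf_A(V)
    hinf[0] = _hinf_A(V)
    taum[0] = _taum_A(V)
    tauh[0] = _tauh_A(V)
    minf[1] = _minf_CaS(V)
    hinf[1] = _hinf_CaS(V)
    taum[1] = _taum_CaS(V)
    tauh[1] = _tauh_CaS(V)
    minf[2] = _minf_CaT(V)
    hinf[2] = _hinf_CaT(V)
    taum[2] = _taum_CaT(V)
    tauh[2] = _tauh_CaT(V)
    minf[3] = _minf_H(V)
    hinf[3] = 1.0
    taum[3] = _taum_H(V)
    tauh[3] = 1.0
    minf[4] = _minf_KCa(V, Ca)
    hinf[4] = 1.0
    taum[4] = _taum_KCa(V)
    tauh[4] = 1.0
    minf[5] = _minf_Kd(V)
    hinf[5] = 1.0
    taum[5] = _taum_Kd(V)
    tauh[5] = 1.0
    minf[6] = 1.0
    hinf[6] = 1.0
    taum[6] = 1.0
    tauh[6] = 1.0
    minf[7] = _minf_NaV(V)
    hinf[7] = _hinf_NaV(V)
    taum[7] = _taum_NaV(V)
    tauh[7] = _tauh_NaV(V)


def _const_one(V):
    return 1.0


def _ignore_ca(f: Callable[[float], float]) -> Callable[[float, float], float]:
    def wrapped(V, Ca=0.0):
        return f(V)

    return wrapped


@dataclass(frozen=True)
class ChannelSpec:
    """Static description of one ion-channel type.

    ``E`` is the fixed reversal potential in mV, or ``None`` for the calcium
    channels whose reversal is computed dynamically from the Nernst equation.
    ``m_inf`` takes ``(V, Ca)`` (the calcium argument only matters for KCa);
    ``h_inf``, ``tau_m`` and ``tau_h`` take ``V`` alone.
    """

    name: str
    E: Optional[float]
    p: int
    q: int
    m_inf: Callable[[float, float], float]
    h_inf: Callable[[float], float]
    tau_m: Callable[[float], float]
    tau_h: Callable[[float], float]
    carries_calcium: bool = False


CHANNELS = {
    "A": ChannelSpec("A", -80.0, 3, 1, _ignore_ca(_minf_A), _hinf_A,
                     _taum_A, _tauh_A),
    "CaS": ChannelSpec("CaS", None, 3, 1, _ignore_ca(_minf_CaS), _hinf_CaS,
                       _taum_CaS, _tauh_CaS, carries_calcium=True),
    "CaT": ChannelSpec("CaT", None, 3, 1, _ignore_ca(_minf_CaT), _hinf_CaT,
                       _taum_CaT, _tauh_CaT, carries_calcium=True),
    "H": ChannelSpec("H", -20.0, 1, 0, _ignore_ca(_minf_H), _const_one,
                     _taum_H, _const_one),
    "KCa": ChannelSpec("KCa", -80.0, 4, 0, _minf_KCa, _const_one,
                       _taum_KCa, _const_one),
    "Kd": ChannelSpec("Kd", -80.0, 4, 0, _ignore_ca(_minf_Kd), _const_one,
                      _taum_Kd, _const_one),
    "Leak": ChannelSpec("Leak", -50.0, 0, 0,
                        _ignore_ca(_const_one), _const_one,
                        _const_one, _const_one),
    "NaV": ChannelSpec("NaV", 50.0, 3, 1, _ignore_ca(_minf_NaV), _hinf_NaV,
                       _taum_NaV, _tauh_NaV),
}
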