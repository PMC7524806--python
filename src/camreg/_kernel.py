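"""Compiled exponential-Euler integrators (hot loops).

Two kernels: a fixed-parameter integrator and a closed-loop integrator that
co-evolves channel mRNA, conductance densities and cell area.  Gating comes
from :func:`camreg.channels.gating_all`; all state updates use the
exponential Euler scheme (exact for the locally-linearised subsystem).

Unit conventions: mV, ms, uM, uS/mm^2, mm^2, mm^3, nF/mm^2.  ``c_flux`` is
the pre-computed calcium flux prefactor phi*A/(2*F*eta) expressed in
uM/ms per nA/mm^2 of calcium current density.
"""
import math

import numpy as np
from numba import njit

from .channels import CARRIES_CA, E_FIXED, P_EXP, Q_EXP, gating_all

#: uM/ms of concentration change per nA of current into 1 mm^3
#: ( = 1e-12 C/ms / (2 F) mol/ms, over 1e-6 L, in uM )
_NA_TO_UM = 5.18216e-6


@njit(cache=True, fastmath=True)
def _current_sums(gbar, m, h, V, eca):
    """Return (total conductance, conductance-weighted reversal, i_Ca)."""
    G = 0.0
    GE = 0.0
    ica = 0.0
    for i in range(8):
        mp = 1.0
        for _ in range(P_EXP[i]):
            mp *= m[i]
        if Q_EXP[i] == 1:
            mp *= h[i]
        g = gbar[i] * mp
        e = eca if CARRIES_CA[i] else E_FIXED[i]
        G += g
        GE += g * e
        if CARRIES_CA[i]:
            ica += g * (V - e)
    return G, GE, ica


@njit(cache=True, fastmath=True)
def integrate_fixed(gbar, c_flux, tau_ca, ca_inf, ca_out, rt_2f, cm, dt,
                    n_steps, rec_stride, V0, Ca0, m0, h0, v_limit):
    """Integrate the membrane + calcium system with fixed conductances.

    Returns (V_rec, Ca_rec, state_end, diverged) where state_end packs
    (V, Ca, m[8], h[8]) and recordings are taken every ``rec_stride`` steps.
    """
    V = V0
    Ca = Ca0
    m = m0.copy()
    h = h0.copy()
    minf = np.empty(8)
    hinf = np.empty(8)
    taum = np.empty(8)
    tauh = np.empty(8)
    n_rec = n_steps // rec_stride
    V_rec = np.empty(n_rec)
    Ca_rec = np.empty(n_rec)
    j = 0
    diverged = False
    for step in range(n_steps):
        gating_all(V, Ca, minf, hinf, taum, tauh)
        eca = rt_2f * math.log(ca_out / Ca)
        G, GE, ica = _current_sums(gbar, m, h, V, eca)
        ca_inst = ca_inf - tau_ca * c_flux * ica
        Ca = ca_inst + (Ca - ca_inst) * math.exp(-dt / tau_ca)
        if Ca < 1e-9:
            Ca = 1e-9
        if G > 0.0:
            vinf = GE / G
            V = vinf + (V - vinf) * math.exp(-dt * G / cm)
        for i in range(8):
            m[i] = minf[i] + (m[i] - minf[i]) * math.exp(-dt / taum[i])
            if Q_EXP[i] == 1:
                h[i] = hinf[i] + (h[i] - hinf[i]) * math.exp(-dt / tauh[i])
        if not math.isfinite(V) or abs(V) > v_limit:
            diverged = True
            break
        if (step + 1) % rec_stride == 0 and j < n_rec:
            V_rec[j] = V
            Ca_rec[j] = Ca
            j += 1
    state_end = np.empty(18)
    state_end[0] = V
    state_end[1] = Ca
    for i in range(8):
        state_end[2 + i] = m[i]
        state_end[10 + i] = h[i]
    return V_rec[:j], Ca_rec[:j], state_end, diverged


@njit(cache=True, fastmath=True)
def integrate_regulated(gbar0, mu0, tau_mu, tau_g, ca_target, growth_k,
                        area0, c_flux, tau_ca, ca_inf, ca_out, rt_2f, cm,
                        dt, n_steps, rec_stride, V0, Ca0, m0, h0, v_limit):
    """Closed-loop integration: membrane + calcium + mRNA + conductances.

    mRNA integrates the calcium error (one timescale per channel),
    conductance densities relax toward mRNA with timescale ``tau_g`` and are
    diluted by area growth (dA/dt = growth_k, thin-shell volume scaled in
    proportion so the calcium prefactor is size-invariant).  Both mRNA and
    conductances are floored at zero.

    Returns (g_rec[n,8], A_rec, Ca_rec, state_end, diverged); state_end packs
    (V, Ca, m[8], h[8], g[8], mu[8], A).
    """
    V = V0
    Ca = Ca0
    m = m0.copy()
    h = h0.copy()
    g = gbar0.copy()
    mu = mu0.copy()
    A = area0
    minf = np.empty(8)
    hinf = np.empty(8)
    taum = np.empty(8)
    tauh = np.empty(8)
    n_rec = n_steps // rec_stride
    g_rec = np.empty((n_rec, 8))
    A_rec = np.empty(n_rec)
    Ca_rec = np.empty(n_rec)
    j = 0
    diverged = False
    eg = math.exp(-dt / tau_g)
    for step in range(n_steps):
        gating_all(V, Ca, minf, hinf, taum, tauh)
        eca = rt_2f * math.log(ca_out / Ca)
        G, GE, ica = _current_sums(g, m, h, V, eca)
        ca_inst = ca_inf - tau_ca * c_flux * ica
        Ca = ca_inst + (Ca - ca_inst) * math.exp(-dt / tau_ca)
        if Ca < 1e-9:
            Ca = 1e-9
        if G > 0.0:
            vinf = GE / G
            V = vinf + (V - vinf) * math.exp(-dt * G / cm)
        for i in range(8):
            m[i] = minf[i] + (m[i] - minf[i]) * math.exp(-dt / taum[i])
            if Q_EXP[i] == 1:
                h[i] = hinf[i] + (h[i] - hinf[i]) * math.exp(-dt / tauh[i])
        err = ca_target - Ca
        dil = A / (A + growth_k * dt) if growth_k > 0.0 else 1.0
        for i in range(8):
            mu[i] += dt * err / tau_mu[i]
            if mu[i] < 0.0:
                mu[i] = 0.0
            g[i] = mu[i] + (g[i] - mu[i]) * eg
            g[i] *= dil
            if g[i] < 0.0:
                g[i] = 0.0
        A += growth_k * dt
        if not math.isfinite(V) or abs(V) > v_limit:
            diverged = True
            break
        if (step + 1) % rec_stride == 0 and j < n_rec:
            for i in range(8):
                g_rec[j, i] = g[i]
            A_rec[j] = A
            Ca_rec[j] = Ca
            j += 1
    state_end = np.empty(35)
    state_end[0] = V
    state_end[1] = Ca
    for i in range(8):
        state_end[2 + i] = m[i]
        state_end[10 + i] = h[i]
        state_end[18 + i] = g[i]
        state_end[26 + i] = mu[i]
    state_end[34] = A
    return g_rec[:j], A_rec[:j], Ca_rec[:j], state_end, diverged
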