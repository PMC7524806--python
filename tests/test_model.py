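"""Core model: calcium current, integration, geometry invariance."""
import math

import numpy as np
import pytest

from camreg import (CalciumParams, Geometry, NeuronModel, SimResult,
                    SimulationDiverged, mean_calcium, reference_model,
                    simulate)
from camreg.model import (default_initial_state, steady_state_gating,
                          total_calcium_current_density, NeuronState)
from camreg.config import QUICK
from camreg.metrics import trace_metrics


def test_calcium_current_zero_without_calcium_conductances():
    m = reference_model()
    g = m.gbar.copy()
    g[1] = g[2] = 0.0  # CaS, CaT
    m = m.with_gbar(g)
    state = default_initial_state(m, V=-40.0)
    assert total_calcium_current_density(m, state) == 0.0


def test_calcium_current_zero_at_reversal():
    m = reference_model()
    ca = 0.05
    eca = m.ca_params.rt_2f * math.log(m.ca_params.ca_out / ca)
    mm, hh = steady_state_gating(eca, ca)
    state = NeuronState(V=eca, Ca=ca, m=mm, h=hh)
    assert total_calcium_current_density(m, state) == pytest.approx(0.0, abs=1e-12)


def test_calcium_current_matches_term_by_term_hand_evaluation():
    """Independent spreadsheet-style evaluation of the two calcium terms at
    V = -40 mV, Ca = 0.05 uM, steady-state gating."""
    V, ca = -40.0, 0.05
    eca = 12.1983 * math.log(3000.0 / ca)
    m_cas = 1.0 / (1.0 + math.exp(-(V + 33.0) / 8.1))
    h_cas = 1.0 / (1.0 + math.exp((V + 60.0) / 6.2))
    m_cat = 1.0 / (1.0 + math.exp(-(V + 27.1) / 7.2))
    h_cat = 1.0 / (1.0 + math.exp((V + 32.1) / 5.5))
    expected = (165.0 * m_cas ** 3 * h_cas * (V - eca)
                + 2.35 * m_cat ** 3 * h_cat * (V - eca))
    model = reference_model()
    mm, hh = steady_state_gating(V, ca)
    state = NeuronState(V=V, Ca=ca, m=mm, h=hh)
    got = total_calcium_current_density(model, state)
    assert got == pytest.approx(expected, rel=1e-9)
    assert got < 0  # inward at -40 mV


def test_passive_membrane_relaxes_to_leak_reversal():
    g = np.zeros(8)
    g[6] = 0.46  # Leak only
    m = NeuronModel(g)
    res = simulate(m, 2000.0, burn_in=0.0)
    # monotone approach to E_Leak = -50 from V0 = -60
    assert np.all(np.diff(res.V) >= -1e-12)
    assert res.V[-1] == pytest.approx(-50.0, abs=0.01)


def test_all_leak_calcium_relaxes_to_resting_level():
    g = np.zeros(8)
    g[6] = 0.46
    m = NeuronModel(g)
    res = simulate(m, 3000.0, burn_in=1500.0)
    assert mean_calcium(res) == pytest.approx(m.ca_params.ca_inf, rel=1e-6)


def test_mean_calcium_of_constant_trace():
    t = np.arange(1.0, 2001.0)
    res = SimResult(t, np.full_like(t, -50.0), np.full_like(t, 3.7), 1.0, 0.0)
    assert mean_calcium(res) == pytest.approx(3.7)
    with pytest.raises(ValueError):
        mean_calcium(SimResult(t[:10], t[:10], t[:10], 1.0, 0.0))


def test_divergence_is_signalled():
    # with an artificially tight sanity bound, spikes trip the detector
    with pytest.raises(SimulationDiverged):
        simulate(reference_model(), 2000.0, v_limit=30.0)


def test_simulation_is_deterministic():
    m = reference_model()
    a = simulate(m, 3000.0, burn_in=1000.0)
    b = simulate(m, 3000.0, burn_in=1000.0)
    assert np.array_equal(a.V, b.V) and np.array_equal(a.Ca, b.Ca)


def test_burst_period_agrees_with_fine_step_reference():
    """Exponential Euler at dt=0.05 ms vs a 10x finer reference integration:
    burst period agreement to <2%."""
    m = reference_model()
    res = simulate(m, QUICK.burn_in + QUICK.window, dt=0.05,
                   burn_in=QUICK.burn_in)
    ref = simulate(m, QUICK.burn_in + QUICK.window, dt=0.005,
                   burn_in=QUICK.burn_in, record_stride=10)
    p = trace_metrics(res).burst_period
    p_ref = trace_metrics(ref).burst_period
    assert abs(p / p_ref - 1) < 0.02


def test_random_models_stay_finite_with_bounded_gating():
    """Traces stay finite and end-state gating stays in [0,1] across the
    database hypercube."""
    rng = np.random.default_rng(123)
    hi = 2.0 * reference_model().gbar
    for _ in range(1000):
        m = NeuronModel(rng.uniform(0, hi))
        res = simulate(m, 1000.0, record_stride=100,
                       raise_on_divergence=False)
        assert np.all(np.isfinite(res.V)) and np.all(np.isfinite(res.Ca))
        s = res.end_state
        assert np.all((s.m >= 0) & (s.m <= 1))
        assert np.all((s.h >= 0) & (s.h <= 1))
        assert s.Ca > 0


def test_geometry_scaling_preserves_flux_prefactor():
    g = Geometry()
    assert g.scaled(3.0).area / g.scaled(3.0).eta == pytest.approx(g.area / g.eta)
    with pytest.raises(ValueError):
        Geometry(area=0.0)


def test_model_validation():
    with pytest.raises(ValueError):
        NeuronModel(np.full(8, -1.0))
    with pytest.raises(ValueError):
        NeuronModel(np.ones(5))
    with pytest.raises(ValueError):
        CalciumParams(tau_ca=0.0)
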