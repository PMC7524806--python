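"""Master-regulation controller: timescale rule, direction law, homeostasis."""
import numpy as np
import pytest

from camreg import NeuronModel, reference_model
from camreg.regulation import (GrowthParams, integrate_closed_loop,
                               integrate_open_loop,
                               set_regulation_timescales,
                               tuned_open_loop_rates)


def test_timescales_invert_conductances():
    g = np.array([100.0, 200.0, 100, 100, 100, 100, 100, 100])
    reg = set_regulation_timescales(NeuronModel(g), ca_target=50.0,
                                    constant=5000.0)
    assert reg.tau_mu[0] == pytest.approx(50.0)
    assert reg.tau_mu[1] == pytest.approx(25.0)


def test_timescale_ratios_match_conductance_ratios():
    ref = reference_model()
    reg = set_regulation_timescales(ref, ca_target=50.0)
    # tau_mu_CaT / tau_mu_A = g_A / g_CaT
    assert reg.tau_mu[2] / reg.tau_mu[0] == pytest.approx(379.0 / 2.35)


def test_zero_conductance_rejected():
    g = reference_model().gbar.copy()
    g[3] = 0.0
    with pytest.raises(ValueError):
        set_regulation_timescales(NeuronModel(g), ca_target=50.0)


def test_direction_law_and_ray_confinement(ref_model, ca_target):
    """The controller moves along the ray: conductance increments satisfy
    dg_j/dg_i = tau_mu_i/tau_mu_j (to 1%), and conductance ratios are
    conserved along the whole trajectory."""
    start = ref_model.scaled(0.25)
    reg = set_regulation_timescales(ref_model, ca_target)
    reg.mu = start.gbar.copy()
    traj = integrate_closed_loop(start, reg, GrowthParams(), 60_000.0)
    i0 = np.searchsorted(traj.t, 10_000.0)
    dg = traj.gbar[-1] - traj.gbar[i0]
    expected = reg.tau_mu[0] / reg.tau_mu  # relative to channel 0
    assert np.abs(dg / dg[0] / expected - 1).max() < 0.01
    # ray confinement: ratios to channel 0 conserved over the trajectory
    ratios = traj.gbar / traj.gbar[:, :1]
    ref_ratio = ref_model.gbar / ref_model.gbar[0]
    assert np.abs(ratios / ref_ratio - 1).max() < 0.01


def test_reference_model_is_a_homeostatic_steady_state(ref_model, ca_target):
    """With no growth, the controller started at the reference drifts <2%
    over 100 translation timescales (500 s)."""
    reg = set_regulation_timescales(ref_model, ca_target)
    traj = integrate_closed_loop(ref_model, reg, GrowthParams(), 500_000.0)
    assert np.abs(traj.gbar / ref_model.gbar - 1).max() < 0.02


def test_open_loop_tuned_rates_preserve_density_exactly(ref_model):
    rates = tuned_open_loop_rates(ref_model, r_growth=1e-6)
    traj = integrate_open_loop(ref_model, rates, t_total=5e5)
    assert np.abs(traj.gbar / ref_model.gbar[None, :] - 1).max() < 1e-12


def test_open_loop_mismatch_dilutes_by_expected_factor(ref_model):
    """5x-too-fast membrane growth: density converges to 1/5 of the tuned
    line (linear dynamics)."""
    tuned = tuned_open_loop_rates(ref_model, r_growth=1e-6)
    rates = GrowthParams(r=tuned.r, r_growth=5e-6)
    A0 = ref_model.geometry.area
    T = 99.0 * A0 / 5e-6  # area x100: asymptotic regime
    traj = integrate_open_loop(ref_model, rates, T)
    end_factor = traj.gbar[-1] / ref_model.gbar
    assert np.allclose(end_factor, end_factor[0])
    assert end_factor[0] == pytest.approx(0.2, rel=0.05)


def test_growth_params_validation():
    with pytest.raises(ValueError):
        GrowthParams(k=-1.0)
    with pytest.raises(ValueError):
        integrate_open_loop(reference_model(), GrowthParams(), 1000.0)
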