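"""Analytic silent-state solver: roots, residuals, and existence threshold."""
import numpy as np
import pytest

from camreg import NeuronModel, reference_model
from camreg.plane import default_planes
from camreg.silent import (marginal_stability, required_calcium_current,
                           silent_set, solve_V_Ca, solve_V_V,
                           steady_calcium_current, steady_membrane_current,
                           validate_branch_by_simulation)


def _ca_scaled(model, factor):
    g = model.gbar.copy()
    g[1] *= factor
    g[2] *= factor
    return model.with_gbar(g)


def test_no_silent_roots_without_calcium_influx(ca_target):
    m = _ca_scaled(reference_model(), 0.0)
    assert solve_V_Ca(m, ca_target) == []


def test_silent_roots_need_supercritical_calcium_conductance(ca_target):
    """Roots of the calcium ODE appear only above a critical calcium-channel
    density (window current must supply the required influx)."""
    ref = reference_model()
    assert solve_V_Ca(ref, ca_target) == []
    roots = solve_V_Ca(_ca_scaled(ref, 12.0), ca_target)
    assert len(roots) == 2  # lower and upper branch of the window current
    assert all(-80.0 < v < 0.0 for v in roots)


def test_calcium_root_residuals_are_tiny(ca_target):
    m = _ca_scaled(reference_model(), 12.0)
    i_req = required_calcium_current(m, ca_target)
    for v in solve_V_Ca(m, ca_target):
        resid = steady_calcium_current(m, v, ca_target) - i_req
        assert abs(resid / i_req) < 1e-9


def test_pure_leak_voltage_root_at_leak_reversal(ca_target):
    g = np.zeros(8)
    g[6] = 1.0
    roots = solve_V_V(NeuronModel(g), ca_target)
    assert len(roots) == 1
    assert roots[0] == pytest.approx(-50.0, abs=1e-6)


def test_voltage_roots_match_dense_grid_oracle(ca_target):
    """Roots of the steady-state current agree with a 0.01 mV brute-force
    scan (count and location)."""
    m = reference_model()
    roots = solve_V_V(m, ca_target)
    grid = np.arange(-80.0, 0.0, 0.01)
    vals = np.array([steady_membrane_current(m, v, ca_target) for v in grid])
    crossings = grid[:-1][np.sign(vals[:-1]) != np.sign(vals[1:])]
    assert len(roots) == len(crossings)
    for r, c in zip(sorted(roots), sorted(crossings)):
        assert abs(r - c) < 0.02


def test_silent_set_absent_without_calcium_conductance(ca_target):
    plane = default_planes(reference_model())["calcium"]
    sols = silent_set(plane, ca_target, n_x=5, n_y=10,
                      x_range=(1e-3 * plane.x_ref, 0.5 * plane.x_ref))
    assert sols == []


def test_silent_set_points_match_voltages_and_validate(ca_target):
    """On the curve |V_V - V_Ca| is below tolerance; a low-y (stable-branch)
    point stays quiescent under direct simulation while a high-y point does
    not."""
    plane = default_planes(reference_model())["calcium"]
    sols = silent_set(plane, ca_target, n_x=6, n_y=40,
                      x_range=(8.0 * plane.x_ref, 14.0 * plane.x_ref),
                      y_range=(0.01 * plane.y_ref, 2.5 * plane.y_ref))
    assert len(sols) >= 6
    for s in sols:
        assert abs(s.V_V - s.V_Ca) < 0.05
    low = min(sols, key=lambda s: s.y)
    high = max(sols, key=lambda s: s.y)
    m_low = plane.model_at(low.x, low.y)
    m_high = plane.model_at(high.x, high.y)
    assert validate_branch_by_simulation(m_low, low, ca_target) == "stable"
    assert validate_branch_by_simulation(m_high, high, ca_target) == "unstable"
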