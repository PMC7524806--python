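"""Spike detection, burst metrics, and the four-state classifier."""
import numpy as np
import pytest

from camreg import ClassifierConfig, simulate, trace_metrics
from camreg.metrics import (TraceMetrics, burst_metrics, classify,
                            detect_spikes)
from camreg.config import QUICK


def _square_pulse_trace(n_pulses, period=100.0, width=2.0, dt=0.1):
    t = np.arange(dt, n_pulses * period, dt)
    V = np.full_like(t, -60.0)
    for k in range(n_pulses):
        on = (t >= k * period + 10) & (t < k * period + 10 + width)
        V[on] = 20.0
    return t, V


def test_flat_trace_has_no_spikes():
    t = np.arange(0.1, 1000, 0.1)
    assert len(detect_spikes(np.full_like(t, -60.0), t)) == 0


def test_square_pulses_detected_once_each():
    t, V = _square_pulse_trace(5)
    assert len(detect_spikes(V, t)) == 5


def test_detect_spikes_rejects_nan():
    with pytest.raises(ValueError):
        detect_spikes(np.array([-60.0, np.nan]), np.array([0.0, 1.0]))


def test_burst_metrics_on_constructed_periodic_bursts():
    """4 spikes at 10 ms ISI every 1000 ms: period 1000, duty ~ 3 intervals
    plus the configured spike width."""
    st = np.concatenate([k * 1000.0 + np.array([0, 10, 20, 30])
                         for k in range(10)])
    period, duty, n_per, cv = burst_metrics(st, 10_000.0)
    assert period == pytest.approx(1000.0)
    assert 0.03 <= duty <= 0.04
    assert n_per == pytest.approx(4.0)
    assert cv == pytest.approx(0.0)


def test_single_spike_train_takes_tonic_path():
    st = np.arange(0.0, 10_000.0, 500.0)
    period, duty, n_per, cv = burst_metrics(st, 10_000.0)
    tm = TraceMetrics(st, period, duty, n_per, cv)
    assert classify(tm, ClassifierConfig()) == "tonic_or_one_spike"


def test_too_few_spikes_is_undefined_not_zero():
    period, duty, n_per, cv = burst_metrics(np.array([100.0, 200.0]), 1000.0)
    assert period is None and duty is None


def test_zero_spikes_is_silent():
    tm = TraceMetrics(np.empty(0), None, None, None, None)
    assert classify(tm, ClassifierConfig()) == "silent"


def test_duty_cycle_outside_band_is_other_bursting():
    cfg = ClassifierConfig().with_targets(1000.0, 0.3)
    tm = TraceMetrics(np.arange(40.0), 1050.0, 0.3 * 1.3, 4.0, 0.01)
    assert classify(tm, cfg) == "other_bursting"


def test_labels_are_exhaustive_and_unique():
    cfg = ClassifierConfig().with_targets(1000.0, 0.3)
    cases = [
        TraceMetrics(np.empty(0), None, None, None, None),
        TraceMetrics(np.arange(3.0), None, None, 1.0, None),
        TraceMetrics(np.arange(40.0), 1000.0, 0.3, 4.0, 0.01),
        TraceMetrics(np.arange(40.0), 2000.0, 0.3, 4.0, 0.01),
        TraceMetrics(np.arange(40.0), 1000.0, 0.3, 4.0, 0.9),
    ]
    from camreg.metrics import STATE_LABELS

    for tm in cases:
        assert classify(tm, cfg) in STATE_LABELS


def test_reference_model_is_canonical_against_its_own_targets(
        ref_model, ref_metrics, target_classifier):
    assert classify(ref_metrics, target_classifier) == "canonical"


def test_classification_is_stable_across_disjoint_windows(ref_model,
                                                          target_classifier):
    """Burst period, duty cycle and label agree to <2% between two disjoint
    analysis windows after burn-in."""
    long = simulate(ref_model, QUICK.burn_in + 2 * QUICK.window,
                    burn_in=QUICK.burn_in)
    half = len(long.t) // 2
    from camreg.model import SimResult

    win1 = SimResult(long.t[:half], long.V[:half], long.Ca[:half],
                     long.dt, long.burn_in)
    win2 = SimResult(long.t[half:] - long.t[half - 1], long.V[half:],
                     long.Ca[half:], long.dt, long.burn_in)
    tm1 = trace_metrics(win1, target_classifier)
    tm2 = trace_metrics(win2, target_classifier)
    assert tm1.state_label == tm2.state_label == "canonical"
    assert abs(tm1.burst_period / tm2.burst_period - 1) < 0.02
    assert abs(tm1.duty_cycle / tm2.duty_cycle - 1) < 0.02
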