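"""Burst metrics and the four-way classification of voltage dynamics.

A trace is reduced to spike times, burst period, duty cycle and mean
calcium, then labelled as one of four mutually exclusive states:

- ``canonical``      — regular bursting with period and duty cycle within a
                       tolerance (default 10%) of the target dynamics;
- ``other_bursting`` — bursting outside that tolerance (or irregular);
- ``tonic_or_one_spike`` — periodic spiking without multi-spike burst
                       structure (tonic firing and one-spike bursting are
                       indistinguishable at the spike-train level);
- ``silent``         — no spikes.

Bursts are delimited where an interspike interval exceeds a multiple of the
median ISI; with fewer than three burst starts (or fewer than two spikes per
burst) period and duty cycle are undefined and classification falls back to
the spike count.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .model import SimResult

__all__ = [
    "STATE_LABELS",
    "ClassifierConfig",
    "TraceMetrics",
    "detect_spikes",
    "burst_metrics",
    "classify",
    "trace_metrics",
]

STATE_LABELS = ("canonical", "other_bursting", "tonic_or_one_spike", "silent")


@dataclass(frozen=True)
class ClassifierConfig:
    spike_threshold: float = 0.0  # mV, upward crossing
    isi_break_factor: float = 3.0  # burst break at ISI > factor * median ISI
    spike_width: float = 5.0  # ms added to burst duration for duty cycle
    canonical_tol: float = 0.10  # fractional band around the targets
    cv_gate: float = 0.20  # max CV of burst periods for "regular"
    target_period: Optional[float] = None  # ms
    target_duty: Optional[float] = None

    def __post_init__(self):
        if self.canonical_tol <= 0 or self.isi_break_factor <= 1:
            raise ValueError("invalid classifier configuration")

    def with_targets(self, period: float, duty: float) -> "ClassifierConfig":
        import dataclasses

        return dataclasses.replace(self, target_period=period,
                                   target_duty=duty)


@dataclass
class TraceMetrics:
    spike_times: np.ndarray
    burst_period: Optional[float]  # ms; None when undefined
    duty_cycle: Optional[float]
    n_spikes_per_burst: Optional[float]
    period_cv: Optional[float]
    mean_Ca: Optional[float] = None  # uM
    state_label: Optional[str] = None


def detect_spikes(V: np.ndarray, t: np.ndarray,
                  threshold: float = 0.0) -> np.ndarray:
    """Spike times (ms) as upward threshold crossings of the V trace."""
    V = np.asarray(V)
    if not np.all(np.isfinite(V)):
        raise ValueError("voltage trace contains non-finite values")
    idx = np.flatnonzero((V[1:] >= threshold) & (V[:-1] < threshold))
    return np.asarray(t)[idx + 1]


def burst_metrics(spike_times: np.ndarray, duration: float,
                  cfg: ClassifierConfig = ClassifierConfig()):
    """(burst_period, duty_cycle, n_spikes_per_burst, period_cv).

    Entries are None when the window does not contain enough burst structure
    (undefined metrics are flagged, never silently zeroed).
    """
    st = np.asarray(spike_times, dtype=float)
    if len(st) < 4:
        return None, None, None, None
    isi = np.diff(st)
    med = np.median(isi)
    breaks = np.flatnonzero(isi > cfg.isi_break_factor * med)
    if len(breaks) == 0:
        # no burst structure resolved: tonic train (or one long burst)
        return None, None, 1.0, None
    starts = st[np.concatenate(([0], breaks + 1))]
    ends = st[np.concatenate((breaks, [len(st) - 1]))]
    if len(starts) < 3:
        return None, None, None, None
    periods = np.diff(starts)
    period = float(periods.mean())
    cv = float(periods.std() / period)
    # only complete bursts (all but the possibly-truncated last one)
    durations = (ends - starts)[:-1] + cfg.spike_width
    duty = float(durations.mean() / period)
    n_per = float(len(st) / len(starts))
    return period, duty, n_per, cv


def classify(metrics: TraceMetrics, cfg: ClassifierConfig) -> str:
    """Assign one of the four state labels (exhaustive, mutually exclusive)."""
    if len(metrics.spike_times) == 0:
        return "silent"
    if metrics.burst_period is None or metrics.duty_cycle is None:
        return "tonic_or_one_spike"
    if metrics.n_spikes_per_burst is not None and metrics.n_spikes_per_burst < 2:
        return "tonic_or_one_spike"
    if metrics.period_cv is not None and metrics.period_cv > cfg.cv_gate:
        return "other_bursting"
    if cfg.target_period and cfg.target_duty:
        ok_p = abs(metrics.burst_period / cfg.target_period - 1) <= cfg.canonical_tol
        ok_d = abs(metrics.duty_cycle / cfg.target_duty - 1) <= cfg.canonical_tol
        if ok_p and ok_d:
            return "canonical"
    return "other_bursting"


def trace_metrics(result: SimResult,
                  cfg: ClassifierConfig = ClassifierConfig()) -> TraceMetrics:
    """Full metric extraction + classification for one simulated trace."""
    if len(result.t) == 0:
        # divergent / empty recording: treat as undefined-silent
        tm = TraceMetrics(np.empty(0), None, None, None, None, None)
        tm.state_label = "silent"
        return tm
    st = detect_spikes(result.V, result.t, cfg.spike_threshold)
    period, duty, n_per, cv = burst_metrics(st, result.t[-1], cfg)
    tm = TraceMetrics(st, period, duty, n_per, cv,
                      mean_Ca=float(result.Ca.mean()))
    tm.state_label = classify(tm, cfg)
    return tm
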