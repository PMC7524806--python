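"""Fixed-point analysis along the growth ray (uniform conductance scaling).

Because the master regulator can only move the conductance vector along the
ray through the model's own point (see :mod:`camreg.regulation`), whether
regulation compensates a size change reduces to a one-dimensional question:
where does the mean-calcium-versus-scale curve cross the model's calcium
target, and with what slope?  Upward crossings (calcium increasing with
scale) are stable fixed points of the negative-feedback controller; downward
crossings are unstable.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .config import QUICK, SimTier
from .metrics import ClassifierConfig, TraceMetrics, trace_metrics
from .model import NeuronModel, SimulationDiverged, mean_calcium, simulate

__all__ = ["RayScan", "scan_ray", "find_fixed_points",
           "compensation_outcomes", "model_mean_calcium"]


@dataclass
class RayScan:
    model: NeuronModel
    ca_target: float
    scales: np.ndarray
    mean_ca: np.ndarray  # normalised by ca_target; NaN where divergent
    metrics: list  # TraceMetrics per scale (None where divergent)
    tier: SimTier
    fixed_points: Optional[list] = None  # filled by find_fixed_points

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s, c, m in zip(self.scales, self.mean_ca, self.metrics):
            rows.append({
                "scale": s,
                "mean_ca_norm": c,
                "burst_period": None if m is None else m.burst_period,
                "duty_cycle": None if m is None else m.duty_cycle,
                "state": None if m is None else m.state_label,
            })
        return pd.DataFrame(rows)


def model_mean_calcium(model: NeuronModel, tier: SimTier = QUICK) -> float:
    """A model's own long-run average calcium (its regulation target)."""
    res = simulate(model, tier.burn_in + tier.window, dt=tier.dt,
                   burn_in=tier.burn_in)
    return mean_calcium(res)


def _scale_mean_ca(model: NeuronModel, scale: float, tier: SimTier,
                   cfg: Optional[ClassifierConfig] = None):
    """(normalised-free mean Ca, metrics) at one ray scale; NaN on divergence."""
    try:
        res = simulate(model.scaled(scale), tier.burn_in + tier.window,
                       dt=tier.dt, burn_in=tier.burn_in)
    except SimulationDiverged:
        return np.nan, None
    tm = trace_metrics(res, cfg or ClassifierConfig())
    return tm.mean_Ca, tm


def scan_ray(model: NeuronModel, ca_target: float,
             scales: Optional[Sequence[float]] = None,
             tier: SimTier = QUICK,
             classifier: Optional[ClassifierConfig] = None) -> RayScan:
    """Mean calcium and burst metrics at each uniform scaling of the model.

    ``scales`` defaults to the tier's log-spaced grid; scale 1 (the model
    itself) is always included.  Divergent simulations are recorded as
    missing rather than fatal.
    """
    if scales is None:
        scales = np.geomspace(tier.scale_min, tier.scale_max, tier.n_scales)
    scales = np.unique(np.concatenate([np.asarray(scales, float), [1.0]]))
    mean_ca = np.empty(len(scales))
    metrics: List[Optional[TraceMetrics]] = []
    for i, s in enumerate(scales):
        ca, tm = _scale_mean_ca(model, s, tier, classifier)
        mean_ca[i] = ca / ca_target
        metrics.append(tm)
    return RayScan(model, ca_target, scales, mean_ca, metrics, tier)


def _confirmed_sides(y: np.ndarray, floor: float):
    """Indices and signs of points clearly off the target level.

    Excursions smaller than ``floor`` (relative units) are treated as
    finite-window jitter and do not generate crossings.
    """
    idx = np.flatnonzero((np.abs(y) > floor) & np.isfinite(y))
    return idx, np.sign(y[idx])


def find_fixed_points(scan: RayScan, floor: float = 0.05,
                      refine: bool = True, n_bisect: int = 4
                      ) -> List[Tuple[float, bool]]:
    """Fixed points of the regulator along the ray: (scale, is_stable).

    Crossings of the target level are detected with a hysteresis band of
    ``floor`` (relative to the target) to suppress sampling jitter, then
    optionally refined by bisection simulations between the bracketing grid
    scales.  A crossing with positive slope of mean calcium versus scale is
    stable (negative feedback restores motion toward it).
    """
    if len(scan.scales) < 10:
        raise ValueError("ray scan too coarse for fixed-point detection")
    y = scan.mean_ca - 1.0
    idx, signs = _confirmed_sides(y, floor)
    fps: List[Tuple[float, bool]] = []
    for a, b, sa, sb in zip(idx[:-1], idx[1:], signs[:-1], signs[1:]):
        if sa == sb:
            continue
        stable = sb > sa  # upward crossing: calcium rises through target
        s_lo, s_hi = scan.scales[a], scan.scales[b]
        if refine:
            f_lo = y[a]
            for _ in range(n_bisect):
                s_mid = float(np.sqrt(s_lo * s_hi))
                ca_mid, _ = _scale_mean_ca(scan.model, s_mid, scan.tier)
                if not np.isfinite(ca_mid):
                    break
                y_mid = ca_mid / scan.ca_target - 1.0
                if np.sign(y_mid) == np.sign(f_lo) or y_mid == 0.0:
                    s_lo, f_lo = s_mid, y_mid
                else:
                    s_hi = s_mid
            s_star = float(np.sqrt(s_lo * s_hi))
        else:
            # log-linear interpolation on the grid bracket
            w = y[a] / (y[a] - y[b])
            s_star = float(np.exp((1 - w) * np.log(s_lo) + w * np.log(s_hi)))
        fps.append((s_star, bool(stable)))
    scan.fixed_points = fps
    return fps


def compensation_outcomes(scans: Sequence[RayScan],
                          targets: Sequence[TraceMetrics],
                          classifier: Optional[ClassifierConfig] = None
                          ) -> pd.DataFrame:
    """Burst metrics at every stable fixed point, normalised per model.

    ``targets`` holds each model's own target metrics (burst period and duty
    cycle of the unscaled model).  Silent or undefined fixed-point dynamics
    are recorded with NaN normalised metrics, not dropped.
    """
    rows = []
    for model_idx, (scan, tgt) in enumerate(zip(scans, targets)):
        fps = scan.fixed_points
        if fps is None:
            fps = find_fixed_points(scan)
        for s_star, stable in fps:
            if not stable:
                continue
            _, tm = _scale_mean_ca(scan.model, s_star, scan.tier, classifier)
            row = {"model": model_idx, "scale": s_star,
                   "period_norm": np.nan, "duty_norm": np.nan,
                   "state": None if tm is None else tm.state_label}
            if (tm is not None and tm.burst_period is not None
                    and tgt.burst_period):
                row["period_norm"] = tm.burst_period / tgt.burst_period
            if tm is not None and tm.duty_cycle is not None and tgt.duty_cycle:
                row["duty_norm"] = tm.duty_cycle / tgt.duty_cycle
            rows.append(row)
    return pd.DataFrame(rows,
                        columns=["model", "scale", "period_norm",
                                 "duty_norm", "state"])
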