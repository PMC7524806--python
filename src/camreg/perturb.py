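"""Generic high-dimensional conductance perturbations and recovery.

A perturbation of the conductance vector is summarised by the mean and
standard deviation (N-1 denominator) of the per-channel relative changes
(g - g0)/g0.  Zero deviation means a pure scaling — equivalent to a size
change — while large deviation disrupts the conductance ratios that the
master regulator is built to preserve.  Recovery experiments run the
closed-loop system from a perturbed model and report the terminal burst
metrics.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional

import numpy as np
import pandas as pd

from .config import QUICK, SimTier
from .metrics import ClassifierConfig, trace_metrics
from .model import NeuronModel, SimulationDiverged, simulate
from .regulation import run_closed_loop_to_convergence, set_regulation_timescales

__all__ = ["PerturbationSummary", "summarise", "sample_perturbations",
           "recovery_experiment", "recovery_sweep"]


@dataclass(frozen=True)
class PerturbationSummary:
    mu: float  # mean relative conductance change
    sigma: float  # standard deviation of relative changes (N-1 denominator)
    rel: np.ndarray  # per-channel (g - g0)/g0


def summarise(g0: np.ndarray, g: np.ndarray) -> PerturbationSummary:
    g0 = np.asarray(g0, float)
    g = np.asarray(g, float)
    if np.any(g0 <= 0):
        raise ValueError("baseline conductances must be strictly positive")
    rel = (g - g0) / g0
    return PerturbationSummary(mu=float(rel.mean()),
                               sigma=float(rel.std(ddof=1)), rel=rel)


def sample_perturbations(model: NeuronModel, mu: float, sigma: float,
                         n: int, seed: int = 0,
                         max_retries: int = 1000) -> List[NeuronModel]:
    """Perturbed models whose realised (mu, sigma) match the request exactly.

    Relative changes are drawn from a normal distribution and then
    re-standardised to the requested sample moments; vectors that would
    produce a negative conductance are redrawn.  ``sigma = 0`` gives the
    pure scaling (1 + mu).
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    rng = np.random.default_rng(seed)
    out = []
    nchan = len(model.gbar)
    for _ in range(n):
        for attempt in range(max_retries):
            if sigma == 0.0:
                rel = np.full(nchan, mu)
            else:
                z = rng.standard_normal(nchan)
                sd = z.std(ddof=1)
                if sd == 0.0:
                    continue
                z = (z - z.mean()) / sd
                rel = mu + sigma * z
            if np.all(rel >= -1.0):
                out.append(model.with_gbar(model.gbar * (1.0 + rel)))
                break
        else:
            raise RuntimeError(
                f"could not draw a non-negative perturbation for "
                f"mu={mu}, sigma={sigma} in {max_retries} attempts")
    return out


def recovery_experiment(perturbed: NeuronModel, reference: NeuronModel,
                        ca_target: float, classifier: ClassifierConfig,
                        tier: SimTier = QUICK) -> dict:
    """Run the closed loop from a perturbed model to steady state.

    The controller is the reference model's (its timescales and calcium
    target); mRNA starts at the perturbed conductance levels.  Returns the
    terminal state label, burst period and duty cycle (NaN when undefined).
    """
    reg = set_regulation_timescales(reference, ca_target)
    reg.mu = perturbed.gbar.copy()
    try:
        end_model, converged, t_el, _ = run_closed_loop_to_convergence(
            perturbed, reg, dt=tier.dt, chunk=tier.reg_chunk,
            max_time=tier.reg_max_time, tol=tier.reg_tol)
    except SimulationDiverged:
        return {"label": "divergent", "period": np.nan, "duty": np.nan,
                "converged": False, "t_model": np.nan}
    if not converged:
        return {"label": "unconverged", "period": np.nan, "duty": np.nan,
                "converged": False, "t_model": t_el}
    try:
        res = simulate(end_model, tier.burn_in + tier.window, dt=tier.dt,
                       burn_in=tier.burn_in)
        tm = trace_metrics(res, classifier)
    except SimulationDiverged:
        return {"label": "divergent", "period": np.nan, "duty": np.nan,
                "converged": True, "t_model": t_el}
    return {"label": tm.state_label,
            "period": np.nan if tm.burst_period is None else tm.burst_period,
            "duty": np.nan if tm.duty_cycle is None else tm.duty_cycle,
            "converged": True, "t_model": t_el}


def recovery_sweep(reference: NeuronModel, ca_target: float,
                   classifier: ClassifierConfig,
                   mus, sigmas, n_per_cell: int = 3, seed: int = 0,
                   tier: SimTier = QUICK) -> pd.DataFrame:
    """Grid of recovery experiments over perturbation (mu, sigma) cells."""
    rows = []
    for i, mu in enumerate(mus):
        for j, sigma in enumerate(sigmas):
            cell_seed = seed + 1000 * i + j
            models = sample_perturbations(reference, mu, sigma, n_per_cell,
                                          seed=cell_seed)
            for k, pm in enumerate(models):
                out = recovery_experiment(pm, reference, ca_target,
                                          classifier, tier)
                rows.append({"mu": mu, "sigma": sigma, "replicate": k,
                             "seed": cell_seed, **out})
    return pd.DataFrame(rows)
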