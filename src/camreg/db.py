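"""Seeded random databases of bursting neuron models (synthetic data).

Models are drawn uniformly from a hypercube in the 8-dimensional space of
conductance densities and kept when their simulated dynamics are regular
bursting with burst period and duty cycle within tolerance of a target
activity (by default the reference model's).  This is the population over
which the fixed-point census and compensation statistics are computed.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional

import numpy as np
import pandas as pd

from .channels import CHANNEL_ORDER
from .config import QUICK, SimTier
from .metrics import ClassifierConfig, TraceMetrics, trace_metrics
from .model import (NeuronModel, SimulationDiverged, reference_model,
                    simulate)

__all__ = ["DbConfig", "ModelRecord", "generate", "save_db", "load_db"]

_SCHEMA_VERSION = 1


@dataclass(frozen=True)
class DbConfig:
    """Sampling bounds, acceptance bands and budget for one database."""

    lo: np.ndarray  # per-channel lower bounds, uS/mm^2
    hi: np.ndarray  # per-channel upper bounds
    target_period: float  # ms
    target_duty: float
    period_tol: float = 0.20  # fractional acceptance band
    duty_tol: float = 0.20
    count: int = 30
    seed: int = 0
    draw_budget: int = 6000
    cv_gate: float = 0.20

    def __post_init__(self):
        lo = np.asarray(self.lo, float)
        hi = np.asarray(self.hi, float)
        if lo.shape != (8,) or hi.shape != (8,):
            raise ValueError("bounds must be length-8 vectors")
        if np.any(lo < 0) or np.any(hi < lo):
            raise ValueError("bounds must satisfy 0 <= lo <= hi")
        if min(self.period_tol, self.duty_tol) <= 0:
            raise ValueError("tolerances must be positive")
        object.__setattr__(self, "lo", lo)
        object.__setattr__(self, "hi", hi)

    @classmethod
    def default(cls, target_period: float, target_duty: float,
                seed: int = 0, count: int = 30,
                draw_budget: int = 6000) -> "DbConfig":
        ref = reference_model().gbar
        return cls(lo=np.zeros(8), hi=2.0 * ref,
                   target_period=target_period, target_duty=target_duty,
                   seed=seed, count=count, draw_budget=draw_budget)


@dataclass
class ModelRecord:
    gbar: np.ndarray
    metrics: TraceMetrics
    mean_ca: float  # the model's own calcium target, uM
    seed: int
    draw_index: int

    @property
    def model(self) -> NeuronModel:
        return NeuronModel(self.gbar)


def _accepts(tm: TraceMetrics, cfg: DbConfig) -> bool:
    if tm.burst_period is None or tm.duty_cycle is None:
        return False
    if tm.period_cv is not None and tm.period_cv > cfg.cv_gate:
        return False
    if tm.n_spikes_per_burst is not None and tm.n_spikes_per_burst < 2:
        return False
    return (abs(tm.burst_period / cfg.target_period - 1) <= cfg.period_tol
            and abs(tm.duty_cycle / cfg.target_duty - 1) <= cfg.duty_tol)


def generate(cfg: DbConfig, tier: SimTier = QUICK,
             verbose: bool = False) -> List[ModelRecord]:
    """Rejection sampling until ``cfg.count`` models or budget exhaustion.

    Fully reproducible from ``cfg.seed``.  On budget exhaustion the partial
    database is returned with a warning.
    """
    rng = np.random.default_rng(cfg.seed)
    records: List[ModelRecord] = []
    n_drawn = 0
    classifier = ClassifierConfig()
    while len(records) < cfg.count and n_drawn < cfg.draw_budget:
        gbar = rng.uniform(cfg.lo, cfg.hi)
        n_drawn += 1
        model = NeuronModel(gbar)
        try:
            res = simulate(model, tier.burn_in + tier.window, dt=tier.dt,
                           burn_in=tier.burn_in)
        except SimulationDiverged:
            continue
        tm = trace_metrics(res, classifier)
        if _accepts(tm, cfg):
            records.append(ModelRecord(gbar, tm, tm.mean_Ca, cfg.seed,
                                       n_drawn - 1))
            if verbose:
                print(f"accepted {len(records)}/{cfg.count} "
                      f"after {n_drawn} draws")
    if len(records) < cfg.count:
        import warnings

        warnings.warn(f"draw budget exhausted: {len(records)}/{cfg.count} "
                      f"models accepted from {n_drawn} draws")
    return records


def save_db(records: List[ModelRecord], cfg: DbConfig, path) -> None:
    """CSV of conductances/metrics + JSON manifest (seed, bounds, schema)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in records:
        row = {f"g_{n}": g for n, g in zip(CHANNEL_ORDER, rec.gbar)}
        row.update(burst_period=rec.metrics.burst_period,
                   duty_cycle=rec.metrics.duty_cycle,
                   n_spikes_per_burst=rec.metrics.n_spikes_per_burst,
                   period_cv=rec.metrics.period_cv,
                   mean_ca=rec.mean_ca, seed=rec.seed,
                   draw_index=rec.draw_index)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path / "models.csv", index=False)
    manifest = {
        "schema_version": _SCHEMA_VERSION,
        "seed": cfg.seed,
        "count": len(records),
        "lo": cfg.lo.tolist(),
        "hi": cfg.hi.tolist(),
        "target_period": cfg.target_period,
        "target_duty": cfg.target_duty,
        "period_tol": cfg.period_tol,
        "duty_tol": cfg.duty_tol,
    }
    (path / "manifest.json").write_text(json.dumps(manifest, indent=2))


def load_db(path):
    """Round-trip load: (records, config).  Rejects unknown schema versions."""
    path = Path(path)
    manifest = json.loads((path / "manifest.json").read_text())
    if manifest.get("schema_version") != _SCHEMA_VERSION:
        raise ValueError(
            f"unsupported database schema {manifest.get('schema_version')!r}")
    df = pd.read_csv(path / "models.csv")
    cfg = DbConfig(lo=np.array(manifest["lo"]), hi=np.array(manifest["hi"]),
                   target_period=manifest["target_period"],
                   target_duty=manifest["target_duty"],
                   period_tol=manifest["period_tol"],
                   duty_tol=manifest["duty_tol"],
                   count=manifest["count"], seed=manifest["seed"])
    records = []
    for _, row in df.iterrows():
        gbar = np.array([row[f"g_{n}"] for n in CHANNEL_ORDER])
        tm = TraceMetrics(np.empty(0), row["burst_period"],
                          row["duty_cycle"], row["n_spikes_per_burst"],
                          row["period_cv"], mean_Ca=row["mean_ca"])
        tm.state_label = "canonical"
        records.append(ModelRecord(gbar, tm, row["mean_ca"],
                                   int(row["seed"]), int(row["draw_index"])))
    return records, cfg
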