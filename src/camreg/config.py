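"""Simulation tiers and YAML config plumbing.

Two tiers ship with the package: ``quick`` (desk-scale — the sizes used by
the test suite and the acceptance script) and ``full`` (full-scale
population sizes and longer averaging windows).  All durations in ms.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["SimTier", "QUICK", "FULL", "get_tier", "load_yaml", "dump_yaml"]


@dataclass(frozen=True)
class SimTier:
    name: str
    dt: float = 0.05
    burn_in: float = 10_000.0
    window: float = 20_000.0
    #: ray-scan grid
    scale_min: float = 0.05
    scale_max: float = 3.0
    n_scales: int = 30
    #: database
    db_count: int = 30
    db_draw_budget: int = 6000
    #: closed-loop runs
    reg_chunk: float = 50_000.0
    reg_max_time: float = 500_000.0
    reg_tol: float = 0.005
    #: plane sampling
    plane_budget: int = 140
    plane_n_init: int = 25

    def replace(self, **kw) -> "SimTier":
        return dataclasses.replace(self, **kw)


QUICK = SimTier(name="quick", burn_in=5_000.0, window=10_000.0)
FULL = SimTier(name="full", db_count=635, db_draw_budget=60_000,
                plane_budget=600, plane_n_init=40)


def get_tier(name: str) -> SimTier:
    tiers = {"quick": QUICK, "full": FULL}
    if name not in tiers:
        raise KeyError(f"unknown tier {name!r}; expected one of {sorted(tiers)}")
    return tiers[name]


def load_yaml(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def dump_yaml(obj, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=False)


def tier_from_config(cfg: dict) -> SimTier:
    """Build a tier from a config mapping: {tier: quick, overrides: {...}}."""
    tier = get_tier(cfg.get("tier", "quick"))
    overrides = cfg.get("overrides") or {}
    unknown = set(overrides) - {f.name for f in dataclasses.fields(SimTier)}
    if unknown:
        raise KeyError(f"unknown override keys: {sorted(unknown)}")
    return tier.replace(**overrides)
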