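#!/usr/bin/env python
"""Level set, acute map, basins and robustness segmentation in the
calcium-vs-rest conductance plane.

Writes the calcium level set, the acute (fixed-parameter) classification,
the basin-of-attraction labels under regulation, and the four-way
robustness segmentation under results/plane/.
"""
import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from camreg import reference_model, simulate, trace_metrics
from camreg.config import QUICK
from camreg.metrics import ClassifierConfig
from camreg.plane import (acute_map, adaptive_level_set, basin_map,
                          default_planes, diagonal_crossings,
                          segment_robustness)


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--budget-level", type=int, default=140)
    ap.add_argument("--budget-basin", type=int, default=60)
    ap.add_argument("--out", type=Path, default=Path("results/plane"))
    args = ap.parse_args()

    ref = reference_model()
    res = simulate(ref, QUICK.burn_in + QUICK.window, burn_in=QUICK.burn_in)
    tm = trace_metrics(res)
    clf = ClassifierConfig().with_targets(tm.burst_period, tm.duty_cycle)
    plane = default_planes(ref)["calcium"]
    args.out.mkdir(parents=True, exist_ok=True)

    level = adaptive_level_set(plane, level=tm.mean_Ca,
                               budget=args.budget_level, seed=args.seed)
    level.to_frame().to_csv(args.out / "level_set_samples.csv", index=False)
    pd.DataFrame(level.level_points(), columns=["x", "y"]).to_csv(
        args.out / "level_set_points.csv", index=False)
    print(f"calcium level set: {len(level.segments)} segments, "
          f"{diagonal_crossings(level)} diagonal crossing(s)")

    basins = basin_map(plane, tm.mean_Ca, clf, budget=args.budget_basin,
                       seed=args.seed)
    basins.to_frame().to_csv(args.out / "basin_samples.csv", index=False)
    counts = pd.Series(basins.labels).value_counts()
    print("basin labels:\n" + counts.to_string())

    acute = acute_map(plane, basins.points, clf)
    acute.to_frame().to_csv(args.out / "acute_samples.csv", index=False)
    seg = segment_robustness(acute, basins)
    seg.to_frame().to_csv(args.out / "segmentation.csv", index=False)
    seg_counts = pd.Series(seg.labels).value_counts()
    print("robustness segmentation:\n" + seg_counts.to_string())


if __name__ == "__main__":
    main()
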