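#!/usr/bin/env python
"""Agonist-potency metrics (NPo and mean open time) on multi-channel patches.

Simulates a patch holding two independent channels gated by a weak agonist
(low opening rate), sums their occupancy, and computes NPo = sum_i i*P_o,i
over simultaneously-open levels plus the mean single-level open time — the
metrics used to rank the PEG-QA compounds' intrinsic agonist activity.
Writes results/04_agonist_activity.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from pegblock.blockade import agonist_activity
from pegblock.schemes import CLOSED, OPEN, Conditions, Edge, KineticScheme, RateLaw
from pegblock.simulate import simulate_dwells

OUT = Path(__file__).resolve().parents[1] / "results"


def level_events(dwell_list, dt=1e-4, horizon=120.0):
    """Sum per-channel occupancy on a grid and run-length encode the levels."""
    grid = None
    for d in dwell_list:
        codes, durs = d.class_dwells()
        edges = np.concatenate(([0.0], np.cumsum(durs)))
        mid = np.arange(int(horizon / dt)) * dt + dt / 2
        lv = codes[np.clip(np.searchsorted(edges, mid, "right") - 1, 0, len(durs) - 1)]
        grid = lv.astype(int) if grid is None else grid + lv
    change = np.flatnonzero(np.diff(grid)) + 1
    starts = np.concatenate(([0], change))
    lens = np.diff(np.concatenate((starts, [grid.size])))
    return grid[starts], lens * dt


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    rows = []
    for name, opening in (("strong agonist", 150.0), ("weak agonist", 12.0)):
        scheme = KineticScheme(
            ["C", "O"], {"C": CLOSED, "O": OPEN},
            [Edge("C", "O", RateLaw(opening), "opening"),
             Edge("O", "C", RateLaw(400.0), "closing")],
        )
        for cell in range(3):
            chans = [simulate_dwells(scheme, Conditions(), total_time=130.0,
                                     seed=10 * cell + k) for k in (1, 2)]
            levels, durs = level_events(chans)
            act = agonist_activity(levels, durs, N_max=2)
            rows.append({"compound": name, "cell": cell, "NPo": act.NPo,
                         "mean_open_ms": act.mean_open_time * 1e3})
    df = pd.DataFrame(rows)
    df.to_csv(OUT / "04_agonist_activity.csv", index=False)
    print(df.to_string(index=False))
    g = df.groupby("compound")["NPo"].agg(["mean", "std"])
    print("\nNPo (mean ± SD over 3 synthetic cells):")
    print(g.to_string())
    print("\nfinding: the weak agonist's NPo is an order of magnitude lower, "
          "mirroring how channel activity ranks agonist potency.")


if __name__ == "__main__":
    main()
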