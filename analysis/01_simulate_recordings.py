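#!/usr/bin/env python
"""Generate the synthetic single-channel dose series and describe it.

Simulates the study design — 100 µM ACh, blocker at 0/5/10/20 µM, three
cells, 3000 events per recording — from the AChR gating + one-blocked-state
scheme with the reference blockade kinetics (k+B = 15 µM^-1 s^-1,
k-B = 2 s^-1), and writes the true dwell sequences (DWT) plus a manifest
under results/01_recordings/.  Prints per-condition record statistics:
apparent mean open time falls with dose while long blocked dwells appear.
"""

import json
from pathlib import Path

import numpy as np

from pegblock import io as pio
from pegblock.pipeline import PipelineConfig, events_from_dwells
from pegblock.simulate import synth_experiment

OUT = Path(__file__).resolve().parents[1] / "results" / "01_recordings"


def main() -> None:
    config = PipelineConfig(doses_uM=[0.0, 5.0, 10.0, 20.0], master_seed=1)
    OUT.mkdir(parents=True, exist_ok=True)
    recordings = synth_experiment(config.experiment(), config.master_seed)
    chash = config.config_hash()

    rows = []
    for rec in recordings:
        ev = events_from_dwells(rec)
        pio.write_dwt(OUT / f"cell{rec.cell}_dose{rec.dose_uM:g}.dwt", ev,
                      comment=f"config_hash={chash} true dwell sequence")
        opens = ev.open_durations()
        rows.append({
            "cell": rec.cell, "dose_uM": rec.dose_uM,
            "record_s": round(ev.total_time, 1),
            "n_events": len(ev),
            "tau_app_ms": round(float(opens.mean()) * 1e3, 3),
            "n_clusters": int(rec.dwells.cluster_ids.max()) + 1,
        })
    (OUT / "manifest.json").write_text(json.dumps(
        {"config_hash": chash, "config": config.to_dict(), "datasets": rows}, indent=1))

    print(f"wrote {len(recordings)} recordings to {OUT}")
    print(f"{'cell':>4} {'dose µM':>8} {'record s':>9} {'τ_app ms':>9} {'clusters':>9}")
    for r in rows:
        print(f"{r['cell']:>4} {r['dose_uM']:>8g} {r['record_s']:>9} "
              f"{r['tau_app_ms']:>9} {r['n_clusters']:>9}")
    tau0 = np.mean([r["tau_app_ms"] for r in rows if r["dose_uM"] == 0])
    tau20 = np.mean([r["tau_app_ms"] for r in rows if r["dose_uM"] == 20])
    print(f"\nfinding: mean open time falls from {tau0:.2f} ms (control) to "
          f"{tau20:.2f} ms at 20 µM blocker — the open-channel-block signature.")


if __name__ == "__main__":
    main()
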