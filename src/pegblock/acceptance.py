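"""Reference end-to-end runs that reproduce the study's headline numbers.

``pq5_dose_series`` regenerates the dose-dependence experiment with the
blockade kinetics reported for the reference PEG-QA blocker (PQ5):
one-blocked-state scheme, 100 µM ACh, blocker at 0/5/10/20 µM, three
synthetic cells with 3000 events each, rendered at 10 kHz and processed by
the full SKM idealization (0.2 ms dead time) + two-stage MIL pipeline.
``complexity_ratio`` recomputes the fold-difference in Bertz complexity
between (+)-tubocurarine and the PQ2–PQ5 set from the bundled structures.
"""

from __future__ import annotations

from typing import Any

from .blockade import ModeSummary
from .complexity import affinity_complexity_table, score_blockers
from .pipeline import PipelineConfig, analyze_experiment
from .simulate import synth_experiment


def pq5_dose_series(master_seed: int = 1, n_cells: int = 3, n_events: int = 3000,
                    render: bool = True) -> dict[str, Any]:
    """Simulate + idealize + fit the PQ5-like dose series; returns the
    analysis dict of :func:`pegblock.pipeline.analyze_experiment` plus the
    headline mode summary under ``"mode"``."""
    config = PipelineConfig(
        doses_uM=[0.0, 5.0, 10.0, 20.0],
        n_cells=n_cells,
        n_events=n_events,
        master_seed=master_seed,
        render=render,
    )
    recordings = synth_experiment(config.experiment(), config.master_seed)
    result = analyze_experiment(recordings, config)
    mode: ModeSummary = result["summary"].modes["single"]
    result["mode"] = mode
    result["config"] = config
    return result


def complexity_ratio() -> tuple[float, int]:
    """Bertz fold-complexity ratio (+)-tubocurarine / mean(PQ2-5) from the
    bundled reconstructed structures; returns (ratio, n_compounds)."""
    df = score_blockers()
    _, ratio = affinity_complexity_table(df)
    return ratio, len(df)
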