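"""End-to-end dose-series pipeline: simulate -> idealize -> fit -> summarize.

The analysis chain mirrors single-channel practice for open-channel block:

1. simulate (or load) one recording per (cell, dose) at fixed agonist
   concentration;
2. idealize each trace with SKM and impose the dead time;
3. per cell, estimate the gating rates (opening/closing and the three
   desensitization pairs) by MIL on the blocker-free control recording;
4. per (cell, dose > 0), estimate the blocking/unblocking rates by MIL with
   the gating rates fixed at that cell's control estimates;
5. aggregate: blocking rate vs. dose slope -> k+B, mean unblocking -> k-B,
   Kd = k-B / k+B, plus the apparent-open-time dose table.

``run_pipeline`` adds configuration validation, per-stage resumability and
provenance (a config hash stamped into every output file).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd

from . import io as pio
from .blockade import apparent_open_time, blocking_kinetics, closed_time_components, BlockadeSummary
from .idealize import IdealizedEvents, impose_dead_time, skm_idealize
from .mil import Dataset, FitResult, fit_mil
from .schemes import Conditions, KineticScheme, build_blockade_scheme
from .simulate import (
    ACHR_GATING_RATES,
    ExperimentConfig,
    SyntheticRecording,
    default_rate_table,
    synth_experiment,
)

__version__ = "0.1.0"

GATING_FREE = ["opening", "closing", "d1_on", "d1_off", "d2_on", "d2_off", "d3_on", "d3_off"]
BLOCK_FREE = {1: ["kb_on", "kb_off"], 2: ["kb_fast_on", "kb_fast_off", "kb_slow_on", "kb_slow_off"]}
# generic data-independent starting guesses for the blockade rates
BLOCK_STARTS = {
    1: {"kb_on": 2.0, "kb_off": 10.0},
    2: {"kb_fast_on": 2.0, "kb_fast_off": 50.0, "kb_slow_on": 2.0, "kb_slow_off": 5.0},
}


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class FitOptions:
    n_starts: int = 4
    jitter_sd: float = 0.7
    bounds: tuple[float, float] = (1e-3, 1e6)
    seed: int = 0


@dataclasses.dataclass
class PipelineConfig:
    """Validated configuration of one dose-series run.

    Unknown keys are rejected with the offending path; ``doses_uM`` is
    required and must include 0 (the gating control) plus at least two
    nonzero doses for the slope fit.
    """

    doses_uM: list[float]
    n_cells: int = 3
    n_events: int = 3000
    conc_ACh_uM: float = 100.0
    rate_table: dict[str, float] = dataclasses.field(default_factory=default_rate_table)
    n_block_modes: int = 1
    amplitude_pA: float = 7.0
    noise_sd_pA: float = 1.0
    sample_rate_hz: float = 10_000.0
    filter_cutoff_hz: float = 4_000.0
    dead_time_ms: float = 0.2
    tau_crit_ms: float | None = None
    master_seed: int = 1
    render: bool = True
    fit: FitOptions = dataclasses.field(default_factory=FitOptions)

    @classmethod
    def from_dict(cls, doc: Mapping[str, Any]) -> "PipelineConfig":
        doc = dict(doc)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "doses_uM" not in doc:
            raise ValueError("config missing required key 'doses_uM'")
        if "fit" in doc and isinstance(doc["fit"], Mapping):
            fit_doc = dict(doc["fit"])
            fit_known = {f.name for f in dataclasses.fields(FitOptions)}
            fit_unknown = set(fit_doc) - fit_known
            if fit_unknown:
                raise ValueError(f"unknown config keys under 'fit': {sorted(fit_unknown)}")
            if "bounds" in fit_doc:
                fit_doc["bounds"] = tuple(fit_doc["bounds"])
            doc["fit"] = FitOptions(**fit_doc)
        return cls(**doc)

    def __post_init__(self) -> None:
        if not self.doses_uM:
            raise ValueError("doses_uM must not be empty")
        if any(d < 0 for d in self.doses_uM):
            raise ValueError("doses_uM must be >= 0")
        if self.n_block_modes not in (1, 2):
            raise ValueError("n_block_modes must be 1 or 2")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["fit"]["bounds"] = list(d["fit"]["bounds"])
        return d

    def config_hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]

    def experiment(self) -> ExperimentConfig:
        return ExperimentConfig(
            doses_uM=tuple(self.doses_uM),
            n_cells=self.n_cells,
            n_events=self.n_events,
            conc_ACh=self.conc_ACh_uM,
            rate_table=dict(self.rate_table),
            n_block_modes=self.n_block_modes,
            amplitude_pA=self.amplitude_pA,
            noise_sd_pA=self.noise_sd_pA,
            sample_rate_hz=self.sample_rate_hz,
            filter_cutoff_hz=self.filter_cutoff_hz,
            render=self.render,
        )


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------

def events_from_dwells(recording: SyntheticRecording) -> IdealizedEvents:
    """Ground-truth idealization: the simulated class dwells themselves."""
    codes, durs = recording.dwells.class_dwells()
    return IdealizedEvents(
        class_codes=codes,
        durations=durs,
        mean_amplitudes=np.full(len(durs), np.nan),
    )


def idealize_recording(recording: SyntheticRecording, config: PipelineConfig) -> IdealizedEvents:
    """SKM-idealize the rendered trace (or pass through the true dwells) and
    impose the configured dead time."""
    if recording.trace is not None:
        events = skm_idealize(recording.trace, n_classes=2)
    else:
        events = events_from_dwells(recording)
    return impose_dead_time(events, config.dead_time_ms * 1e-3)


def heuristic_gating_start(
    events: IdealizedEvents, conc_ACh: float, n_closed_components: int = 4
) -> dict[str, float]:
    """Data-driven starting values for the gating fit.

    The open-dwell mean gives the total open exit rate; an exponential-
    mixture decomposition of the closed dwells supplies candidate lifetimes
    (exit rates) and areas (relative entry frequencies) for C and D1..D3,
    the fastest component playing the role of the activatable closed state.
    """
    opens = events.open_durations()
    closeds = events.closed_durations()
    if opens.size < 10 or closeds.size < 50:
        raise ValueError("too few dwells for a gating fit")
    exit_rate = 1.0 / float(opens.mean())
    mix = closed_time_components(closeds, n_components=n_closed_components)
    taus, areas = mix.taus, mix.areas
    while taus.size < n_closed_components:  # EM dropped a component
        taus = np.append(taus, taus[-1] * 10.0)
        areas = np.append(areas, 1.0 / closeds.size)
    start = {
        "opening": max(1.0 / taus[0] / max(conc_ACh, 1e-9), 1e-3),
        "closing": max(exit_rate * areas[0], 1e-3),
    }
    for k, d in enumerate(("d1", "d2", "d3"), start=1):
        start[f"{d}_on"] = max(exit_rate * areas[k], 1e-3)
        start[f"{d}_off"] = max(1.0 / taus[k], 1e-3)
    return start


def fit_gating(
    events: IdealizedEvents, cond: Conditions, config: PipelineConfig
) -> FitResult:
    """MIL fit of the 8 gating rates on a blocker-free recording."""
    start = heuristic_gating_start(events, cond.conc_ACh)
    table = {**{k: ACHR_GATING_RATES[k] for k in GATING_FREE}, **start}
    scheme = build_blockade_scheme({**default_rate_table(1), **table}, n_block_modes=1)
    # restrict to the gating sub-model: blocker absent, kb rates inert
    ds = Dataset(events.class_codes, events.durations, cond, dead_time=events.dead_time)
    return fit_mil(
        scheme,
        [ds],
        free=GATING_FREE,
        start=start,
        bounds=config.fit.bounds,
        n_starts=config.fit.n_starts,
        jitter_sd=config.fit.jitter_sd,
        seed=config.fit.seed,
    )


def fit_block(
    events: IdealizedEvents,
    cond: Conditions,
    gating: Mapping[str, float],
    config: PipelineConfig,
) -> FitResult:
    """MIL fit of the blockade rates with the gating fixed per cell."""
    n_modes = config.n_block_modes
    free = BLOCK_FREE[n_modes]
    table = {**{k: float(gating[k]) for k in GATING_FREE}, **BLOCK_STARTS[n_modes]}
    scheme = build_blockade_scheme(table, n_block_modes=n_modes)
    ds = Dataset(events.class_codes, events.durations, cond, dead_time=events.dead_time)
    return fit_mil(
        scheme,
        [ds],
        free=free,
        start=BLOCK_STARTS[n_modes],
        bounds=config.fit.bounds,
        n_starts=config.fit.n_starts,
        jitter_sd=config.fit.jitter_sd,
        seed=config.fit.seed,
    )


def analyze_experiment(
    recordings: Sequence[SyntheticRecording],
    config: PipelineConfig,
    events_by_key: dict[tuple, IdealizedEvents] | None = None,
) -> dict[str, Any]:
    """Idealize + two-stage MIL + aggregation for a dose-series experiment.

    Returns a dict with the tidy per-dataset ``rates`` table, the
    :class:`BlockadeSummary`, the apparent-open-time table, the per-cell
    gating fits, and the idealized events keyed by (cell, dose).
    """
    events_by_key = dict(events_by_key or {})
    for rec in recordings:
        key = (rec.cell, rec.dose_uM)
        if key not in events_by_key:
            events_by_key[key] = idealize_recording(rec, config)

    cells = sorted({rec.cell for rec in recordings})
    doses = sorted({rec.dose_uM for rec in recordings})
    cond_by_key = {(r.cell, r.dose_uM): Conditions(config.conc_ACh_uM, r.dose_uM, r.V_m)
                   for r in recordings}

    gating_fits: dict[int, FitResult] = {}
    for cell in cells:
        key = (cell, 0.0)
        if key in events_by_key:
            gating_fits[cell] = fit_gating(events_by_key[key], cond_by_key[key], config)

    rows = []
    block_fits: dict[tuple, FitResult] = {}
    for cell in cells:
        if cell in gating_fits:
            gating = gating_fits[cell].estimates
        else:
            # no control recording: fall back to the configured gating table
            gating = {k: config.rate_table[k] for k in GATING_FREE}
        for dose in doses:
            if dose <= 0:
                continue
            key = (cell, dose)
            if key not in events_by_key:
                continue
            fr = fit_block(events_by_key[key], cond_by_key[key], gating, config)
            block_fits[key] = fr
            if config.n_block_modes == 1:
                mode_map = {"single": ("kb_on", "kb_off")}
            else:
                mode_map = {"fast": ("kb_fast_on", "kb_fast_off"),
                            "slow": ("kb_slow_on", "kb_slow_off")}
            for mode, (on, off) in mode_map.items():
                rows.append(
                    {
                        "cell": cell,
                        "dose_uM": dose,
                        "mode": mode,
                        "kb_on_uM_s": fr.estimates[on],
                        "kb_on_se": fr.standard_errors[on],
                        "blocking_rate": fr.estimates[on] * dose,
                        "blocking_se": (fr.standard_errors[on] or np.nan) * dose,
                        "unblocking_rate": fr.estimates[off],
                        "unblocking_se": fr.standard_errors[off],
                        "log_likelihood": fr.log_likelihood,
                        "n_events": fr.n_events,
                        "converged": fr.converged,
                    }
                )
    rates = pd.DataFrame(rows)
    if config.n_block_modes == 2 and not rates.empty:
        # relabel per fit so "fast" is the larger unblocking rate
        rates = rates.drop(columns=["mode"])
        from .blockade import label_modes_by_unblocking

        rates = label_modes_by_unblocking(rates)
    summary = blocking_kinetics(rates) if not rates.empty else None

    tau_rows = []
    for dose in doses:
        per_cell = [events_by_key[(c, dose)].open_durations()
                    for c in cells if (c, dose) in events_by_key]
        if per_cell:
            mean_s, sem_s = apparent_open_time(per_cell)
            tau_rows.append({"dose_uM": dose, "tau_app_ms": mean_s * 1e3,
                             "tau_app_sem_ms": sem_s * 1e3, "n_cells": len(per_cell)})
    tau_app = pd.DataFrame(tau_rows)
    if summary is not None:
        summary.tau_app = tau_app

    return {
        "rates": rates,
        "summary": summary,
        "tau_app": tau_app,
        "gating_fits": gating_fits,
        "block_fits": block_fits,
        "events": events_by_key,
    }


# ---------------------------------------------------------------------------
# run_pipeline: staged, resumable, provenance-stamped
# ---------------------------------------------------------------------------

def summary_to_dict(summary: BlockadeSummary) -> dict:
    out: dict[str, Any] = {"modes": {}}
    for name, m in summary.modes.items():
        out["modes"][name] = {
            "k_plus_B_uM_s": m.k_plus_B,
            "k_plus_B_se": m.k_plus_B_se,
            "k_plus_B_intercept_s": m.k_plus_B_intercept,
            "k_plus_B_through_origin_uM_s": m.k_plus_B_origin,
            "k_minus_B_s": m.k_minus_B,
            "k_minus_B_sem": m.k_minus_B_sem,
            "n_unblocking": m.n_unblocking,
            "Kd_uM": m.Kd_uM,
            "Kd_se_uM": m.Kd_se,
        }
    if summary.tau_app is not None:
        out["tau_app_per_dose"] = summary.tau_app.to_dict(orient="records")
    return out


def run_pipeline(
    config: PipelineConfig | Mapping[str, Any],
    out_dir: str | Path,
    resume: bool = False,
    keep_dwell_files: bool = True,
) -> dict[str, Any]:
    """Run simulate -> idealize -> fit -> summarize, writing a result bundle.

    Identical config (including master_seed) produces identical outputs.
    With ``resume=True``, per-dataset idealized-event files found in
    ``out_dir`` are loaded instead of recomputed.  On a stage failure the
    manifest records the failed stage and partial outputs are kept.
    """
    if not isinstance(config, PipelineConfig):
        config = PipelineConfig.from_dict(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    manifest: dict[str, Any] = {
        "config_hash": chash,
        "master_seed": config.master_seed,
        "version": __version__,
        "stages": {},
        "config": config.to_dict(),
    }
    man_path = out / "manifest.json"

    def mark(stage: str, status: str, **extra) -> None:
        manifest["stages"][stage] = {"status": status, **extra}
        man_path.write_text(json.dumps(manifest, indent=1))

    events_dir = out / "events"
    events_dir.mkdir(exist_ok=True)

    stage = "simulate"
    try:
        t0 = time.time()
        recordings = synth_experiment(config.experiment(), config.master_seed)
        mark(stage, "done", seconds=round(time.time() - t0, 2),
             n_datasets=len(recordings))

        stage = "idealize"
        t0 = time.time()
        events_by_key: dict[tuple, IdealizedEvents] = {}
        for rec in recordings:
            key = (rec.cell, rec.dose_uM)
            fname = events_dir / f"cell{rec.cell}_dose{rec.dose_uM:g}.dwt"
            if resume and fname.exists():
                segs = pio.read_dwt(fname)
                segs[0].dead_time = config.dead_time_ms * 1e-3
                events_by_key[key] = segs[0]
                continue
            ev = idealize_recording(rec, config)
            events_by_key[key] = ev
            if keep_dwell_files:
                pio.write_dwt(fname, ev, comment=f"config_hash={chash}")
        mark(stage, "done", seconds=round(time.time() - t0, 2))

        stage = "fit"
        t0 = time.time()
        result = analyze_experiment(recordings, config, events_by_key=events_by_key)
        rates_path = out / "rates.csv"
        with open(rates_path, "w") as fh:
            fh.write(f"# config_hash={chash}\n")
            result["rates"].to_csv(fh, index=False)
        mark(stage, "done", seconds=round(time.time() - t0, 2))

        stage = "summarize"
        summary = result["summary"]
        doc = {
            "config_hash": chash,
            "master_seed": config.master_seed,
            "summary": None if summary is None else summary_to_dict(summary),
            "gating_estimates": {
                str(cell): fr.estimates for cell, fr in result["gating_fits"].items()
            },
        }
        (out / "summary.json").write_text(json.dumps(doc, indent=1, sort_keys=True))
        mark(stage, "done")
    except Exception as exc:
        mark(stage, "failed", error=str(exc))
        raise
    result["manifest"] = manifest
    result["out_dir"] = out
    return result
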