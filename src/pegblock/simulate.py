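"""Synthetic single-channel recordings with the structure the analysis assumes.

Exact continuous-time Markov-chain (Gillespie) simulation of dwell sequences
from a kinetic scheme, rendering of those dwells into noisy low-pass-filtered
current traces emulating a cell-attached patch, and a dose/voltage/cell
experiment generator that stands in for the study's patch-clamp data set.

Default rate constants emulate adult muscle AChR gating at 100 µM ACh —
clusters of ~ms openings separated by desensitized dwells tens of ms to
seconds long — plus sequential open-channel block with the kinetics measured
for the strongest PEG-bis-quaternary-ammonium blocker (k+B = 15 µM^-1 s^-1,
k-B = 2 s^-1, i.e. Kd = 0.13 µM and blocked dwells of ~0.5 s).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .schemes import (
    CLASS_CODE,
    CLOSED,
    OPEN,
    Conditions,
    KineticScheme,
    build_blockade_scheme,
    equilibrium_distribution,
    generator_matrix,
)

#: AChR-like gating rates used as the study conditions for synthetic data.
#: opening is µM^-1 s^-1 in ACh (200 s^-1 at the standard 100 µM);
#: desensitized lifetimes 20 ms / 80 ms / 1 s, ranked like D1 < D2 < D3.
ACHR_GATING_RATES: dict[str, float] = {
    "opening": 2.0,
    "closing": 150.0,
    "d1_on": 25.0,
    "d1_off": 50.0,
    "d2_on": 8.0,
    "d2_off": 12.5,
    "d3_on": 1.5,
    "d3_off": 1.0,
}

#: One-mode blockade kinetics of the reference PEG-QA blocker (PQ5).
PQ5_BLOCK_RATES: dict[str, float] = {"kb_on": 15.0, "kb_off": 2.0}

#: Two-mode blockade kinetics representative of the smaller-QA blockers
#: (fast mode k-B in the tens of s^-1, slow mode a few s^-1).
TWO_MODE_BLOCK_RATES: dict[str, float] = {
    "kb_fast_on": 10.0,
    "kb_fast_off": 60.0,
    "kb_slow_on": 8.0,
    "kb_slow_off": 3.0,
}


def default_rate_table(n_block_modes: int = 1) -> dict[str, float]:
    """Gating + blockade rate table used by the synthetic experiments."""
    table = dict(ACHR_GATING_RATES)
    table.update(PQ5_BLOCK_RATES if n_block_modes == 1 else TWO_MODE_BLOCK_RATES)
    return table


# ---------------------------------------------------------------------------
# dwell-sequence simulation
# ---------------------------------------------------------------------------

@dataclass
class DwellSequence:
    """State-resolved dwell events from one simulated (or decoded) recording.

    ``states`` are scheme state labels, ``class_codes`` the aggregated
    conductance class per event (0 closed / 1 open), ``durations`` seconds.
    ``cluster_ids`` group events into activation clusters: the counter
    advances each time the channel leaves a desensitized (``D*``) sojourn,
    so a long desensitized dwell closes the cluster it follows.
    """

    states: list[str]
    class_codes: np.ndarray
    durations: np.ndarray
    cluster_ids: np.ndarray
    conditions: Conditions
    seed: int | None = None

    def __post_init__(self) -> None:
        self.class_codes = np.asarray(self.class_codes, dtype=np.int8)
        self.durations = np.asarray(self.durations, dtype=float)
        self.cluster_ids = np.asarray(self.cluster_ids, dtype=int)
        if np.any(self.durations <= 0):
            raise ValueError("durations must be positive")
        for a, b in zip(self.states[:-1], self.states[1:]):
            if a == b:
                raise ValueError("consecutive events must differ in state")

    def __len__(self) -> int:
        return len(self.durations)

    @property
    def total_time(self) -> float:
        return float(self.durations.sum())

    def class_dwells(self) -> tuple[np.ndarray, np.ndarray]:
        """Aggregate consecutive same-class events; classes then alternate."""
        codes = self.class_codes
        if codes.size == 0:
            return codes.copy(), self.durations.copy()
        new_run = np.flatnonzero(np.diff(codes) != 0) + 1
        starts = np.concatenate(([0], new_run))
        agg_codes = codes[starts]
        agg_dur = np.add.reduceat(self.durations, starts)
        return agg_codes, agg_dur

    def open_durations(self) -> np.ndarray:
        codes, durs = self.class_dwells()
        return durs[codes == CLASS_CODE[OPEN]]

    def closed_durations(self) -> np.ndarray:
        codes, durs = self.class_dwells()
        return durs[codes == CLASS_CODE[CLOSED]]


def _resolve_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def simulate_dwells(
    scheme: KineticScheme,
    cond: Conditions,
    n_events: int | None = None,
    total_time: float | None = None,
    seed=None,
    initial_state: str | None = None,
) -> DwellSequence:
    """Exact stochastic simulation of the aggregated Markov chain.

    The sojourn in state i is Exponential(-Q[i, i]); the successor is drawn
    with probabilities Q[i, j] / (-Q[i, i]).  The initial state is drawn from
    the stationary distribution unless given.  Stop after ``n_events`` events
    or once the accumulated time exceeds ``total_time`` (the final dwell is
    kept whole so the sequence remains a sequence of complete sojourns).
    """
    if (n_events is None) == (total_time is None):
        raise ValueError("specify exactly one of n_events or total_time")
    if n_events is not None and n_events <= 0:
        raise ValueError("n_events must be positive")
    if total_time is not None and total_time <= 0:
        raise ValueError("total_time must be positive")
    rng = _resolve_rng(seed)
    Q = generator_matrix(scheme, cond)
    n = Q.shape[0]
    exit_rates = -np.diag(Q)
    if np.any(exit_rates <= 0):
        raise RuntimeError("absorbing state in scheme; invariants violated")
    P = Q / exit_rates[:, None]
    np.fill_diagonal(P, 0.0)
    cum_P = np.cumsum(P, axis=1)
    if initial_state is None:
        pi = equilibrium_distribution(Q)
        state = int(rng.choice(n, p=pi))
    else:
        state = scheme.state_index(initial_state)

    class_codes = scheme.class_codes()
    desensitized = np.array([s.startswith("D") for s in scheme.states])

    states: list[int] = []
    durations: list[float] = []
    clusters: list[int] = []
    cluster = 0
    t_acc = 0.0
    while True:
        dwell = rng.exponential(1.0 / exit_rates[state])
        states.append(state)
        durations.append(dwell)
        clusters.append(cluster)
        if desensitized[state]:
            cluster += 1  # leaving a desensitized sojourn starts a new cluster
        t_acc += dwell
        if n_events is not None and len(states) >= n_events:
            break
        if total_time is not None and t_acc >= total_time:
            break
        state = int(np.searchsorted(cum_P[state], rng.random(), side="right"))
        state = min(state, n - 1)

    return DwellSequence(
        states=[scheme.states[i] for i in states],
        class_codes=class_codes[np.array(states, dtype=int)],
        durations=np.array(durations),
        cluster_ids=np.array(clusters, dtype=int),
        conditions=cond,
        seed=None if isinstance(seed, np.random.Generator) else seed,
    )


# ---------------------------------------------------------------------------
# trace rendering
# ---------------------------------------------------------------------------

#: Gaussian filter: -3 dB amplitude cutoff f_c corresponds to a time-domain
#: sigma of 0.1325 / f_c (sqrt(ln 2) / (2 pi f_c)).
GAUSSIAN_SIGMA_FACTOR = float(np.sqrt(np.log(2.0)) / (2.0 * np.pi))


@dataclass
class SampledTrace:
    """Uniformly sampled, filtered, noisy current record (pA)."""

    samples: np.ndarray
    sample_rate: float
    amplitudes: tuple[float, float]  # (closed, open) pA; open more positive
    noise_sd: float
    filter_cutoff: float | None
    conditions: Conditions | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.size < 1:
            raise ValueError("trace must contain at least one sample")
        if self.filter_cutoff is not None and self.sample_rate <= 2.0 * self.filter_cutoff:
            raise ValueError("sample_rate must exceed twice the filter cutoff")

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.sample_rate


def render_trace(
    dwells: DwellSequence | tuple[np.ndarray, np.ndarray],
    amplitudes: tuple[float, float] = (0.0, 7.0),
    noise_sd: float = 1.0,
    sample_rate: float = 10_000.0,
    filter_cutoff: float | None = 4_000.0,
    seed=None,
    conditions: Conditions | None = None,
) -> SampledTrace:
    """Render class dwells into a sampled current trace.

    The piecewise-constant ideal current (closed/open amplitudes, openings as
    positive deflections) is convolved with a Gaussian low-pass kernel whose
    -3 dB cutoff is ``filter_cutoff`` (``None`` disables filtering), then
    i.i.d. Gaussian noise of SD ``noise_sd`` is added at the samples.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if filter_cutoff is not None and sample_rate <= 2.0 * filter_cutoff:
        raise ValueError("sample_rate must exceed twice the filter cutoff")
    if isinstance(dwells, DwellSequence):
        codes, durs = dwells.class_dwells()
        conditions = conditions or dwells.conditions
    else:
        codes, durs = dwells
        codes = np.asarray(codes, dtype=int)
        durs = np.asarray(durs, dtype=float)
    amp = np.asarray(amplitudes, dtype=float)
    edges = np.concatenate(([0.0], np.cumsum(durs)))
    n = int(np.floor(edges[-1] * sample_rate))
    if n < 1:
        raise ValueError("dwell sequence shorter than one sampling interval")
    t_mid = (np.arange(n) + 0.5) / sample_rate
    which = np.clip(np.searchsorted(edges, t_mid, side="right") - 1, 0, len(durs) - 1)
    ideal = amp[codes[which]]
    if filter_cutoff is not None:
        sigma = GAUSSIAN_SIGMA_FACTOR * sample_rate / filter_cutoff
        ideal = gaussian_filter1d(ideal, sigma, mode="nearest")
    rng = _resolve_rng(seed)
    if noise_sd > 0:
        ideal = ideal + rng.normal(0.0, noise_sd, size=n)
    return SampledTrace(
        samples=ideal,
        sample_rate=float(sample_rate),
        amplitudes=(float(amp[0]), float(amp[1])),
        noise_sd=float(noise_sd),
        filter_cutoff=None if filter_cutoff is None else float(filter_cutoff),
        conditions=conditions,
        seed=None if isinstance(seed, np.random.Generator) else seed,
    )


def render_multichannel_trace(
    dwell_list: Sequence[DwellSequence],
    unit_amplitude: float = 7.0,
    noise_sd: float = 1.0,
    sample_rate: float = 10_000.0,
    filter_cutoff: float | None = 4_000.0,
    seed=None,
) -> SampledTrace:
    """Summed current of k independent channels (for NPo-style activity)."""
    if not dwell_list:
        raise ValueError("need at least one channel")
    total = min(d.total_time for d in dwell_list)
    n = int(np.floor(total * sample_rate))
    t_mid = (np.arange(n) + 0.5) / sample_rate
    level = np.zeros(n)
    for d in dwell_list:
        codes, durs = d.class_dwells()
        edges = np.concatenate(([0.0], np.cumsum(durs)))
        which = np.clip(np.searchsorted(edges, t_mid, side="right") - 1, 0, len(durs) - 1)
        level += codes[which]
    ideal = unit_amplitude * level
    if filter_cutoff is not None:
        sigma = GAUSSIAN_SIGMA_FACTOR * sample_rate / filter_cutoff
        ideal = gaussian_filter1d(ideal, sigma, mode="nearest")
    rng = _resolve_rng(seed)
    if noise_sd > 0:
        ideal = ideal + rng.normal(0.0, noise_sd, size=n)
    return SampledTrace(
        samples=ideal,
        sample_rate=float(sample_rate),
        amplitudes=(0.0, float(unit_amplitude)),
        noise_sd=float(noise_sd),
        filter_cutoff=None if filter_cutoff is None else float(filter_cutoff),
    )


# ---------------------------------------------------------------------------
# experiment generator
# ---------------------------------------------------------------------------

@dataclass
class ExperimentConfig:
    """Design of a synthetic dose/voltage series over replicate cells.

    Defaults mirror the study conditions: 100 µM ACh, blocker at 0/5/10/20 µM,
    3 cells, 3000 events per recording, 10 kHz sampling with a 4 kHz Gaussian
    filter, 7 pA open-channel amplitude and 1 pA noise.
    """

    doses_uM: tuple[float, ...] = (0.0, 5.0, 10.0, 20.0)
    n_cells: int = 3
    n_events: int = 3000
    conc_ACh: float = 100.0
    rate_table: dict[str, float] = field(default_factory=default_rate_table)
    n_block_modes: int = 1
    voltage_sensitivity: dict[str, float] | None = None
    V_m_mV: tuple[float, ...] = (0.0,)
    amplitude_pA: float = 7.0
    noise_sd_pA: float = 1.0
    sample_rate_hz: float = 10_000.0
    filter_cutoff_hz: float = 4_000.0
    render: bool = True

    def __post_init__(self) -> None:
        if len(self.doses_uM) == 0:
            raise ValueError("dose list must not be empty")
        if self.n_cells < 1 or self.n_events < 1:
            raise ValueError("n_cells and n_events must be positive")

    def scheme(self) -> KineticScheme:
        return build_blockade_scheme(
            self.rate_table, self.n_block_modes, self.voltage_sensitivity
        )


@dataclass
class SyntheticRecording:
    cell: int
    dose_uM: float
    V_m: float
    dwells: DwellSequence
    trace: SampledTrace | None
    seed: int


def dataset_seed(master_seed: int, cell: int, dose_uM: float, V_m: float) -> int:
    """Deterministic per-dataset seed; independent of the condition list order."""
    ss = np.random.SeedSequence(
        (int(master_seed), int(cell), int(round(dose_uM * 1000)), int(round(V_m * 1000)))
    )
    return int(ss.generate_state(1, dtype=np.uint64)[0] % (2**31))


def synth_experiment(
    config: ExperimentConfig, master_seed: int = 1
) -> list[SyntheticRecording]:
    """One recording per (cell, dose, V_m): dwell simulation and optional trace.

    Per-dataset seeds derive from ``(master_seed, cell, condition)`` so adding
    a condition never perturbs the others.
    """
    scheme = config.scheme()
    out: list[SyntheticRecording] = []
    for cell in range(config.n_cells):
        for V_m in config.V_m_mV:
            for dose in config.doses_uM:
                cond = Conditions(conc_ACh=config.conc_ACh, conc_blocker=dose, V_m=V_m)
                seed = dataset_seed(master_seed, cell, dose, V_m)
                rng = np.random.default_rng(seed)
                dwells = simulate_dwells(
                    scheme, cond, n_events=config.n_events, seed=rng
                )
                trace = None
                if config.render:
                    trace = render_trace(
                        dwells,
                        amplitudes=(0.0, config.amplitude_pA),
                        noise_sd=config.noise_sd_pA,
                        sample_rate=config.sample_rate_hz,
                        filter_cutoff=config.filter_cutoff_hz,
                        seed=rng,
                        conditions=cond,
                    )
                out.append(
                    SyntheticRecording(
                        cell=cell, dose_uM=dose, V_m=V_m,
                        dwells=dwells, trace=trace, seed=seed,
                    )
                )
    return out
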