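"""Segmented-k-means hidden-Markov idealization of sampled traces.

The SKM variant implemented here alternates (i) Viterbi decoding of the
per-sample class sequence under a discrete HMM with Gaussian emissions
(per-class means, one pooled variance) and (ii) re-estimation of the class
amplitudes, the pooled variance, and the transition probabilities from the
current segmentation, stopping when the segmentation no longer changes.
Classes are reported ordered by amplitude, so the open class is the more
positive one regardless of initialization.  No amplitude constraints,
baseline-drift nodes, or sub-conductance classes are modelled.

Dead-time imposition and cluster segmentation — standard preprocessing for
interval-likelihood fitting — also live here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy.optimize import brentq

from .simulate import SampledTrace


@dataclass
class IdealizedEvents:
    """Run-length-encoded dwell events from an idealized trace.

    ``class_codes`` are amplitude-ranked (0 = closed = least positive);
    durations in seconds; ``mean_amplitudes`` per event in pA.
    """

    class_codes: np.ndarray
    durations: np.ndarray
    mean_amplitudes: np.ndarray
    dead_time: float = 0.0
    amplitudes: tuple[float, ...] | None = None  # fitted class means, ranked
    noise_sd: float | None = None
    converged: bool = True
    n_iter: int = 0
    source: str | None = None

    def __post_init__(self) -> None:
        self.class_codes = np.asarray(self.class_codes, dtype=np.int8)
        self.durations = np.asarray(self.durations, dtype=float)
        self.mean_amplitudes = np.asarray(self.mean_amplitudes, dtype=float)

    def __len__(self) -> int:
        return len(self.durations)

    @property
    def total_time(self) -> float:
        return float(self.durations.sum())

    def open_durations(self) -> np.ndarray:
        return self.durations[self.class_codes == 1]

    def closed_durations(self) -> np.ndarray:
        return self.durations[self.class_codes == 0]


@njit(cache=False)
def _viterbi_path(x, means, inv_two_var, logA):  # pragma: no cover - numba
    n = x.shape[0]
    K = means.shape[0]
    prev = np.empty(K)
    cur = np.empty(K)
    back = np.empty((n, K), dtype=np.uint8)
    for k in range(K):
        d = x[0] - means[k]
        prev[k] = -d * d * inv_two_var
    for i in range(1, n):
        for k in range(K):
            best = -1e300
            arg = 0
            for j in range(K):
                v = prev[j] + logA[j, k]
                if v > best:
                    best = v
                    arg = j
            d = x[i] - means[k]
            cur[k] = best - d * d * inv_two_var
            back[i, k] = arg
        m = cur[0]
        for k in range(1, K):
            if cur[k] > m:
                m = cur[k]
        for k in range(K):
            prev[k] = cur[k] - m
    path = np.empty(n, dtype=np.uint8)
    b = 0
    for k in range(1, K):
        if prev[k] > prev[b]:
            b = k
    path[n - 1] = b
    for i in range(n - 1, 0, -1):
        path[i - 1] = back[i, path[i]]
    return path


def _run_length_encode(path: np.ndarray, x: np.ndarray, sample_rate: float):
    change = np.flatnonzero(np.diff(path)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [path.size]))
    codes = path[starts].astype(np.int8)
    durations = (ends - starts) / sample_rate
    sums = np.concatenate(([0.0], np.cumsum(x)))
    amps = (sums[ends] - sums[starts]) / (ends - starts)
    return codes, durations, amps


def skm_idealize(
    trace: SampledTrace,
    n_classes: int = 2,
    init_amplitudes=None,
    max_iter: int = 50,
    tol: float = 0.0,
) -> IdealizedEvents:
    """Idealize a sampled trace into amplitude-ranked dwell events.

    ``init_amplitudes`` defaults to spread percentiles of the trace; the
    iteration stops when the Viterbi segmentation is unchanged (``tol`` is
    an optional extra stop on the amplitude update) or after ``max_iter``
    sweeps, in which case the best-so-far result is returned flagged
    non-converged.  A class left with no samples is re-initialized once.
    """
    x = np.asarray(trace.samples, dtype=float)
    if x.size <= 10:
        raise ValueError("trace too short to idealize")
    if n_classes < 2:
        raise ValueError("need at least two conductance classes")
    if init_amplitudes is None:
        means = np.percentile(x, np.linspace(2, 98, n_classes)).astype(float)
        if np.unique(means).size < n_classes:  # flat trace: spread artificially
            means = means + np.arange(n_classes) * max(1e-6, 1e-3 * (abs(means[0]) + 1))
    else:
        means = np.asarray(init_amplitudes, dtype=float).copy()
        if means.size != n_classes or np.unique(means).size != n_classes:
            raise ValueError("init_amplitudes must be n_classes distinct values")
    var = max(float(np.var(x)) / 4.0, 1e-12)
    A = np.full((n_classes, n_classes), 0.01 / max(n_classes - 1, 1))
    np.fill_diagonal(A, 0.99)
    path_prev = None
    reinitialized = False
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        path = _viterbi_path(x, means, 1.0 / (2.0 * var), np.log(A))
        new_means = means.copy()
        resid = 0.0
        for k in range(n_classes):
            sel = path == k
            cnt = int(sel.sum())
            if cnt == 0:
                if reinitialized:
                    raise RuntimeError(f"class {k} degenerate after re-initialization")
                # one-shot re-initialization away from the surviving classes
                new_means[k] = x.max() if k == np.argmax(means) else x.min()
                reinitialized = True
                continue
            new_means[k] = x[sel].mean()
        resid = float(np.mean((x - new_means[path]) ** 2))
        var = max(resid, 1e-12)
        counts = np.ones((n_classes, n_classes)) * 0.5  # smoothing prior
        np.add.at(counts, (path[:-1], path[1:]), 1.0)
        A = counts / counts.sum(axis=1, keepdims=True)
        shift = float(np.max(np.abs(new_means - means)))
        means = new_means
        if path_prev is not None and np.array_equal(path, path_prev) and shift <= tol:
            converged = True
            break
        path_prev = path
    # rank classes by amplitude: 0 = least positive (closed)
    order = np.argsort(means)
    rank = np.empty_like(order)
    rank[order] = np.arange(n_classes)
    path = rank[path_prev if path_prev is not None else path]
    codes, durations, amps = _run_length_encode(path, x, trace.sample_rate)
    return IdealizedEvents(
        class_codes=codes,
        durations=durations,
        mean_amplitudes=amps,
        dead_time=0.0,
        amplitudes=tuple(np.sort(means)),
        noise_sd=float(np.sqrt(var)),
        converged=converged,
        n_iter=it,
    )


# ---------------------------------------------------------------------------
# dead time
# ---------------------------------------------------------------------------

def impose_dead_time(events: IdealizedEvents, td: float) -> IdealizedEvents:
    """Delete events shorter than ``td`` and absorb them into their flanks.

    In an alternating sequence both flanks share a class, so a deleted event
    merges its neighbours into one event of that class; the sweep repeats
    left-to-right until every remaining event is >= ``td``.  Total duration
    is conserved exactly.  Idempotent for fixed ``td``.
    """
    if td < 0:
        raise ValueError("dead time must be >= 0")
    total_before = float(events.durations.sum())
    if td == 0:
        return IdealizedEvents(
            events.class_codes.copy(), events.durations.copy(),
            events.mean_amplitudes.copy(), dead_time=0.0,
            amplitudes=events.amplitudes, noise_sd=events.noise_sd,
            converged=events.converged, n_iter=events.n_iter, source=events.source,
        )
    if td > total_before:
        raise ValueError("dead time exceeds the record duration")
    codes = list(map(int, events.class_codes))
    durs = list(map(float, events.durations))
    amp_wt = [a * d for a, d in zip(events.mean_amplitudes, events.durations)]

    changed = True
    while changed:
        changed = False
        i = 0
        while i < len(durs):
            if durs[i] >= td:
                i += 1
                continue
            changed = True
            if len(durs) == 1:
                raise ValueError("dead time removes the entire record")
            if i == 0:
                durs[1] += durs[0]
                amp_wt[1] += amp_wt[0]
                del codes[0], durs[0], amp_wt[0]
            elif i == len(durs) - 1:
                durs[i - 1] += durs[i]
                amp_wt[i - 1] += amp_wt[i]
                del codes[i], durs[i], amp_wt[i]
            else:
                # flanks merge into one event (same class in alternating input)
                durs[i - 1] += durs[i] + durs[i + 1]
                amp_wt[i - 1] += amp_wt[i] + amp_wt[i + 1]
                cls = codes[i - 1] if codes[i - 1] == codes[i + 1] else codes[i - 1]
                codes[i - 1] = cls
                del codes[i : i + 2], durs[i : i + 2], amp_wt[i : i + 2]
                # after a merge re-scan from the merged event
                i = max(i - 1, 0)
        # collapse any adjacent same-class events produced by boundary merges
        j = 1
        while j < len(durs):
            if codes[j] == codes[j - 1]:
                durs[j - 1] += durs[j]
                amp_wt[j - 1] += amp_wt[j]
                del codes[j], durs[j], amp_wt[j]
            else:
                j += 1

    durations = np.array(durs)
    return IdealizedEvents(
        class_codes=np.array(codes, dtype=np.int8),
        durations=durations,
        mean_amplitudes=np.array(amp_wt) / durations,
        dead_time=float(td),
        amplitudes=events.amplitudes,
        noise_sd=events.noise_sd,
        converged=events.converged,
        n_iter=events.n_iter,
        source=events.source,
    )


# ---------------------------------------------------------------------------
# cluster segmentation
# ---------------------------------------------------------------------------

def segment_clusters(events: IdealizedEvents, tau_crit: float) -> list[tuple[int, int]]:
    """Split events into activation clusters at long closed dwells.

    A closed event with duration > ``tau_crit`` terminates the running
    cluster; clusters containing no opening are discarded.  Returns
    ``(start, stop)`` half-open index ranges into the event arrays.
    """
    if tau_crit <= 0:
        raise ValueError("tau_crit must be positive")
    codes = events.class_codes
    durs = events.durations
    clusters: list[tuple[int, int]] = []
    start = 0
    for i in range(len(durs)):
        if codes[i] == 0 and durs[i] > tau_crit:
            if np.any(codes[start:i] == 1):
                clusters.append((start, i))
            start = i + 1
    if start < len(durs) and np.any(codes[start:] == 1):
        clusters.append((start, len(durs)))
    return clusters


def critical_time(tau_fast: float, area_fast: float, tau_slow: float, area_slow: float) -> float:
    """Equal-misclassification boundary between two closed-time exponentials.

    Solves ``a_f exp(-t/tau_f) = a_s (1 - exp(-t/tau_s))`` — the expected
    number of fast dwells longer than t equals the number of slow dwells
    shorter than t (Colquhoun–Sakmann criterion).
    """
    if not (0 < tau_fast < tau_slow):
        raise ValueError("need 0 < tau_fast < tau_slow")
    if area_fast <= 0 or area_slow <= 0:
        raise ValueError("areas must be positive")

    def g(t):
        return area_fast * np.exp(-t / tau_fast) - area_slow * (1.0 - np.exp(-t / tau_slow))

    hi = tau_slow * 20.0
    while g(hi) > 0:
        hi *= 2.0
    return float(brentq(g, 1e-12, hi))
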