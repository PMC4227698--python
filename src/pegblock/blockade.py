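"""Dose, voltage and agonist-activity analysis of open-channel blockade.

This is the headline analysis chain: apparent mean open time versus blocker
dose, exponential-mixture decomposition of closed-time histograms, per-dose
blocking/unblocking rates aggregated into rate constants —

    k+B  = slope of the least-squares line of blocking rate vs. dose
           (SE = standard error of the slope),
    k-B  = unweighted mean of the unblocking rates over all doses and cells
           (± SEM),
    Kd   = k-B / k+B  with first-order (delta-method) error propagation —

computed per blockade mode (modes labelled by unblocking rate: "fast" is the
larger k-B), plus cell-attached voltage-dependence (V_m = V_rest - V_hold
with V_rest from the amplitude-vs-V_hold line) and NPo-style agonist
activity from multi-channel records.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats


def _sem(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    if x.size <= 1:
        return 0.0
    return float(np.std(x, ddof=1) / np.sqrt(x.size))


# ---------------------------------------------------------------------------
# apparent open time
# ---------------------------------------------------------------------------

def apparent_open_time(open_durations_per_cell: Sequence[np.ndarray]) -> tuple[float, float]:
    """Mean open-dwell duration (s), pooled within cells, mean ± SEM across cells.

    Raises if any cell contributed no openings.
    """
    means = []
    for durs in open_durations_per_cell:
        durs = np.asarray(durs, dtype=float)
        if durs.size == 0:
            raise ValueError("a cell contributed no open events")
        means.append(float(durs.mean()))
    return float(np.mean(means)), _sem(np.array(means))


# ---------------------------------------------------------------------------
# closed-time exponential mixtures
# ---------------------------------------------------------------------------

@dataclass
class ExponentialMixture:
    """Maximum-likelihood exponential mixture fit of dwell durations."""

    taus: np.ndarray            # seconds, ascending
    areas: np.ndarray           # fractions, sum to 1
    log_likelihood: float
    n: int
    bic: float
    dropped_components: int = 0
    hist_bin_edges: np.ndarray | None = None  # log10-spaced, seconds
    hist_counts: np.ndarray | None = None
    hist_sqrt_counts: np.ndarray | None = None

    def density(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return np.sum(
            self.areas[:, None] / self.taus[:, None] * np.exp(-t[None, :] / self.taus[:, None]),
            axis=0,
        )


def _em_fit(t: np.ndarray, taus0: np.ndarray, max_iter: int, tol: float):
    k = taus0.size
    taus = taus0.copy()
    areas = np.full(k, 1.0 / k)
    ll_prev = -np.inf
    for _ in range(max_iter):
        dens = areas[None, :] / taus[None, :] * np.exp(-t[:, None] / taus[None, :])
        tot = dens.sum(axis=1)
        tot = np.maximum(tot, 1e-300)
        ll = float(np.log(tot).sum())
        r = dens / tot[:, None]
        w = r.sum(axis=0)
        areas = w / t.size
        taus = (r * t[:, None]).sum(axis=0) / np.maximum(w, 1e-300)
        taus = np.maximum(taus, 1e-9)
        if ll - ll_prev < tol:
            ll_prev = ll
            break
        ll_prev = ll
    order = np.argsort(taus)
    return taus[order], areas[order], ll_prev


def closed_time_components(
    durations: Sequence[float] | np.ndarray,
    n_components: int | None = None,
    bic_range: tuple[int, int] = (1, 6),
    max_iter: int = 1000,
    tol: float = 1e-10,
    n_bins_per_decade: int = 8,
) -> ExponentialMixture:
    """Exponential-mixture fit of closed dwells plus a log-binned histogram.

    EM in linear time with deterministic quantile-of-log-duration
    initialization.  ``n_components`` fixes the component count; otherwise a
    BIC scan over ``bic_range`` chooses it.  Components with fitted area
    below 1/n are dropped and the mixture refitted (count reported).
    The histogram uses log10-spaced bins and a square-root ordinate, the
    standard display for dwell-time distributions.
    """
    t = np.asarray(durations, dtype=float)
    if t.size < 50:
        raise ValueError("need at least 50 closed dwells")
    if np.any(t <= 0):
        raise ValueError("durations must be positive")

    def init_taus(k: int) -> np.ndarray:
        qs = np.linspace(0, 1, k + 2)[1:-1]
        return np.maximum(np.exp(np.quantile(np.log(t), qs)), 1e-9)

    def fit_k(k: int):
        taus, areas, ll = _em_fit(t, init_taus(k), max_iter, tol)
        dropped = 0
        while np.any(areas < 1.0 / t.size) and taus.size > 1:
            keep = areas >= 1.0 / t.size
            dropped += int((~keep).sum())
            taus, areas, ll = _em_fit(t, taus[keep], max_iter, tol)
        n_par = 2 * taus.size - 1
        bic = n_par * math.log(t.size) - 2.0 * ll
        return taus, areas, ll, bic, dropped

    if n_components is not None:
        taus, areas, ll, bic, dropped = fit_k(int(n_components))
    else:
        fits = [fit_k(k) for k in range(bic_range[0], bic_range[1] + 1)]
        taus, areas, ll, bic, dropped = min(fits, key=lambda f: f[3])

    lo = math.floor(math.log10(t.min()))
    hi = math.ceil(math.log10(t.max()))
    edges = np.logspace(lo, hi, int((hi - lo) * n_bins_per_decade) + 1)
    counts, _ = np.histogram(t, bins=edges)
    return ExponentialMixture(
        taus=taus,
        areas=areas / areas.sum(),
        log_likelihood=ll,
        n=int(t.size),
        bic=bic,
        dropped_components=dropped,
        hist_bin_edges=edges,
        hist_counts=counts,
        hist_sqrt_counts=np.sqrt(counts),
    )


# ---------------------------------------------------------------------------
# blockade summary (dose dependence)
# ---------------------------------------------------------------------------

@dataclass
class ModeSummary:
    mode: str
    k_plus_B: float            # µM^-1 s^-1, slope of blocking rate vs dose
    k_plus_B_se: float         # SE of the slope
    k_plus_B_intercept: float  # s^-1, fitted intercept (reported, not used)
    k_plus_B_origin: float     # slope of the through-origin variant
    k_minus_B: float           # s^-1, mean over all doses and cells
    k_minus_B_sem: float
    n_unblocking: int
    Kd_uM: float
    Kd_se: float
    per_dose: pd.DataFrame = field(repr=False, default=None)


@dataclass
class BlockadeSummary:
    """Aggregate dose-dependence results for one blocker."""

    modes: dict[str, ModeSummary]
    tau_app: pd.DataFrame | None = None  # per dose: mean ± SEM (ms), n_cells

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for m in self.modes.values():
            rows.append(
                {
                    "mode": m.mode,
                    "k_plus_B_uM_s": m.k_plus_B,
                    "k_plus_B_se": m.k_plus_B_se,
                    "k_minus_B_s": m.k_minus_B,
                    "k_minus_B_sem": m.k_minus_B_sem,
                    "Kd_uM": m.Kd_uM,
                    "Kd_se": m.Kd_se,
                    "n_unblocking": m.n_unblocking,
                }
            )
        return pd.DataFrame(rows)


def propagate_kd_error(k_minus: float, se_minus: float, k_plus: float, se_plus: float):
    """Kd = k-B/k+B with first-order error propagation."""
    if k_plus <= 0 or k_minus <= 0:
        raise ValueError("rate constants must be positive")
    kd = k_minus / k_plus
    se = kd * math.sqrt((se_minus / k_minus) ** 2 + (se_plus / k_plus) ** 2)
    return kd, se


def label_modes_by_unblocking(df: pd.DataFrame) -> pd.DataFrame:
    """Label per-fit modes fast/slow by unblocking rate within (cell, dose).

    Matching across doses follows nearest log-unblocking-rate ordering: the
    larger k-B in each fit is "fast".  A single-mode table is labelled
    "single".
    """
    df = df.copy()
    if "mode" in df.columns:
        return df
    n_modes = df.groupby(["cell", "dose_uM"]).size().max()
    if n_modes == 1:
        df["mode"] = "single"
        return df
    labels = []
    for _, grp in df.groupby(["cell", "dose_uM"], sort=False):
        order = grp["unblocking_rate"].rank(ascending=False, method="first")
        labels.append(pd.Series(np.where(order == 1, "fast", "slow"), index=grp.index))
    df["mode"] = pd.concat(labels).sort_index()
    return df


def blocking_kinetics(per_dose: pd.DataFrame) -> BlockadeSummary:
    """Rate constants from per-(cell, dose[, mode]) MIL estimates.

    ``per_dose`` columns: cell, dose_uM, blocking_rate (s^-1),
    unblocking_rate (s^-1), optional mode, optional boolean ``excluded``.
    Requires at least two distinct nonzero doses.  Per mode: the line fitted
    to the per-dose mean blocking rates gives k+B (slope ± slope SE, with the
    intercept fitted and reported; the through-origin slope is also
    reported); k-B is the unweighted mean of all unblocking rates ± SEM;
    Kd = k-B/k+B with delta-method SE.
    """
    df = per_dose.copy()
    if "excluded" in df.columns:
        df = df[~df["excluded"].astype(bool)]
    df = df[df["dose_uM"] > 0]
    if df["dose_uM"].nunique() < 2:
        raise ValueError("need at least two distinct nonzero doses for the slope")
    df = label_modes_by_unblocking(df)

    modes = {}
    for mode, grp in df.groupby("mode"):
        per_dose_stats = (
            grp.groupby("dose_uM")
            .agg(
                blocking_mean=("blocking_rate", "mean"),
                blocking_sem=("blocking_rate", _sem),
                unblocking_mean=("unblocking_rate", "mean"),
                unblocking_sem=("unblocking_rate", _sem),
                n_cells=("blocking_rate", "size"),
            )
            .reset_index()
        )
        if len(per_dose_stats) < 2:
            raise ValueError(f"mode {mode!r} has a single dose; slope undefined")
        x = per_dose_stats["dose_uM"].to_numpy(float)
        y = per_dose_stats["blocking_mean"].to_numpy(float)
        fit = stats.linregress(x, y)
        slope_origin = float((x @ y) / (x @ x))
        k_minus_all = grp["unblocking_rate"].to_numpy(float)
        k_minus = float(k_minus_all.mean())
        k_minus_sem = _sem(k_minus_all)
        kd, kd_se = propagate_kd_error(k_minus, k_minus_sem, float(fit.slope), float(fit.stderr))
        modes[mode] = ModeSummary(
            mode=mode,
            k_plus_B=float(fit.slope),
            k_plus_B_se=float(fit.stderr),
            k_plus_B_intercept=float(fit.intercept),
            k_plus_B_origin=slope_origin,
            k_minus_B=k_minus,
            k_minus_B_sem=k_minus_sem,
            n_unblocking=int(k_minus_all.size),
            Kd_uM=kd,
            Kd_se=kd_se,
            per_dose=per_dose_stats,
        )
    # rename two-mode labels so "fast" has the larger mean k-B overall
    if set(modes) == {"fast", "slow"} and modes["fast"].k_minus_B < modes["slow"].k_minus_B:
        modes["fast"], modes["slow"] = modes["slow"], modes["fast"]
        modes["fast"].mode, modes["slow"].mode = "fast", "slow"
    return BlockadeSummary(modes=modes)


# ---------------------------------------------------------------------------
# voltage dependence
# ---------------------------------------------------------------------------

@dataclass
class VoltageSeries:
    V_hold: np.ndarray
    V_rest: float
    V_m: np.ndarray             # V_rest - V_hold
    amplitude_slope: float      # pA / mV
    amplitude_intercept: float  # pA
    ln_kplus_slope: float       # per mV, d ln(k+B) / d V_m
    ln_kplus_slope_se: float
    ln_kplus_intercept: float
    tau_app_ms: np.ndarray | None = None
    increases_with_hyperpolarization: bool = False


def voltage_dependence(
    V_hold: Sequence[float],
    amplitudes_pA: Sequence[float],
    k_plus_B: Sequence[float],
    tau_app_ms: Sequence[float] | None = None,
    slope_tol: float = 1e-9,
) -> VoltageSeries:
    """Voltage dependence of block from a holding-potential series.

    V_rest is the zero-current crossing of the least-squares line of
    single-channel amplitude vs. V_hold; membrane potential is
    V_m = V_rest - V_hold; the least-squares line of ln(k+B) vs. V_m gives
    the voltage slope ± SE.  A negative slope means blocker binding speeds
    up with hyperpolarization (more negative V_m).
    """
    V_hold = np.asarray(V_hold, dtype=float)
    amps = np.asarray(amplitudes_pA, dtype=float)
    kb = np.asarray(k_plus_B, dtype=float)
    if V_hold.size < 3:
        raise ValueError("need at least three holding potentials")
    if np.any(kb <= 0):
        raise ValueError("k+B values must be positive")
    amp_fit = stats.linregress(V_hold, amps)
    if abs(amp_fit.slope) < slope_tol:
        raise ValueError("amplitude-vs-V_hold slope is degenerate; V_rest undefined")
    V_rest = -float(amp_fit.intercept) / float(amp_fit.slope)
    V_m = V_rest - V_hold
    ln_fit = stats.linregress(V_m, np.log(kb))
    return VoltageSeries(
        V_hold=V_hold,
        V_rest=V_rest,
        V_m=V_m,
        amplitude_slope=float(amp_fit.slope),
        amplitude_intercept=float(amp_fit.intercept),
        ln_kplus_slope=float(ln_fit.slope),
        ln_kplus_slope_se=float(ln_fit.stderr),
        ln_kplus_intercept=float(ln_fit.intercept),
        tau_app_ms=None if tau_app_ms is None else np.asarray(tau_app_ms, float),
        increases_with_hyperpolarization=bool(ln_fit.slope < 0),
    )


# ---------------------------------------------------------------------------
# agonist activity (NPo)
# ---------------------------------------------------------------------------

@dataclass
class AgonistActivity:
    NPo: float
    N_max: int
    P_open_levels: np.ndarray   # fractions of time at 0..N_max open channels
    mean_open_time: float       # s, from single-open-level sojourns


def agonist_activity(
    level_codes: Sequence[int] | np.ndarray,
    durations: Sequence[float] | np.ndarray,
    N_max: int | None = None,
) -> AgonistActivity:
    """NPo = sum_i i * P_o,i from an idealized multi-level record.

    ``level_codes`` give the number of simultaneously open channels per
    event.  P_o,i is the fraction of record time at level i (i = 0..N_max);
    the levels therefore sum to one.  Mean open time is taken from sojourns
    at exactly one open channel.
    """
    levels = np.asarray(level_codes, dtype=int)
    durs = np.asarray(durations, dtype=float)
    if levels.shape != durs.shape or levels.size == 0:
        raise ValueError("levels and durations must be aligned and non-empty")
    if np.any(durs <= 0) or np.any(levels < 0):
        raise ValueError("durations must be positive and levels >= 0")
    observed_max = int(levels.max())
    if N_max is None:
        N_max = observed_max
    if observed_max > N_max:
        raise ValueError("levels exceed N_max")
    if N_max == 0:
        warnings.warn("record contains no openings; NPo = 0", stacklevel=2)
        return AgonistActivity(0.0, 0, np.array([1.0]), float("nan"))
    total = durs.sum()
    P = np.array([durs[levels == i].sum() / total for i in range(N_max + 1)])
    npo = float(np.sum(np.arange(N_max + 1) * P))
    singles = durs[levels == 1]
    mot = float(singles.mean()) if singles.size else float("nan")
    return AgonistActivity(NPo=npo, N_max=int(N_max), P_open_levels=P, mean_open_time=mot)
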