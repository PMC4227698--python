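"""Maximum interval likelihood (MIL) estimation of rate constants.

The likelihood of an idealized dwell sequence under an aggregated Markov
model is

    L = pi_e^T [ prod_i exp(Q_{a_i a_i} t_i) Q_{a_i a_{i+1}} ] 1

where ``a_i`` is the conductance class of interval i, ``Q_{aa}`` the
within-class block of the generator, ``Q_{ab}`` the transition block,
``pi_e`` the equilibrium entry vector into the first interval's class, and
the final interval contributes only its survivor function.  Evaluation is
done in log space with per-interval normalization; for the common case of a
single open-class state the product factorizes exactly and is evaluated in
one vectorized pass over the closed dwells via an eigendecomposition of the
closed-class block.

``fit_mil`` maximizes the summed log-likelihood over several recordings with
respect to a named subset of log-transformed base rates (shared across
recordings; each recording's conditions supply its own ligand and voltage
scaling), using multi-start L-BFGS-B.  Standard errors come from the inverse
observed information in log-rate space, delta-method transformed to the rate
scale.

Dead-time-imposed dwells are handled with the standard first-order
missed-event correction: undetected excursions into the other aggregate
(shorter than the dead time td) are folded into effective within-aggregate
blocks ``Q'_aa = Q_aa + Q_ab (int_0^td exp(Q_bb s) ds) Q_ba``, apparent
durations are evaluated as ``exp(Q'_aa (t - td))``, and each detected
transition carries the survival factor ``Q_ab exp(Q_bb td)`` of the next
sojourn past td.  With td = 0 this reduces exactly to the ideal likelihood.
The correction is first order in td: it is accurate while dwell-time scales
are several times the dead time, the regime of the bundled experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import linalg
from scipy.optimize import minimize

from .schemes import (
    CLASS_CODE,
    CLOSED,
    OPEN,
    Conditions,
    KineticScheme,
    equilibrium_distribution,
    generator_matrix,
)

_TINY = 1e-300


@dataclass
class Dataset:
    """One recording's alternating class dwells plus its conditions.

    ``dead_time`` is the resolution (s) already imposed on the dwells; the
    likelihood applies the first-order missed-event correction for it.
    """

    class_codes: np.ndarray
    durations: np.ndarray
    cond: Conditions
    dead_time: float = 0.0

    def __post_init__(self) -> None:
        self.class_codes = np.asarray(self.class_codes, dtype=np.int8)
        self.durations = np.asarray(self.durations, dtype=float)
        if self.class_codes.shape != self.durations.shape:
            raise ValueError("class_codes and durations must align")
        if np.any(self.durations <= 0):
            raise ValueError("durations must be positive")
        if np.any(self.class_codes[1:] == self.class_codes[:-1]):
            raise ValueError("dwell classes must alternate")

    def __len__(self) -> int:
        return len(self.durations)


@dataclass
class FitResult:
    """MIL estimates for one or more recordings fitted jointly."""

    estimates: dict[str, float]
    standard_errors: dict[str, float]
    log_likelihood: float
    n_events: int
    converged: bool
    non_identifiable: list[str] = field(default_factory=list)
    ses_available: bool = True
    conditions: list[Conditions] = field(default_factory=list)
    message: str = ""
    n_starts_tried: int = 0


# ---------------------------------------------------------------------------
# likelihood evaluation
# ---------------------------------------------------------------------------

def _aggregate_info(scheme: KineticScheme):
    idx_c = scheme.class_indices(CLOSED)
    idx_o = scheme.class_indices(OPEN)
    return {CLASS_CODE[CLOSED]: idx_c, CLASS_CODE[OPEN]: idx_o}


def _entry_vector_code(Q: np.ndarray, idx: Mapping[int, np.ndarray], code: int) -> np.ndarray:
    own = idx[code]
    other = idx[1 - code]
    pi = equilibrium_distribution(Q)
    flux = pi[other] @ Q[np.ix_(other, own)]
    s = flux.sum()
    if s <= 0:
        raise ValueError("no equilibrium flux into the first interval's class")
    return flux / s


def _corrected_blocks(Q: np.ndarray, idx: Mapping[int, np.ndarray], td: float):
    """First-order dead-time-corrected within-class blocks and transition
    factors: Q'_aa = Q_aa + Q_ab (int_0^td e^{Q_bb s} ds) Q_ba and
    T_ab = Q_ab e^{Q_bb td}.  With td = 0: Q'_aa = Q_aa, T_ab = Q_ab."""
    blocks, trans = {}, {}
    for a, ia in idx.items():
        b = 1 - a
        ib = idx[b]
        Qaa = Q[np.ix_(ia, ia)]
        Qab = Q[np.ix_(ia, ib)]
        if td > 0:
            Qbb = Q[np.ix_(ib, ib)]
            E_b = linalg.expm(Qbb * td)
            I_b = np.linalg.solve(Qbb, E_b - np.eye(len(ib)))  # int_0^td e^{Qbb s} ds
            blocks[a] = Qaa + Qab @ I_b @ Q[np.ix_(ib, ia)]
            trans[a] = Qab @ E_b
        else:
            blocks[a] = Qaa
            trans[a] = Qab
    return blocks, trans


def _loglik_general(Q: np.ndarray, idx: Mapping[int, np.ndarray],
                    codes: np.ndarray, durs: np.ndarray, td: float = 0.0) -> float:
    """Scaled forward pass over intervals; works for any aggregate sizes."""
    blocks, trans = _corrected_blocks(Q, idx, td)
    eig = {}
    for code in idx:
        lam, V = np.linalg.eig(blocks[code])
        eig[code] = (lam, V, np.linalg.inv(V))
    v = _entry_vector_code(Q, idx, int(codes[0])).astype(complex)
    ll = 0.0
    n = len(durs)
    for i in range(n):
        a = int(codes[i])
        lam, V, Vinv = eig[a]
        v = ((v @ V) * np.exp(lam * (durs[i] - td))) @ Vinv
        if i < n - 1:
            v = v @ trans[a]
            s = np.abs(v).sum()
        else:
            s = max(float(np.real(v.sum())), _TINY)
            ll += np.log(s)
            return float(ll)
        if not s > 0:
            return -np.inf
        ll += np.log(s)
        v = v / s
    return float(ll)


def _loglik_single_open(Q: np.ndarray, idx: Mapping[int, np.ndarray],
                        codes: np.ndarray, durs: np.ndarray, td: float = 0.0) -> float:
    """Vectorized exact likelihood when the open aggregate has one state.

    Every closed sojourn is entered from the unique open state, so the
    interval product factorizes into per-interval scalars: open intervals
    contribute exp(Q'_oo (t - td)), interior closed intervals
    [Q_oc e^{Q_cc td}] exp(Q'_cc (t - td)) [Q_co e^{Q_oo td}], and the
    boundary intervals use the equilibrium entry vector / the survivor
    vector instead (first-order dead-time correction; exact for td = 0).
    """
    o = idx[1][0]
    c = idx[0]
    r = -Q[o, o]
    Qoc = Q[o, c]
    Qco = Q[c, o]
    Qcc = Q[np.ix_(c, c)]
    if td > 0:
        E_c = linalg.expm(Qcc * td)
        I_c = np.linalg.solve(Qcc, E_c - np.eye(len(c)))
        i_o = (1.0 - np.exp(-r * td)) / r
        Qcc_eff = Qcc + i_o * np.outer(Qco, Qoc)
        r_eff = r - float(Qoc @ I_c @ Qco)
        A_row = Qoc @ E_c                 # open -> detected closed sojourn
        Qco_eff = Qco * np.exp(-r * td)   # closed -> detected open sojourn
    else:
        Qcc_eff, r_eff, A_row, Qco_eff = Qcc, r, Qoc, Qco
    lam, V = np.linalg.eig(Qcc_eff)
    Vinv = np.linalg.inv(V)
    A_int = A_row @ V
    B_out = Vinv @ Qco_eff
    B_surv = Vinv @ np.ones(len(c))

    closed_mask = codes == 0
    t_closed = durs[closed_mask] - td
    n = len(durs)
    first_closed = codes[0] == 0
    last_closed = codes[n - 1] == 0

    ll = -r_eff * float(durs[~closed_mask].sum() - td * (~closed_mask).sum())

    if t_closed.size:
        if np.any(t_closed < -1e-15):
            raise ValueError("durations shorter than the dead time")
        # weights per closed interval: A x B with boundary replacements
        Aw = np.broadcast_to(A_int, (t_closed.size, len(c))).copy()
        Bw = np.broadcast_to(B_out, (t_closed.size, len(c))).copy()
        if first_closed:
            pe = _entry_vector_code(Q, idx, 0)
            Aw[0] = pe @ V
        if last_closed:
            Bw[-1] = B_surv
        vals = np.real(np.einsum("ik,ik->i",
                                 np.exp(np.outer(np.maximum(t_closed, 0.0), lam)) * Aw,
                                 Bw))
        if np.any(vals <= 0):
            return _loglik_general(Q, idx, codes, durs, td)
        ll += float(np.log(vals).sum())
    # a final open dwell contributes only its survivor (already in the
    # open-time sum); a first open dwell has entry probability 1.
    return float(ll)


def interval_log_likelihood(
    scheme: KineticScheme,
    cond: Conditions,
    class_codes: Sequence[int] | np.ndarray,
    durations: Sequence[float] | np.ndarray,
    method: str = "auto",
    dead_time: float = 0.0,
) -> float:
    """Log-likelihood of an alternating dwell sequence under the scheme.

    ``method`` selects the evaluation path: "auto" (vectorized when the open
    aggregate is a single state), "general" (scaled interval-by-interval
    forward pass), or "fast".  ``dead_time`` (s) applies the first-order
    missed-event correction for dwells recorded at that resolution.
    """
    codes = np.asarray(class_codes, dtype=np.int8)
    durs = np.asarray(durations, dtype=float)
    if codes.size == 0:
        raise ValueError("empty dwell sequence")
    if np.any(durs <= 0):
        raise ValueError("durations must be positive")
    if np.any(codes[1:] == codes[:-1]):
        raise ValueError("dwell classes must alternate")
    Q = generator_matrix(scheme, cond)
    idx = _aggregate_info(scheme)
    single_open = idx[1].size == 1
    if dead_time < 0:
        raise ValueError("dead_time must be >= 0")
    if method == "general" or (method == "auto" and not single_open):
        return _loglik_general(Q, idx, codes, durs, dead_time)
    if not single_open:
        raise ValueError("fast path requires a single open-class state")
    return _loglik_single_open(Q, idx, codes, durs, dead_time)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

class _QBuilder:
    """Precomputed map from free log-rates to a dataset's generator matrix."""

    def __init__(self, scheme: KineticScheme, cond: Conditions, free: Sequence[str]):
        free = list(free)
        n = len(scheme.states)
        fixed = np.zeros((n, n))
        self.entries: list[tuple[int, int, float]] = []
        for e in scheme.edges:
            i = scheme.state_index(e.source)
            j = scheme.state_index(e.target)
            if e.name in free:
                mult = e.rate.value(cond) / e.rate.base_rate  # ligand x voltage factor
                self.entries.append((i, j, mult))
            else:
                fixed[i, j] += e.rate.value(cond)
        order = {name: k for k, name in enumerate(free)}
        self.entry_order = [order[e.name] for e in scheme.edges if e.name in free]
        self.fixed = fixed

    def build(self, rates: np.ndarray) -> np.ndarray:
        Q = self.fixed.copy()
        for (i, j, mult), k in zip(self.entries, self.entry_order):
            Q[i, j] += rates[k] * mult
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        return Q


def _fd_hessian(fun, x: np.ndarray, rel_step: float = 1e-4) -> np.ndarray:
    p = x.size
    h = rel_step * np.maximum(1.0, np.abs(x))
    H = np.empty((p, p))
    f0 = fun(x)
    for i in range(p):
        for j in range(i, p):
            ei = np.zeros(p); ei[i] = h[i]
            ej = np.zeros(p); ej[j] = h[j]
            if i == j:
                f1 = fun(x + ei)
                f2 = fun(x - ei)
                H[i, i] = (f1 - 2.0 * f0 + f2) / (h[i] ** 2)
            else:
                fpp = fun(x + ei + ej)
                fpm = fun(x + ei - ej)
                fmp = fun(x - ei + ej)
                fmm = fun(x - ei - ej)
                H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4.0 * h[i] * h[j])
    return H


def fit_mil(
    scheme: KineticScheme,
    datasets: Sequence[Dataset],
    free: Sequence[str],
    start: Mapping[str, float] | None = None,
    bounds: tuple[float, float] = (1e-3, 1e6),
    n_starts: int = 5,
    jitter_sd: float = 0.3,
    seed: int = 0,
    curvature_tol: float = 1e-6,
) -> FitResult:
    """Maximize the summed interval likelihood over the named free rates.

    Free base rates are shared across datasets; ligand/voltage scaling comes
    from each dataset's conditions.  Optimization runs in log-rate space
    under box bounds with ``n_starts`` multiplicatively jittered starts
    (fixed jitter seed).  Rates whose log-space curvature at the optimum is
    below ``curvature_tol`` are flagged non-identifiable and get no SE.
    """
    free = list(free)
    if not datasets:
        raise ValueError("need at least one dataset")
    names = set(scheme.rate_names())
    unknown = [f for f in free if f not in names]
    if unknown:
        raise KeyError(f"free rates not in scheme: {unknown}")
    if not free:
        raise ValueError("free must name at least one rate")

    builders = [_QBuilder(scheme, ds.cond, free) for ds in datasets]
    idx = _aggregate_info(scheme)
    single_open = idx[1].size == 1
    data = [(np.asarray(ds.class_codes, np.int8), np.asarray(ds.durations, float),
             float(ds.dead_time)) for ds in datasets]

    def nll(theta: np.ndarray) -> float:
        rates = np.exp(theta)
        total = 0.0
        for builder, (codes, durs, td) in zip(builders, data):
            Q = builder.build(rates)
            if single_open:
                ll = _loglik_single_open(Q, idx, codes, durs, td)
            else:
                ll = _loglik_general(Q, idx, codes, durs, td)
            if not np.isfinite(ll):
                return 1e12
            total += ll
        return -total

    base = scheme.base_rates()
    theta0 = np.log([float((start or {}).get(f, base[f])) for f in free])
    lo, hi = np.log(bounds[0]), np.log(bounds[1])
    theta0 = np.clip(theta0, lo, hi)
    rng = np.random.default_rng(seed)
    box = [(lo, hi)] * len(free)

    best = None
    tried = 0
    for s in range(max(1, n_starts)):
        th = theta0 if s == 0 else np.clip(theta0 + rng.normal(0, jitter_sd, theta0.size), lo, hi)
        res = minimize(
            nll, th, method="L-BFGS-B", bounds=box,
            options={"ftol": 1e-13, "gtol": 1e-9, "maxiter": 1000},
        )
        tried += 1
        if best is None or (res.fun < best.fun):
            best = res
    assert best is not None
    n_events = int(sum(len(ds) for ds in datasets))
    conditions = [ds.cond for ds in datasets]

    if not np.isfinite(best.fun) or best.fun >= 1e12:
        return FitResult(
            estimates={f: float(np.exp(t)) for f, t in zip(free, best.x)},
            standard_errors={f: float("nan") for f in free},
            log_likelihood=float(-best.fun),
            n_events=n_events,
            converged=False,
            ses_available=False,
            conditions=conditions,
            message="all starts failed to reach a finite optimum",
            n_starts_tried=tried,
        )

    theta_hat = best.x
    rates_hat = np.exp(theta_hat)
    H = _fd_hessian(nll, theta_hat)
    non_ident = [f for f, d in zip(free, np.diag(H)) if not (d > curvature_tol)]
    ses = {}
    ses_available = True
    try:
        cov = np.linalg.inv(H)
        diag = np.diag(cov)
        if np.any(diag <= 0):
            raise np.linalg.LinAlgError("non-positive-definite information")
        se_log = np.sqrt(diag)
        for f, r, s_log in zip(free, rates_hat, se_log):
            ses[f] = float("nan") if f in non_ident else float(r * s_log)
    except np.linalg.LinAlgError:
        ses_available = False
        ses = {f: float("nan") for f in free}
    if non_ident and ses_available:
        # information matrix is singular in those directions
        ses_available = len(non_ident) < len(free)
    return FitResult(
        estimates={f: float(r) for f, r in zip(free, rates_hat)},
        standard_errors=ses,
        log_likelihood=float(-best.fun),
        n_events=n_events,
        converged=bool(best.success),
        non_identifiable=non_ident,
        ses_available=ses_available,
        conditions=conditions,
        message=str(best.message),
        n_starts_tried=tried,
    )
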