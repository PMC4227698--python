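"""Aggregated Markov schemes for single-channel gating and open-channel block.

A kinetic scheme is a continuous-time Markov chain over a handful of channel
conformations, observed only through conductance classes (open vs. closed).
Edges carry :class:`RateLaw` objects: a base rate constant, optional first-order
mass-action scaling by a named ligand (agonist or blocker), and an optional
exponential voltage factor ``exp(s * V_m)`` for rates that sense the
transmembrane field.  The canonical scheme built here is the sequential-block
model of the adult muscle nicotinic receptor: an agonist-dependent C <-> O
gate, three desensitized states attached to the open state, and one or two
blocked states entered from the open state by mass-action blocker binding.

Blocked and desensitized states are non-conducting, so the observable dwell
distributions are phase-type (mixtures of exponentials); closed forms for
those densities and their moments live here and serve as analytic ground
truth for the simulator and the interval-likelihood fitter.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import linalg
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

CLOSED = "closed"
OPEN = "open"
CONDUCTANCE_CLASSES = (CLOSED, OPEN)
#: integer codes used throughout the package for aggregated dwell classes
CLASS_CODE = {CLOSED: 0, OPEN: 1}
LIGANDS = ("none", "ACh", "blocker")


@dataclass(frozen=True)
class Conditions:
    """Experimental condition: concentrations in µM, membrane potential in mV.

    ``V_m`` follows the cell-attached convention V_m = V_rest - V_hold.
    """

    conc_ACh: float = 0.0
    conc_blocker: float = 0.0
    V_m: float = 0.0

    def __post_init__(self) -> None:
        if self.conc_ACh < 0 or self.conc_blocker < 0:
            raise ValueError("concentrations must be >= 0")
        if not math.isfinite(self.V_m):
            raise ValueError("V_m must be finite")

    def ligand_concentration(self, ligand: str) -> float:
        if ligand == "none":
            return 1.0
        if ligand == "ACh":
            return self.conc_ACh
        if ligand == "blocker":
            return self.conc_blocker
        raise ValueError(f"unknown ligand {ligand!r}")


@dataclass(frozen=True)
class RateLaw:
    """A transition rate: ``base_rate * [ligand] * exp(s * V_m)``.

    ``base_rate`` is in s^-1 for unimolecular steps and µM^-1 s^-1 for
    ligand-dependent (mass-action) steps; ``voltage_sensitivity`` is per mV.
    """

    base_rate: float
    ligand: str = "none"
    voltage_sensitivity: float = 0.0

    def __post_init__(self) -> None:
        if not (self.base_rate > 0 and math.isfinite(self.base_rate)):
            raise ValueError(f"base_rate must be positive and finite, got {self.base_rate}")
        if self.ligand not in LIGANDS:
            raise ValueError(f"ligand must be one of {LIGANDS}, got {self.ligand!r}")
        if not math.isfinite(self.voltage_sensitivity):
            raise ValueError("voltage_sensitivity must be finite")

    def value(self, cond: Conditions) -> float:
        """Evaluate the rate (s^-1) under the given conditions."""
        v = self.base_rate * cond.ligand_concentration(self.ligand)
        if self.voltage_sensitivity != 0.0:
            v *= math.exp(self.voltage_sensitivity * cond.V_m)
        return v


@dataclass(frozen=True)
class Edge:
    source: str
    target: str
    rate: RateLaw
    name: str = ""

    def __post_init__(self) -> None:
        if self.source == self.target:
            raise ValueError(f"self-edge on state {self.source!r}")
        if not self.name:
            object.__setattr__(self, "name", f"{self.source}->{self.target}")


class KineticScheme:
    """States, conductance classes and rate-law edges of an aggregated model."""

    def __init__(
        self,
        states: Sequence[str],
        classes: Mapping[str, str],
        edges: Iterable[Edge],
    ) -> None:
        self.states = tuple(states)
        if len(set(self.states)) != len(self.states):
            raise ValueError("duplicate state labels")
        self.classes = dict(classes)
        self.edges = list(edges)
        self._index = {s: i for i, s in enumerate(self.states)}
        self._validate()

    # -- validation -------------------------------------------------------
    def _validate(self) -> None:
        for s in self.states:
            if self.classes.get(s) not in CONDUCTANCE_CLASSES:
                raise ValueError(f"state {s!r} lacks a valid conductance class")
        extra = set(self.classes) - set(self.states)
        if extra:
            raise ValueError(f"classes given for unknown states {sorted(extra)}")
        seen_names = set()
        seen_pairs = set()
        for e in self.edges:
            if e.source not in self._index or e.target not in self._index:
                raise ValueError(f"edge {e.name!r} references unknown state")
            if e.name in seen_names:
                raise ValueError(f"duplicate edge name {e.name!r}")
            if (e.source, e.target) in seen_pairs:
                raise ValueError(f"duplicate edge {e.source}->{e.target}")
            seen_names.add(e.name)
            seen_pairs.add((e.source, e.target))
        if not any(c == OPEN for c in self.classes.values()):
            raise ValueError("scheme needs at least one open-class state")
        if not any(c == CLOSED for c in self.classes.values()):
            raise ValueError("scheme needs at least one closed-class state")
        n = len(self.states)
        row = [self._index[e.source] for e in self.edges]
        col = [self._index[e.target] for e in self.edges]
        out_deg = np.zeros(n, dtype=int)
        for i in row:
            out_deg[i] += 1
        if np.any(out_deg == 0):
            dead = [self.states[i] for i in np.flatnonzero(out_deg == 0)]
            raise ValueError(f"states without outgoing edges: {dead}")
        adj = csr_matrix((np.ones(len(row)), (row, col)), shape=(n, n))
        n_comp, _ = connected_components(adj, directed=True, connection="strong")
        if n_comp != 1:
            raise ValueError("scheme graph is not strongly connected")

    # -- introspection ----------------------------------------------------
    def state_index(self, state: str) -> int:
        return self._index[state]

    def class_states(self, cls: str) -> list[str]:
        return [s for s in self.states if self.classes[s] == cls]

    def class_indices(self, cls: str) -> np.ndarray:
        return np.array([self._index[s] for s in self.class_states(cls)], dtype=int)

    def class_codes(self) -> np.ndarray:
        """Per-state aggregate code (0 = closed, 1 = open)."""
        return np.array([CLASS_CODE[self.classes[s]] for s in self.states], dtype=np.int8)

    def rate_names(self) -> list[str]:
        return [e.name for e in self.edges]

    def edge(self, name: str) -> Edge:
        for e in self.edges:
            if e.name == name:
                return e
        raise KeyError(name)

    def base_rates(self) -> dict[str, float]:
        return {e.name: e.rate.base_rate for e in self.edges}

    def with_rates(self, rates: Mapping[str, float]) -> "KineticScheme":
        """Copy of the scheme with named base rates replaced."""
        unknown = set(rates) - set(self.rate_names())
        if unknown:
            raise KeyError(f"unknown rate names {sorted(unknown)}")
        edges = []
        for e in self.edges:
            if e.name in rates:
                rl = RateLaw(float(rates[e.name]), e.rate.ligand, e.rate.voltage_sensitivity)
                edges.append(Edge(e.source, e.target, rl, e.name))
            else:
                edges.append(e)
        return KineticScheme(self.states, self.classes, edges)

    def relabeled(self, order: Sequence[str]) -> "KineticScheme":
        """Same scheme with states listed in a different order."""
        if sorted(order) != sorted(self.states):
            raise ValueError("order must be a permutation of the states")
        return KineticScheme(order, self.classes, self.edges)

    # -- numerics ---------------------------------------------------------
    def generator_matrix(self, cond: Conditions) -> np.ndarray:
        return generator_matrix(self, cond)

    # -- serialization ----------------------------------------------------
    def to_json(self) -> str:
        doc = {
            "states": list(self.states),
            "classes": self.classes,
            "edges": [
                {
                    "from": e.source,
                    "to": e.target,
                    "rate": e.rate.base_rate,
                    "ligand": e.rate.ligand,
                    "vsens": e.rate.voltage_sensitivity,
                    "name": e.name,
                }
                for e in self.edges
            ],
        }
        return json.dumps(doc, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "KineticScheme":
        doc = json.loads(text)
        edges = [
            Edge(
                d["from"],
                d["to"],
                RateLaw(d["rate"], d.get("ligand", "none"), d.get("vsens", 0.0)),
                d.get("name", ""),
            )
            for d in doc["edges"]
        ]
        return cls(doc["states"], doc["classes"], edges)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"KineticScheme(states={self.states}, n_edges={len(self.edges)})"


# ---------------------------------------------------------------------------
# canonical blockade scheme
# ---------------------------------------------------------------------------

GATING_RATE_NAMES = (
    "opening", "closing",
    "d1_on", "d1_off", "d2_on", "d2_off", "d3_on", "d3_off",
)
ONE_MODE_BLOCK_NAMES = ("kb_on", "kb_off")
TWO_MODE_BLOCK_NAMES = ("kb_fast_on", "kb_fast_off", "kb_slow_on", "kb_slow_off")


def build_blockade_scheme(
    rate_table: Mapping[str, float],
    n_block_modes: int = 1,
    voltage_sensitivity: Mapping[str, float] | None = None,
) -> KineticScheme:
    """Gating + sequential-blockade scheme of the muscle AChR.

    ``C <-> O`` agonist-dependent gate, three desensitized states D1..D3
    attached to O (star topology; their exact interconnection is a nuisance
    for blockade estimation and is configurable by building a custom scheme),
    and one blocked state B (``n_block_modes=1``) or two blocked states
    B_fast / B_slow (``n_block_modes=2``), each adjacent only to O.  Blocking
    steps are first-order in the blocker concentration.

    ``rate_table`` must provide positive values for
    ``opening`` (µM^-1 s^-1, ACh), ``closing``, ``d{1,2,3}_{on,off}`` (s^-1)
    and, per blockade mode, ``kb_on`` (µM^-1 s^-1) / ``kb_off`` (s^-1)
    (one mode) or ``kb_{fast,slow}_{on,off}`` (two modes).

    ``voltage_sensitivity`` optionally maps rate names to exponential slopes
    per mV; by default no rate is voltage-sensitive (blocker binding is the
    one rate a caller will typically flag).
    """
    if n_block_modes not in (1, 2):
        raise ValueError(f"n_block_modes must be 1 or 2, got {n_block_modes}")
    block_names = ONE_MODE_BLOCK_NAMES if n_block_modes == 1 else TWO_MODE_BLOCK_NAMES
    required = GATING_RATE_NAMES + block_names
    missing = [k for k in required if k not in rate_table]
    if missing:
        raise ValueError(f"rate_table missing entries: {missing}")
    for k in required:
        v = rate_table[k]
        if not (v > 0 and math.isfinite(v)):
            raise ValueError(f"rate {k!r} must be positive and finite, got {v}")
    vs = dict(voltage_sensitivity or {})
    unknown_vs = set(vs) - set(required)
    if unknown_vs:
        raise ValueError(f"voltage_sensitivity for unknown rates {sorted(unknown_vs)}")

    def law(name: str, ligand: str = "none") -> RateLaw:
        return RateLaw(float(rate_table[name]), ligand, float(vs.get(name, 0.0)))

    states = ["C", "O", "D1", "D2", "D3"]
    classes = {"C": CLOSED, "O": OPEN, "D1": CLOSED, "D2": CLOSED, "D3": CLOSED}
    edges = [
        Edge("C", "O", law("opening", "ACh"), "opening"),
        Edge("O", "C", law("closing"), "closing"),
    ]
    for d in ("D1", "D2", "D3"):
        k = d.lower()
        edges.append(Edge("O", d, law(f"{k}_on"), f"{k}_on"))
        edges.append(Edge(d, "O", law(f"{k}_off"), f"{k}_off"))
    if n_block_modes == 1:
        states.append("B")
        classes["B"] = CLOSED
        edges.append(Edge("O", "B", law("kb_on", "blocker"), "kb_on"))
        edges.append(Edge("B", "O", law("kb_off"), "kb_off"))
    else:
        for mode in ("fast", "slow"):
            b = f"B_{mode}"
            states.append(b)
            classes[b] = CLOSED
            edges.append(Edge("O", b, law(f"kb_{mode}_on", "blocker"), f"kb_{mode}_on"))
            edges.append(Edge(b, "O", law(f"kb_{mode}_off"), f"kb_{mode}_off"))
    return KineticScheme(states, classes, edges)


# ---------------------------------------------------------------------------
# generator matrix and phase-type dwell quantities
# ---------------------------------------------------------------------------

def generator_matrix(scheme: KineticScheme, cond: Conditions) -> np.ndarray:
    """Q-matrix: Q[i, j] = rate i->j evaluated under ``cond``; rows sum to 0."""
    n = len(scheme.states)
    Q = np.zeros((n, n))
    for e in scheme.edges:
        Q[scheme.state_index(e.source), scheme.state_index(e.target)] += e.rate.value(cond)
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def equilibrium_distribution(Q: np.ndarray) -> np.ndarray:
    """Stationary distribution pi with pi @ Q = 0, pi >= 0, sum(pi) = 1."""
    ns = linalg.null_space(Q.T)
    if ns.shape[1] == 0:
        raise np.linalg.LinAlgError("Q has no stationary distribution")
    pi = np.real(ns[:, 0])
    if pi.sum() < 0:
        pi = -pi
    pi = np.clip(pi, 0.0, None)
    return pi / pi.sum()


def class_entry_vector(
    scheme: KineticScheme, cond: Conditions, cls: str, Q: np.ndarray | None = None
) -> np.ndarray:
    """Equilibrium entry probabilities into the aggregate ``cls``.

    Component j (for state j in the class) is proportional to the stationary
    probability flux from outside the class into j.
    """
    if Q is None:
        Q = generator_matrix(scheme, cond)
    idx = scheme.class_indices(cls)
    if idx.size == 0:
        raise ValueError(f"class {cls!r} has no states")
    other = np.setdiff1d(np.arange(len(scheme.states)), idx)
    pi = equilibrium_distribution(Q)
    flux = pi[other] @ Q[np.ix_(other, idx)]
    total = flux.sum()
    if total <= 0:
        raise ValueError(f"no equilibrium flux into class {cls!r}")
    return flux / total


def _class_blocks(scheme: KineticScheme, cond: Conditions, cls: str):
    Q = generator_matrix(scheme, cond)
    idx = scheme.class_indices(cls)
    if idx.size == 0:
        raise ValueError(f"class {cls!r} has no states")
    Qcc = Q[np.ix_(idx, idx)]
    pe = class_entry_vector(scheme, cond, cls, Q)
    return Q, idx, Qcc, pe


def phase_type_dwell_density(
    scheme: KineticScheme, cond: Conditions, cls: str, t: float | np.ndarray
) -> np.ndarray | float:
    """Density of a sojourn in aggregate ``cls`` entered at equilibrium.

    f(t) = pi_e^T exp(Q_cc t) q with q the exit-rate vector; integrates to 1.
    """
    _, _, Qcc, pe = _class_blocks(scheme, cond, cls)
    q = -Qcc @ np.ones(Qcc.shape[0])
    lam, V = np.linalg.eig(Qcc)
    a = np.linalg.solve(V.T, pe)  # pe^T V without forming inverse twice
    b = np.linalg.solve(V, q)
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(t_arr < 0):
        raise ValueError("t must be >= 0")
    f = np.real(np.exp(np.outer(t_arr, lam)) @ (a * b))
    f = np.clip(f, 0.0, None)
    return f if np.ndim(t) else float(f[0])


def phase_type_dwell_cdf(
    scheme: KineticScheme, cond: Conditions, cls: str, t: float | np.ndarray
) -> np.ndarray | float:
    """F(t) = 1 - pi_e^T exp(Q_cc t) 1 for a sojourn in aggregate ``cls``."""
    _, _, Qcc, pe = _class_blocks(scheme, cond, cls)
    lam, V = np.linalg.eig(Qcc)
    a = np.linalg.solve(V.T, pe)
    b = np.linalg.solve(V, np.ones(Qcc.shape[0]))
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    surv = np.real(np.exp(np.outer(t_arr, lam)) @ (a * b))
    F = np.clip(1.0 - surv, 0.0, 1.0)
    return F if np.ndim(t) else float(F[0])


def mean_dwell_time(scheme: KineticScheme, cond: Conditions, cls: str) -> float:
    """Closed-form mean sojourn time in ``cls``: -pi_e^T Q_cc^{-1} 1."""
    _, _, Qcc, pe = _class_blocks(scheme, cond, cls)
    return float(-pe @ np.linalg.solve(Qcc, np.ones(Qcc.shape[0])))
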