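"""Bertz graph-complexity scoring and the affinity-vs-complexity comparison.

The Bertz index C = C(eta) + C(E) scores a molecular graph by the
information content of two partitions:

* ``C(eta)``: the ``eta`` "connections" (two-edge paths on the bond-order
  multigraph: a bond of order m counts as m parallel edges, so two bonds of
  orders m1, m2 meeting at an atom contribute m1*m2 connections and a single
  multiple bond contributes C(m, 2); aromatic bonds have order 1.5) are
  partitioned into topological equivalence classes using graph-symmetry atom
  ranks; ``C(eta) = 2 eta log2 eta - sum_i n_i log2 n_i``.
* ``C(E)``: the information content of the heavy-atom element distribution,
  ``N log2 N - sum_e n_e log2 n_e`` (zero for a homoelemental skeleton).

Hydrogens are implicit throughout.  Because published "Bertz index" values
vary between software implementations, cross-compound comparisons are
reported as ratios, which damp variant differences.

The bundled compound table (``data/blockers_synthetic.tsv``) carries
reconstructed structures: the PEG-bis-quaternary-ammonium blockers PQ0–PQ5
assembled from their described composition (an octa(ethylene glycol)
backbone joining two quaternary ammonium groups) and the non-PEG comparator
blockers from their standard published structures, with approximate
literature dissociation constants.  It is a synthetic stand-in, not a
deposited data set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Sequence

import pandas as pd
from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.error")

PEG_CLASS = "PEG-based"
NON_PEG_CLASS = "non-PEG-based"


def _mol_from_smiles(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        problems = Chem.DetectChemistryProblems(Chem.MolFromSmiles(smiles, sanitize=False) or Chem.RWMol())
        detail = "; ".join(p.Message() for p in problems) if problems else "unparsable SMILES"
        raise ValueError(f"cannot parse SMILES {smiles!r}: {detail}")
    if mol.GetNumHeavyAtoms() < 1:
        raise ValueError("molecule needs at least one heavy atom")
    return mol


def _information_content(counts: Iterable[float], total: float, doubled: bool) -> float:
    if total <= 0:
        return 0.0
    base = 2.0 * total * math.log2(total) if doubled else total * math.log2(total)
    return base - sum(n * math.log2(n) for n in counts if n > 0)


def bertz_index(smiles_or_mol: str | Chem.Mol) -> float:
    """Bertz complexity score C(eta) + C(E) of a molecule.

    Accepts a SMILES string or an RDKit Mol; hydrogens are implicit.
    Invariant under atom reordering (equivalence classes come from canonical
    symmetry ranks, not input order).
    """
    mol = _mol_from_smiles(smiles_or_mol) if isinstance(smiles_or_mol, str) else smiles_or_mol
    if mol.GetNumHeavyAtoms() < 1:
        raise ValueError("molecule needs at least one heavy atom")
    ranks = list(Chem.CanonicalRankAtoms(mol, breakTies=False))
    # two-edge paths on the bond-order multigraph, grouped by symmetry class
    classes: dict[tuple, float] = {}
    eta = 0.0
    for atom in mol.GetAtoms():
        bonds = list(atom.GetBonds())
        center = ranks[atom.GetIdx()]
        for i in range(len(bonds)):
            for j in range(i + 1, len(bonds)):
                a = bonds[i].GetOtherAtom(atom).GetIdx()
                b = bonds[j].GetOtherAtom(atom).GetIdx()
                ends = tuple(sorted((ranks[a], ranks[b])))
                key = (center, ends)
                mult = bonds[i].GetBondTypeAsDouble() * bonds[j].GetBondTypeAsDouble()
                classes[key] = classes.get(key, 0.0) + mult
                eta += mult
    for bond in mol.GetBonds():
        m = bond.GetBondTypeAsDouble()
        if m > 1.0:
            # parallel-edge pairs of one multiple bond: C(m, 2)
            self_pairs = m * (m - 1.0) / 2.0
            ends = tuple(sorted((ranks[bond.GetBeginAtomIdx()], ranks[bond.GetEndAtomIdx()])))
            key = ("bond", ends)
            classes[key] = classes.get(key, 0.0) + self_pairs
            eta += self_pairs
    c_eta = _information_content(classes.values(), eta, doubled=True)
    elems: dict[int, int] = {}
    for atom in mol.GetAtoms():
        elems[atom.GetAtomicNum()] = elems.get(atom.GetAtomicNum(), 0) + 1
    c_e = _information_content(elems.values(), mol.GetNumHeavyAtoms(), doubled=False)
    return c_eta + c_e


@dataclass(frozen=True)
class MoleculeRecord:
    name: str
    smiles: str
    bertz_index: float
    kd_uM: float
    pq_class: str

    def __post_init__(self) -> None:
        if self.bertz_index < 0:
            raise ValueError("bertz_index must be >= 0")
        if not self.kd_uM > 0:
            raise ValueError(f"record {self.name!r}: kd_uM must be positive")
        if self.pq_class not in (PEG_CLASS, NON_PEG_CLASS):
            raise ValueError(f"unknown class {self.pq_class!r}")


def load_bundled_blockers() -> pd.DataFrame:
    """Bundled reconstructed blocker table: name, class, kd_uM, SMILES."""
    with resources.files("pegblock.data").joinpath("blockers_synthetic.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t", comment="#")
    return df


def score_blockers(df: pd.DataFrame | None = None) -> pd.DataFrame:
    """Add a ``bertz`` column to a blocker table (bundled table by default)."""
    if df is None:
        df = load_bundled_blockers()
    df = df.copy()
    df["bertz"] = [bertz_index(s) for s in df["smiles"]]
    return df


def affinity_complexity_table(
    records: Sequence[MoleculeRecord] | pd.DataFrame,
    reference: str = "(+)-tubocurarine",
    comparison_set: Sequence[str] = ("PQ2", "PQ3", "PQ4", "PQ5"),
) -> tuple[pd.DataFrame, float]:
    """Scatter-ready (name, class, bertz, log10 Kd) table plus the
    fold-complexity ratio bertz(reference) / mean(bertz(comparison set)).
    """
    if isinstance(records, pd.DataFrame):
        recs = [
            MoleculeRecord(r["name"], r["smiles"], float(r["bertz"]),
                           float(r["kd_uM"]), r["pq_class"])
            for _, r in records.iterrows()
        ]
    else:
        recs = list(records)
    classes = {r.pq_class for r in recs}
    if classes != {PEG_CLASS, NON_PEG_CLASS}:
        raise ValueError("need at least one record per class")
    table = pd.DataFrame(
        {
            "name": [r.name for r in recs],
            "pq_class": [r.pq_class for r in recs],
            "bertz": [r.bertz_index for r in recs],
            "log10_Kd_uM": [math.log10(r.kd_uM) for r in recs],
        }
    )
    by_name = {r.name: r for r in recs}
    if reference not in by_name:
        raise KeyError(f"reference compound {reference!r} not in records")
    missing = [n for n in comparison_set if n not in by_name]
    if missing:
        raise KeyError(f"comparison compounds missing: {missing}")
    mean_pq = sum(by_name[n].bertz_index for n in comparison_set) / len(comparison_set)
    ratio = by_name[reference].bertz_index / mean_pq
    return table, float(ratio)
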