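"""Conditional codes: scaffold fingerprints, property codes, activity codes.

A generation requirement is expressed as a fixed-length numeric code ``c``
that the conditional policy receives at every convolution layer.  Three
schemas are supported:

* **scaffold fingerprint** -- a binary vector over a scaffold set ``S``
  (Bemis-Murcko scaffolds plus ring assemblies extracted from a reference
  corpus); bit ``i`` is set when the molecule contains scaffold ``s_i`` as a
  substructure.
* **(QED, SA)** -- drug-likeness (quantitative estimate of drug-likeness,
  0..1) and the Ertl-Schuffenhauer synthetic-accessibility score (1..10,
  higher = harder to make), both computed with RDKit's reference
  implementations.
* **activity bits** -- per-target binary activity labels from trained
  classifiers (random forest on 2048-bit circular fingerprints of radius 3,
  i.e. ECFP6).

Interval requirements on continuous codes ("QED above 0.84, SA below 1.9")
are boxes in code space; sampling a concrete code for generation draws from
the empirical code distribution of a reference set restricted to the box.
"""

from __future__ import annotations

import os
import sys
from dataclasses import dataclass, field
from typing import Callable, List, Optional, Sequence, Tuple, Union

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem, QED, RDConfig
from rdkit.Chem.Scaffolds import MurckoScaffold

from .molgraph import MolGraph, ParseError, ValidityError, _sanitized

sys.path.append(os.path.join(RDConfig.RDContribDir, "SA_Score"))
import sascorer  # noqa: E402  (RDKit's reference SA-score implementation)

__all__ = [
    "ScaffoldEntry", "ScaffoldSet", "CodeRegion", "Interval",
    "extract_scaffold_set", "scaffold_fingerprint", "property_code",
    "activity_code", "sample_code", "ActivityPredictor", "ecfp6",
]

FP_RADIUS = 3      # circular fingerprint radius ("ECFP6")
FP_BITS = 2048


def _as_mol(g: Union[MolGraph, str, Chem.Mol]) -> Chem.Mol:
    if isinstance(g, Chem.Mol):
        return g
    if isinstance(g, str):
        mol = Chem.MolFromSmiles(g)
        if mol is None:
            raise ParseError(f"unparseable SMILES: {g!r}")
        return mol
    return _sanitized(g)


@dataclass(frozen=True)
class ScaffoldEntry:
    smiles: str                 # canonical
    kind: str                   # "bemis_murcko" | "ring_assembly"


class ScaffoldSet:
    """Ordered, deduplicated scaffold structures ``S = {s_1..s_N}``."""

    def __init__(self, entries: Sequence[ScaffoldEntry]):
        seen = {}
        for e in entries:
            if e.smiles not in seen:
                seen[e.smiles] = e
        self.entries: List[ScaffoldEntry] = sorted(
            seen.values(), key=lambda e: e.smiles)
        self._mols = [Chem.MolFromSmiles(e.smiles) for e in self.entries]
        if any(m is None for m in self._mols):
            raise ParseError("unparseable scaffold in set")

    def __len__(self):
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def mols(self) -> List[Chem.Mol]:
        return self._mols

    def to_lines(self) -> str:
        return "\n".join(f"{e.smiles}\t{e.kind}" for e in self.entries)

    @classmethod
    def from_lines(cls, text: str) -> "ScaffoldSet":
        entries = []
        for line in text.splitlines():
            if not line.strip():
                continue
            smi, kind = line.split("\t")
            entries.append(ScaffoldEntry(smi, kind))
        return cls(entries)


def _ring_assemblies(mol: Chem.Mol) -> List[str]:
    """Connected ring systems (components of the ring-bond subgraph)."""
    ring_bonds = [b.GetIdx() for b in mol.GetBonds() if b.IsInRing()]
    if not ring_bonds:
        return []
    # union-find over atoms joined by ring bonds
    parent = {}

    def find(x):
        while parent.setdefault(x, x) != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for bi in ring_bonds:
        b = mol.GetBondWithIdx(bi)
        ra, rb = find(b.GetBeginAtomIdx()), find(b.GetEndAtomIdx())
        if ra != rb:
            parent[ra] = rb
    groups: dict = {}
    for bi in ring_bonds:
        b = mol.GetBondWithIdx(bi)
        groups.setdefault(find(b.GetBeginAtomIdx()), []).append(bi)
    out = []
    for bonds in groups.values():
        sub = Chem.PathToSubmol(mol, bonds)
        try:
            Chem.SanitizeMol(sub)
        except Exception:
            continue
        out.append(Chem.MolToSmiles(sub))
    return out


def extract_scaffold_set(corpus: Sequence[Union[str, MolGraph]]
                         ) -> ScaffoldSet:
    """Bemis-Murcko scaffolds and ring assemblies of a corpus.

    Acyclic molecules contribute nothing.  The result is deduplicated by
    canonical SMILES and canonically ordered.
    """
    entries = []
    for item in corpus:
        mol = _as_mol(item)
        bm = MurckoScaffold.GetScaffoldForMol(mol)
        if bm is not None and bm.GetNumAtoms() > 0:
            entries.append(ScaffoldEntry(Chem.MolToSmiles(bm),
                                         "bemis_murcko"))
        for smi in _ring_assemblies(mol):
            entries.append(ScaffoldEntry(smi, "ring_assembly"))
    return ScaffoldSet(entries)


def scaffold_fingerprint(g: Union[MolGraph, str], S: ScaffoldSet
                         ) -> np.ndarray:
    """Binary substructure-membership vector of ``g`` over ``S``."""
    mol = _as_mol(g)
    return np.array([1.0 if mol.HasSubstructMatch(s) else 0.0
                     for s in S.mols()])


def property_code(g: Union[MolGraph, str]) -> np.ndarray:
    """``c = (QED, SA)`` via RDKit's QED and SA-score implementations."""
    mol = _as_mol(g)
    return np.array([QED.qed(mol), sascorer.calculateScore(mol)])


def ecfp6(mol: Chem.Mol) -> np.ndarray:
    fp = AllChem.GetMorganFingerprintAsBitVect(mol, FP_RADIUS, nBits=FP_BITS)
    return np.asarray(fp, dtype=np.float64)


class ActivityPredictor:
    """Random-forest activity classifier on ECFP6 fingerprints.

    Class imbalance (actives are typically a percent-scale minority) is
    handled with balanced class weights; the decision threshold is 0.5 on
    the predicted probability.
    """

    def __init__(self, n_estimators: int = 100, seed: int = 0):
        from sklearn.ensemble import RandomForestClassifier
        self._clf = RandomForestClassifier(
            n_estimators=n_estimators, class_weight="balanced",
            random_state=seed)
        self._fitted = False

    def fit(self, molecules: Sequence[Union[str, MolGraph]],
            labels: Sequence[int]) -> "ActivityPredictor":
        X = np.stack([ecfp6(_as_mol(m)) for m in molecules])
        self._clf.fit(X, np.asarray(labels, dtype=int))
        self._fitted = True
        return self

    def predict(self, g: Union[str, MolGraph, Chem.Mol]) -> int:
        if not self._fitted:
            raise RuntimeError("classifier has not been fitted")
        x = ecfp6(_as_mol(g))[None, :]
        classes = list(self._clf.classes_)
        if 1 not in classes:
            return 0
        p_active = self._clf.predict_proba(x)[0, classes.index(1)]
        return int(p_active >= 0.5)


def activity_code(g: Union[MolGraph, str], clf_a: ActivityPredictor,
                  clf_b: ActivityPredictor) -> np.ndarray:
    """Two-target activity bit vector (e.g. JNK3, GSK-3beta profiles)."""
    return np.array([float(clf_a.predict(g)), float(clf_b.predict(g))])


@dataclass(frozen=True)
class Interval:
    lo: float
    hi: float
    closed_lo: bool = False
    closed_hi: bool = False

    def __post_init__(self):
        if self.lo > self.hi:
            raise ValueError(f"empty interval ({self.lo}, {self.hi})")

    def contains(self, x: float) -> bool:
        above = x >= self.lo if self.closed_lo else x > self.lo
        below = x <= self.hi if self.closed_hi else x < self.hi
        return above and below


@dataclass(frozen=True)
class CodeRegion:
    """A box ``C`` in code space: one interval per code dimension."""

    intervals: Tuple[Interval, ...]

    @classmethod
    def box(cls, *bounds: Tuple[float, float]) -> "CodeRegion":
        return cls(tuple(Interval(lo, hi) for lo, hi in bounds))

    def contains(self, code: np.ndarray) -> bool:
        code = np.asarray(code, float)
        if code.shape != (len(self.intervals),):
            raise ValueError("code dimension does not match region")
        return all(iv.contains(float(x))
                   for iv, x in zip(self.intervals, code))


def sample_code(empirical_codes: Sequence[np.ndarray], region: CodeRegion,
                rng: np.random.Generator) -> np.ndarray:
    """Draw a code from ``p(c | c in C)``: the empirical distribution of a
    reference set restricted to the requirement region."""
    inside = [c for c in empirical_codes if region.contains(c)]
    if not inside:
        raise ValueError(
            "no empirical code satisfies the requirement region; "
            "widen C or supply more reference molecules")
    return np.asarray(inside[rng.integers(len(inside))], float)
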