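"""Molecular-graph data model and SMILES interop.

A molecule is a labeled graph ``G = (V, E)``: nodes carry *atom types* --
the triple (element symbol, number of explicit hydrogens, formal charge) --
and edges carry one of four *bond types* (single, double, triple, aromatic).
The nitrogen of pyrrole, for instance, is the triple ``("N", 1, 0)``.
Aromatic bonds are stored as such rather than in kekulized form, because the
dominant failure mode of stepwise graph generation is broken aromaticity and
we want validity checking to report it as its own class.

During sequential generation the graph additionally tracks the *latest
appended atom* ``v*``, the only atom ring-closing ``connect`` actions may
start from.

RDKit does all chemistry: parsing, sanitization, canonical SMILES and
aromaticity perception.  This module is a thin, explicit bridge between the
mutable generation-time graph and RDKit molecules.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from rdkit import Chem, RDLogger

# RDKit logs every sanitize failure; invalid intermediates are expected here.
RDLogger.DisableLog("rdApp.*")

__all__ = [
    "AtomType", "BondType", "AtomVocabulary", "MolGraph",
    "ParseError", "ValidityError", "VocabError", "CorpusError",
    "build_vocab", "graph_from_smiles", "smiles_from_graph", "is_valid",
    "canonical_smiles",
]


class ParseError(ValueError):
    """SMILES could not be parsed / sanitized."""


class ValidityError(ValueError):
    """Graph does not sanitize; ``kind`` is one of valence/aromaticity/other."""

    def __init__(self, message: str, kind: str):
        super().__init__(message)
        self.kind = kind


class VocabError(KeyError):
    """Atom type missing from the vocabulary."""


class CorpusError(ValueError):
    """One or more corpus records failed; carries (line, message) pairs."""

    def __init__(self, records: list):
        self.records = records
        lines = "; ".join(f"line {ln}: {msg}" for ln, msg in records[:5])
        more = "" if len(records) <= 5 else f" (+{len(records) - 5} more)"
        super().__init__(f"unreadable corpus records: {lines}{more}")


@dataclass(frozen=True, order=True)
class AtomType:
    """(symbol, explicit hydrogens, formal charge) node label."""

    symbol: str
    num_explicit_h: int = 0
    formal_charge: int = 0

    def __post_init__(self):
        try:
            ok = Chem.GetPeriodicTable().GetAtomicNumber(self.symbol) > 0
        except Exception:
            ok = False
        if not ok:
            raise ValueError(f"not an element symbol: {self.symbol!r}")
        if self.num_explicit_h < 0:
            raise ValueError("negative explicit-H count")

    def as_tuple(self):
        return (self.symbol, self.num_explicit_h, self.formal_charge)


class BondType(enum.IntEnum):
    SINGLE = 0
    DOUBLE = 1
    TRIPLE = 2
    AROMATIC = 3


_TO_RDKIT_BOND = {
    BondType.SINGLE: Chem.BondType.SINGLE,
    BondType.DOUBLE: Chem.BondType.DOUBLE,
    BondType.TRIPLE: Chem.BondType.TRIPLE,
    BondType.AROMATIC: Chem.BondType.AROMATIC,
}
_FROM_RDKIT_BOND = {v: k for k, v in _TO_RDKIT_BOND.items()}


class AtomVocabulary:
    """Ordered, duplicate-free list of atom types with index lookup."""

    def __init__(self, types: Sequence[AtomType]):
        self._types = list(types)
        self._index = {t: i for i, t in enumerate(self._types)}
        if len(self._index) != len(self._types):
            raise ValueError("duplicate atom types in vocabulary")
        if not self._types:
            raise ValueError("empty vocabulary")

    def __len__(self):
        return len(self._types)

    def __iter__(self):
        return iter(self._types)

    def __getitem__(self, i: int) -> AtomType:
        return self._types[i]

    def __contains__(self, t: AtomType) -> bool:
        return t in self._index

    def __eq__(self, other):
        return isinstance(other, AtomVocabulary) and self._types == other._types

    def index(self, t: AtomType) -> int:
        try:
            return self._index[t]
        except KeyError:
            raise VocabError(f"atom type {t.as_tuple()} not in vocabulary")

    def to_json(self) -> str:
        return json.dumps([list(t.as_tuple()) for t in self._types])

    @classmethod
    def from_json(cls, text: str) -> "AtomVocabulary":
        return cls([AtomType(s, h, q) for s, h, q in json.loads(text)])


@dataclass
class MolGraph:
    """Mutable labeled molecular graph with the ``v*`` marker.

    Invariants: no self-loops, at most one bond per atom pair, indices in
    range.  ``latest`` is the index of the most recently appended atom or
    ``None`` (graphs imported from SMILES carry no generation history).
    """

    atoms: list = field(default_factory=list)
    bonds: list = field(default_factory=list)  # (i, j, BondType), i < j
    latest: Optional[int] = None

    # -- construction ------------------------------------------------------
    def add_atom(self, atom_type: AtomType, *, mark_latest: bool = True) -> int:
        self.atoms.append(atom_type)
        idx = len(self.atoms) - 1
        if mark_latest:
            self.latest = idx
        return idx

    def add_bond(self, i: int, j: int, bond_type: BondType) -> None:
        i, j = int(i), int(j)
        n = len(self.atoms)
        if not (0 <= i < n and 0 <= j < n):
            raise IndexError(f"bond ({i},{j}) out of range for {n} atoms")
        if i == j:
            raise ValueError("self-loop bond")
        if self.has_bond(i, j):
            raise ValueError(f"duplicate bond ({i},{j})")
        self.bonds.append((min(i, j), max(i, j), BondType(bond_type)))

    def copy(self) -> "MolGraph":
        return MolGraph(list(self.atoms), list(self.bonds), self.latest)

    # -- queries -----------------------------------------------------------
    @property
    def num_atoms(self) -> int:
        return len(self.atoms)

    @property
    def num_bonds(self) -> int:
        return len(self.bonds)

    def has_bond(self, i: int, j: int) -> bool:
        key = (min(i, j), max(i, j))
        return any((a, b) == key for a, b, _ in self.bonds)

    def neighbors(self, i: int):
        out = []
        for a, b, t in self.bonds:
            if a == i:
                out.append((b, t))
            elif b == i:
                out.append((a, t))
        return out

    def is_connected(self) -> bool:
        if not self.atoms:
            return True
        seen = {0}
        frontier = [0]
        adj = {i: [] for i in range(self.num_atoms)}
        for a, b, _ in self.bonds:
            adj[a].append(b)
            adj[b].append(a)
        while frontier:
            v = frontier.pop()
            for u in adj[v]:
                if u not in seen:
                    seen.add(u)
                    frontier.append(u)
        return len(seen) == self.num_atoms

    # -- RDKit bridge ------------------------------------------------------
    def to_rdkit(self) -> Chem.RWMol:
        """Build the (unsanitized) RDKit molecule for this graph."""
        rw = Chem.RWMol()
        aromatic_atoms = set()
        for a, b, t in self.bonds:
            if t == BondType.AROMATIC:
                aromatic_atoms.update((a, b))
        for idx, at in enumerate(self.atoms):
            atom = Chem.Atom(at.symbol)
            atom.SetNumExplicitHs(at.num_explicit_h)
            atom.SetFormalCharge(at.formal_charge)
            if idx in aromatic_atoms:
                atom.SetIsAromatic(True)
            rw.AddAtom(atom)
        for a, b, t in self.bonds:
            n = rw.AddBond(a, b, _TO_RDKIT_BOND[t])
            if t == BondType.AROMATIC:
                rw.GetBondWithIdx(n - 1).SetIsAromatic(True)
        return rw

    @classmethod
    def from_rdkit(cls, mol: Chem.Mol) -> "MolGraph":
        g = cls()
        for atom in mol.GetAtoms():
            g.atoms.append(AtomType(atom.GetSymbol(),
                                    atom.GetNumExplicitHs(),
                                    atom.GetFormalCharge()))
        for bond in mol.GetBonds():
            bt = _FROM_RDKIT_BOND.get(bond.GetBondType())
            if bt is None:
                raise ParseError(
                    f"unsupported bond type {bond.GetBondType()}")
            g.bonds.append((min(bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()),
                            max(bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()),
                            bt))
        return g


# -- operations -------------------------------------------------------------

def canonical_smiles(s: str) -> str:
    mol = Chem.MolFromSmiles(s)
    if mol is None:
        raise ParseError(f"unparseable SMILES: {s!r}")
    return Chem.MolToSmiles(mol)


def graph_from_smiles(s: str) -> MolGraph:
    """Parse a SMILES into a :class:`MolGraph` (aromatic bonds kept aromatic)."""
    mol = Chem.MolFromSmiles(s)
    if mol is None:
        raise ParseError(f"unparseable SMILES: {s!r}")
    return MolGraph.from_rdkit(mol)


def _sanitized(g: MolGraph) -> Chem.Mol:
    if g.num_atoms == 0:
        raise ValidityError("empty graph has no molecule", "other")
    mol = g.to_rdkit().GetMol()
    try:
        Chem.SanitizeMol(mol)
    except Chem.AtomValenceException as e:
        raise ValidityError(str(e), "valence") from e
    except (Chem.KekulizeException, Chem.AtomKekulizeException) as e:
        raise ValidityError(str(e), "aromaticity") from e
    except Exception as e:  # pragma: no cover - misc sanitize failures
        raise ValidityError(str(e), "other") from e
    return mol


def smiles_from_graph(g: MolGraph) -> str:
    """Canonical SMILES of ``g``; raises :class:`ValidityError` otherwise."""
    return Chem.MolToSmiles(_sanitized(g))


def is_valid(g: MolGraph):
    """``(True, None)`` if the graph sanitizes, else ``(False, class)``.

    The failure class is ``"valence"``, ``"aromaticity"`` or ``"other"``,
    mirroring the mistakes stepwise graph decoders actually make.
    """
    try:
        _sanitized(g)
        return True, None
    except ValidityError as e:
        return False, e.kind


def _largest_fragment(mol: Chem.Mol) -> Chem.Mol:
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    return max(frags, key=lambda m: m.GetNumAtoms())


def build_vocab(corpus: Iterable[str]) -> AtomVocabulary:
    """Extract the atom-type vocabulary from a SMILES corpus.

    Standardization keeps the largest fragment of each record (salt
    stripping) and does not neutralize charges.  The result is sorted by
    (symbol, explicit H, charge) so vocabulary order is independent of
    corpus order.
    """
    types = set()
    bad = []
    n = 0
    for lineno, smi in enumerate(corpus, start=1):
        n += 1
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            bad.append((lineno, f"unparseable SMILES {smi!r}"))
            continue
        mol = _largest_fragment(mol)
        try:
            g = MolGraph.from_rdkit(mol)
        except ParseError as e:
            bad.append((lineno, str(e)))
            continue
        types.update(g.atoms)
    if n == 0:
        raise CorpusError([(0, "empty corpus")])
    if bad:
        raise CorpusError(bad)
    if not types:
        raise CorpusError([(0, "no atoms found; empty vocabulary")])
    return AtomVocabulary(sorted(types))
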