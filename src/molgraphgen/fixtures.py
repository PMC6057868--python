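"""Bundled desk-scale inputs.

Everything the test-suite and the examples need ships in code: a printed
list of ~30 drug-like molecules (including cimetidine and candesartan,
whose graphs and scaffolds are used as worked examples throughout the
package) and a seeded generator of small random molecular graphs for
stress tests.  No external download or database is involved.

The random generator grows valence-respecting trees atom by atom, closes
an occasional ring, optionally seeds growth from a benzene ring (so that a
substructure-conditioned corpus has both classes represented), and rejects
any draft RDKit refuses to sanitize -- generated molecules are therefore
always chemically valid and deterministic under the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, List, Sequence, Tuple

import numpy as np
from rdkit import Chem

from .molgraph import canonical_smiles

__all__ = ["FixtureSpec", "bundled_corpus", "small_corpus",
           "random_molecules", "synthetic_conditional_corpus"]

# Approved drugs and a few small reference molecules.  The list purposely
# exercises the whole atom-type triple: aromatic rings, charged atoms
# (choline's quaternary nitrogen, ranitidine's nitro group) and
# explicit-hydrogen heteroatoms (imidazole/indole NH).
_BUNDLED = [
    "CC1=C(N=CN1)CSCCNC(=NC)NC#N",                      # cimetidine
    "CCOC1=NC2=CC=CC(=C2N1CC3=CC=C(C=C3)C4=CC=CC=C4C5=NNN=N5)C(=O)O",  # candesartan
    "CC(=O)OC1=CC=CC=C1C(=O)O",                         # aspirin
    "CC(=O)NC1=CC=C(C=C1)O",                            # paracetamol
    "CC(C)CC1=CC=C(C=C1)C(C)C(=O)O",                    # ibuprofen
    "CN1C=NC2=C1C(=O)N(C(=O)N2C)C",                     # caffeine
    "CN1CCCC1C2=CC=CN=C2",                              # nicotine
    "CC(C)NCC(O)COC1=CC=C(CC(N)=O)C=C1",                # atenolol
    "CC(C)NCC(O)COC1=CC=CC2=CC=CC=C12",                 # propranolol
    "CC(=O)CC(C1=CC=CC=C1)C2=C(O)C3=CC=CC=C3OC2=O",     # warfarin
    "CN1C(=O)CN=C(C2=CC=CC=C2)C2=CC(Cl)=CC=C12",        # diazepam
    "CNCCC(OC1=CC=C(C=C1)C(F)(F)F)C1=CC=CC=C1",         # fluoxetine
    "CN(C)C(=N)NC(=N)N",                                # metformin
    "CC1=CC(=NO1)NS(=O)(=O)C2=CC=C(N)C=C2",             # sulfamethoxazole
    "CCN(CC)CCCC(C)NC1=C2C=CC(Cl)=CC2=NC=C1",           # chloroquine
    "C[N+](C)(C)CCO",                                   # choline
    "CCO",                                              # ethanol
    "CC1(C)SC2C(NC(=O)CC3=CC=CC=C3)C(=O)N2C1C(=O)O",    # benzylpenicillin
    "NS(=O)(=O)C1=CC(C(=O)O)=CC(NCC2=CC=CO2)=C1Cl",     # furosemide
    "CNC(=C[N+](=O)[O-])NCCSCC1=CC=C(CN(C)C)O1",        # ranitidine
    "CC1=CN=C(C(C)=C1OC)CS(=O)C1=NC2=CC(OC)=CC=C2N1",   # omeprazole
    "OC(=O)C1=CN(C2CC2)C3=CC(N4CCNCC4)=C(F)C=C3C1=O",   # ciprofloxacin
    "CC1(C)SC2C(NC(=O)C(N)C3=CC=C(O)C=C3)C(=O)N2C1C(=O)O",  # amoxicillin
    "CC(C)(C)NCC(O)C1=CC(CO)=C(O)C=C1",                 # salbutamol
    "COC1=CC(CC2=CN=C(N)N=C2N)=CC(OC)=C1OC",            # trimethoprim
    "NNC(=O)C1=CC=NC=C1",                               # isoniazid
    "CC1=C(CC(=O)O)C2=CC(OC)=CC=C2N1C(=O)C1=CC=C(Cl)C=C1",  # indomethacin
    "CCN(CC)CC(=O)NC1=C(C)C=CC=C1C",                    # lidocaine
    "COC1=CC2=CC=C(C(C)C(=O)O)C=C2C=C1",                # naproxen
    "CCC1(C2=CC=CC=C2)C(=O)NC(=O)NC1=O",                # phenobarbital
]

# Ten small molecules used for overfitting experiments: short enough that a
# tiny policy can memorize all routes within a few hundred iterations.
_SMALL = ["C", "CCO", "CCC", "CC=O", "CCN", "CCOC", "CC(C)O", "C=CC",
          "CC#N", "CCCO"]

_VALENCE = {"C": 4, "N": 3, "O": 2, "S": 2, "F": 1}


def bundled_corpus() -> List[str]:
    """The printed drug-like corpus (all entries sanitize)."""
    return list(_BUNDLED)


def small_corpus() -> List[str]:
    """Ten small molecules for desk-scale overfitting runs."""
    return list(_SMALL)


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of the random molecular-graph generator."""

    n_molecules: int = 20
    max_atoms: int = 20
    elements: Tuple[str, ...] = ("C", "C", "C", "N", "O", "S")
    ring_prob: float = 0.3
    benzene_seed_prob: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_molecules < 1 or self.max_atoms < 1:
            raise ValueError("n_molecules and max_atoms must be positive")
        unknown = set(self.elements) - set(_VALENCE)
        if unknown:
            raise ValueError(f"unsupported elements {unknown}")


def _grow_one(spec: FixtureSpec, rng: np.random.Generator):
    """One random draft molecule as (symbols, bonds, aromatic_flags)."""
    symbols: List[str] = []
    bonds: List[Tuple[int, int, int]] = []  # (i, j, order); 0 = aromatic
    free: List[int] = []
    if spec.benzene_seed_prob > 0 and rng.random() < spec.benzene_seed_prob \
            and spec.max_atoms >= 6:
        symbols = ["C"] * 6
        free = [1] * 6
        bonds = [(i, (i + 1) % 6, 0) for i in range(6)]
    else:
        sym = str(rng.choice(spec.elements))
        symbols = [sym]
        free = [_VALENCE[sym]]
    n_target = int(rng.integers(len(symbols), spec.max_atoms + 1))
    while len(symbols) < n_target:
        anchors = [i for i, f in enumerate(free) if f >= 1]
        if not anchors:
            break
        a = int(anchors[rng.integers(len(anchors))])
        sym = str(rng.choice(spec.elements))
        max_order = min(free[a], _VALENCE[sym], 3)
        orders = list(range(1, max_order + 1))
        weights = np.array([0.85, 0.12, 0.03][:len(orders)])
        order = int(rng.choice(orders, p=weights / weights.sum()))
        symbols.append(sym)
        free.append(_VALENCE[sym] - order)
        free[a] -= order
        bonds.append((a, len(symbols) - 1, order))
    if rng.random() < spec.ring_prob and len(symbols) >= 3:
        bonded = {(min(i, j), max(i, j)) for i, j, _ in bonds}
        candidates = [(i, j) for i in range(len(symbols))
                      for j in range(i + 1, len(symbols))
                      if free[i] >= 1 and free[j] >= 1
                      and (i, j) not in bonded]
        if candidates:
            i, j = candidates[rng.integers(len(candidates))]
            bonds.append((i, j, 1))
    return symbols, bonds


_ORDER_TO_BOND = {0: Chem.BondType.AROMATIC, 1: Chem.BondType.SINGLE,
                  2: Chem.BondType.DOUBLE, 3: Chem.BondType.TRIPLE}


def _draft_to_smiles(symbols, bonds):
    rw = Chem.RWMol()
    aromatic = {i for b in bonds if b[2] == 0 for i in b[:2]}
    for i, sym in enumerate(symbols):
        atom = Chem.Atom(sym)
        if i in aromatic:
            atom.SetIsAromatic(True)
        rw.AddAtom(atom)
    for i, j, order in bonds:
        n = rw.AddBond(i, j, _ORDER_TO_BOND[order])
        if order == 0:
            rw.GetBondWithIdx(n - 1).SetIsAromatic(True)
    mol = rw.GetMol()
    Chem.SanitizeMol(mol)
    return Chem.MolToSmiles(mol)


def random_molecules(spec: FixtureSpec) -> List[str]:
    """Seeded list of random, sanitizing small molecules."""
    rng = np.random.default_rng(spec.seed)
    out = []
    for _ in range(spec.n_molecules):
        for _attempt in range(100):
            try:
                out.append(_draft_to_smiles(*_grow_one(spec, rng)))
                break
            except Exception:
                continue
        else:
            raise RuntimeError("random molecule generation kept failing; "
                               "loosen the fixture spec")
    return out


def synthetic_conditional_corpus(spec: FixtureSpec,
                                 rule: Callable[[str], np.ndarray]):
    """Random corpus annotated with ``rule(molecule)`` condition codes.

    Returns ``(smiles, codes, balance)`` where ``balance`` counts how often
    each distinct code occurs -- conditional-training tests need to know
    both classes are populated.
    """
    smiles = random_molecules(spec)
    codes = [np.asarray(rule(s), float) for s in smiles]
    balance: dict = {}
    for c in codes:
        balance[tuple(c)] = balance.get(tuple(c), 0) + 1
    return smiles, codes, balance
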