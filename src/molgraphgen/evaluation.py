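"""Evaluation metrics for molecular generative models.

Covers the quantitative yardsticks used to compare generators:

* **validity / novelty** -- fraction of samples that sanitize, and the
  fraction of valid samples whose canonical SMILES does not occur in the
  training set;
* **property divergences** -- Kullback-Leibler and Jensen-Shannon
  divergences between generated and reference distributions of molecular
  weight, Crippen LogP and QED, estimated with Gaussian kernel densities
  (Scott's-rule bandwidth) and numerical quadrature;
* **conditional control** -- the matrix ``K_cc' = |N_cc'| / |M_c|`` of
  cross-condition satisfaction rates, its diagonal ``R_c`` (rate of
  correctly conditioned outputs) and the enrichment over random
  ``EOR_c = R_c / R_c^0`` relative to the training-set base rate;
* **reproduction rate** -- ``|(M_c1 u M_c2) n T| / |T|``, the fraction of
  known actives a conditional model regenerates;
* **internal diversity** -- ``I(M) = (1/|M|^2) sum_{x,y} T_d(x, y)``, the
  mean Tanimoto distance between circular fingerprints (radius 3, 2048
  bits) over all ordered pairs.  As written the sum includes self-pairs;
  a diagonal-excluded variant is available via ``include_self=False``.
"""

from __future__ import annotations

from typing import Callable, Dict, Iterable, Optional, Sequence, Union

import numpy as np
from rdkit import Chem, DataStructs
from rdkit.Chem import AllChem, Crippen, Descriptors, QED
from scipy.stats import gaussian_kde

from .conditioning import FP_BITS, FP_RADIUS
from .molgraph import MolGraph, smiles_from_graph

__all__ = [
    "validity_novelty", "kde_divergences", "property_divergences",
    "conditional_matrix", "reproduction_rate", "internal_diversity",
    "canonicalize_samples",
]

_GRID_POINTS = 2048
_DENSITY_FLOOR = 1e-12


def canonicalize_samples(samples: Iterable[Union[str, MolGraph]]):
    """Split samples into canonical SMILES of valid molecules and a count
    of invalid ones."""
    valid, n_invalid = [], 0
    for s in samples:
        try:
            if isinstance(s, MolGraph):
                valid.append(smiles_from_graph(s))
            else:
                mol = Chem.MolFromSmiles(s)
                if mol is None:
                    raise ValueError(s)
                valid.append(Chem.MolToSmiles(mol))
        except Exception:
            n_invalid += 1
    return valid, n_invalid


def validity_novelty(samples: Sequence[Union[str, MolGraph]],
                     training_corpus: Sequence[str]):
    """``(valid, novel, valid_and_novel)`` rates of a sample set.

    ``novel`` is the fraction *of valid samples* absent from the training
    set; ``valid_and_novel`` is the joint fraction of all samples.
    """
    if not samples:
        return 0.0, 0.0, 0.0
    valid, _ = canonicalize_samples(samples)
    train, _ = canonicalize_samples(training_corpus)
    train_set = set(train)
    novel = [s for s in valid if s not in train_set]
    n = len(samples)
    valid_rate = len(valid) / n
    novel_rate = len(novel) / len(valid) if valid else 0.0
    return valid_rate, novel_rate, len(novel) / n


def kde_divergences(generated: np.ndarray, reference: np.ndarray):
    """``(D_KL, D_JS)`` between two 1-D samples via Gaussian KDEs.

    Both densities use Scott's-rule bandwidths and are evaluated on a
    common 2048-point grid spanning the pooled data plus three bandwidths
    of margin; densities are floored at 1e-12 before the logarithms.
    """
    x = np.asarray(generated, float)
    y = np.asarray(reference, float)
    if x.size < 2 or y.size < 2:
        raise ValueError("need at least two observations per sample")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("degenerate (zero-variance) sample")
    kx, ky = gaussian_kde(x), gaussian_kde(y)
    h = max(np.sqrt(kx.covariance[0, 0]), np.sqrt(ky.covariance[0, 0]))
    lo = min(x.min(), y.min()) - 3 * h
    hi = max(x.max(), y.max()) + 3 * h
    grid = np.linspace(lo, hi, _GRID_POINTS)
    p = np.maximum(kx(grid), _DENSITY_FLOOR)
    q = np.maximum(ky(grid), _DENSITY_FLOOR)
    m = 0.5 * (p + q)
    kl = float(np.trapezoid(p * np.log(p / q), grid))
    js = float(0.5 * np.trapezoid(p * np.log(p / m), grid)
               + 0.5 * np.trapezoid(q * np.log(q / m), grid))
    return kl, js


_PROPERTIES = {
    "MW": Descriptors.MolWt,
    "LogP": Crippen.MolLogP,
    "QED": QED.qed,
}


def property_divergences(generated: Sequence[Union[str, MolGraph]],
                         reference: Sequence[Union[str, MolGraph]]
                         ) -> Dict[str, Dict[str, float]]:
    """KL/JS divergences of MW, LogP and QED between two molecule sets."""
    gen, _ = canonicalize_samples(generated)
    ref, _ = canonicalize_samples(reference)
    if len(gen) < 2 or len(ref) < 2:
        raise ValueError("need at least two valid molecules per side")
    gmols = [Chem.MolFromSmiles(s) for s in gen]
    rmols = [Chem.MolFromSmiles(s) for s in ref]
    out: Dict[str, Dict[str, float]] = {}
    for name, fn in _PROPERTIES.items():
        kl, js = kde_divergences(np.array([fn(m) for m in gmols]),
                                 np.array([fn(m) for m in rmols]))
        out[name] = {"kl": kl, "js": js}
    return out


def conditional_matrix(sample_sets: Dict, checker: Callable,
                       training_corpus: Optional[Sequence[str]] = None):
    """Cross-condition satisfaction rates.

    ``sample_sets`` maps each condition ``c`` (any hashable) to its sample
    set ``M_c`` of valid molecules (SMILES); ``checker(molecule, c')`` says
    whether a molecule satisfies condition ``c'``.  Returns ``(K, R, EOR)``
    where ``K[c][c'] = |N_cc'| / |M_c|``, ``R[c] = K[c][c]``, and ``EOR[c] =
    R_c / R_c^0`` with the base rate taken from ``training_corpus`` (``None``
    entries when the base rate is zero or no corpus is given).
    """
    conditions = list(sample_sets)
    K: Dict = {}
    for c in conditions:
        M = sample_sets[c]
        if not M:
            raise ValueError(f"empty sample set for condition {c!r}")
        K[c] = {cp: sum(1 for m in M if checker(m, cp)) / len(M)
                for cp in conditions}
    R = {c: K[c][c] for c in conditions}
    EOR: Dict = {c: None for c in conditions}
    if training_corpus is not None:
        n = len(training_corpus)
        for c in conditions:
            r0 = sum(1 for m in training_corpus if checker(m, c)) / n
            EOR[c] = (R[c] / r0) if r0 > 0 else None
    return K, R, EOR


def reproduction_rate(m_c1: Iterable[str], m_c2: Iterable[str],
                      actives: Iterable[str]) -> float:
    """``|(M_c1 u M_c2) n T| / |T|`` on canonical-SMILES sets."""
    t = set(canonicalize_samples(actives)[0])
    if not t:
        raise ValueError("empty active test set")
    produced = set(canonicalize_samples(m_c1)[0]) \
        | set(canonicalize_samples(m_c2)[0])
    return len(produced & t) / len(t)


def internal_diversity(molecules: Sequence[Union[str, MolGraph]],
                       include_self: bool = True) -> float:
    """Mean pairwise Tanimoto distance of circular fingerprints.

    ``include_self=True`` averages over the full ``M x M`` grid of ordered
    pairs (self-distances are zero); the diagonal-excluded convention is
    available as well.  A singleton (or all-identical) set has diversity 0.
    """
    smis, _ = canonicalize_samples(molecules)
    if not smis:
        raise ValueError("no valid molecules")
    fps = [AllChem.GetMorganFingerprintAsBitVect(
        Chem.MolFromSmiles(s), FP_RADIUS, nBits=FP_BITS) for s in smis]
    n = len(fps)
    if n == 1:
        return 0.0
    total = 0.0
    for i in range(n):
        sims = DataStructs.BulkTanimotoSimilarity(fps[i], fps)
        total += sum(1.0 - s for s in sims)
    if include_self:
        return total / (n * n)
    return total / (n * (n - 1))
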