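"""Sequential decoding of molecular graphs.

A molecule is generated as a sequence of graph transitions: *initialization*
places the first atom, *append* adds a new atom together with its bond to an
existing atom, *connect* closes a ring between the latest appended atom
``v*`` and another atom, and *terminate* ends the process.  Because append
and connect each add exactly one edge, every decoding route of a connected
graph ``G = (V, E)`` has exactly ``|E| + 2`` steps.

A single molecule admits many decoding routes.  This module provides

* :func:`apply_transition` -- the transition semantics (structural only;
  chemically invalid actions are *not* rejected, the policy has to learn
  those constraints),
* :func:`canonical_route` -- the deterministic depth-first route under the
  toolkit's canonical atom ranking,
* :func:`sample_route` -- a draw from ``q_alpha(r | G)``, which follows the
  canonical route but at every step with several consistent actions makes a
  "random mistake" with probability ``1 - alpha``, drawn uniformly over the
  non-canonical actions that can still complete to ``G``.  The realized
  log-probability ``log q`` is returned exactly,
* :func:`enumerate_routes` -- exhaustive enumeration of ``R(G)`` for tiny
  molecules (the likelihood oracle).

Routes are sequences of *transitions*, not of atom identities: two
automorphic constructions that perform identical actions are one route.  The
sampler therefore tracks every embedding of the partial graph into the
target molecule that is consistent with the transitions taken so far, and
merges actions that coincide at the transition level.  This is what makes
``q_alpha`` a proper distribution over ``R(G)`` and its log-probabilities
usable as exact importance weights.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterator, List, Optional, Tuple

import numpy as np
from rdkit import Chem

from .molgraph import AtomType, BondType, MolGraph, _sanitized, smiles_from_graph

__all__ = [
    "Transition", "Init", "Append", "Connect", "Terminate", "TransitionError",
    "DecodingRoute", "apply_transition", "canonical_route", "sample_route",
    "enumerate_routes", "route_length", "replay", "route_to_jsonl",
]


class TransitionError(ValueError):
    """Transition is structurally inapplicable to the graph."""


@dataclass(frozen=True)
class Transition:
    pass


@dataclass(frozen=True)
class Init(Transition):
    atom_type: AtomType


@dataclass(frozen=True)
class Append(Transition):
    anchor: int
    atom_type: AtomType
    bond_type: BondType


@dataclass(frozen=True)
class Connect(Transition):
    target: int
    bond_type: BondType


@dataclass(frozen=True)
class Terminate(Transition):
    pass


def _order_key(t: Transition):
    """Deterministic total order on transitions (used for tie-breaking)."""
    if isinstance(t, Init):
        return (0, 0, t.atom_type.as_tuple(), 0)
    if isinstance(t, Append):
        return (1, t.anchor, t.atom_type.as_tuple(), int(t.bond_type))
    if isinstance(t, Connect):
        return (2, t.target, ("",), int(t.bond_type))
    return (3, 0, ("",), 0)


def apply_transition(g: MolGraph, t: Transition) -> MolGraph:
    """Return the successor graph ``t(G)`` (the input is not mutated).

    Only structural applicability is checked; chemical validity is not
    enforced, matching the training-time action space.
    """
    out = g.copy()
    if isinstance(t, Init):
        if out.num_atoms != 0:
            raise TransitionError("init on a non-empty graph")
        out.add_atom(t.atom_type)
    elif isinstance(t, Append):
        if not (0 <= t.anchor < out.num_atoms):
            raise TransitionError(f"append anchor {t.anchor} out of range")
        new = out.add_atom(t.atom_type)
        out.add_bond(t.anchor, new, t.bond_type)
    elif isinstance(t, Connect):
        if out.latest is None:
            raise TransitionError("connect requires a latest atom v*")
        if not (0 <= t.target < out.num_atoms):
            raise TransitionError(f"connect target {t.target} out of range")
        if t.target == out.latest:
            raise TransitionError("connect target equals v*")
        if out.has_bond(out.latest, t.target):
            raise TransitionError("bond v*-target already exists")
        out.add_bond(out.latest, t.target, t.bond_type)
    elif isinstance(t, Terminate):
        pass
    else:  # pragma: no cover
        raise TransitionError(f"unknown transition {t!r}")
    return out


@dataclass
class DecodingRoute:
    """A complete route ``r = ((G_0, t_0), ..., (G_n, t_n))`` with its
    ``q_alpha`` log-probability.

    ``n_choice_steps`` counts steps at which more than one consistent action
    existed and ``n_noncanonical`` how many of those took a non-canonical
    action ("mistakes"); their ratio estimates ``1 - alpha``.
    """

    steps: List[Tuple[MolGraph, Transition]]
    log_q: float = 0.0
    alpha: float = 1.0
    n_choice_steps: int = 0
    n_noncanonical: int = 0

    def __len__(self):
        return len(self.steps)

    @property
    def transitions(self) -> List[Transition]:
        return [t for _, t in self.steps]

    @property
    def molecule(self) -> MolGraph:
        """The generated graph (state at the terminate step)."""
        return self.steps[-1][0]


def replay(transitions) -> DecodingRoute:
    """Rebuild a route (with snapshots) from a transition sequence."""
    g = MolGraph()
    steps = []
    for t in transitions:
        steps.append((g.copy(), t))
        g = apply_transition(g, t)
    if not steps or not isinstance(steps[-1][1], Terminate):
        raise TransitionError("transition sequence does not terminate")
    return DecodingRoute(steps)


def route_length(g: MolGraph) -> int:
    """Number of decoding steps for ``G = (V, E)``: exactly ``|E| + 2``."""
    if not g.is_connected():
        raise TransitionError("disconnected graphs are not decoded")
    return g.num_bonds + 2


# -- the route state machine ------------------------------------------------


class _Decoder:
    """State machine over partial constructions of a fixed target molecule."""

    def __init__(self, g: MolGraph):
        if g.num_atoms == 0:
            raise TransitionError("cannot decode the empty graph")
        if not g.is_connected():
            raise TransitionError("disconnected graphs are not decoded")
        mol = _sanitized(g)  # also guarantees chemical validity
        self.ranks = list(Chem.CanonicalRankAtoms(mol, breakTies=True))
        self.types = list(g.atoms)
        self.n = g.num_atoms
        self.nbrs = {i: [] for i in range(self.n)}
        self.bond = {}
        for a, b, t in g.bonds:
            self.nbrs[a].append((b, t))
            self.nbrs[b].append((a, t))
            self.bond[(a, b)] = t
            self.bond[(b, a)] = t

    # -- per-state options -------------------------------------------------
    def _emb_options(self, m: tuple, built_pairs: set):
        """Valid (transition, successor-embedding) pairs for embedding ``m``.

        ``built_pairs`` holds the built-node index pairs of edges added so
        far; under ``m`` these map onto target edges.  Returns ``None`` for a
        dead embedding (a missing edge no longer reachable from ``v*``).
        """
        image = set(m)
        pos = {t: i for i, t in enumerate(m)}
        vstar_t = m[-1]
        built_images = {frozenset((m[i], m[j])) for i, j in built_pairs}
        missing = []
        for u in image:
            for w, bt in self.nbrs[u]:
                if w in image and u < w and frozenset((u, w)) not in built_images:
                    missing.append((u, w, bt))
        if missing:
            opts = []
            for u, w, bt in missing:
                if vstar_t not in (u, w):
                    return None
                other = w if u == vstar_t else u
                opts.append((Connect(pos[other], bt), m))
            canon = min(opts, key=lambda o: self.ranks[m[o[0].target]])[0]
            return opts, canon
        if len(m) < self.n:
            opts = []
            canon = None
            for ui in range(len(m) - 1, -1, -1):
                ut = m[ui]
                absent = [(w, bt) for w, bt in self.nbrs[ut] if w not in image]
                for w, bt in absent:
                    opts.append((Append(ui, self.types[w], bt), m + (w,)))
                if absent and canon is None:
                    # depth-first: deepest (most recently appended) atom with
                    # an unplaced neighbor; lowest-rank neighbor first
                    w, bt = min(absent, key=lambda x: self.ranks[x[0]])
                    canon = Append(ui, self.types[w], bt)
            return opts, canon
        return [(Terminate(), m)], Terminate()

    def step_options(self, embs: Optional[list], built_pairs: set):
        """Distinct transitions available from a state.

        Returns ``(available, canonical, successors)`` where ``successors``
        maps each transition to the deduplicated list of surviving
        embeddings.  The canonical transition is the per-embedding canonical
        action of the lexicographically rank-minimal embedding, which along
        the mistake-free path coincides with depth-first decoding from the
        canonical root atom.
        """
        succ: dict = {}
        if embs is None:  # initialization
            root = min(range(self.n), key=lambda i: self.ranks[i])
            canonical = Init(self.types[root])
            for a in range(self.n):
                succ.setdefault(Init(self.types[a]), []).append((a,))
        else:
            canonical = None
            for m in sorted(embs, key=lambda m: tuple(self.ranks[t] for t in m)):
                res = self._emb_options(m, built_pairs)
                if res is None:
                    continue
                opts, emb_canon = res
                if canonical is None:
                    canonical = emb_canon
                for t, m2 in opts:
                    succ.setdefault(t, []).append(m2)
        available = sorted(succ, key=_order_key)
        successors = {t: sorted(set(ms)) for t, ms in succ.items()}
        return available, canonical, successors


def _generate_route(g: MolGraph, alpha: float,
                    rng: Optional[np.random.Generator]) -> DecodingRoute:
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    dec = _Decoder(g)
    built = MolGraph()
    built_pairs: set = set()
    embs: Optional[list] = None
    steps = []
    log_q = 0.0
    n_choice = 0
    n_mistake = 0
    while True:
        available, canonical, successors = dec.step_options(embs, built_pairs)
        alts = [t for t in available if t != canonical]
        if alts:
            n_choice += 1
            if rng is None or rng.random() < alpha:
                t = canonical
                log_q += math.log(alpha) if alpha > 0 else -math.inf
            else:
                t = alts[rng.integers(len(alts))]
                log_q += math.log((1.0 - alpha) / len(alts))
                n_mistake += 1
        else:
            t = canonical
        steps.append((built.copy(), t))
        if isinstance(t, Terminate):
            break
        prev_atoms = built.num_atoms
        built = apply_transition(built, t)
        if built.num_bonds > len(built_pairs):
            a, b, _ = built.bonds[-1]
            built_pairs = built_pairs | {(a, b)}
        embs = successors[t]
        assert embs, "chosen transition must keep at least one embedding"
        del prev_atoms
    return DecodingRoute(steps, log_q=log_q, alpha=alpha,
                         n_choice_steps=n_choice, n_noncanonical=n_mistake)


def canonical_route(g: MolGraph) -> DecodingRoute:
    """Deterministic depth-first decoding route under canonical ordering.

    Ring-closing connects are emitted as soon as both endpoints exist and one
    of them is ``v*``, in ascending canonical-rank order of the target atom.
    ``log_q`` is 0: this is the single route of ``q_alpha`` at ``alpha = 1``.
    """
    return _generate_route(g, 1.0, None)


def sample_route(g: MolGraph, alpha: float,
                 rng: np.random.Generator) -> DecodingRoute:
    """Draw a route from ``q_alpha(r | G)`` with its exact log-probability."""
    return _generate_route(g, alpha, rng)


def enumerate_routes(g: MolGraph, max_atoms: int = 5) -> Iterator[DecodingRoute]:
    """Yield every decoding route of ``g`` (tiny molecules only).

    The number of routes grows combinatorially, so enumeration is capped at
    ``max_atoms`` heavy atoms.
    """
    if g.num_atoms > max_atoms:
        raise TransitionError(
            f"enumeration capped at {max_atoms} atoms, got {g.num_atoms}")
    dec = _Decoder(g)

    def rec(embs, built, built_pairs, prefix):
        available, _, successors = dec.step_options(embs, built_pairs)
        for t in available:
            step = (built.copy(), t)
            if isinstance(t, Terminate):
                yield DecodingRoute(prefix + [step])
                continue
            nxt = apply_transition(built, t)
            pairs = built_pairs
            if nxt.num_bonds > len(built_pairs):
                a, b, _ = nxt.bonds[-1]
                pairs = built_pairs | {(a, b)}
            yield from rec(successors[t], nxt, pairs, prefix + [step])

    yield from rec(None, MolGraph(), set(), [])


def route_q_logp(route: DecodingRoute, g: MolGraph, alpha: float) -> float:
    """Exact ``log q_alpha(r | G)`` of an arbitrary route of ``g``.

    Used by the enumeration oracle; the sampler already reports this for its
    own draws.
    """
    dec = _Decoder(g)
    embs: Optional[list] = None
    built_pairs: set = set()
    built = MolGraph()
    logq = 0.0
    for _, t in route.steps:
        available, canonical, successors = dec.step_options(embs, built_pairs)
        if t not in successors:
            return -math.inf
        alts = len(available) - 1
        if alts:
            if t == canonical:
                logq += math.log(alpha) if alpha > 0 else -math.inf
            else:
                logq += math.log((1.0 - alpha) / alts) if alpha < 1 else -math.inf
        if isinstance(t, Terminate):
            break
        built = apply_transition(built, t)
        if built.num_bonds > len(built_pairs):
            a, b, _ = built.bonds[-1]
            built_pairs = built_pairs | {(a, b)}
        embs = successors[t]
    return logq


def route_to_jsonl(route: DecodingRoute) -> str:
    """Debug dump: one JSON object per step with the cumulative SMILES."""
    lines = []
    g = MolGraph()
    for i, (_, t) in enumerate(route.steps):
        g = apply_transition(g, t)
        try:
            smi = smiles_from_graph(g) if g.num_atoms else ""
        except Exception:
            smi = ""
        if isinstance(t, Init):
            rec = {"action_tag": "init",
                   "params": {"atom_type": list(t.atom_type.as_tuple())}}
        elif isinstance(t, Append):
            rec = {"action_tag": "append",
                   "params": {"anchor": t.anchor,
                              "atom_type": list(t.atom_type.as_tuple()),
                              "bond_type": int(t.bond_type)}}
        elif isinstance(t, Connect):
            rec = {"action_tag": "connect",
                   "params": {"target": t.target,
                              "bond_type": int(t.bond_type)}}
        else:
            rec = {"action_tag": "terminate", "params": {}}
        rec["step"] = i
        rec["cumulative_smiles"] = smi
        lines.append(json.dumps(rec))
    return "\n".join(lines)
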