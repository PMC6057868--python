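"""Neural decoding policies: MolMP and MolRNN.

Both policies map a partial molecular graph (plus, optionally, a conditional
code ``c``) to a jointly normalized distribution over the next transition:

* ``p_v^A`` -- an ``|A| x |B|`` matrix per atom ``v``: append a new atom of
  type ``a`` to ``v`` with a bond of type ``b``;
* ``p_v^C`` -- a length-``|B|`` vector per atom: connect ``v*`` to ``v``;
* ``p*`` -- terminate.

The shared trunk embeds each atom from (atom type, is-``v*`` flag), runs a
stack of edge-conditioned graph convolutions

    h_v = W h_v + sum_b Theta_b sum_{u in N_b(v)} h_u
              + sum_{1<d<=D} Phi_d sum_{u at distance d} h_u  (+ Psi c),

concatenates all layer outputs (dense skip connection), and finishes with a
fully connected stack to per-atom representations ``h_v``; the molecule
representation ``h_G`` is their average.  Convolution layers after the first
use the pre-activation BN-ReLU-Conv order.  MolMP is Markov: the action
heads see ``(h_v, h_G)`` only.  MolRNN threads a molecule-level GRU stack
``h_RNN' = GRU(h_RNN, h_{v*}, h_G)`` and feeds its state to the heads in
place of ``h_G``, making the policy history-dependent.

Action heads use an exponential output activation; normalization divides by
the total unnormalized mass ``P``.  Internally everything stays in
log-space (logits are the pre-exponential outputs) and probabilities are
materialized through max-shifted softmaxes.

Scoring is batched: all graph states of all decoding routes in a mini-batch
are stacked block-diagonally and pushed through the trunk in one pass, so
batch-normalization statistics are computed over the atoms of the whole
mini-batch -- the same statistics the running averages converge to, keeping
training-time and sampling-time behavior consistent.

The empty graph has no atoms for the trunk to see, so the very first
(initialization) step is scored by a separate learned categorical over atom
types, linearly shifted by the conditional code when one is present.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from . import nn
from .decoding import Append, Connect, DecodingRoute, Init, Terminate
from .molgraph import AtomVocabulary, BondType, MolGraph

__all__ = [
    "PolicyConfig", "PolicyOutput", "RnnState", "GraphConv",
    "MolMP", "MolRNN", "N_BOND_TYPES",
]

N_BOND_TYPES = len(BondType)


@dataclass(frozen=True)
class PolicyConfig:
    """Architecture hyperparameters.

    Defaults follow the reference architecture: 16-dim atom embeddings, six
    convolution layers of widths 32-256, receptive field D = 3, a 256/512
    fully connected stack, a 128-wide action head and a three-layer GRU of
    width 512.  ``desk()`` returns a scaled-down configuration for CPU-scale
    experiments and tests.
    """

    embedding_dim: int = 16
    conv_widths: Tuple[int, ...] = (32, 64, 128, 128, 256, 256)
    receptive_field: int = 3
    mlp_widths: Tuple[int, ...] = (256, 512)
    head_hidden: int = 128
    rnn_width: int = 512
    rnn_layers: int = 3
    code_dim: Optional[int] = None

    @classmethod
    def desk(cls, code_dim: Optional[int] = None, rnn_width: int = 64,
             conv_widths: Tuple[int, ...] = (16, 32)) -> "PolicyConfig":
        return cls(embedding_dim=8, conv_widths=conv_widths,
                   receptive_field=3, mlp_widths=(32, 48), head_hidden=32,
                   rnn_width=rnn_width, rnn_layers=1, code_dim=code_dim)

    def to_dict(self) -> dict:
        return {
            "embedding_dim": self.embedding_dim,
            "conv_widths": list(self.conv_widths),
            "receptive_field": self.receptive_field,
            "mlp_widths": list(self.mlp_widths),
            "head_hidden": self.head_hidden,
            "rnn_width": self.rnn_width,
            "rnn_layers": self.rnn_layers,
            "code_dim": self.code_dim,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PolicyConfig":
        d = dict(d)
        d["conv_widths"] = tuple(d["conv_widths"])
        d["mlp_widths"] = tuple(d["mlp_widths"])
        return cls(**d)


@dataclass
class PolicyOutput:
    """Jointly normalized transition probabilities for one graph state."""

    p_append: np.ndarray      # (|V|, |A|, |B|)
    p_connect: np.ndarray     # (|V|, |B|)
    p_terminate: float
    raw_append: np.ndarray    # unnormalized exp-activations
    raw_connect: np.ndarray
    raw_terminate: float
    normalizer: float         # P

    def total(self) -> float:
        return float(self.p_append.sum() + self.p_connect.sum()
                     + self.p_terminate)


@dataclass
class RnnState:
    """Hidden states of the molecule-level GRU stack (zeros at start)."""

    hidden: List[nn.Tensor]

    @classmethod
    def zeros(cls, config: PolicyConfig) -> "RnnState":
        return cls([nn.Tensor(np.zeros((1, config.rnn_width)))
                    for _ in range(config.rnn_layers)])


class GraphConv:
    """One edge-conditioned graph convolution layer (no bias; BN supplies
    the shift in the pre-activation stack)."""

    def __init__(self, n_in: int, n_out: int, receptive_field: int,
                 code_dim: Optional[int], rng: np.random.Generator):
        self.W = nn.Parameter(nn.glorot(rng, (n_in, n_out)))
        self.theta = [nn.Parameter(nn.glorot(rng, (n_in, n_out)))
                      for _ in range(N_BOND_TYPES)]
        self.phi = [nn.Parameter(nn.glorot(rng, (n_in, n_out)))
                    for _ in range(2, receptive_field + 1)]
        self.psi = (nn.Parameter(nn.glorot(rng, (code_dim, n_out)))
                    if code_dim else None)
        self.receptive_field = receptive_field

    def __call__(self, h: nn.Tensor, adj_b: Sequence[np.ndarray],
                 adj_d: Sequence[np.ndarray],
                 code_atoms: Optional[np.ndarray]) -> nn.Tensor:
        out = h @ self.W
        for A, theta in zip(adj_b, self.theta):
            out = out + nn.matmul(nn.Tensor(A), h) @ theta
        for A, phi in zip(adj_d, self.phi):
            out = out + nn.matmul(nn.Tensor(A), h) @ phi
        if self.psi is not None:
            if code_atoms is None:
                raise ValueError("conditional layer called without a code")
            out = out + nn.matmul(nn.Tensor(code_atoms), self.psi)
        return out

    def apply_to_graph(self, h_in: np.ndarray, g: MolGraph,
                       code: Optional[np.ndarray] = None) -> np.ndarray:
        """Convenience single-graph evaluation (no gradient tracking)."""
        adj_b, adj_d = _adjacency(g, self.receptive_field)
        mat = None if code is None else np.tile(
            np.asarray(code, float), (g.num_atoms, 1))
        return self(nn.Tensor(h_in), adj_b, adj_d, mat).data


# -- batch assembly ---------------------------------------------------------


def _bfs_distances(n: int, adj: List[List[int]], source: int) -> np.ndarray:
    dist = np.full(n, -1, dtype=int)
    dist[source] = 0
    frontier = [source]
    d = 0
    while frontier:
        d += 1
        nxt = []
        for v in frontier:
            for u in adj[v]:
                if dist[u] < 0:
                    dist[u] = d
                    nxt.append(u)
        frontier = nxt
    return dist


def _adjacency(g: MolGraph, receptive_field: int):
    """Per-bond-type and per-distance adjacency matrices of one graph."""
    n = g.num_atoms
    adj_b = [np.zeros((n, n)) for _ in range(N_BOND_TYPES)]
    nbr = [[] for _ in range(n)]
    for a, b, t in g.bonds:
        adj_b[int(t)][a, b] = adj_b[int(t)][b, a] = 1.0
        nbr[a].append(b)
        nbr[b].append(a)
    adj_d = [np.zeros((n, n)) for _ in range(2, receptive_field + 1)]
    if receptive_field >= 2 and n > 1:
        for v in range(n):
            dist = _bfs_distances(n, nbr, v)
            for d in range(2, receptive_field + 1):
                adj_d[d - 2][v, dist == d] = 1.0
    return adj_b, adj_d


class _GraphBatch:
    """Block-diagonal stack of several graph states."""

    def __init__(self, graphs: Sequence[MolGraph], vocab: AtomVocabulary,
                 receptive_field: int):
        self.graphs = list(graphs)
        self.offsets = np.cumsum([0] + [g.num_atoms for g in graphs])[:-1]
        n_total = sum(g.num_atoms for g in graphs)
        n_steps = len(graphs)
        self.n_total, self.n_steps = n_total, n_steps
        self.type_idx = np.zeros(n_total, dtype=int)
        self.latest_flag = np.zeros(n_total)
        self.latest_rows = np.zeros(n_steps, dtype=int)
        self.Sseg = np.zeros((n_steps, n_total))
        self.adj_b = [np.zeros((n_total, n_total))
                      for _ in range(N_BOND_TYPES)]
        self.adj_d = [np.zeros((n_total, n_total))
                      for _ in range(2, receptive_field + 1)]
        for k, (g, off) in enumerate(zip(graphs, self.offsets)):
            n = g.num_atoms
            if n == 0:
                raise ValueError("empty graph in policy batch")
            for i, at in enumerate(g.atoms):
                self.type_idx[off + i] = vocab.index(at)
            if g.latest is not None:
                self.latest_flag[off + g.latest] = 1.0
                self.latest_rows[k] = off + g.latest
            else:
                self.latest_rows[k] = off
            self.Sseg[k, off:off + n] = 1.0
            ab, ad = _adjacency(g, receptive_field)
            for t in range(N_BOND_TYPES):
                self.adj_b[t][off:off + n, off:off + n] = ab[t]
            for d in range(len(self.adj_d)):
                self.adj_d[d][off:off + n, off:off + n] = ad[d]
        counts = self.Sseg.sum(axis=1, keepdims=True)
        self.Snorm = self.Sseg / counts
        self.Sexpand = self.Sseg.T


# -- policies ---------------------------------------------------------------


class _PolicyBase:
    """Trunk + heads shared by MolMP and MolRNN."""

    def __init__(self, vocab: AtomVocabulary, config: PolicyConfig,
                 rng: np.random.Generator):
        self.vocab = vocab
        self.config = config
        A = len(vocab)
        cd = config.code_dim
        self.type_table = nn.Parameter(
            nn.glorot(rng, (A, config.embedding_dim)))
        self.latest_vec = nn.Parameter(
            rng.normal(0.0, 0.1, (1, config.embedding_dim)))
        widths = [config.embedding_dim, *config.conv_widths]
        self.convs = [GraphConv(widths[i], widths[i + 1],
                                config.receptive_field, cd, rng)
                      for i in range(len(config.conv_widths))]
        # pre-activation BN for conv layers 2..L
        self.conv_bns = [nn.BatchNorm(w) for w in config.conv_widths[:-1]]
        skip = sum(config.conv_widths)
        self.skip_bn = nn.BatchNorm(skip)
        dims = [skip, *config.mlp_widths]
        self.fc = [nn.Linear(dims[i], dims[i + 1], rng)
                   for i in range(len(config.mlp_widths))]
        self.fc_bns = [nn.BatchNorm(w) for w in config.mlp_widths]
        head_in = config.mlp_widths[-1] + self._context_dim()
        n_actions = A * N_BOND_TYPES + N_BOND_TYPES
        self.head1 = nn.Linear(head_in, config.head_hidden, rng)
        self.head2 = nn.Linear(config.head_hidden, n_actions, rng)
        self.head_star = nn.Linear(self._context_dim(), 1, rng)
        self.init_logits = nn.Parameter(np.zeros(A))
        self.init_code = (nn.Parameter(nn.glorot(rng, (cd, A)))
                          if cd else None)

    # subclasses ----------------------------------------------------------
    def _context_dim(self) -> int:
        raise NotImplementedError

    def _contexts(self, H: nn.Tensor, hG: nn.Tensor, batch: _GraphBatch,
                  state: Optional[RnnState], resets: frozenset):
        """Per-step head context (and the final recurrent state, if any).

        ``resets`` holds step indices at which a fresh route begins (the
        recurrent state, if any, restarts from zeros there).
        """
        raise NotImplementedError

    # shared forward pieces ------------------------------------------------
    def embed_atoms(self, g: MolGraph) -> np.ndarray:
        """Initial per-atom embeddings ``h^0_v`` (no gradient tracking)."""
        batch = _GraphBatch([g], self.vocab, self.config.receptive_field)
        return self._embed(batch).data

    def _embed(self, batch: _GraphBatch) -> nn.Tensor:
        emb = nn.embedding(self.type_table, batch.type_idx)
        return emb + nn.mul(nn.Tensor(batch.latest_flag[:, None]),
                            self.latest_vec)

    def _atom_repr(self, batch: _GraphBatch,
                   code_atoms: Optional[np.ndarray], training: bool):
        h = self._embed(batch)
        hs = []
        for i, conv in enumerate(self.convs):
            x = h if i == 0 else nn.relu(self.conv_bns[i - 1](h, training))
            h = conv(x, batch.adj_b, batch.adj_d, code_atoms)
            hs.append(h)
        x = nn.relu(self.skip_bn(nn.concat(hs, axis=1), training))
        for lin, bn in zip(self.fc, self.fc_bns):
            x = nn.relu(bn(lin(x), training))
        return x

    def _forward_batch(self, batch: _GraphBatch,
                       code_atoms: Optional[np.ndarray],
                       state: Optional[RnnState], resets: frozenset,
                       training: bool):
        if self.config.code_dim is not None and code_atoms is None:
            raise ValueError("conditional policy requires a code")
        H = self._atom_repr(batch, code_atoms, training)
        hG = nn.matmul(nn.Tensor(batch.Snorm), H)
        ctx, new_state = self._contexts(H, hG, batch, state, resets)
        ctx_atoms = nn.matmul(nn.Tensor(batch.Sexpand), ctx)
        head_in = nn.concat([H, ctx_atoms], axis=1)
        atom_logits = self.head2(nn.relu(self.head1(head_in)))
        term_logit = self.head_star(ctx)
        return atom_logits, term_logit, new_state

    # -- initialization head ----------------------------------------------
    def init_log_probs(self, code: Optional[np.ndarray] = None) -> nn.Tensor:
        """Log-probabilities of the initialization step (length ``|A|``)."""
        logits = self.init_logits
        if self.init_code is not None:
            if code is None:
                raise ValueError("conditional policy requires a code")
            row = nn.matmul(nn.Tensor(np.asarray(code, float).reshape(1, -1)),
                            self.init_code)
            logits = logits + nn.reshape(row, (-1,))
        return nn.log_softmax(logits)

    def _init_terms(self, type_idx: np.ndarray,
                    codes: Optional[np.ndarray]) -> nn.Tensor:
        """Per-route init log-probabilities, batched (length n_routes)."""
        R = len(type_idx)
        A = len(self.vocab)
        logits = nn.reshape(self.init_logits, (1, A)) + np.zeros((R, 1))
        if self.init_code is not None:
            logits = logits + nn.matmul(nn.Tensor(codes), self.init_code)
        m = logits.data.max(axis=1, keepdims=True)
        lse = nn.log(nn.exp(logits - m).sum(axis=1, keepdims=True)) + m
        picked = nn.take(logits, np.arange(R) * A + type_idx)
        return picked - nn.reshape(lse, (-1,))

    # -- public API --------------------------------------------------------
    def score_routes(self, routes: Sequence[DecodingRoute],
                     codes: Optional[Sequence[np.ndarray]] = None,
                     training: bool = False) -> nn.Tensor:
        """Differentiable ``log p_theta(G, r)`` for each route (vector).

        All graph states of all routes are scored in a single batched
        forward pass; batch-norm statistics therefore span the whole batch.
        """
        A = len(self.vocab)
        graphs: List[MolGraph] = []
        transitions = []
        step_route = []          # route id of every non-init step
        resets = []
        init_types = []
        for ri, route in enumerate(routes):
            if not isinstance(route.steps[0][1], Init):
                raise ValueError("route does not start with an init step")
            init_types.append(self.vocab.index(route.steps[0][1].atom_type))
            resets.append(len(graphs))
            for g, t in route.steps[1:]:
                graphs.append(g)
                transitions.append(t)
                step_route.append(ri)
        batch = _GraphBatch(graphs, self.vocab, self.config.receptive_field)
        code_atoms = None
        code_mat = None
        if codes is not None:
            code_mat = np.stack([np.asarray(c, float) for c in codes])
            step_codes = code_mat[np.asarray(step_route)]
            counts = batch.Sseg.sum(axis=1).astype(int)
            code_atoms = np.repeat(step_codes, counts, axis=0)
        atom_logits, term_logit, _ = self._forward_batch(
            batch, code_atoms, RnnState.zeros(self.config),
            frozenset(resets), training)
        n_cols = atom_logits.data.shape[1]
        # per-step log-normalizer, max-shifted
        M = float(max(atom_logits.data.max(), term_logit.data.max()))
        row_mass = nn.exp(atom_logits - M).sum(axis=1, keepdims=True)
        seg_mass = nn.matmul(nn.Tensor(batch.Sseg), row_mass)
        logZ = nn.log(seg_mass + nn.exp(term_logit - M)) + M  # (S, 1)
        # realized-transition logits
        flat_idx, pick_route = [], []
        term_steps, term_route = [], []
        for k, t in enumerate(transitions):
            off = batch.offsets[k]
            if isinstance(t, Append):
                col = self.vocab.index(t.atom_type) * N_BOND_TYPES \
                    + int(t.bond_type)
                flat_idx.append((off + t.anchor) * n_cols + col)
                pick_route.append(step_route[k])
            elif isinstance(t, Connect):
                col = A * N_BOND_TYPES + int(t.bond_type)
                flat_idx.append((off + t.target) * n_cols + col)
                pick_route.append(step_route[k])
            elif isinstance(t, Terminate):
                term_steps.append(k)
                term_route.append(step_route[k])
            else:
                raise ValueError(f"unexpected transition {t!r}")
        R = len(routes)
        total = self._init_terms(np.asarray(init_types), code_mat)
        if flat_idx:
            Mpick = np.zeros((R, len(flat_idx)))
            Mpick[pick_route, np.arange(len(flat_idx))] = 1.0
            picked = nn.take(atom_logits, flat_idx)
            total = total + nn.reshape(
                nn.matmul(nn.Tensor(Mpick), nn.reshape(picked, (-1, 1))),
                (-1,))
        if term_steps:
            Mterm = np.zeros((R, len(term_steps)))
            Mterm[term_route, np.arange(len(term_steps))] = 1.0
            tpick = nn.take(term_logit, np.asarray(term_steps))
            total = total + nn.reshape(
                nn.matmul(nn.Tensor(Mterm), nn.reshape(tpick, (-1, 1))),
                (-1,))
        Mz = np.zeros((R, batch.n_steps))
        Mz[step_route, np.arange(batch.n_steps)] = 1.0
        total = total - nn.reshape(nn.matmul(nn.Tensor(Mz), logZ), (-1,))
        return total

    def score_route(self, route: DecodingRoute,
                    code: Optional[np.ndarray] = None,
                    training: bool = False) -> nn.Tensor:
        """``log p_theta(G, r)`` of a single route (scalar tensor)."""
        codes = None if code is None else [code]
        return self.score_routes([route], codes, training=training).sum()

    def forward(self, g: MolGraph, code: Optional[np.ndarray] = None,
                state: Optional[RnnState] = None):
        """Normalized :class:`PolicyOutput` for one graph state.

        For MolRNN also returns the updated recurrent state; evaluation mode
        (running batch-norm statistics) is used throughout.
        """
        batch = _GraphBatch([g], self.vocab, self.config.receptive_field)
        code_atoms = None if code is None else np.tile(
            np.asarray(code, float), (g.num_atoms, 1))
        atom_logits, term_logit, new_state = self._forward_batch(
            batch, code_atoms, state, frozenset(), training=False)
        A = len(self.vocab)
        al = atom_logits.data
        tl = float(term_logit.data[0, 0])
        M = max(al.max(), tl)
        ea, et = np.exp(al - M), np.exp(tl - M)
        P = ea.sum() + et
        app = (ea[:, :A * N_BOND_TYPES] / P).reshape(
            g.num_atoms, A, N_BOND_TYPES)
        con = ea[:, A * N_BOND_TYPES:] / P
        out = PolicyOutput(
            p_append=app, p_connect=con, p_terminate=float(et / P),
            raw_append=np.exp(al[:, :A * N_BOND_TYPES]).reshape(
                g.num_atoms, A, N_BOND_TYPES),
            raw_connect=np.exp(al[:, A * N_BOND_TYPES:]),
            raw_terminate=float(np.exp(tl)),
            normalizer=float(np.exp(M) * P))
        if isinstance(self, MolRNN):
            return out, new_state
        return out

    def init_distribution(self, code: Optional[np.ndarray] = None
                          ) -> np.ndarray:
        return np.exp(self.init_log_probs(code).data)

    # -- parameters --------------------------------------------------------
    @property
    def bn_layers(self):
        return [*self.conv_bns, self.skip_bn, *self.fc_bns]

    @property
    def params(self) -> List[nn.Tensor]:
        out = [self.type_table, self.latest_vec]
        for conv in self.convs:
            out += [conv.W] + conv.theta + conv.phi
            if conv.psi is not None:
                out.append(conv.psi)
        for bn in self.bn_layers:
            out += bn.params
        for lin in self.fc:
            out += lin.params
        out += self.head1.params + self.head2.params + self.head_star.params
        out.append(self.init_logits)
        if self.init_code is not None:
            out.append(self.init_code)
        return out


class MolMP(_PolicyBase):
    """Markov decoding policy: ``p(t | G_i, ..., G_0) = p(t | G_i)``."""

    def _context_dim(self) -> int:
        return self.config.mlp_widths[-1]

    def _contexts(self, H, hG, batch, state, resets):
        return hG, None


class MolRNN(_PolicyBase):
    """History-dependent policy with a molecule-level GRU stack.

    The heads receive the updated recurrent state
    ``h' = GRU(h, h_{v*}, h_G)`` in place of ``h_G``.
    """

    def __init__(self, vocab, config, rng):
        super().__init__(vocab, config, rng)
        in_dim = 2 * config.mlp_widths[-1]
        self.gru = [nn.GRUCell(in_dim if i == 0 else config.rnn_width,
                               config.rnn_width, rng)
                    for i in range(config.rnn_layers)]

    def _context_dim(self) -> int:
        return self.config.rnn_width

    def _contexts(self, H, hG, batch, state, resets):
        if state is None:
            state = RnnState.zeros(self.config)
        hidden = list(state.hidden)
        rows = []
        for k in range(batch.n_steps):
            if k in resets:
                hidden = list(RnnState.zeros(self.config).hidden)
            r = int(batch.latest_rows[k])
            x = nn.concat([H[r:r + 1], hG[k:k + 1]], axis=1)
            inp = x
            for layer, cell in enumerate(self.gru):
                hidden[layer] = cell(inp, hidden[layer])
                inp = hidden[layer]
            rows.append(hidden[-1])
        ctx = rows[0] if len(rows) == 1 else nn.concat(rows, axis=0)
        return ctx, RnnState(hidden)

    @property
    def params(self):
        out = super().params
        for cell in self.gru:
            out += cell.params
        return out
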