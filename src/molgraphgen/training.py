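"""Optimization loop, fine-tuning, sampling loop and checkpoints.

Training minimizes the mean importance-weighted negative log-likelihood
over mini-batches with Adam (beta1 = 0.9, beta2 = 0.999, eps = 1e-8),
starting from a learning rate of 0.001 with a decay rate of 0.001 applied
every 100 iterations; the default run lasts 5 epochs with mini-batches of
200 molecules.  Fine-tuning on a focused subset continues from a checkpoint
with a learning rate of 0.0001 and a decay rate of 0.002 per 100 iterations
for 10 epochs.

"Decay rate d every 100 iterations" is read as inverse-time decay,
``lr_t = lr_0 / (1 + d * floor(t / 100))``; an exponential alternative
``lr_t = lr_0 * (1 - d) ** floor(t / 100)`` is available via
``TrainConfig.schedule``.

Generation runs the decoding loop forward: the first atom is drawn from the
initialization head, every later transition from the policy's normalized
output, until the terminate action fires or a step cap is hit.  Connect
actions whose target is ``v*`` itself or already bonded to ``v*`` are
structurally impossible and are masked out at sampling time (they are left
unmasked during training, where the model is expected to learn chemistry's
constraints on its own).
"""

from __future__ import annotations

import io
import json
import math
from dataclasses import dataclass, field
from typing import Callable, List, Optional, Sequence, Tuple, Union

import numpy as np

from . import nn
from .decoding import (Append, Connect, Init, Terminate, apply_transition)
from .likelihood import LossConfig, iw_nll
from .molgraph import (AtomVocabulary, BondType, MolGraph, graph_from_smiles,
                       is_valid)
from .policy import (MolMP, MolRNN, N_BOND_TYPES, PolicyConfig, RnnState)

__all__ = ["TrainConfig", "FineTuneConfig", "GenerationConfig", "train",
           "fine_tune", "generate", "save_checkpoint", "load_checkpoint"]


@dataclass
class FineTuneConfig:
    lr: float = 0.0001
    lr_decay: float = 0.002
    epochs: int = 10


@dataclass
class TrainConfig:
    lr: float = 0.001
    lr_decay: float = 0.001
    decay_interval: int = 100
    epochs: int = 5
    batch_size: int = 200
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    schedule: str = "inverse_time"  # or "exponential"
    seed: int = 0
    max_iterations: Optional[int] = None
    fine_tune: FineTuneConfig = field(default_factory=FineTuneConfig)

    def __post_init__(self):
        if min(self.lr, self.batch_size, self.decay_interval) <= 0:
            raise ValueError("hyperparameters must be positive")
        if self.schedule not in ("inverse_time", "exponential"):
            raise ValueError(f"unknown schedule {self.schedule!r}")


@dataclass
class GenerationConfig:
    max_steps: int = 100
    n_samples: int = 100
    temperature: float = 1.0

    def __post_init__(self):
        if self.max_steps < 2:
            raise ValueError("max_steps must allow init + terminate")


def _lr_at(cfg: TrainConfig, lr0: float, decay: float, t: int) -> float:
    k = t // cfg.decay_interval
    if cfg.schedule == "inverse_time":
        return lr0 / (1.0 + decay * k)
    return lr0 * (1.0 - decay) ** k


def _encode_corpus(corpus: Sequence[Union[str, MolGraph]]) -> List[MolGraph]:
    out = []
    for item in corpus:
        out.append(graph_from_smiles(item) if isinstance(item, str)
                   else item)
    return out


def train(corpus: Sequence[Union[str, MolGraph]], policy,
          loss_cfg: LossConfig, train_cfg: TrainConfig,
          codes: Optional[Sequence[np.ndarray]] = None,
          callback: Optional[Callable[[int, float], None]] = None
          ) -> List[float]:
    """Fit the policy on a corpus; returns the per-iteration loss trace.

    ``codes`` optionally pairs each molecule with its conditional code.
    Deterministic for a fixed seed when ``alpha = 1``.  A non-finite loss
    aborts with diagnostics rather than silently diverging.
    """
    graphs = _encode_corpus(corpus)
    if codes is not None and len(codes) != len(graphs):
        raise ValueError("codes must align with the corpus")
    if not graphs:
        raise ValueError("empty corpus")
    rng = np.random.default_rng(train_cfg.seed)
    opt = nn.Adam(policy.params, lr=train_cfg.lr, beta1=train_cfg.beta1,
                  beta2=train_cfg.beta2, eps=train_cfg.eps)
    return _optimize(graphs, codes, policy, loss_cfg, train_cfg, opt, rng,
                     train_cfg.lr, train_cfg.lr_decay, train_cfg.epochs,
                     callback)


def _batch_loss(idx, graphs, codes, policy, loss_cfg, rng) -> nn.Tensor:
    """Mean importance-weighted NLL of one mini-batch, single forward pass.

    All k routes of all molecules are scored together so batch-norm
    statistics span the whole mini-batch.
    """
    from .decoding import canonical_route, sample_route
    routes, logqs, mol_ids, route_codes = [], [], [], []
    for j, i in enumerate(idx):
        for _ in range(loss_cfg.k):
            r = canonical_route(graphs[i]) if loss_cfg.alpha == 1.0 \
                else sample_route(graphs[i], loss_cfg.alpha, rng)
            routes.append(r)
            logqs.append(r.log_q)
            mol_ids.append(j)
            if codes is not None:
                route_codes.append(codes[i])
    lps = policy.score_routes(routes, route_codes or None, training=True)
    adj = lps - np.asarray(logqs)
    mol_ids = np.asarray(mol_ids)
    n_mol, n_routes = len(idx), len(routes)
    m = np.full(n_mol, -np.inf)
    np.maximum.at(m, mol_ids, adj.data)
    w = nn.exp(adj - m[mol_ids])
    Mm = np.zeros((n_mol, n_routes))
    Mm[mol_ids, np.arange(n_routes)] = 1.0
    sums = nn.matmul(nn.Tensor(Mm), nn.reshape(w, (-1, 1)))
    lp_mol = nn.reshape(nn.log(sums), (-1,)) + m - math.log(loss_cfg.k)
    return -lp_mol.mean()


def _optimize(graphs, codes, policy, loss_cfg, train_cfg, opt, rng,
              lr0, decay, epochs, callback) -> List[float]:
    n = len(graphs)
    trace: List[float] = []
    t = 0
    for _ in range(epochs):
        perm = rng.permutation(n)
        for start in range(0, n, train_cfg.batch_size):
            idx = perm[start:start + train_cfg.batch_size]
            opt.lr = _lr_at(train_cfg, lr0, decay, t)
            opt.zero_grad()
            batch_loss = _batch_loss(idx, graphs, codes, policy, loss_cfg,
                                     rng)
            val = batch_loss.item()
            if not math.isfinite(val):
                raise RuntimeError(
                    f"non-finite loss {val} at iteration {t}; "
                    f"lr={opt.lr:.2e}, batch={list(idx)}")
            batch_loss.backward()
            opt.step()
            trace.append(val)
            if callback is not None:
                callback(t, val)
            t += 1
            if train_cfg.max_iterations is not None \
                    and t >= train_cfg.max_iterations:
                return trace
    return trace


def fine_tune(policy, sub_corpus: Sequence[Union[str, MolGraph]],
              loss_cfg: LossConfig, train_cfg: TrainConfig,
              codes: Optional[Sequence[np.ndarray]] = None,
              callback: Optional[Callable[[int, float], None]] = None
              ) -> List[float]:
    """Continue optimization on a focused subset with the fine-tune schedule.

    Used to enrich rare classes (e.g. predicted actives) after unconditional
    pre-training.  The sub-corpus must encode under the policy's vocabulary.
    """
    graphs = _encode_corpus(sub_corpus)
    if not graphs:
        raise ValueError("empty fine-tuning corpus")
    for g in graphs:  # vocabulary compatibility check up front
        for at in g.atoms:
            policy.vocab.index(at)
    ft = train_cfg.fine_tune
    rng = np.random.default_rng(train_cfg.seed)
    opt = nn.Adam(policy.params, lr=ft.lr, beta1=train_cfg.beta1,
                  beta2=train_cfg.beta2, eps=train_cfg.eps)
    return _optimize(graphs, codes, policy, loss_cfg, train_cfg, opt, rng,
                     ft.lr, ft.lr_decay, ft.epochs, callback)


# -- sampling ---------------------------------------------------------------


def _apply_temperature(p: np.ndarray, temperature: float) -> np.ndarray:
    if temperature == 1.0:
        return p / p.sum()
    q = p ** (1.0 / temperature)
    return q / q.sum()


def _sample_step(policy, g: MolGraph, code, state, temperature, rng):
    """Draw one transition from the masked, normalized policy output."""
    out = policy.forward(g, code=code, state=state)
    new_state = None
    if isinstance(policy, MolRNN):
        out, new_state = out
    A = len(policy.vocab)
    con = out.p_connect.copy()
    vstar = g.latest
    con[vstar, :] = 0.0
    for u, _ in g.neighbors(vstar):
        con[u, :] = 0.0
    flat = np.concatenate([out.p_append.reshape(-1), con.reshape(-1),
                           [out.p_terminate]])
    flat = _apply_temperature(flat, temperature)
    choice = rng.choice(flat.size, p=flat)
    n_app = g.num_atoms * A * N_BOND_TYPES
    if choice < n_app:
        v, rest = divmod(choice, A * N_BOND_TYPES)
        a, b = divmod(rest, N_BOND_TYPES)
        t = Append(v, policy.vocab[a], BondType(b))
    elif choice < n_app + g.num_atoms * N_BOND_TYPES:
        v, b = divmod(choice - n_app, N_BOND_TYPES)
        t = Connect(v, BondType(b))
    else:
        t = Terminate()
    return t, new_state


def generate(policy, gen_cfg: GenerationConfig, rng: np.random.Generator,
             code: Optional[np.ndarray] = None
             ) -> List[Tuple[MolGraph, str]]:
    """Sample molecules from the policy.

    Returns ``(graph, status)`` pairs with status ``"ok"`` (terminated and
    chemically valid), ``"invalid_chemistry"`` (terminated but fails
    sanitization) or ``"step_cap"`` (hit the transition limit).
    """
    samples = []
    for _ in range(gen_cfg.n_samples):
        p0 = _apply_temperature(policy.init_distribution(code),
                                gen_cfg.temperature)
        a = rng.choice(len(p0), p=p0)
        g = apply_transition(MolGraph(), Init(policy.vocab[a]))
        state = RnnState.zeros(policy.config) \
            if isinstance(policy, MolRNN) else None
        status = "step_cap"
        for _ in range(gen_cfg.max_steps - 1):
            t, state = _sample_step(policy, g, code, state,
                                    gen_cfg.temperature, rng)
            if isinstance(t, Terminate):
                status = "ok" if is_valid(g)[0] else "invalid_chemistry"
                break
            g = apply_transition(g, t)
        samples.append((g, status))
    return samples


# -- checkpoints ------------------------------------------------------------

_MODEL_CLASSES = {"MolMP": MolMP, "MolRNN": MolRNN}


def save_checkpoint(path: str, policy, extra: Optional[dict] = None) -> None:
    """Serialize weights + architecture config + vocabulary to one file."""
    meta = {
        "model": type(policy).__name__,
        "config": policy.config.to_dict(),
        "vocab": [list(t.as_tuple()) for t in policy.vocab],
        "extra": extra or {},
    }
    arrays = {f"p{i}": p.data for i, p in enumerate(policy.params)}
    for i, bn in enumerate(policy.bn_layers):
        arrays[f"bn{i}_mean"] = bn.running_mean
        arrays[f"bn{i}_var"] = bn.running_var
    arrays["__meta__"] = np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_checkpoint(path: str):
    """Rebuild a policy from :func:`save_checkpoint` output."""
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        from .molgraph import AtomType
        vocab = AtomVocabulary(
            [AtomType(s, h, q) for s, h, q in meta["vocab"]])
        config = PolicyConfig.from_dict(meta["config"])
        cls = _MODEL_CLASSES[meta["model"]]
        policy = cls(vocab, config, np.random.default_rng(0))
        for i, p in enumerate(policy.params):
            arr = data[f"p{i}"]
            if arr.shape != p.data.shape:
                raise ValueError(f"checkpoint shape mismatch at p{i}")
            p.data = arr.copy()
        for i, bn in enumerate(policy.bn_layers):
            bn.running_mean = data[f"bn{i}_mean"].copy()
            bn.running_var = data[f"bn{i}_var"].copy()
    return policy, meta["extra"]
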