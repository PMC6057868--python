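"""Route likelihoods and the importance-weighted marginal bound.

The step-wise policy makes the joint likelihood of a molecule and one of its
decoding routes tractable,

    log p(G, r) = sum_i log p(t_i | G_i, ...),

but the marginal log p(G) = log sum_{r in R(G)} p(G, r) requires summing
over every route.  Training instead maximizes the importance-sampled lower
bound obtained by drawing k routes from ``q_alpha(r | G)``:

    log p(G) >= log (1/k) sum_i p(G, r_i) / q_alpha(r_i | G).

At ``alpha = 1`` the sampler is deterministic and the bound collapses to the
exact likelihood of the canonical route.  For molecules of at most a few
atoms, :func:`enumerate_logp` computes the marginal exactly by enumerating
``R(G)``; it is the oracle the estimator is validated against.

All arithmetic is carried out in log-space (log-sum-exp) since route
probabilities underflow quickly.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np

from . import nn
from .decoding import (DecodingRoute, canonical_route, enumerate_routes,
                       route_q_logp, sample_route)
from .molgraph import MolGraph

__all__ = ["LossConfig", "route_logp", "iw_nll", "enumerate_logp",
           "iw_logp_estimate"]

_BAD_LOGP = -1e6  # stand-in for -inf so gradients stay finite


@dataclass
class LossConfig:
    """Likelihood-estimation settings.

    ``alpha`` controls the randomness of the route distribution (1.0 is
    deterministic canonical decoding); ``k`` is the number of routes per
    molecule, 1 when ``alpha = 1`` and 5 otherwise by default.
    """

    alpha: float = 0.8
    k: Optional[int] = None
    reduction: str = "mean"

    def __post_init__(self):
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if self.k is None:
            self.k = 1 if self.alpha == 1.0 else 5
        if self.k < 1:
            raise ValueError("k must be >= 1")


def route_logp(route: DecodingRoute, policy,
               code: Optional[np.ndarray] = None,
               training: bool = False) -> float:
    """``log p_theta(G, r)``: sum of step log-probabilities along a route."""
    lp = policy.score_route(route, code=code, training=training).item()
    if not math.isfinite(lp):
        warnings.warn("route received zero probability; returning -inf")
        return -math.inf
    return lp


def _finite(lp: nn.Tensor) -> nn.Tensor:
    if not np.isfinite(lp.data):
        warnings.warn("non-finite route log-probability clamped")
        return nn.Tensor(_BAD_LOGP)
    return lp


def iw_nll(g: MolGraph, policy, cfg: LossConfig,
           rng: np.random.Generator, code: Optional[np.ndarray] = None,
           training: bool = True) -> nn.Tensor:
    """Negative importance-weighted likelihood bound for one molecule.

    Differentiable; with ``alpha = 1`` and ``k = 1`` it is the exact
    negative log-likelihood of the canonical route.
    """
    if cfg.alpha == 1.0:
        routes = [canonical_route(g) for _ in range(cfg.k)]
    else:
        routes = [sample_route(g, cfg.alpha, rng) for _ in range(cfg.k)]
    terms = [_finite(policy.score_route(r, code=code, training=training))
             - r.log_q for r in routes]
    m = max(t.item() for t in terms)
    acc = None
    for t in terms:
        e = nn.exp(t - m)
        acc = e if acc is None else acc + e
    return -(nn.log(acc) + m - math.log(cfg.k))


def enumerate_logp(g: MolGraph, policy,
                   code: Optional[np.ndarray] = None,
                   max_atoms: int = 5) -> float:
    """Exact ``log p_theta(G)`` by exhausting ``R(G)`` (tiny molecules)."""
    lps = [route_logp(r, policy, code=code)
           for r in enumerate_routes(g, max_atoms=max_atoms)]
    m = max(lps)
    if not math.isfinite(m):
        return -math.inf
    return m + math.log(sum(math.exp(lp - m) for lp in lps))


def iw_logp_estimate(g: MolGraph, policy, alpha: float, k: int,
                     rng: np.random.Generator,
                     code: Optional[np.ndarray] = None):
    """Monte-Carlo estimate of ``log p_theta(G)`` with its raw weights.

    Draws ``k`` routes from ``q_alpha``, deduplicates them (small molecules
    have few distinct routes, so each is scored once) and returns
    ``(log mean weight, weights)`` where ``weights[i] = p(G, r_i) /
    q_alpha(r_i | G)`` per draw.  The weights let callers form Monte-Carlo
    standard errors; their mean is an unbiased estimate of ``p_theta(G)``.
    """
    counts: dict = {}
    qs: dict = {}
    reps: dict = {}
    for _ in range(k):
        r = sample_route(g, alpha, rng)
        key = tuple(r.transitions)
        counts[key] = counts.get(key, 0) + 1
        if key not in qs:
            qs[key] = r.log_q
            reps[key] = r
    weights = np.empty(k)
    pos = 0
    for key, c in counts.items():
        lp = route_logp(reps[key], policy, code=code)
        w = math.exp(lp - qs[key])
        weights[pos:pos + c] = w
        pos += c
    return math.log(weights.mean()), weights


def exhaustive_q_check(g: MolGraph, alpha: float, max_atoms: int = 5) -> float:
    """Total ``q_alpha`` mass over all routes of ``g`` (should be 1)."""
    return sum(math.exp(route_q_logp(r, g, alpha))
               for r in enumerate_routes(g, max_atoms=max_atoms))
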