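# Methods

## The generative model

A molecule is a labeled graph `G = (V, E)`: nodes carry atom types — the
triple *(element symbol, number of explicit hydrogens, formal charge)*, so
the pyrrole nitrogen is `("N", 1, 0)` — and edges carry one of four bond
types (single, double, triple, aromatic). Generation is sequential: starting
from the empty graph, a *decoding policy* repeatedly samples one of

* **initialization** — place the first atom,
* **append** — add a new atom bonded to an existing atom,
* **connect** — close a ring between the latest appended atom `v*` and
  another atom (only `v*` may start a connect),
* **terminate** — stop.

Append and connect each add exactly one edge, so every decoding route of a
connected molecule has exactly `|E| + 2` steps. Chemically invalid actions
are *not* masked during training; learning valence and aromaticity rules is
part of the modeling task, and the validity checker classifies failures into
valence, aromaticity and other (broken aromaticity is the characteristic
failure mode of stepwise graph decoding, because aromaticity is a
whole-ring property that the decoder only ever sees partially).

### Policies

Two architectures share one trunk. Atoms are embedded from (atom type,
is-`v*` flag) and passed through `L` edge-conditioned graph convolutions

    h_v <- W h_v + Σ_b Θ_b Σ_{u∈N_b(v)} h_u
                 + Σ_{1<d≤D} Φ_d Σ_{u: dist(u,v)=d} h_u   (+ Ψ c),

where `N_b(v)` are the neighbors joined to `v` by a bond of type `b` and the
distance terms give a receptive field of `D` hops per layer (shortest paths
are recomputed on each partial graph). Layers after the first use the
pre-activation BN–ReLU–Conv order; all layer outputs are concatenated (dense
skip connection) and finished by a two-layer fully connected stack into
per-atom representations `h_v`; the molecule representation `h_G` is their
mean.

* **MolMP** is Markov: the action heads see `(h_v, h_G)` only.
* **MolRNN** threads a molecule-level GRU stack
  `h' = GRU(h, h_{v*}, h_G)` and feeds the updated state to the heads in
  place of `h_G`, making the policy history-dependent. We take `h_{v*}`
  from the final per-atom representation (the trunk output); the
  alternative — an intermediate layer — is architecturally possible but
  was not adopted.

The heads emit an `|A|×|B|` append matrix per atom, a length-`|B|` connect
vector per atom and a terminate scalar, all with exponential output
activation, jointly normalized by their total mass `P`. Internally
everything stays in log space; probabilities are materialized through
max-shifted softmaxes, so the normalization identity holds to machine
precision regardless of logit scale.

The empty graph gives the trunk nothing to condition on, so the
initialization step has its own learned categorical over atom types
(linearly shifted by the conditional code when present). This head is this
package's answer to a question the architecture leaves open.

### Likelihood

For a given route, `log p(G, r)` is the sum of step log-probabilities. The
marginal `log p(G)` sums over all routes `R(G)` and is intractable except
for tiny molecules; training maximizes the importance-sampled lower bound
with `k` routes drawn from `q_α(r | G)`:

    log p(G) ≥ log (1/k) Σ_i p(G, r_i) / q_α(r_i | G).

`q_α` follows canonical depth-first decoding but at each step where more
than one action can still complete to `G` takes, with probability `1 − α`, a
uniform draw over the non-canonical such actions. Consequences we rely on:

* the canonical action has probability exactly `α` at decision steps, so
  the empirical mistake rate calibrates to `1 − α`;
* `α = 1` collapses to deterministic canonical decoding (`log q = 0`,
  `k = 1`);
* `q_α` is a proper distribution over `R(G)`: routes are *transition
  sequences*, and automorphic constructions that perform identical actions
  are one route. The sampler tracks every embedding of the partial graph
  into the target that is consistent with the actions taken so far and
  merges actions at the transition level; by enumeration,
  `Σ_r q_α(r | G) = 1` exactly. Without this collapsing, symmetric
  molecules (ethane, benzene) would be overcounted and the importance
  weights biased.

The canonical order is RDKit's canonical atom ranking with ties broken;
depth-first descent prefers the deepest atom with unplaced neighbors, ring
closures are emitted as soon as both endpoints exist (ascending target
rank). An exhaustive enumerator (`≤ 5` heavy atoms) provides the exact
marginal as a test oracle; it is not part of the user-facing API surface
beyond `likelihood.enumerate_logp`.

### Conditional generation

A requirement is a numeric code `c` injected as `Ψ c` into every
convolution layer. Three schemas: scaffold fingerprints (binary
substructure membership over a scaffold set built from Bemis–Murcko
scaffolds plus ring assemblies), `(QED, SA)` property pairs (RDKit QED and
the Ertl–Schuffenhauer SA score), and per-target activity bits from a
random-forest classifier on 2048-bit radius-3 circular fingerprints
(ECFP6), balanced class weights, 0.5 threshold. Interval requirements are
boxes in code space; generation draws concrete codes from the empirical
code distribution of a reference set restricted to the box.

Ring assemblies are defined as connected components of the ring-bond
subgraph (extracted with RDKit `PathToSubmol`); fused systems stay whole,
linker-joined rings split.

## Training

Adam (β₁ = 0.9, β₂ = 0.999, ε = 1e-8), initial learning rate 0.001 with a
decay rate of 0.001 applied every 100 iterations, 5 epochs, mini-batches of
200 molecules; fine-tuning on a focused subset uses lr 0.0001, decay 0.002,
10 epochs. The decay phrase is read as inverse-time decay
`lr_t = lr₀ / (1 + d·⌊t/100⌋)`; an exponential variant
`lr₀ (1 − d)^⌊t/100⌋` is selectable, as both readings are defensible.

All `k` routes of all molecules in a mini-batch are scored in a single
block-diagonal forward pass. This matters beyond speed: batch-norm
statistics are then computed over the atoms of the whole mini-batch — the
quantity the running averages converge to — so the distribution the model
is trained under is the same one it samples from at generation time. An
earlier per-molecule formulation made BN statistics molecule-specific
during training and measurably hurt sample fidelity.

Sampling masks structurally impossible connects (target is `v*` or already
bonded to it) and renormalizes; chemical validity is still left to the
model. Each sample ends with `ok`, `invalid_chemistry` or `step_cap`
status; the cap defaults to 100 transitions, comfortably above the
`|E| + 2` routes of drug-sized (≤ 50 heavy atom) molecules.

## Architecture defaults and the desk-scale configuration

Defaults mirror the reference architecture: 16-dim embeddings; six
convolution layers of widths 32, 64, 128, 128, 256, 256; receptive field
D = 3; 256/512 fully connected stack; 128-wide action head; three GRU
layers of width 512. `PolicyConfig.desk()` — 8-dim embeddings, two
convolution layers (16, 32), a 32/48 stack and a single 64-wide GRU layer —
is what the tests, the worked example and the acceptance script use: it
trains in seconds on one CPU while exercising every architectural
component. Reported desk-scale numbers (overfit recovery, conditional
control) therefore probe the machinery, not ChEMBL-scale generative
quality.

## The numerical substrate

The policies run on a small reverse-mode automatic-differentiation engine
over NumPy arrays (`molgraphgen.nn`): float64 tensors, the ~20 operations
the networks need, BN with running statistics, GRU cells and Adam.
Gradients are verified against central finite differences in the test
suite. Graph convolutions are evaluated as dense matrix products against
per-bond-type and per-distance adjacency matrices of the block-diagonal
batch graph.

## Synthetic data

The fixture generator grows random valence-respecting trees over
{C, N, O, S}, closes an occasional ring, optionally seeds growth from a
benzene ring (so substructure-conditioned corpora have both classes), and
rejects drafts RDKit will not sanitize; it is deterministic under its seed.
It emulates the *combinatorial* structure of small organic molecules —
branching, rings, heteroatoms, valence limits — but not the property
distributions, functional-group chemistry or size of a real screening
corpus. Passing tests therefore demonstrate that decoding, likelihood
estimation, conditioning and metrics behave correctly, not that a
desk-scale model generates drug-like chemistry. The bundled 30-molecule
drug list (including cimetidine and candesartan) covers aromatic systems,
charged atoms and explicit-hydrogen heteroatoms for the data model and
scaffold machinery.

## Numerical choices and degenerate inputs

* Log-sum-exp everywhere a normalizer or a route sum appears; route
  probabilities underflow quickly otherwise.
* KDE divergences: Gaussian kernels with Scott's-rule bandwidths, a
  2048-point grid spanning the pooled data ± 3 bandwidths, densities
  floored at 1e-12 before logs, trapezoidal quadrature. Zero-variance
  samples are rejected rather than smoothed.
* Internal diversity follows the ordered-pair definition including
  self-pairs (a singleton set has diversity 0); the diagonal-excluded
  convention is available behind a flag since both are in circulation.
* Canonical-route tie-breaks are fully deterministic (broken atom ranks,
  ascending-rank neighbor order, transition-order comparison for the
  embedding-merged canonical action), so `α = 1` training is bitwise
  reproducible under a fixed seed.
* Disconnected molecules are rejected by the decoder; multi-fragment
  inputs are reduced to their largest fragment during vocabulary
  extraction only.
* BN with a single atom in the batch is legal (ε keeps the variance
  positive); at inference running averages are used.
* A route assigned zero probability would yield `−inf`; the loss clamps
  such terms to a large finite penalty with a warning (softmax outputs make
  this unreachable in practice).

## Known limitations

* No stereochemistry, isotopes or multi-fragment molecules.
* Exact marginal likelihoods only for molecules small enough to enumerate.
* Pure-NumPy training is single-process and CPU-bound: suitable for the
  desk-scale configurations here, not for millions of molecules.
* The mistake model of `q_α` is one concrete choice (uniform over
  g-consistent non-canonical actions); other randomization schemes would
  also interpolate between deterministic and fully random decoding.
* Scaffold-conditioned generation quality depends on the scaffold set
  actually covering the corpus; acyclic molecules have all-zero scaffold
  fingerprints and are only reachable under the all-zero code.
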