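# molgraphgen

De novo molecular design by sequential graph generation. Molecules are
built atom-by-atom and bond-by-bond by a learned *decoding policy*: from the
empty graph, the policy repeatedly chooses to **append** a new atom,
**connect** the latest atom back into a ring, or **terminate** — so
generating `G = (V, E)` always takes exactly `|E| + 2` steps. Compared with
SMILES language models, the policy works directly on the molecular graph
and never has to learn string grammar.

The package is for researchers in computational drug discovery who want a
transparent, fully tested CPU implementation of graph-based molecule
generation: the two policy architectures (**MolMP**, a Markov policy, and
**MolRNN**, which adds a molecule-level GRU), the edge-conditioned graph
convolution behind them, the **α-randomized importance-sampled likelihood**
used for training, **conditional generation** (scaffold fingerprints,
(QED, SA) property codes, activity bits), and the standard evaluation
metrics (validity/novelty, KDE-based KL/JS divergences of molecular
properties, conditional control matrices `K_cc'`/`R_c`/`EOR_c`,
reproduction rate, internal Tanimoto diversity).

## The model in brief

The policy outputs, for the current partial graph (and optional condition
code `c`), a jointly normalized distribution over all transitions: an
`|A|×|B|` append matrix per atom, a `|B|`-vector of ring closures per atom,
and a terminate scalar. Atom representations come from graph convolutions

    h_v ← W h_v + Σ_b Θ_b Σ_{u∈N_b(v)} h_u + Σ_{1<d≤D} Φ_d Σ_{dist(u,v)=d} h_u + Ψ c

Training maximizes the importance-weighted bound

    log p(G) ≥ log (1/k) Σᵢ p(G, rᵢ) / q_α(rᵢ | G),

where `q_α` follows canonical depth-first decoding but makes a "random
mistake" with probability `1 − α` at each step; `α = 1` is deterministic
canonical decoding. See `docs/methods.md` for the full account.

Everything runs on NumPy (a small built-in reverse-mode autodiff engine
powers the networks); RDKit does all chemistry. No GPU, no downloads — a
bundled 30-drug corpus and a seeded random-molecule generator make the
whole package exercisable offline.

## Worked example

Train a small MolRNN to memorize ten tiny molecules, then sample from it:

```python
import numpy as np
from molgraphgen import (build_vocab, MolRNN, PolicyConfig, LossConfig,
                         TrainConfig, GenerationConfig, train, generate,
                         smiles_from_graph)
from molgraphgen.fixtures import small_corpus
from molgraphgen.evaluation import validity_novelty, internal_diversity

corpus = small_corpus()                      # 10 molecules, e.g. "CCO"
vocab = build_vocab(corpus)                  # atom-type triples
policy = MolRNN(vocab, PolicyConfig.desk(), np.random.default_rng(0))
trace = train(corpus, policy, LossConfig(alpha=1.0),
              TrainConfig(epochs=200, batch_size=200, seed=0))
print(f"final NLL: {trace[-1]:.3f} nats/molecule")

samples = generate(policy, GenerationConfig(n_samples=200, max_steps=30),
                   np.random.default_rng(1))
valid, novel, _ = validity_novelty([g for g, s in samples if s == "ok"],
                                   corpus)
smiles = [smiles_from_graph(g) for g, s in samples if s == "ok"]
print(f"novel among valid: {novel:.2f}")
print(f"internal diversity: {internal_diversity(smiles):.3f}")
```

Output:

```
final NLL: 3.168 nats/molecule
novel among valid: 0.42
internal diversity: 0.833
```

The final negative log-likelihood of ~3.2 nats is close to the entropy
floor for a ten-molecule corpus (log 10 ≈ 2.3 nats to pick the molecule,
plus residual route uncertainty); 99% of samples are chemically valid,
42% of them are small variations outside the training set, and the mean
pairwise Tanimoto distance of 0.833 shows the model has not collapsed onto
a single structure.

The same workflow is available from the shell:

```bash
molgraphgen fixtures --bundled --out drugs.smi
molgraphgen scaffolds --corpus drugs.smi --out S.smi
molgraphgen encode --schema qed_sa --corpus drugs.smi --out annotated.smi
molgraphgen train --corpus annotated.smi --config cfg.yaml --out ckpt.npz
molgraphgen sample --ckpt ckpt.npz -n 1000 --condition "0.7,2.5" --out out.smi
molgraphgen evaluate --samples out.smi --reference drugs.smi \
    --train drugs.smi --report report.json
```

## Package layout

| Module | Contents |
| --- | --- |
| `molgraphgen.molgraph` | graph data model, atom/bond vocabularies, SMILES round-trip, validity classification |
| `molgraphgen.decoding` | transitions, canonical routes, the `q_α` sampler, route enumeration |
| `molgraphgen.policy` | graph convolution, MolMP, MolRNN, normalized action heads |
| `molgraphgen.likelihood` | route log-likelihoods, importance-weighted bound, enumeration oracle |
| `molgraphgen.training` | Adam loop with schedules, fine-tuning, sampling, checkpoints |
| `molgraphgen.conditioning` | scaffold sets/fingerprints, (QED, SA) codes, activity predictors, code regions |
| `molgraphgen.evaluation` | validity/novelty, KL/JS divergences, `K_cc'`/`R_c`/`EOR_c`, reproduction rate, internal diversity |
| `molgraphgen.fixtures` | bundled drug corpus, seeded random-molecule generator |
| `molgraphgen.nn` | the NumPy autodiff engine behind the policies |
| `molgraphgen.cli` | `molgraphgen` command-line tool |

Not covered (out of scope): stereochemistry, SMILES-based baseline
generators, reinforcement-learning fine-tuning, and database-scale training
corpora.
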