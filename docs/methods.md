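# Methods

## Overview

`moltree` generates candidate small molecules for a protein target by
decoding a conditional autoregressive SMILES language model with a
reward-guided Monte Carlo Tree Search (MCTS), alongside greedy and beam
baselines. The package covers the full loop: curation of binding records
into (protein, ligand) training pairs, a protein-to-SMILES encoder–decoder
transformer, three decoding strategies, a composable reward stack
(validity, Lipinski Rule of Five, QED, optional docking affinity), and
distribution-learning evaluation metrics.

## Data model and curation

Input records follow the BindingDB convention: an organism annotation,
optional IC50/Kd/EC50 potencies in nM, a ligand SMILES, and the target
protein sequence. The curation rule keeps a record iff

1. the organism is *Homo sapiens*;
2. a SMILES string is present;
3. the highest-priority potency that is *present* — IC50, else Kd, else
   EC50 — is strictly below 100 nM.

The rule is a priority chain, not a disjunction: a present-but-failing
IC50 excludes the record even when a Kd below the cutoff exists. Records
with no measurement, or with negative/non-finite values, are dropped and
counted in the log. Filtering is order-preserving and idempotent. Kept
ligands are canonicalized with RDKit; pairs whose SMILES does not parse
are dropped with a logged count. The train/test split is an exact random
partition over pairs (train size `round(n * frac)`), uniform over pairs —
no deduplication or stratification by protein is applied.

## SMILES tokenization

The tokenizer is a regular expression over the SMILES grammar: bracket
atoms (`[N+]`, `[nH]`, ...), two-letter organic-subset elements (`Cl`,
`Br`), single-letter atoms and aromatics, `%nn` two-digit ring closures,
ring digits, and bond/branch/stereo punctuation. Concatenating the tokens
reproduces the input exactly; an unrecognized character raises an error
naming its position. The vocabulary is frozen from the training corpus
plus three specials (PAD, BOS, EOS) that occupy the first indices and
never appear inside chemical tokens.

## The conditional prior

The prior is an encoder–decoder transformer implemented directly in NumPy
(forward pass, hand-written backpropagation, Adam), with:

- learned token embeddings scaled by sqrt(d_model) plus fixed sinusoidal
  positional encodings;
- post-norm residual blocks: encoder = self-attention + feed-forward,
  decoder = causal self-attention + cross-attention over the encoder
  output + feed-forward, each followed by layer normalization;
- multi-head scaled dot-product attention, `softmax(QK^T / sqrt(d_k)) V`,
  with per-head rows of the attention matrix summing to 1 (asserted in
  tests);
- seed-controlled uniform(-0.08, 0.08) weight initialization;
- teacher-forced cross-entropy training with gradient accumulation over
  mini-batches and Adam (β = 0.9/0.999, ε = 1e-8).

Gradient correctness is verified against central finite differences for a
representative parameter in every block type.

Two configurations matter:

| parameter      | full-scale default | toy (`TransformerConfig.toy()`) |
|----------------|--------------------|---------------------------------|
| layers         | 6                  | 2                               |
| d_model        | 512                | 64                              |
| heads          | 8                  | 4                               |
| learning rate  | 1e-4               | 1e-3                            |
| batch size     | 5                  | 5                               |
| epochs         | 25                 | 15                              |
| max protein len| 500                | 300                             |

The full-scale defaults document the training regime appropriate for
database-scale corpora (hundreds of thousands of pairs); everything this
package trains and tests runs at the toy scale, where a 200-pair corpus
fits in about a minute of CPU. The faster toy learning rate compensates
for the much smaller corpus and model; it was chosen once from the loss
trajectory on synthetic data.

Decoding is pull-based: all decoders consume the single contract
`next_token_distribution(ctx, prefix) -> probability vector`, so a
deterministic table-driven `MockModel` substitutes for the transformer in
every decoder test. Encoding a protein precomputes the cross-attention
keys/values per decoder layer, which makes per-token inference cheap.

## Decoding strategies

**Greedy** emits the argmax token per step (ties to the lowest vocabulary
index; BOS/PAD are never emitted) until EOS or a length cap.

**Beam** keeps the k best partial sequences per step under the score
`sum(log P(token)) / len**alpha` (len counts generated tokens, EOS
included; alpha = 0 disables length normalization). Finished sequences
move to a pool and compete in the final ranking. Zero-probability
extensions (log-prob −∞) are pruned, which never changes the top of the
ranking. With k = 1 beam reduces to greedy token-for-token; with an
exhaustive width it provably returns the enumeration argmax, which is how
it is tested.

**MCTS** runs a fixed budget of simulations, each with four phases:

1. *Selection* — descend from the BOS root by maximizing the UCT value
   `r_i/n_i + c * sqrt(ln(N_i)/n_i)`, where `r_i` is the node's cumulative
   reward, `n_i` its visit count and `N_i` the parent's; unvisited nodes
   score +∞ and are tried first; ties break toward earlier children.
   The default exploration constant is c = 2.
2. *Expansion* — if the selected leaf is not terminal (EOS or the depth
   cap), create one child per vocabulary token with positive prior
   probability. Children are ordered by descending prior probability
   (ties by token index), so the child rolled out immediately after
   expansion is the model's preferred continuation. This matters: with
   arbitrary (e.g. alphabetical) child order the first rollout is forced
   through whatever token happens to sort first — often a bond or branch
   symbol — and the search spends its budget scoring junk prefixes.
   Zero-prior children are pruned; when the model has full support this is
   identical to expanding every token.
3. *Simulation* — complete the sequence by sampling from the prior until
   EOS or the depth cap, then score the detokenized SMILES with the
   composite reward. One rollout per iteration by default.
4. *Backpropagation* — add the composite reward to `cum_reward` and
   increment `n_visits` on every node from the expanded leaf up to the
   root.

The returned molecule is the highest-composite-reward *valid* terminal
sequence observed anywhere in the run (rollouts included). If no valid
terminal is seen within the budget the search raises rather than return
an invalid string — the generated-set validity of the gated search is
therefore 1 by construction whenever a valid molecule is reachable.
Rewards are memoized per SMILES within a search. All stochasticity flows
from a single seeded generator.

## Rewards

The composite reward is a weighted sum of four components with a hard
validity gate:

- **validity** ∈ {0, 1}: the string parses and sanitizes under RDKit;
- **RO5** ∈ {0, 1}: the four Lipinski criteria, evaluated inclusively —
  MW ≤ 500 Da, Crippen logP ≤ 5, H-bond donors (OH + NH) ≤ 5, H-bond
  acceptors (N + O) ≤ 10. Inclusive bounds mean a molecule sitting
  exactly on a threshold passes. The rule is often summarized with five
  conditions; the four enumerated criteria above are what this package
  implements.
- **QED** ∈ [0, 1]: Bickerton et al.'s weighted geometric mean of eight
  desirability functions, via RDKit;
- **affinity** ∈ [0, 1], optional: a docking score in kcal/mol mapped by
  `clip(score / floor, 0, 1)` with floor = −12 kcal/mol, so a −12 (or
  stronger) binder scores 1 and a non-binder 0. The linear clip makes an
  unbounded, lower-is-better quantity commensurable with the other terms.

Default weights are (1, 1, 1, 0): affinity off. With the gate on, an
invalid molecule scores exactly 0 regardless of weights. Docking is
isolated behind an adapter that shells out to an external program
(AutoDock Vina-style command template with receptor/box/seed
placeholders) and parses the best reported score; a missing executable is
a configuration error and a failed run raises with the captured
diagnostics — a docking failure is never silently scored 0. Tests inject
a mock scorer; no docking executable is required anywhere in the loop.

## Evaluation metrics

For a generated set against a training corpus (GuacaMol
distribution-learning conventions):

- validity = valid / generated;
- uniqueness = distinct-canonical / valid;
- novelty = distinct-canonical-not-in-training / distinct-canonical;
- mean QED over valid molecules.

Membership is tested on canonical SMILES strings. The property report
tabulates MW, logP, HBD, HBA, rotatable bonds and ring count per valid
molecule with min/max/mean summaries.

## Synthetic data

The fixture generator emulates a curated binding database at toy scale:
each record pairs a random 50–300-residue protein with a ligand drawn
from a packaged library of ~70 small, valid, RO5-passing drug-like
molecules, and carries exactly one potency (IC50, Kd or EC50, uniformly
below the cutoff) to exercise the priority chain. A requested fraction of
records violates exactly one curation criterion (wrong organism, missing
SMILES, or all potencies at/above 100 nM), so filter counts are known by
construction.

What the generator does *not* emulate: real ligand–target specificity
(ligands are assigned to proteins at random, so there is no biochemical
signal for the model to learn, only sequence co-occurrence), the size and
diversity of a real ligand corpus, assay noise and unit heterogeneity,
and multi-chain or post-translationally modified targets. Passing tests
therefore demonstrate that the curation, training, search and scoring
machinery behaves correctly under controlled conditions — not that the
toy model learns true binding relationships.

## Reduced-scale benchmark

`scripts/acceptance.py` trains the toy prior on 200 synthetic pairs and
runs 100 gated MCTS generations (c = 2, 200 simulations each, depth cap
60, weights 1/1/1), one per target protein cycling through the training
set, then reports the generated-set validity and the maximum logP and
molecular weight. These problem sizes were chosen as the smallest runs
that exercise every stage meaningfully; training takes about a minute and
generation a few minutes on one CPU. At this scale uniqueness, novelty
and mean QED are reported but not asserted: they depend on corpus size
and training quality and are only meaningful for database-scale models.

## Numerical and design choices

- Argmax ties: lowest vocabulary index, everywhere.
- UCT: standard `r/n + c*sqrt(ln N / n)` with N the parent's visits;
  first-play urgency via infinite UCB for unvisited nodes.
- Final MCTS answer: best valid terminal observed, rather than the
  max-visit path — at small budgets the max-visit path is frequently
  truncated, while best-of-rollouts is well-defined from the first
  simulation.
- Layer norm ε = 1e-5; cross-entropy clamped with +1e-12 inside the log.
- Affinity floor −12 kcal/mol: typical strong-binder docking scores sit
  around −9 to −12, so the unit interval is used without saturating on
  ordinary candidates.
- `split_train_test` sorts each side by original index after the random
  draw, so outputs are deterministic and order-stable.
- Degenerate inputs fail loudly: empty protein, residues outside the
  20 + X alphabet, over-long sequences, invalid SMILES in training pairs,
  empty generated sets.

## Known limitations

- The NumPy transformer is CPU-only and single-sequence; it is not meant
  for database-scale training.
- Stereochemistry is carried through tokenization and canonicalization
  but no 3D reasoning of any kind is performed; the docking adapter
  delegates all geometry to the external program.
- Beam search with practical widths is a heuristic; only the exhaustive
  configuration carries an optimality guarantee.
- The search can rediscover the same high-reward molecule for similar
  contexts; uniqueness at toy scale is sensitive to corpus diversity.
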