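# moltree

Conditional de novo molecule generation: an autoregressive SMILES language
model conditioned on a protein target, decoded by a reward-guided Monte
Carlo Tree Search (with greedy and beam-search baselines).

## The problem

De novo drug design asks for novel molecules that (a) are chemically
valid, (b) look like oral drugs, and (c) bind a given protein target.
Autoregressive chemical language models handle (a)–(b) only implicitly:
decoding them greedily or with beam search frequently yields invalid
SMILES strings and property distributions that drift outside the
drug-like region. `moltree` treats decoding itself as the optimization:
a tree search over SMILES token sequences whose value function is a
composite reward

&nbsp;&nbsp;&nbsp;&nbsp;R(s) = w₁·validity(s) + w₂·RO5(s) + w₃·QED(s) + w₄·affinity(s)

with a hard validity gate (an unparseable string scores 0). Selection
uses the UCT rule

&nbsp;&nbsp;&nbsp;&nbsp;UCB(i) = rᵢ/nᵢ + c·√(ln Nᵢ / nᵢ)

over cumulative rewards rᵢ and visit counts nᵢ; expansion creates one
child per vocabulary token with positive prior probability; simulation
completes the prefix by sampling from the language model ("the prior");
backpropagation pushes the reward up the path. The search returns the
best-scoring *valid* molecule it observed, so generated-set validity is
1.0 by construction. RO5 is Lipinski's Rule of Five (MW ≤ 500, logP ≤ 5,
HBD ≤ 5, HBA ≤ 10, evaluated inclusively); QED is the quantitative
estimate of drug-likeness in [0, 1]; the optional affinity term plugs in
an external docking program (AutoDock Vina-style) behind an adapter.

The conditional prior is an encoder–decoder transformer (protein residues
in, SMILES tokens out) implemented self-contained in NumPy, trained by
teacher forcing at a reduced scale suitable for CPU experiments. See
`docs/methods.md` for the full model description and design rationale.

## Worked example

The whole pipeline on synthetic fixtures, from the shell:

```
$ moltree make-fixtures --n 100 --seed 1 --fail-fraction 0.3 --out records.tsv
wrote 100 records to records.tsv

$ moltree prepare-data records.tsv --train-frac 0.7 --seed 0 --out-dir data
kept 70 of 100 records
split 70 pairs into 49 train / 21 test

$ moltree train-toy --synthetic 60 --epochs 10 --seed 3 --out model.npz
trained on 60 pairs: loss 3.257 -> 1.053; saved model.npz

$ moltree generate --model model.npz --target target.fasta \
      --decoder mcts -n 5 --n-simulations 200 --seed 11 --out gen.smi
wrote 5 molecules to gen.smi

$ cat gen.smi
Cc1cnsc1
F[N+](F)c1ccccc2cccc21
NS(=O)CC1cccccc1
Oc1c2[nH]c2cn(F)cc1
N1ccnc1

$ moltree evaluate gen.smi data/train.smi
{
  "validity": 1.0,
  "uniqueness": 1.0,
  "novelty": 1.0,
  "mean_qed": 0.5529774568478409,
  "n_generated": 5
}
```

Reading the numbers: 100 synthetic binding records were generated with 30
engineered curation violations; the filter kept exactly the 70 passing
records (human target, SMILES present, best-priority potency < 100 nM)
and split them 49/21. After ten epochs of teacher forcing the training
cross-entropy fell from 3.26 to 1.05 nats/token. All five molecules
returned by the gated tree search parse (validity 1.0), are pairwise
distinct (uniqueness 1.0), and none occurs in the training set
(novelty 1.0); their mean QED is 0.55. Per-molecule reward components are
written to the `gen.smi.json` sidecar along with the run configuration.

The same machinery is available as a library (`moltree.mcts_generate`,
`moltree.compute_metrics`, ...); the mock model in
`moltree.prior.MockModel` makes every decoder testable without training.

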