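# codroplet

A pair-representation transformer that scores the **co-condensation
propensity** of protein pairs — the probability that two proteins partition
into the same biomolecular condensate (membraneless organelles such as
nucleoli, P-bodies and stress granules) — from AlphaFold2-style residue
representations, together with the condensate-derived dataset construction,
the training/evaluation harness and the downstream condensate analyses.

It is aimed at computational structural biologists studying liquid–liquid
phase separation who want a transparent, fully seeded reimplementation of
this model family that runs at desk scale: a built-in surrogate feature
generator plants a known pairwise-compatibility signal so the whole pipeline
can be trained and validated on a single CPU, without AlphaFold2, GPUs or
access to the condensate databases.

## The model

Each protein enters as three AlphaFold2-style arrays: a single
representation `f_msa ∈ R^{L×384}`, a pair representation
`f_pair ∈ R^{L×L×128}` and a structure representation `f_struc ∈ R^{L×384}`.
A shared encoder maps each protein to a residue graph with node features
`n_i ∈ R^{c_n}` (`c_n = 256`) and edge features `e_ij ∈ R^{c_e−1}`
(`c_e = 32`). The two graphs are concatenated into a two-chain complex whose
inter-chain edges are zero-padded, with the reserved last edge channel
holding the binary same-chain/different-chain indicator. Eight transformer
blocks of gated multi-head self-attention with pair bias,

    a_ij^h = q_i^h · k_j^h / √c'_n ,   attention = softmax_j(a_ij^h + b_ij^h) ,
    o_i^h  = g_i^h ⊙ Σ_j attention_ij^h v_j^h ,

followed by residual Transition blocks, exchange information between the
chains; the edge features are updated from the pre-bias attention logits. A
prediction head average-pools all residues of the complex and maps the
pooled vector through an MLP and a sigmoid to the co-condensation
probability. Training minimises binary cross-entropy with an L2 penalty
(minibatch 4, per-epoch class rebalancing, Adam), with fully seeded
determinism. The network, including its gradients, is implemented on a small
reverse-mode autodiff tape over numpy — no deep-learning framework is
required. See `docs/methods.md` for the full specification and the design
choices.

## Worked example

```python
from codroplet import CoDropleT, TrainConfig, ModelConfig
from codroplet.benchmarks import make_planted_pairs
from codroplet.features import generate_cohort

# 20 surrogate proteins in two latent compatibility clusters
sequences, profiles, bundles = generate_cohort(20, length=(8, 12), n_clusters=2, seed=7)
features = {b.protein_id: b for b in bundles}

# balanced labeled pairs: positive = same cluster
pairs = make_planted_pairs(profiles, n_per_class=30, seed=7)
train_pairs, test_pairs = pairs[:40], pairs[40:]

config = TrainConfig(epochs=8, learning_rate=1e-3, seed=7,
                     model=ModelConfig.desk_scale())
results = CoDropleT(train_pairs, features, config).fit()
print(results.summary())

report = results.evaluate(test_pairs)
print(f"held-out: accuracy={report.accuracy:.3f}  auc={report.auc:.3f}  mcc={report.mcc:.3f}")
```

prints (about a minute on one CPU):

```
          Co-condensation propensity model
========================================================
Training pairs:             40 (20 positive / 20 negative)
Epochs:                     8    Batch size: 4
Learning rate:              0.001    L2 lambda: 0.0001
Architecture:               c_n=32, c_e=8, 2 layers, 2 heads
Parameters:                 5062296
Seed:                       7
Initial / final loss:       2.3618 / 1.3041
========================================================
held-out: accuracy=1.000  auc=1.000  mcc=1.000
```

The loss falls from 2.36 to 1.30 over eight epochs and the model separates
held-out same-cluster from cross-cluster pairs perfectly — the planted
compatibility signal has been recovered from the surrogate features. On
real data the equivalent workflow consumes externally computed AlphaFold2
bundles from the HDF5 feature store instead of the surrogate generator.

## Command line

The same pipeline is scriptable end to end:

```bash
codroplet featurize     --fasta proteins.fasta --out store.h5 --seed 1
codroplet build-dataset --condensates cdcode.tsv --fasta proteins.fasta \
                        --n-max 50 --m 12 --split 0.8 --seed 1 \
                        --out-train train.tsv --out-test test.tsv
codroplet train         --pairs train.tsv --features store.h5 --out ckpt.npz
codroplet eval          --pairs test.tsv --features store.h5 --params ckpt.npz \
                        --report report.json
codroplet predict       --features store.h5 --pairs pairs.tsv --params ckpt.npz \
                        --out scores.csv
codroplet analyze mlo|scaffold|proteome --scores scores.csv ...
```

Every artifact gets a `.meta.json` sidecar recording the resolved options
and seed; identical seeds reproduce every artifact byte for byte.

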