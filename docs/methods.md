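# Methods

## The prediction problem

Biomolecular condensates (membraneless organelles such as nucleoli, P-bodies
and stress granules) form by liquid–liquid phase separation of proteins and
nucleic acids. `codroplet` scores an unordered pair of proteins for its
*co-condensation propensity* — the probability that the two proteins
partition into the same condensate — from AlphaFold2-style residue
representations, and provides everything around that score: dataset
construction from condensate membership tables, training and evaluation, and
the downstream condensate analyses.

## Input representations

Each protein enters as three arrays produced upstream (in production, by the
Evoformer and structure module of AlphaFold2; here, optionally by a surrogate
generator):

| array | shape | role |
| --- | --- | --- |
| `f_msa` | `L × 384` | single (MSA-derived) representation |
| `f_pair` | `L × L × 128` | pair representation (inter-residue relations) |
| `f_struc` | `L × 384` | structure-module representation |

The channel widths are fixed contracts of the bundle type; `L` is the
residue count. Sequences longer than 1,024 residues are excluded from the
datasets (exclusion, not truncation).

## Architecture

1. **Protein encoder.** `f_msa` and `f_struc` each pass through a Transition
   block (layer norm → linear ×4 expansion → ReLU → linear) followed by a
   layer norm, are concatenated residue-wise (768 channels) and projected by
   a Transition to the node dimension `c_n` (default 256). `f_pair` passes
   through a Transition + layer norm and a Transition projection to
   `c_e − 1 = 31` edge channels. Both proteins use the same encoder weights.
2. **Complex combination.** Residues of the two chains are concatenated;
   inter-chain edge blocks are zero-padded in the encoded channels; the
   reserved last edge channel carries the binary same-chain/different-chain
   indicator (two copies of the same protein are still marked as different
   chains).
3. **Transformer stack.** Eight (default) blocks of gated multi-head
   self-attention with pair bias followed by node and edge Transitions, all
   residual and passed through dropout during training. Per head, attention
   logits are `q·k/√c'` with an additive scalar bias projected from the edge
   features; node outputs are sigmoid-gated value aggregates. The updated
   edge features are computed from the **pre-bias, pre-softmax** logits
   through a two-layer MLP — the original algorithm listing orders the edge
   update before the bias addition, and that order is implemented literally
   even though the AlphaFold2 convention differs.
4. **Prediction head.** Per-residue layer norm → dropout → two-layer MLP,
   average pooling over *all* residues of the complex into one vector, then
   a three-layer MLP and a sigmoid. Training minimises binary cross-entropy
   plus `λ·Σw²` over the weight matrices (λ default `1e-4`).

Ambiguities resolved as package design choices:

* The Transition block is dimension-preserving in the stack but the encoder
  assigns its outputs to new widths; the second linear simply targets the
  required output dimension.
* Whether `f_pair` is layer-normed before or after its Transition is not
  decidable from the garbled source line; the implementation applies
  Transition first, then layer norm, matching the unambiguous treatment of
  `f_msa` and `f_struc`.
* The head pools the combined complex's residues together (not per chain).
* Pair order: a co-condensation propensity is physically order-free, so
  `predict_pair` defaults to symmetrizing — the mean of the two chain
  orders — with a flag to disable.

## Training

Per the published recipe: minibatches of 4 pairs, per-epoch resampling of
the minority class to a 1:1 ratio, 40 epochs by default with a 20-epoch
continuation phase on the self-pair-expanded dataset. The optimizer and
learning rate are unstated upstream; the package uses Adam
(β₁ = 0.9, β₂ = 0.999) with default learning rate `1e-4`, configurable, and
dropout rates of 0.1 for attention, transition and head (also unstated
upstream, set to common transformer practice). All randomness — parameter
initialisation, resampling, shuffling, dropout masks — derives from the
single config seed, making runs bit-reproducible.

No deep-learning framework is used: forward and backward passes run on a
small reverse-mode tape over numpy (`codroplet.autodiff`), whose gradients
are verified against central finite differences (relative 1e-3 over randomly
chosen parameters; observed agreement is ~1e-6). Training can run in float32
(`ModelConfig(dtype="float32")`), which roughly halves CPU time; evaluation
metrics are computed in float64.

## Datasets from condensate tables

* **Positives:** all unordered within-condensate pairs from condensates with
  at most `n_max = 50` members; duplicates across condensates are merged
  with the union of their source condensates.
* **Negatives:** candidate proteins are members of condensates with at most
  `m = 12` members; every candidate pair co-occurring in *no* condensate of
  the full table is a negative. (The original description quotes both
  `m = 5` and `m = 12` in different places; both are the same flag here,
  defaulting to the concluding value 12.)
* **Self pairs:** `(P, P)` positives for every condensate protein; `(Q, Q)`
  negatives for proteins outside all condensates with no direct
  protein–protein-interaction edge (InWeb3-style network) to any condensate
  protein. Both pools pass the redundancy filter. Self pairs are used in a
  continued-training phase (20 epochs) on the expanded dataset.
* **Redundancy filter:** greedy longest-first selection keeping a sequence
  only if its global-alignment identity (matches / alignment columns,
  Biopython pairwise aligner) to every kept sequence is ≤ 0.5. The
  comparator is pluggable since the original filtering tool is unnamed.
* **Split:** condensates are assigned whole to train or test (random order,
  greedy until the train side holds ~80% of within-condensate pair weight);
  a positive pair must have *all* its source condensates on one side, else
  it is dropped (logged). This guarantees that no condensate contributes
  positive pairs to both sides. Negatives are split at the same fraction.

## The surrogate feature generator

Running AlphaFold2 is out of scope, so tests and desk-scale training use a
surrogate world in which the truth is planted. Each protein carries a latent
compatibility vector `v ∈ R^8` (its cluster center, unit norm); the
generator embeds the residue one-hot identity and `v` through fixed
seed-derived Gaussian projection bases into `f_msa` and `f_struc`, and
builds `f_pair[i, j]` from a projection of the elementwise product of the
two residues' embeddings, so pairwise structure exists for the attention
bias to exploit. Gaussian noise (default σ = 0.1 against signal entries of
order 1) is added from a per-protein stream, keeping regeneration
bit-reproducible. At zero noise the latent vector is exactly linearly
decodable from the `f_msa` row means (verified by a least-squares oracle).

What the surrogate does *not* emulate: realistic sequence lengths and
compositions, structural correlations between the three representations,
evolutionary covariation, or any real condensate biology. Passing the
planted-recovery tests therefore shows that the architecture and training
loop can extract a pairwise-compatibility signal of this kind — it says
nothing about accuracy on real condensate data, which requires genuine
AlphaFold2 features and the curated condensate tables.

## Desk-scale study conditions

The learnability benchmark trains the complete pipeline (encoder →
combination → stack → head) at reduced width and depth chosen once for a
single-CPU numpy budget: `c_n = 32`, `c_e = 8`, 2 heads, 2 layers, float32
(`ModelConfig.desk_scale()`); feature dimensions stay at the production
384/128/384. Conditions: 60 proteins of length 8–12 in two latent clusters,
200 balanced training pairs, 600 balanced held-out pairs, 20 epochs at
minibatch 4, learning rate `1e-3`. A sound implementation reaches held-out
ROC-AUC ≥ 0.9 (typically 1.0); the same protocol with shuffled labels stays
at 0.5 ± 0.05. The larger held-out set narrows the sampling noise of the
chance-level AUC (null standard deviation ≈ 0.024).

## Evaluation metrics

Confusion matrix at a 0.5 threshold (configurable; unstated upstream),
accuracy, precision, recall, F1, Matthews correlation coefficient, and the
empirical ROC curve swept over all distinct score thresholds with
trapezoidal AUC. Metrics with zero denominators are reported as NaN and
flagged (`undefined`), never silently zeroed — except MCC, which takes the
conventional value 0 when a marginal is empty. AUC equals the Mann–Whitney
U statistic divided by `n₊·n₋` (tested against scipy and scikit-learn).

## Analyses

* **MLO vs random:** within-set pairwise score distributions for an MLO
  protein set against five (default) size-matched random subsets of a
  background pool, sampled without replacement, seeded; medians reported.
* **Scaffold–client:** mean scaffold score against an in-set vs an out-set
  of partners, with the raw per-pair lists.
* **Proteome partner counts:** partners are pairs scoring strictly above
  0.8 (default); quintile partition takes the top and bottom `⌊n/5⌋`
  proteins by partner count (ties broken by id).
* **Composition contrast:** per-protein residue fractions; per amino acid,
  difference of set means, standard error `√(s₁²/n₁ + s₂²/n₂)` and a Welch
  two-sample t-test. The category map is configurable with defaults
  positively charged {R,K,H}, negatively charged {D,E}, aromatic {F,W,Y},
  disorder-promoting {G,P,S,A}, hydrophobic {L,I,V,M,C}, hydrophilic
  {N,Q,T}.

## Known limitations

* Real-data performance is out of reach here by construction: it requires
  genuine AlphaFold2 representations, the curated condensate/interaction
  databases and the originally trained weights.
* The numpy training path is single-threaded and desk-scale; production
  widths (`c_n = 256`, 8 layers, length-1,024 proteins) are supported by the
  code but not by a CPU time budget.
* Cross-condensate generalisation on surrogate data requires the latent
  clusters to span several condensates; a cluster confined to a single
  held-out condensate presents an unseen latent center, which no classifier
  of this form can be expected to score correctly.
* The greedy redundancy filter is O(n²) alignments; for large cohorts an
  external clustering tool can be plugged in as the comparator.
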