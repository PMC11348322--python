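"""Planted-signal benchmark: the surrogate world where the truth is known.

Proteins are assigned to latent compatibility clusters; a pair is labeled
positive iff both proteins share a cluster.  Because the cluster vector is
planted into every feature bundle by the surrogate generator, a sound
implementation of the architecture and training loop must recover the labels
on held-out pairs — and must *not* beat chance when the labels are shuffled.
"""

from __future__ import annotations

import itertools

import numpy as np

from .dataset import PairExample
from .features import LatentProfile, generate_cohort
from .network import ModelConfig
from .training import TrainConfig, evaluate, train

__all__ = ["make_planted_pairs", "planted_learnability"]


def make_planted_pairs(profiles: list[LatentProfile], n_per_class: int, seed: int = 0,
                       shuffle_labels: bool = False) -> list[PairExample]:
    """Sample a balanced labeled pair set from cluster co-membership.

    Positives are same-cluster pairs, negatives cross-cluster pairs, each
    sampled without replacement.  With ``shuffle_labels`` the labels are
    permuted across the sampled pairs, destroying the signal while keeping
    the class balance (the chance-level control).
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x9A185]))
    same = [(a.protein_id, b.protein_id)
            for a, b in itertools.combinations(profiles, 2) if a.cluster_id == b.cluster_id]
    diff = [(a.protein_id, b.protein_id)
            for a, b in itertools.combinations(profiles, 2) if a.cluster_id != b.cluster_id]
    if n_per_class > len(same) or n_per_class > len(diff):
        raise ValueError(f"requested {n_per_class} pairs per class, have "
                         f"{len(same)} same-cluster and {len(diff)} cross-cluster")
    pos_idx = rng.choice(len(same), size=n_per_class, replace=False)
    neg_idx = rng.choice(len(diff), size=n_per_class, replace=False)
    labels = [1] * n_per_class + [0] * n_per_class
    chosen = [same[i] for i in pos_idx] + [diff[i] for i in neg_idx]
    if shuffle_labels:
        labels = list(rng.permutation(labels))
    pairs = [PairExample(a, b, int(y)) for (a, b), y in zip(chosen, labels)]
    rng.shuffle(pairs)
    return pairs


def planted_learnability(
    n_proteins: int = 60,
    length: tuple[int, int] = (8, 12),
    n_train_per_class: int = 100,
    n_test_per_class: int = 50,
    epochs: int = 20,
    noise_sd: float = 0.1,
    seed: int = 0,
    shuffle_labels: bool = False,
    config: TrainConfig | None = None,
) -> dict:
    """Train on planted two-cluster surrogate data and report held-out metrics.

    Defaults are the desk-scale conditions: ~60 short proteins in two latent
    clusters, 200 balanced training pairs, 20 epochs at minibatch four, with
    the narrow CPU architecture.  Returns the held-out :class:`EvalReport`
    fields plus the loss history.
    """
    _, profiles, bundles = generate_cohort(n_proteins, length=length, n_clusters=2,
                                           noise_sd=noise_sd, seed=seed)
    feature_map = {b.protein_id: b for b in bundles}
    all_pairs = make_planted_pairs(profiles, n_train_per_class + n_test_per_class,
                                   seed=seed, shuffle_labels=shuffle_labels)
    # split keeps the classes balanced on both sides
    pos = [p for p in all_pairs if p.label == 1]
    neg = [p for p in all_pairs if p.label == 0]
    train_pairs = pos[:n_train_per_class] + neg[:n_train_per_class]
    test_pairs = pos[n_train_per_class:] + neg[n_train_per_class:]
    if config is None:
        config = TrainConfig(epochs=epochs, batch_size=4, learning_rate=1e-3,
                             l2_lambda=1e-4, seed=seed, model=ModelConfig.desk_scale())
    params, history = train(train_pairs, feature_map, config)
    report = evaluate(params, test_pairs, feature_map, config.model)
    return {
        "auc": report.auc,
        "accuracy": report.accuracy,
        "mcc": report.mcc,
        "report": report,
        "history": history,
        "n_train": len(train_pairs),
        "n_test": len(test_pairs),
        "params": params,
        "config": config,
    }
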