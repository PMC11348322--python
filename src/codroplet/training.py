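"""Training loop and evaluation metrics for the pair classifier.

Training follows the published recipe: per-epoch resampling to a 1:1 class
ratio, minibatches of four pairs, binary cross-entropy with an L2 penalty on
the weight matrices, and 40 epochs by default (20 for the continuation phase
on the self-pair-expanded dataset).  The update rule is Adam.  Evaluation
reports the full confusion matrix, accuracy, precision, recall, F1, the
empirical ROC curve with trapezoidal AUC, and the Matthews correlation
coefficient.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np

from . import network
from .dataset import PairExample, rebalance, split_by_condensate, SplitSpec, CondensateTable
from .features import FeatureBundle, list_features, load_features
from .network import ModelConfig, as_tensors, combine_complex, pps_head, transformer_stack

logger = logging.getLogger(__name__)

__all__ = ["TrainConfig", "EvalReport", "train", "evaluate", "compute_metrics",
           "f1_from_precision_recall", "roc_curve", "cross_validate", "score_pairs"]


def f1_from_precision_recall(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall."""
    if precision + recall == 0:
        return float("nan")
    return 2.0 * precision * recall / (precision + recall)


@dataclass
class TrainConfig:
    """Hyperparameters of one training run."""

    epochs: int = 40
    continuation_epochs: int = 20
    batch_size: int = 4
    l2_lambda: float = 1e-4
    learning_rate: float = 1e-4
    seed: int = 0
    max_len: int = 1024
    model: ModelConfig = field(default_factory=ModelConfig)

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")


@dataclass
class EvalReport:
    """Confusion matrix plus the scalar metric suite."""

    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float
    precision: float
    recall: float
    f1: float
    mcc: float
    auc: float
    roc_points: list
    decision_threshold: float = 0.5
    undefined: frozenset = frozenset()

    def to_dict(self) -> dict:
        """JSON-safe dict; undefined (NaN) metrics become ``None``."""
        def clean(x):
            return None if isinstance(x, float) and math.isnan(x) else x

        return {
            "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
            "accuracy": clean(self.accuracy), "precision": clean(self.precision),
            "recall": clean(self.recall), "f1": clean(self.f1), "mcc": clean(self.mcc),
            "auc": clean(self.auc), "decision_threshold": self.decision_threshold,
            "roc_points": [list(p) for p in self.roc_points],
            "undefined": sorted(self.undefined),
        }


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def roc_curve(scores, labels) -> list[tuple[float, float]]:
    """Empirical ROC points swept over all distinct score thresholds.

    Returns (fpr, tpr) pairs from (0, 0) to (1, 1), monotone nondecreasing in
    both coordinates.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC requires both classes")
    order = np.argsort(-scores, kind="stable")
    sorted_scores = scores[order]
    sorted_labels = labels[order]
    points = [(0.0, 0.0)]
    tp = fp = 0
    for i in range(len(sorted_scores)):
        tp += int(sorted_labels[i] == 1)
        fp += int(sorted_labels[i] == 0)
        if i + 1 < len(sorted_scores) and sorted_scores[i + 1] == sorted_scores[i]:
            continue  # ties: emit one point per distinct threshold
        points.append((fp / n_neg, tp / n_pos))
    return points


def _trapezoid_auc(points) -> float:
    xs = np.array([p[0] for p in points])
    ys = np.array([p[1] for p in points])
    return float(np.trapezoid(ys, xs))


def compute_metrics(tp: int, fp: int, tn: int, fn: int,
                    scores=None, labels=None, threshold: float = 0.5) -> EvalReport:
    """Metric suite from a confusion matrix (AUC/ROC if scores are given).

    Division-by-zero cases are reported as NaN and flagged in ``undefined``
    rather than raised — except MCC, which takes the conventional value 0
    when any marginal is empty (the correlation of a constant vector).
    """
    if min(tp, fp, tn, fn) < 0:
        raise ValueError("confusion-matrix counts must be nonnegative")
    total = tp + fp + tn + fn
    undefined: set[str] = set()

    def ratio(num, den, name):
        if den == 0:
            undefined.add(name)
            return float("nan")
        return num / den

    accuracy = ratio(tp + tn, total, "accuracy")
    precision = ratio(tp, tp + fp, "precision")
    recall = ratio(tp, tp + fn, "recall")
    if math.isnan(precision) or math.isnan(recall) or (precision + recall) == 0:
        undefined.add("f1")
        f1 = float("nan")
    else:
        f1 = 2 * precision * recall / (precision + recall)
    denom = math.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = 0.0 if denom == 0 else (tp * tn - fp * fn) / denom

    auc = float("nan")
    points: list = []
    if scores is not None and labels is not None:
        try:
            points = roc_curve(scores, labels)
            auc = _trapezoid_auc(points)
        except ValueError:
            undefined.add("auc")
    else:
        undefined.add("auc")
    return EvalReport(tp=tp, fp=fp, tn=tn, fn=fn, accuracy=accuracy,
                      precision=precision, recall=recall, f1=f1, mcc=mcc,
                      auc=auc, roc_points=points, decision_threshold=threshold,
                      undefined=frozenset(undefined))


# ---------------------------------------------------------------------------
# Feature access
# ---------------------------------------------------------------------------

def _as_feature_map(features) -> dict[str, FeatureBundle]:
    """Accept a mapping id -> bundle, a list of bundles, or a store path."""
    if isinstance(features, dict):
        return features
    if isinstance(features, (list, tuple)):
        return {b.protein_id: b for b in features}
    return {pid: load_features(features, pid) for pid in list_features(features)}


def _bundle(feature_map, protein_id: str) -> FeatureBundle:
    try:
        return feature_map[protein_id]
    except KeyError:
        raise KeyError(f"no features for protein {protein_id!r} in the feature store") from None


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def _batch_loss(batch: list[PairExample], feature_map, tparams, model: ModelConfig, rng):
    """Mean BCE over a minibatch (one shared tape; L2 is added analytically).

    Proteins appearing in several pairs of the batch are encoded once.
    """
    unique_ids = sorted({pid for p in batch for pid in (p.id_a, p.id_b)})
    bundles = [_bundle(feature_map, pid) for pid in unique_ids]
    reps = dict(zip(unique_ids, network.encode_proteins(bundles, tparams, model)))
    total = None
    for pair in batch:
        complex_rep = combine_complex(reps[pair.id_a], reps[pair.id_b])
        out_rep = transformer_stack(complex_rep, tparams, model, training=True, rng=rng)
        pred = pps_head(out_rep, tparams, model, label=pair.label, training=True, rng=rng)
        total = pred.loss_tensor if total is None else total + pred.loss_tensor
    return total / len(batch)


def train(train_pairs: list[PairExample], features, config: TrainConfig,
          init_params: dict | None = None, heldout_pairs: list[PairExample] | None = None,
          eval_every: int = 0):
    """Train the network; returns ``(params, history)``.

    ``history`` is a list of per-epoch dicts with the mean minibatch loss and,
    if ``heldout_pairs`` is given and ``eval_every`` > 0, the held-out AUC.
    Fully deterministic for a fixed ``config.seed``.
    """
    feature_map = _as_feature_map(features)
    for pair in train_pairs:
        _bundle(feature_map, pair.id_a), _bundle(feature_map, pair.id_b)

    model = config.model
    source = init_params if init_params is not None else network.init_params(model, config.seed)
    drop_rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 0xD0]))

    # flat parameter/Adam buffers: the per-name dict holds views into `flat`,
    # so one vectorised update serves every weight matrix at once
    names = sorted(source)
    shapes = {k: source[k].shape for k in names}
    sizes = {k: int(np.prod(shapes[k])) for k in names}
    dt = np.dtype(model.dtype)
    flat = np.concatenate([np.asarray(source[k], dtype=dt).ravel() for k in names])
    params: dict[str, np.ndarray] = {}
    offset = 0
    for k in names:
        params[k] = flat[offset:offset + sizes[k]].reshape(shapes[k])
        offset += sizes[k]
    weight_mask = np.concatenate([
        np.full(sizes[k], 1.0 if k.endswith(".w") else 0.0, dtype=dt) for k in names])
    grad_flat = np.zeros_like(flat)
    m = np.zeros_like(flat)
    v = np.zeros_like(flat)
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0

    history = []
    for epoch in range(config.epochs):
        epoch_pairs = rebalance(train_pairs, seed=config.seed + epoch) \
            if _both_classes(train_pairs) else list(train_pairs)
        losses = []
        for start in range(0, len(epoch_pairs), config.batch_size):
            batch = epoch_pairs[start:start + config.batch_size]
            tparams = as_tensors(params, trainable=True)
            loss = _batch_loss(batch, feature_map, tparams, model, drop_rng)
            loss.backward()
            offset = 0
            for k in names:
                g = tparams[k].grad
                seg = grad_flat[offset:offset + sizes[k]]
                if g is None:
                    seg[:] = 0.0
                else:
                    seg[:] = g.ravel()
                offset += sizes[k]
            # analytic gradient and value of the L2 term lambda * sum(w^2)
            if config.l2_lambda > 0:
                grad_flat += (2.0 * config.l2_lambda) * (flat * weight_mask)
                l2_val = config.l2_lambda * float(np.dot(flat * weight_mask, flat))
            else:
                l2_val = 0.0
            losses.append(float(loss.data) + l2_val)
            step += 1
            m *= beta1
            m += (1 - beta1) * grad_flat
            v *= beta2
            v += (1 - beta2) * grad_flat * grad_flat
            bc1 = 1.0 - beta1 ** step
            bc2 = 1.0 - beta2 ** step
            flat -= config.learning_rate * (m / bc1) / (np.sqrt(v / bc2) + eps)
        record = {"epoch": epoch + 1, "loss": float(np.mean(losses))}
        if heldout_pairs and eval_every and (epoch + 1) % eval_every == 0:
            record["heldout_auc"] = evaluate(params, heldout_pairs, feature_map, model).auc
        history.append(record)
        logger.info("epoch %d: loss %.4f", epoch + 1, record["loss"])
    return {k: params[k].copy() for k in names}, history


def _both_classes(pairs) -> bool:
    labels = {p.label for p in pairs}
    return labels == {0, 1}


def score_pairs(params, pairs, features, model: ModelConfig) -> np.ndarray:
    """Eval-mode scores for a list of pairs (symmetrized per the config)."""
    feature_map = _as_feature_map(features)
    return np.array([
        network.predict_pair(_bundle(feature_map, p.id_a), _bundle(feature_map, p.id_b),
                             params, model)
        for p in pairs
    ])


def evaluate(params, test_pairs: list[PairExample], features, model: ModelConfig,
             threshold: float = 0.5) -> EvalReport:
    """Score the test pairs in eval mode and compute the metric suite."""
    if not test_pairs:
        raise ValueError("test set is empty")
    scores = score_pairs(params, test_pairs, features, model)
    labels = np.array([p.label for p in test_pairs])
    preds = (scores > threshold).astype(int)
    tp = int(((preds == 1) & (labels == 1)).sum())
    fp = int(((preds == 1) & (labels == 0)).sum())
    tn = int(((preds == 0) & (labels == 0)).sum())
    fn = int(((preds == 0) & (labels == 1)).sum())
    return compute_metrics(tp, fp, tn, fn, scores=scores, labels=labels, threshold=threshold)


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------

def cross_validate(pairs: list[PairExample], features, configs: list[TrainConfig],
                   k_folds: int, condensates: CondensateTable, seed: int = 0):
    """Condensate-aware k-fold selection of the best training configuration.

    Folds are built by repeatedly applying the condensate-aware splitter so
    no condensate leaks positives across a fold boundary.  The config with
    the highest mean held-out AUC wins; ties break toward smaller
    ``l2_lambda``, then smaller ``learning_rate``.
    """
    if k_folds < 2:
        raise ValueError("k_folds must be >= 2")
    folds = []
    for i in range(k_folds):
        spec = SplitSpec(train_fraction=1.0 - 1.0 / k_folds, seed=seed + i)
        train_p, test_p = split_by_condensate(pairs, condensates, spec)
        if not test_p or not _both_classes(test_p):
            logger.warning("fold %d is degenerate; skipped", i)
            continue
        folds.append((train_p, test_p))
    if not folds:
        raise ValueError("no usable folds")

    results = []
    for cfg in configs:
        aucs = []
        for fold_idx, (train_p, test_p) in enumerate(folds):
            fold_cfg = replace(cfg, seed=cfg.seed + fold_idx)
            params, _ = train(train_p, features, fold_cfg)
            report = evaluate(params, test_p, features, fold_cfg.model)
            aucs.append(report.auc)
        results.append({"config": cfg, "fold_aucs": aucs, "mean_auc": float(np.nanmean(aucs))})
    best = max(results, key=lambda r: (r["mean_auc"], -r["config"].l2_lambda,
                                       -r["config"].learning_rate))
    return best["config"], results
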