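"""Model/Results interface over the training machinery.

``CoDropleT`` bundles a labeled pair dataset, a feature source and a
training configuration; ``fit()`` runs the training loop and returns a
``CoDropleTResults`` carrying the learned parameters, the loss history and
the evaluation/prediction methods, with a ``summary()`` table in the style
of the classical statistical modelling packages.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import network, training
from .dataset import PairExample
from .training import EvalReport, TrainConfig

__all__ = ["CoDropleT", "CoDropleTResults"]


class CoDropleT:
    """Co-condensation propensity model over labeled protein pairs."""

    def __init__(self, train_pairs: list[PairExample], features,
                 config: TrainConfig | None = None):
        if not train_pairs:
            raise ValueError("train_pairs must be nonempty")
        self.train_pairs = list(train_pairs)
        self.features = training._as_feature_map(features)
        self.config = config if config is not None else TrainConfig()

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, features,
                       config: TrainConfig | None = None) -> "CoDropleT":
        """Build from a frame with columns protein_a, protein_b, label."""
        pairs = [
            PairExample(str(r.protein_a), str(r.protein_b), int(r.label))
            for r in df.itertuples(index=False)
        ]
        return cls(pairs, features, config)

    def fit(self, init_params: dict | None = None,
            heldout_pairs: list[PairExample] | None = None,
            eval_every: int = 0) -> "CoDropleTResults":
        params, history = training.train(
            self.train_pairs, self.features, self.config,
            init_params=init_params, heldout_pairs=heldout_pairs, eval_every=eval_every,
        )
        return CoDropleTResults(self, params, history)


class CoDropleTResults:
    """Fitted parameters plus prediction, evaluation and reporting."""

    def __init__(self, model: CoDropleT, params: dict, history: list[dict]):
        self.model = model
        self.params = params
        self.history = history

    @property
    def config(self) -> TrainConfig:
        return self.model.config

    def predict(self, pairs: list[PairExample], features=None) -> np.ndarray:
        """Symmetrized eval-mode scores for each pair."""
        feats = self.model.features if features is None else training._as_feature_map(features)
        return training.score_pairs(self.params, pairs, feats, self.config.model)

    def evaluate(self, test_pairs: list[PairExample], features=None,
                 threshold: float = 0.5) -> EvalReport:
        feats = self.model.features if features is None else training._as_feature_map(features)
        return training.evaluate(self.params, test_pairs, feats, self.config.model, threshold)

    def continue_training(self, pairs: list[PairExample], epochs: int | None = None
                          ) -> "CoDropleTResults":
        """Continuation phase (e.g. on the self-pair-expanded dataset)."""
        from dataclasses import replace
        cfg = replace(self.config, epochs=epochs or self.config.continuation_epochs,
                      seed=self.config.seed + 1)
        sub = CoDropleT(pairs, self.model.features, cfg)
        fitted = sub.fit(init_params=self.params)
        fitted.history = self.history + fitted.history
        return fitted

    def save(self, path) -> None:
        network.save_checkpoint(path, self.params, self.config.model)

    def summary(self) -> str:
        cfg, mc = self.config, self.config.model
        n_params = sum(int(np.prod(v.shape)) for v in self.params.values())
        n_pos = sum(p.label for p in self.model.train_pairs)
        n = len(self.model.train_pairs)
        lines = [
            "          Co-condensation propensity model",
            "=" * 56,
            f"{'Training pairs:':<28}{n} ({n_pos} positive / {n - n_pos} negative)",
            f"{'Epochs:':<28}{cfg.epochs}    Batch size: {cfg.batch_size}",
            f"{'Learning rate:':<28}{cfg.learning_rate:g}    L2 lambda: {cfg.l2_lambda:g}",
            f"{'Architecture:':<28}c_n={mc.c_n}, c_e={mc.c_e}, "
            f"{mc.n_layers} layers, {mc.n_head} heads",
            f"{'Parameters:':<28}{n_params}",
            f"{'Seed:':<28}{cfg.seed}",
        ]
        if self.history:
            lines.append(f"{'Initial / final loss:':<28}"
                         f"{self.history[0]['loss']:.4f} / {self.history[-1]['loss']:.4f}")
            aucs = [h["heldout_auc"] for h in self.history if "heldout_auc" in h]
            if aucs:
                lines.append(f"{'Last held-out AUC:':<28}{aucs[-1]:.4f}")
        lines.append("=" * 56)
        return "\n".join(lines)
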