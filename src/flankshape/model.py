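"""Model/Results interface for per-feature shape prediction.

:class:`ShapeFeatureModel` bundles a training corpus with a feature
definition and hyperparameters; :meth:`ShapeFeatureModel.fit` trains the
network and returns a :class:`ShapeFeatureResults` carrying the trained
weights, the loss trajectory, diagnostics, and prediction/plotting methods.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np

from .features import NormalizationStats, ShapeFeatureSpec, compute_norm_stats, normalize
from .network import ModelConfig, ShapeNet, receptive_radius
from .training import (
    TrainingExample,
    TrainingRun,
    evaluate_layerwise_mae,
    load_training_file,
    train_feature_model,
)

__all__ = ["ShapeFeatureModel", "ShapeFeatureResults"]


class ShapeFeatureModel:
    """A per-feature shape network specified against a training corpus.

    Parameters
    ----------
    examples : raw training examples (values on the feature's own scale,
        NaN/False-mask at undefined positions).  Normalization stats are
        computed from the pooled defined values unless supplied.
    feature : the shape feature being modelled (fixes node kind/channels).
    config : hyperparameters; defaults to the published operating point.
    """

    def __init__(
        self,
        examples: Sequence[TrainingExample],
        feature: ShapeFeatureSpec,
        config: ModelConfig | None = None,
        stats: NormalizationStats | None = None,
    ) -> None:
        if not examples:
            raise ValueError("empty training set")
        self.feature = feature
        self.config = config or ModelConfig()
        self.examples = list(examples)
        if stats is None:
            pooled = np.concatenate([ex.raw[ex.mask] for ex in self.examples])
            stats = compute_norm_stats(pooled)
        self.stats = stats
        for ex in self.examples:
            if ex.targets is None:
                ex.targets = np.where(
                    ex.mask, normalize(np.nan_to_num(ex.raw), stats), np.nan
                )

    @classmethod
    def from_training_file(
        cls,
        path: str | Path,
        feature: ShapeFeatureSpec,
        config: ModelConfig | None = None,
    ) -> "ShapeFeatureModel":
        examples, stats = load_training_file(path, feature)
        return cls(examples, feature, config=config, stats=stats)

    def fit(self, seed: int | None = None, callback=None) -> "ShapeFeatureResults":
        """Train with SGD + momentum on the masked multi-layer MAE loss."""
        run = train_feature_model(
            self.examples, self.feature, self.config,
            stats=self.stats, seed=seed, callback=callback,
        )
        return ShapeFeatureResults(self, run)


class ShapeFeatureResults:
    """Fitted per-feature shape model.

    Exposes raw-scale prediction at any flanking depth, the training loss
    history, layer-wise diagnostics, perturbation-probed receptive radius,
    and single-file save/load.
    """

    def __init__(self, model: ShapeFeatureModel, run: TrainingRun) -> None:
        self.model = model
        self.net = run.net
        self.config = run.config
        self.seed = run.seed
        self.loss_history = run.loss_history
        self.stats = model.stats
        self.feature = model.feature

    # -- prediction ---------------------------------------------------- #

    def predict(self, seq: str, depth: int | None = None,
                symmetrize: bool = False) -> np.ndarray:
        """Raw-scale profile; ``depth`` selects how many flanking bp the
        prediction may draw on (default: the deepest layer)."""
        return self.net.predict(seq, depth=depth, symmetrize=symmetrize)

    def predict_normalized(self, seq: str, depth: int | None = None) -> np.ndarray:
        return self.net.forward_sequence(seq, depth=depth)

    def receptive_radius(self, depth: int | None = None, seed: int = 0) -> int:
        return receptive_radius(self.net, depth=depth, seed=seed)

    def layerwise_mae(self, examples: Sequence[TrainingExample] | None = None) -> np.ndarray:
        """Masked per-layer MAE (normalized scale); defaults to training data."""
        return evaluate_layerwise_mae(self.net, examples or self.model.examples)

    # -- reporting ----------------------------------------------------- #

    def summary(self) -> str:
        L = self.config.n_shape_layers
        mae = self.layerwise_mae()
        lines = [
            f"Shape feature model: {self.feature.name} "
            f"({self.feature.node_kind}, {self.feature.units})",
            "=" * 64,
            f"{'shape layers':<28}{L}",
            f"{'filter size':<28}{self.config.filter_size}",
            f"{'epochs':<28}{self.config.epochs}",
            f"{'learning rate / momentum':<28}"
            f"{self.config.learning_rate} / {self.config.momentum}",
            f"{'dropout ratio':<28}{self.config.dropout_ratio}",
            f"{'seed':<28}{self.seed}",
            f"{'training sequences':<28}{len(self.model.examples)}",
            f"{'norm median [p1, p99]':<28}{self.stats.median:.4g} "
            f"[{self.stats.p1:.4g}, {self.stats.p99:.4g}]",
            f"{'final training loss':<28}{self.loss_history[-1]:.6g}",
            "-" * 64,
            "layer   flank bp   train MAE (normalized)",
        ]
        for l in range(L):
            lines.append(f"{l + 1:>5}   {l + 1:>8}   {mae[l]:.6g}")
        return "\n".join(lines)

    # -- persistence --------------------------------------------------- #

    def save(self, path: str | Path) -> None:
        self.net.save(path)

    @staticmethod
    def load_net(path: str | Path) -> ShapeNet:
        """Load the network artifact alone (prediction-only use)."""
        return ShapeNet.load(path)

    # -- plotting ------------------------------------------------------ #

    def plot_loss(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(np.arange(1, len(self.loss_history) + 1), self.loss_history)
        ax.set_xlabel("epoch")
        ax.set_ylabel("training loss (masked MAE)")
        ax.set_title(f"{self.feature.name} training")
        return ax

    def plot_profile(self, seq: str, depth: int | None = None,
                     symmetrize: bool = False, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        prof = self.predict(seq, depth=depth, symmetrize=symmetrize)
        ax.plot(np.arange(1, prof.size + 1), prof, marker="o")
        ax.set_xlabel("position (1-based)")
        ax.set_ylabel(f"{self.feature.name} ({self.feature.units})")
        return ax
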