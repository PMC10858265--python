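"""Per-feature model training: masked multi-layer MAE loss, SGD with
momentum, the training-file dialect, and a small grid search.

Training files pair sequences with position-wise raw shape values; undefined
positions (e.g. groove width at terminal base pairs) carry ``NA`` and are
excluded from both the normalization statistics and the loss.  Every layer's
head contributes to the loss with equal weight, which trains the model to
predict well at *every* flanking-region depth, not only the deepest one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np

from .encoding import add_caps, encode_for
from .features import NormalizationStats, ShapeFeatureSpec, compute_norm_stats, normalize
from .network import ModelConfig, ShapeNet

__all__ = [
    "TrainingExample",
    "TrainingRun",
    "TrainingDivergedError",
    "load_training_file",
    "write_training_file",
    "attach_targets",
    "multi_layer_masked_mae",
    "train_feature_model",
    "grid_search",
    "evaluate_layerwise_mae",
]


def attach_targets(
    examples: Sequence["TrainingExample"], stats: NormalizationStats
) -> Sequence["TrainingExample"]:
    """Normalize raw values into each example's ``targets`` in place."""
    for ex in examples:
        ex.targets = np.where(
            ex.mask, normalize(np.nan_to_num(ex.raw), stats), np.nan
        )
    return examples


class TrainingDivergedError(RuntimeError):
    """Raised when the training loss becomes non-finite."""


@dataclass
class TrainingExample:
    """One sequence with raw values, a defined-mask, and normalized targets.

    ``raw`` keeps NaN at masked positions; ``targets`` is the normalized copy
    (NaN at masked positions, never read by the loss).
    """

    seq_id: str
    sequence: str
    raw: np.ndarray
    mask: np.ndarray
    targets: np.ndarray | None = None

    def n_nodes(self, node_kind: str) -> int:
        return len(self.sequence) - 1 if node_kind == "per-step" else len(self.sequence)


@dataclass
class TrainingRun:
    """Outcome of one training: config, seed, loss history, trained net."""

    config: ModelConfig
    seed: int
    loss_history: np.ndarray
    net: ShapeNet


def load_training_file(
    path: str | Path, feature: ShapeFeatureSpec
) -> tuple[list[TrainingExample], NormalizationStats]:
    """Read a per-feature training TSV.

    Dialect: ``seq_id<TAB>sequence<TAB>v1,v2,...`` with ``NA`` for undefined
    positions; per-step features carry n-1 values per n-mer.  Normalization
    statistics are pooled over all defined values and the targets are stored
    normalized.
    """
    examples: list[TrainingExample] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 tab-separated fields")
            seq_id, seq, values = parts
            tokens = values.split(",")
            expected = len(seq) - 1 if feature.node_kind == "per-step" else len(seq)
            if len(tokens) != expected:
                raise ValueError(
                    f"{path}:{lineno}: {len(tokens)} values for a "
                    f"{len(seq)}-mer {feature.node_kind} feature (expected {expected})"
                )
            raw = np.empty(expected)
            mask = np.empty(expected, dtype=bool)
            for i, tok in enumerate(tokens):
                if tok == "NA":
                    raw[i] = np.nan
                    mask[i] = False
                else:
                    try:
                        raw[i] = float(tok)
                    except ValueError:
                        raise ValueError(
                            f"{path}:{lineno}: non-numeric token {tok!r}"
                        ) from None
                    mask[i] = True
            examples.append(TrainingExample(seq_id, seq.upper(), raw, mask))
    pooled = np.concatenate([ex.raw[ex.mask] for ex in examples]) if examples else []
    stats = compute_norm_stats(pooled)
    for ex in examples:
        ex.targets = np.where(ex.mask, normalize(np.nan_to_num(ex.raw), stats), np.nan)
    return examples, stats


def write_training_file(
    path: str | Path, records: Iterable[tuple[str, str, np.ndarray]]
) -> None:
    """Write ``(seq_id, sequence, values)`` records; NaN emits ``NA``."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for seq_id, seq, values in records:
            toks = ["NA" if not np.isfinite(v) else repr(float(v)) for v in values]
            fh.write(f"{seq_id}\t{seq}\t{','.join(toks)}\n")


def multi_layer_masked_mae(
    preds: Sequence[np.ndarray], targets: np.ndarray, mask: np.ndarray
) -> float:
    """Mean over layers of the masked mean absolute error.

    Each layer's error is summed over defined nodes and divided by the count
    of defined nodes; masked nodes contribute nothing regardless of their
    target values.
    """
    if len(preds) == 0:
        raise ValueError("need at least one layer of predictions")
    mask = np.asarray(mask, dtype=bool)
    n_def = int(mask.sum())
    if n_def == 0:
        raise ValueError("no defined nodes in batch")
    t = np.where(mask, targets, 0.0)
    total = 0.0
    for p in preds:
        total += float(np.abs(np.where(mask, p, 0.0) - t).sum()) / n_def
    return total / len(preds)


def _mae_grads(
    preds: Sequence[np.ndarray], targets: np.ndarray, mask: np.ndarray
) -> list[np.ndarray]:
    """d(multi_layer_masked_mae)/d(preds[l])."""
    n_def = int(mask.sum())
    scale = 1.0 / (n_def * len(preds))
    t = np.where(mask, targets, 0.0)
    return [np.sign(np.where(mask, p, 0.0) - t) * mask * scale for p in preds]


def _prepare_batches(
    examples: Sequence[TrainingExample], feature: ShapeFeatureSpec
) -> list[dict]:
    """Pre-encode every example (capped) and group by node count."""
    items = []
    for ex in examples:
        if ex.targets is None:
            raise ValueError(
                f"example {ex.seq_id!r} has no normalized targets; "
                "attach them with attach_targets() first"
            )
        enc = add_caps(encode_for(ex.sequence, feature.node_kind))
        n = enc.n_nodes
        tgt = np.full(n, np.nan)
        msk = np.zeros(n, dtype=bool)
        tgt[1:-1] = ex.targets
        msk[1:-1] = ex.mask
        items.append(dict(matrix=enc.matrix, targets=np.nan_to_num(tgt), mask=msk, n=n))
    return items


def train_feature_model(
    examples: Sequence[TrainingExample],
    feature: ShapeFeatureSpec,
    config: ModelConfig | None = None,
    stats: NormalizationStats | None = None,
    seed: int | None = None,
    callback: Callable[[int, float], None] | None = None,
) -> TrainingRun:
    """Train one per-feature network with SGD + momentum on the masked
    multi-layer MAE.

    Deterministic given (dataset, config, seed): the same seed drives weight
    initialization, epoch shuffling, and dropout masks.  Variable-length
    sequences are grouped by length into mini-batches so no padding is needed
    and cap semantics stay exact.
    """
    config = config or ModelConfig()
    if seed is None:
        seed = config.seed
    if not examples:
        raise ValueError("empty dataset")
    if not any(ex.mask.any() for ex in examples):
        raise ValueError("dataset has no defined nodes")
    net = ShapeNet(feature, config, stats=stats, init_seed=seed)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5EED]))
    items = _prepare_batches(examples, feature)
    lengths = np.array([it["n"] for it in items])
    velocity = {k: np.zeros_like(v) for k, v in net.params.items()}
    loss_history = np.empty(config.epochs)
    order0 = np.arange(len(items))
    for epoch in range(config.epochs):
        perm = rng.permutation(order0)
        perm = perm[np.argsort(lengths[perm], kind="stable")]
        epoch_loss = 0.0
        epoch_ndef = 0
        start = 0
        while start < len(perm):
            stop = start + config.batch_size
            idx = perm[start:stop]
            # keep the batch single-length
            n0 = lengths[idx[0]]
            same = idx[lengths[idx] == n0]
            idx = same
            start += len(idx)
            X = np.stack([items[i]["matrix"] for i in idx])
            T = np.stack([items[i]["targets"] for i in idx])
            M = np.stack([items[i]["mask"] for i in idx])
            if not M.any():
                continue
            heads, cache = net.forward(X, training=True, dropout_rng=rng,
                                       want_cache=True)
            loss = multi_layer_masked_mae(heads, T, M)
            if not np.isfinite(loss):
                raise TrainingDivergedError(
                    f"non-finite loss at epoch {epoch}, batch of {len(idx)} "
                    f"sequences (lr={config.learning_rate})"
                )
            grads = net.backward(cache, _mae_grads(heads, T, M))
            for name, g in grads.items():
                v = velocity[name]
                v *= config.momentum
                v -= config.learning_rate * g
                net.params[name] += v
            ndef = int(M.sum())
            epoch_loss += loss * ndef
            epoch_ndef += ndef
        loss_history[epoch] = epoch_loss / epoch_ndef
        if callback is not None:
            callback(epoch, loss_history[epoch])
    return TrainingRun(config=config, seed=seed, loss_history=loss_history, net=net)


def evaluate_layerwise_mae(
    net: ShapeNet, examples: Sequence[TrainingExample]
) -> np.ndarray:
    """Masked MAE per layer (normalized scale) over a dataset, inference mode."""
    items = _prepare_batches(examples, net.feature)
    L = net.config.n_shape_layers
    err = np.zeros(L)
    n_def = 0
    by_len: dict[int, list[dict]] = {}
    for it in items:
        by_len.setdefault(it["n"], []).append(it)
    for group in by_len.values():
        X = np.stack([it["matrix"] for it in group])
        T = np.stack([it["targets"] for it in group])
        M = np.stack([it["mask"] for it in group])
        heads = net.forward(X, training=False)
        for l, h in enumerate(heads):
            err[l] += float(np.abs(np.where(M, h, 0.0) - np.where(M, T, 0.0)).sum())
        n_def += int(M.sum())
    return err / n_def


@dataclass
class GridSearchResult:
    best_config: ModelConfig
    best_mae: float
    table: list[dict] = field(default_factory=list)


def grid_search(
    examples: Sequence[TrainingExample],
    feature: ShapeFeatureSpec,
    grid: Sequence[ModelConfig],
    split_seed: int = 0,
    val_fraction: float = 0.1,
    stats: NormalizationStats | None = None,
) -> GridSearchResult:
    """Grid search over configs on a single fixed train/validation split.

    The best config minimizes the deepest layer's validation MAE; per-layer
    validation MAE is recorded for every config.
    """
    if not grid:
        raise ValueError("empty grid")
    n = len(examples)
    n_val = max(1, int(round(n * val_fraction)))
    if n_val >= n:
        raise ValueError("validation split leaves no training data")
    perm = np.random.default_rng(split_seed).permutation(n)
    val_idx = set(perm[:n_val].tolist())
    train = [ex for i, ex in enumerate(examples) if i not in val_idx]
    val = [ex for i, ex in enumerate(examples) if i in val_idx]
    rows = []
    best = None
    for config in grid:
        run = train_feature_model(train, feature, config, stats=stats)
        layer_mae = evaluate_layerwise_mae(run.net, val)
        rows.append(
            dict(config=config, val_mae=float(layer_mae[-1]),
                 layer_mae=layer_mae.copy())
        )
        if best is None or rows[-1]["val_mae"] < best["val_mae"]:
            best = rows[-1]
    return GridSearchResult(best_config=best["config"], best_mae=best["val_mae"],
                            table=rows)
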