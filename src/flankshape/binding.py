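"""Shape-aware TF binding-specificity regression and profile analyses.

Aligned fixed-length binding records (sequence, relative affinity) are
encoded as position-specific k-mer indicators plus per-position shape
profiles from trained shape models, then fitted with L2-regularized multiple
linear regression under nested 10-fold cross-validation: an inner 10-fold CV
on each outer training split selects the ridge penalty, and the ten folds of
held-out predictions are pooled before computing R².

Column counts for an n-length alignment follow the standard bookkeeping:
4n for 1-mers, 16(n-1) for 2-mers, 64(n-2) for 3-mers, and n (per-bp/groove
feature) or n-1 (per-step feature) columns per shape feature.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from sklearn.linear_model import Ridge
from sklearn.metrics import r2_score
from sklearn.model_selection import KFold

__all__ = [
    "BindingRecord",
    "FeatureConfig",
    "RegressionResult",
    "read_binding_table",
    "encode_feature_matrix",
    "fit_l2_nested_cv",
    "aggregate_profiles",
    "cap_scan",
    "BindingSpecificityModel",
    "BindingSpecificityResults",
    "DEFAULT_LAMBDA_GRID",
]

_BASES = "ACGT"

#: 13 penalties log-spaced over 1e-6 .. 1e6.
DEFAULT_LAMBDA_GRID = tuple(np.logspace(-6, 6, 13))


@dataclass(frozen=True)
class BindingRecord:
    """One aligned probe: fixed-length sequence and relative affinity."""

    sequence: str
    affinity: float


@dataclass(frozen=True)
class FeatureConfig:
    """Which feature families enter the design matrix.

    ``shape_normalization``: ``"minmax"`` scales each shape column to [0, 1]
    over the dataset; ``"zscore"`` centres and scales to unit variance;
    ``"none"`` leaves raw values.
    """

    kmer_orders: tuple[int, ...] = (1,)
    shape_features: tuple[str, ...] = ()
    shape_depth: int | None = None
    shape_symmetrize: bool = False
    shape_normalization: str = "minmax"
    log_affinity: bool = False

    def __post_init__(self) -> None:
        if not self.kmer_orders and not self.shape_features:
            raise ValueError("enable at least one feature family")
        if any(k not in (1, 2, 3) for k in self.kmer_orders):
            raise ValueError("kmer orders limited to 1, 2, 3")
        if self.shape_normalization not in ("minmax", "zscore", "none"):
            raise ValueError("unknown shape normalization mode")


def read_binding_table(path: str | Path) -> list[BindingRecord]:
    """TSV ``sequence<TAB>affinity``; all sequences must share one length."""
    records = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            seq, aff = line.split("\t")
            records.append(BindingRecord(seq.upper(), float(aff)))
    _check_aligned(records)
    return records


def _check_aligned(records: Sequence[BindingRecord]) -> int:
    if not records:
        raise ValueError("empty binding dataset")
    n = len(records[0].sequence)
    if any(len(r.sequence) != n for r in records):
        raise ValueError("binding records must share one aligned length")
    return n


def _kmer_block(seqs: Sequence[str], k: int) -> tuple[np.ndarray, list[str]]:
    n = len(seqs[0])
    n_pos = n - k + 1
    X = np.zeros((len(seqs), n_pos * 4 ** k))
    labels = []
    index = {}
    for p in range(n_pos):
        for code in range(4 ** k):
            kmer = "".join(
                _BASES[(code // 4 ** (k - 1 - j)) % 4] for j in range(k)
            )
            labels.append(f"{k}mer_p{p + 1}_{kmer}")
    for i, seq in enumerate(seqs):
        for p in range(n_pos):
            code = 0
            for ch in seq[p:p + k]:
                code = code * 4 + _BASES.index(ch)
            X[i, p * 4 ** k + code] = 1.0
    return X, labels


def encode_feature_matrix(
    records: Sequence[BindingRecord],
    config: FeatureConfig,
    predictors: Mapping[str, object] | None = None,
) -> tuple[np.ndarray, list[str]]:
    """Design matrix + column labels for aligned binding records.

    ``predictors`` maps each requested shape feature name to a fitted model
    with ``predict(seq, depth, symmetrize)`` (a
    :class:`~flankshape.model.ShapeFeatureResults` or a bare network).
    """
    n = _check_aligned(records)
    seqs = [r.sequence for r in records]
    blocks, labels = [], []
    for k in sorted(config.kmer_orders):
        X, lab = _kmer_block(seqs, k)
        blocks.append(X)
        labels.extend(lab)
    for name in config.shape_features:
        if predictors is None or name not in predictors:
            raise ValueError(f"no trained predictor for shape feature {name!r}")
        predictor = predictors[name]
        profiles = np.stack([
            np.asarray(
                predictor.predict(s, depth=config.shape_depth,
                                  symmetrize=config.shape_symmetrize)
            )
            for s in seqs
        ])
        blocks.append(_normalize_block(profiles, config.shape_normalization))
        labels.extend(f"{name}_p{j + 1}" for j in range(profiles.shape[1]))
    return np.concatenate(blocks, axis=1), labels


def _normalize_block(X: np.ndarray, mode: str) -> np.ndarray:
    if mode == "none":
        return X
    if mode == "minmax":
        lo = X.min(axis=0)
        span = X.max(axis=0) - lo
        span[span == 0.0] = 1.0
        return (X - lo) / span
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0.0] = 1.0
    return (X - mu) / sd


def expected_feature_counts(n: int, config: FeatureConfig,
                            node_kinds: Mapping[str, str] | None = None) -> int:
    """Closed-form column count for an n-length alignment."""
    total = 0
    for k in config.kmer_orders:
        total += 4 ** k * (n - k + 1)
    for name in config.shape_features:
        kind = (node_kinds or {}).get(name, "per-bp")
        total += n - 1 if kind == "per-step" else n
    return total


@dataclass
class RegressionResult:
    """Pooled out-of-fold ridge predictions and diagnostics."""

    oof_predictions: np.ndarray
    fold_assignment: np.ndarray
    fold_lambdas: list[float]
    r_squared: float
    seed: int


def fit_l2_nested_cv(
    X: np.ndarray,
    y: np.ndarray,
    seed: int = 0,
    lambda_grid: Sequence[float] = DEFAULT_LAMBDA_GRID,
    n_folds: int = 10,
) -> RegressionResult:
    """Nested-CV ridge regression with pooled out-of-fold R².

    Outer ``n_folds``-fold split (seeded, shuffled); on each outer training
    set an inner 10-fold CV picks the penalty minimizing validation MSE; the
    model refits on the full outer training set and predicts its test fold.
    Every record is predicted exactly once out of fold.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.shape[0] < 20:
        raise ValueError("need at least 20 rows")
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite affinities")
    if not np.any(X.std(axis=0) > 0):
        raise ValueError("design matrix has no varying column")
    outer = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    oof = np.empty_like(y)
    assignment = np.empty(len(y), dtype=int)
    fold_lambdas = []
    for fold, (tr, te) in enumerate(outer.split(X)):
        inner = KFold(n_splits=n_folds, shuffle=True, random_state=seed + 1)
        best_lam, best_mse = None, np.inf
        for lam in lambda_grid:
            mse = 0.0
            for itr, ite in inner.split(X[tr]):
                model = Ridge(alpha=lam)
                model.fit(X[tr][itr], y[tr][itr])
                resid = model.predict(X[tr][ite]) - y[tr][ite]
                mse += float(resid @ resid)
            if mse < best_mse:
                best_mse, best_lam = mse, lam
        model = Ridge(alpha=best_lam)
        model.fit(X[tr], y[tr])
        oof[te] = model.predict(X[te])
        assignment[te] = fold
        fold_lambdas.append(float(best_lam))
    return RegressionResult(
        oof_predictions=oof,
        fold_assignment=assignment,
        fold_lambdas=fold_lambdas,
        r_squared=float(r2_score(y, oof)),
        seed=seed,
    )


class BindingSpecificityModel:
    """Binding records + feature config, fitted by nested-CV ridge."""

    def __init__(
        self,
        records: Sequence[BindingRecord],
        config: FeatureConfig,
        predictors: Mapping[str, object] | None = None,
    ) -> None:
        _check_aligned(records)
        self.records = list(records)
        self.config = config
        self.X, self.column_labels = encode_feature_matrix(
            records, config, predictors
        )
        y = np.array([r.affinity for r in records])
        self.y = np.log(y) if config.log_affinity else y

    def fit(self, seed: int = 0,
            lambda_grid: Sequence[float] = DEFAULT_LAMBDA_GRID
            ) -> "BindingSpecificityResults":
        reg = fit_l2_nested_cv(self.X, self.y, seed=seed,
                               lambda_grid=lambda_grid)
        return BindingSpecificityResults(self, reg)


class BindingSpecificityResults:
    def __init__(self, model: BindingSpecificityModel, reg: RegressionResult):
        self.model = model
        self.result = reg
        self.r_squared = reg.r_squared
        self.fold_lambdas = reg.fold_lambdas
        self.oof_predictions = reg.oof_predictions

    def summary(self) -> str:
        cfg = self.model.config
        lines = [
            "Binding-specificity ridge regression (nested 10-fold CV)",
            "=" * 60,
            f"{'records':<26}{len(self.model.records)}",
            f"{'design columns':<26}{self.model.X.shape[1]}",
            f"{'k-mer orders':<26}{list(cfg.kmer_orders)}",
            f"{'shape features':<26}{list(cfg.shape_features)}",
            f"{'pooled out-of-fold R^2':<26}{self.r_squared:.4f}",
            f"{'fold lambdas':<26}"
            + ", ".join(f"{l:.3g}" for l in self.fold_lambdas),
        ]
        return "\n".join(lines)

    def to_json_dict(self) -> dict:
        return {
            "r_squared": self.r_squared,
            "fold_lambdas": self.fold_lambdas,
            "seed": self.result.seed,
            "n_records": len(self.model.records),
            "n_columns": int(self.model.X.shape[1]),
        }


def aggregate_profiles(
    records: Sequence[BindingRecord],
    predictor,
    top_fraction: float = 0.25,
    depth: int | None = None,
    symmetrize: bool = False,
    n_bins: int | None = None,
) -> dict:
    """Affinity-sorted shape-profile matrix for the strongest binders.

    Keeps the ``ceil(top_fraction * N)`` highest-affinity records, sorted by
    descending affinity (row 0 = strongest), and predicts the shape profile
    at every aligned position.  With ``n_bins`` it also emits per-affinity-bin
    mean curves (bin 0 = strongest binders).
    """
    _check_aligned(records)
    if not (0.0 < top_fraction <= 1.0):
        raise ValueError("top_fraction must be in (0, 1]")
    order = sorted(range(len(records)), key=lambda i: -records[i].affinity)
    keep = order[: math.ceil(top_fraction * len(records))]
    profiles = np.stack([
        np.asarray(predictor.predict(records[i].sequence, depth=depth,
                                     symmetrize=symmetrize))
        for i in keep
    ])
    out = {
        "profiles": profiles,
        "affinities": np.array([records[i].affinity for i in keep]),
        "indices": np.array(keep),
    }
    if n_bins is not None:
        edges = np.array_split(np.arange(len(keep)), n_bins)
        out["bin_means"] = np.stack([
            profiles[idx].mean(axis=0) for idx in edges if len(idx)
        ])
    return out


def cap_scan(
    cap5: str,
    cap3: str,
    core_length: int,
    predictor,
    depth: int | None = None,
    symmetrize: bool = False,
    sample_size: int = 4096,
    seed: int = 0,
    enumerate_limit: int = 65536,
) -> dict:
    """Shape distribution across random cores between fixed caps.

    Enumerates all ``4**core_length`` cores when that is at most
    ``enumerate_limit``; otherwise draws ``sample_size`` seeded random cores.
    Returns per-position five-number summaries in boxplot convention:
    quartiles, median, and whisker bounds at 1.5 interquartile ranges beyond
    the quartiles.
    """
    if core_length < 1:
        raise ValueError("core_length must be >= 1")
    n_total = 4 ** core_length
    if n_total <= enumerate_limit:
        cores = []
        for code in range(n_total):
            cores.append("".join(
                _BASES[(code // 4 ** (core_length - 1 - j)) % 4]
                for j in range(core_length)
            ))
    else:
        rng = np.random.default_rng(seed)
        cores = ["".join(rng.choice(list(_BASES), size=core_length))
                 for _ in range(sample_size)]
    profiles = np.stack([
        np.asarray(predictor.predict(cap5 + core + cap3, depth=depth,
                                     symmetrize=symmetrize))
        for core in cores
    ])
    q1, med, q3 = np.percentile(profiles, [25.0, 50.0, 75.0], axis=0)
    iqr = q3 - q1
    return {
        "n_sequences": len(cores),
        "enumerated": n_total <= enumerate_limit,
        "positions": np.arange(1, profiles.shape[1] + 1),
        "median": med,
        "q1": q1,
        "q3": q3,
        "whisker_low": q1 - 1.5 * iqr,
        "whisker_high": q3 + 1.5 * iqr,
        "profiles": profiles,
    }
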