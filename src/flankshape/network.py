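"""The recurrent graph shape network.

A sequence is a chain of nodes (bases or dinucleotide steps) with N-cap nodes
self-linked at both ends.  The architecture is

* a *self layer*: a width-1 convolution (position-wise linear map) lifting the
  4- or 16-channel one-hot encoding to ``filter_size`` channels;
* ``n_shape_layers`` stacked *shape layers*.  Each layer gathers the 5' and 3'
  neighbour features and computes, per node i,

      lam = W1 . X[i-1] + W2 . X[i+1] + b1
      alp = T1 . X[i-1] + T2 . X[i+1] + b2
      u   = batchnorm(relu(lam * X[i] + alp))
      Xnew[i] = GRUCell(input=u, state=X[i])

  so each layer widens the receptive field by exactly one node: after k
  layers a node's features depend on nodes at most k away, which makes the
  flanking-region influence selectable by reading the head of layer k;
* a scalar *head* per layer: tanh of the channel mean of that layer's node
  features, one bounded value per node on the normalized shape scale.

The GRU cell uses the standard convention: update and reset gates are
sigmoids of affine maps of (input, state); the candidate is a tanh with the
reset gate applied to the state; new state = (1-z)*state + z*candidate.

Everything is plain numpy with explicit reverse-mode gradients
(:meth:`ShapeNet.backward`); a finite-difference test in the suite checks the
analytic gradients end to end.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .features import NormalizationStats, ShapeFeatureSpec, denormalize, rc_transform_profile
from .encoding import add_caps, encode_for, reverse_complement

__all__ = ["ModelConfig", "ShapeNet", "receptive_radius"]

_BN_EPS = 1e-5
_BN_MOMENTUM = 0.9
_FORMAT_VERSION = 1


@dataclass(frozen=True)
class ModelConfig:
    """Hyperparameters of one per-feature shape network.

    Defaults are the published operating point of the method: 7 shape layers,
    filter size 64, dropout 0.5, SGD with learning rate 0.05 and momentum
    0.95 for 1500 epochs.
    """

    n_shape_layers: int = 7
    filter_size: int = 64
    dropout_ratio: float = 0.5
    learning_rate: float = 0.05
    momentum: float = 0.95
    epochs: int = 1500
    batch_size: int = 32
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_shape_layers < 1:
            raise ValueError("n_shape_layers must be >= 1")
        if not (0.0 <= self.dropout_ratio < 1.0):
            raise ValueError("dropout_ratio must be in [0, 1)")
        if self.filter_size < 1:
            raise ValueError("filter_size must be >= 1")


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


class ShapeNet:
    """Trainable per-feature shape network (parameters + buffers).

    Parameters live in ``self.params`` (name -> float64 array); batch-norm
    running statistics live in ``self.buffers``.  The network is tied to one
    shape feature (its node kind fixes the input channel count) and carries
    the normalization stats needed to report raw-scale predictions.
    """

    def __init__(
        self,
        feature: ShapeFeatureSpec,
        config: ModelConfig | None = None,
        stats: NormalizationStats | None = None,
        init_seed: int | None = None,
    ) -> None:
        self.feature = feature
        self.config = config or ModelConfig()
        self.stats = stats
        seed = self.config.seed if init_seed is None else init_seed
        rng = np.random.default_rng(seed)
        F = self.config.filter_size
        C = feature.n_channels
        p: dict[str, np.ndarray] = {}
        b: dict[str, np.ndarray] = {}
        p["self_W"] = _glorot(rng, C, F)
        p["self_b"] = np.zeros(F)
        for l in range(self.config.n_shape_layers):
            k = f"L{l}_"
            for name in ("W1", "W2", "T1", "T2"):
                p[k + name] = _glorot(rng, F, F)
            p[k + "b1"] = np.zeros(F)
            p[k + "b2"] = np.zeros(F)
            p[k + "bn_gamma"] = np.ones(F)
            p[k + "bn_beta"] = np.zeros(F)
            for g in ("z", "r", "c"):
                p[k + f"W{g}"] = _glorot(rng, F, F)
                p[k + f"U{g}"] = _glorot(rng, F, F)
                p[k + f"b{g}"] = np.zeros(F)
            b[k + "bn_mean"] = np.zeros(F)
            b[k + "bn_var"] = np.ones(F)
        self.params = p
        self.buffers = b

    # ------------------------------------------------------------------ #
    # forward / backward

    def forward(
        self,
        X: np.ndarray,
        training: bool = False,
        dropout_rng: np.random.Generator | None = None,
        want_cache: bool = False,
    ):
        """Run a batch through the network.

        Parameters
        ----------
        X : (batch, n_nodes, channels) capped encodings, equal lengths.
        training : use batch statistics for batch norm, apply dropout, and
            update running statistics.  Inference uses frozen running stats
            and no dropout, so predictions are deterministic.
        dropout_rng : randomness source for dropout masks (training only).

        Returns
        -------
        heads : list of (batch, n_nodes) arrays, one per shape layer, each
            strictly inside (-1, 1) (tanh of the channel mean).  Cap nodes
            are included; callers strip or mask them.
        cache : opaque state for :meth:`backward` when ``want_cache``.
        """
        if X.ndim != 3 or X.shape[2] != self.feature.n_channels:
            raise ValueError(
                f"expected (batch, nodes, {self.feature.n_channels}) input, "
                f"got {X.shape}"
            )
        p = self.params
        keep = 1.0 - self.config.dropout_ratio
        use_dropout = training and self.config.dropout_ratio > 0.0
        if use_dropout and dropout_rng is None:
            raise ValueError("training with dropout requires dropout_rng")

        H = X @ p["self_W"] + p["self_b"]
        heads: list[np.ndarray] = []
        layer_caches = []
        X_in = H
        for l in range(self.config.n_shape_layers):
            k = f"L{l}_"
            Xl = np.concatenate([X_in[:, :1], X_in[:, :-1]], axis=1)
            Xr = np.concatenate([X_in[:, 1:], X_in[:, -1:]], axis=1)
            lam = Xl @ p[k + "W1"] + Xr @ p[k + "W2"] + p[k + "b1"]
            alp = Xl @ p[k + "T1"] + Xr @ p[k + "T2"] + p[k + "b2"]
            pre = lam * X_in + alp
            act = np.maximum(pre, 0.0)
            if training:
                mu = act.mean(axis=(0, 1))
                var = act.var(axis=(0, 1))
                self.buffers[k + "bn_mean"] = (
                    _BN_MOMENTUM * self.buffers[k + "bn_mean"] + (1 - _BN_MOMENTUM) * mu
                )
                self.buffers[k + "bn_var"] = (
                    _BN_MOMENTUM * self.buffers[k + "bn_var"] + (1 - _BN_MOMENTUM) * var
                )
            else:
                mu = self.buffers[k + "bn_mean"]
                var = self.buffers[k + "bn_var"]
            inv_std = 1.0 / np.sqrt(var + _BN_EPS)
            xhat = (act - mu) * inv_std
            u = p[k + "bn_gamma"] * xhat + p[k + "bn_beta"]
            z = _sigmoid(u @ p[k + "Wz"] + X_in @ p[k + "Uz"] + p[k + "bz"])
            r = _sigmoid(u @ p[k + "Wr"] + X_in @ p[k + "Ur"] + p[k + "br"])
            rh = r * X_in
            c = np.tanh(u @ p[k + "Wc"] + rh @ p[k + "Uc"] + p[k + "bc"])
            Xn = (1.0 - z) * X_in + z * c
            if use_dropout:
                mask = (dropout_rng.random(Xn.shape) < keep) / keep
                Xd = Xn * mask
            else:
                mask = None
                Xd = Xn
            y = np.tanh(Xd.mean(axis=2))
            heads.append(y)
            if want_cache:
                layer_caches.append(
                    dict(X_in=X_in, Xl=Xl, Xr=Xr, lam=lam, pre=pre,
                         xhat=xhat, inv_std=inv_std, u=u, z=z, r=r, rh=rh,
                         c=c, mask=mask, Xd=Xd, y=y)
                )
            X_in = Xd
        if not want_cache:
            return heads
        cache = dict(X0=X, layers=layer_caches, training=training)
        return heads, cache

    def backward(self, cache, dheads: Sequence[np.ndarray]) -> dict[str, np.ndarray]:
        """Reverse-mode gradients of a scalar loss wrt every parameter.

        ``dheads[l]`` is dLoss/dheads[l]; batch-norm backward matches the
        mode used in the cached forward (batch statistics during training,
        frozen statistics otherwise).
        """
        p = self.params
        F = self.config.filter_size
        grads = {name: np.zeros_like(arr) for name, arr in p.items()}
        dXd = np.zeros_like(cache["layers"][-1]["Xd"])
        training = cache["training"]
        for l in range(self.config.n_shape_layers - 1, -1, -1):
            k = f"L{l}_"
            cl = cache["layers"][l]
            X_in = cl["X_in"]
            # head: y = tanh(mean_channels(Xd))
            dXd = dXd + (dheads[l] * (1.0 - cl["y"] ** 2))[..., None] / F
            dXn = dXd * cl["mask"] if cl["mask"] is not None else dXd
            # GRU
            z, r, c, u, rh = cl["z"], cl["r"], cl["c"], cl["u"], cl["rh"]
            dz = dXn * (c - X_in)
            dc = dXn * z
            dh = dXn * (1.0 - z)
            dac = dc * (1.0 - c * c)
            du = dac @ p[k + "Wc"].T
            drh = dac @ p[k + "Uc"].T
            dr = drh * X_in
            dh = dh + drh * r
            _acc(grads, k + "Wc", u, dac)
            _acc(grads, k + "Uc", rh, dac)
            grads[k + "bc"] += dac.sum(axis=(0, 1))
            dar = dr * r * (1.0 - r)
            du += dar @ p[k + "Wr"].T
            dh += dar @ p[k + "Ur"].T
            _acc(grads, k + "Wr", u, dar)
            _acc(grads, k + "Ur", X_in, dar)
            grads[k + "br"] += dar.sum(axis=(0, 1))
            daz = dz * z * (1.0 - z)
            du += daz @ p[k + "Wz"].T
            dh += daz @ p[k + "Uz"].T
            _acc(grads, k + "Wz", u, daz)
            _acc(grads, k + "Uz", X_in, daz)
            grads[k + "bz"] += daz.sum(axis=(0, 1))
            # batch norm
            xhat, inv_std = cl["xhat"], cl["inv_std"]
            grads[k + "bn_gamma"] += (du * xhat).sum(axis=(0, 1))
            grads[k + "bn_beta"] += du.sum(axis=(0, 1))
            dxhat = du * p[k + "bn_gamma"]
            if training:
                N = xhat.shape[0] * xhat.shape[1]
                da = (inv_std / N) * (
                    N * dxhat
                    - dxhat.sum(axis=(0, 1))
                    - xhat * (dxhat * xhat).sum(axis=(0, 1))
                )
            else:
                da = dxhat * inv_std
            dpre = da * (cl["pre"] > 0.0)
            # pre = lam * X_in + alp
            dh = dh + dpre * cl["lam"]
            dlam = dpre * X_in
            dalp = dpre
            dXl = dlam @ p[k + "W1"].T + dalp @ p[k + "T1"].T
            dXr = dlam @ p[k + "W2"].T + dalp @ p[k + "T2"].T
            _acc(grads, k + "W1", cl["Xl"], dlam)
            _acc(grads, k + "W2", cl["Xr"], dlam)
            grads[k + "b1"] += dlam.sum(axis=(0, 1))
            _acc(grads, k + "T1", cl["Xl"], dalp)
            _acc(grads, k + "T2", cl["Xr"], dalp)
            grads[k + "b2"] += dalp.sum(axis=(0, 1))
            # adjoint of neighbour gather (cap self-links at both ends)
            dh[:, :-1] += dXl[:, 1:]
            dh[:, 0] += dXl[:, 0]
            dh[:, 1:] += dXr[:, :-1]
            dh[:, -1] += dXr[:, -1]
            dXd = dh
        X0 = cache["X0"]
        _acc(grads, "self_W", X0, dXd)
        grads["self_b"] += dXd.sum(axis=(0, 1))
        return grads

    # ------------------------------------------------------------------ #
    # prediction

    def forward_sequence(self, seq: str, depth: int | None = None) -> np.ndarray:
        """Normalized per-node profile at layer ``depth`` (caps stripped)."""
        depth = self._check_depth(depth)
        enc = add_caps(encode_for(seq, self.feature.node_kind))
        heads = self.forward(enc.matrix[None], training=False)
        return heads[depth - 1][0, 1:-1].copy()

    def predict(self, seq: str, depth: int | None = None,
                symmetrize: bool = False) -> np.ndarray:
        """Raw-scale shape profile for one sequence.

        With ``symmetrize`` the profile is averaged with the strand-
        transformed prediction on the reverse complement, making the output
        consistent between a sequence and its reverse complement.
        """
        if self.stats is None:
            raise ValueError("network has no normalization stats attached")
        prof = self.forward_sequence(seq, depth)
        if symmetrize:
            rc_prof = self.forward_sequence(reverse_complement(seq), depth)
            prof = 0.5 * (prof + rc_transform_profile(rc_prof, self.feature))
        return denormalize(prof, self.stats)

    def _check_depth(self, depth: int | None) -> int:
        if depth is None:
            return self.config.n_shape_layers
        if not (1 <= depth <= self.config.n_shape_layers):
            raise ValueError(
                f"depth {depth} outside 1..{self.config.n_shape_layers}"
            )
        return depth

    # ------------------------------------------------------------------ #
    # serialization

    def save(self, path: str | Path) -> None:
        """Write a single-file model artifact (manifest + weight arrays)."""
        manifest = {
            "format_version": _FORMAT_VERSION,
            "feature": asdict(self.feature),
            "config": asdict(self.config),
            "stats": None if self.stats is None else {
                "median": repr(self.stats.median),
                "p1": repr(self.stats.p1),
                "p99": repr(self.stats.p99),
            },
        }
        arrays = {f"param/{k}": v for k, v in self.params.items()}
        arrays.update({f"buffer/{k}": v for k, v in self.buffers.items()})
        arrays["__manifest__"] = np.frombuffer(
            json.dumps(manifest, sort_keys=True).encode(), dtype=np.uint8
        )
        with open(path, "wb") as fh:
            np.savez(fh, **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "ShapeNet":
        with np.load(path) as data:
            manifest = json.loads(bytes(data["__manifest__"]).decode())
            if manifest["format_version"] != _FORMAT_VERSION:
                raise ValueError("unsupported model file version")
            feature = ShapeFeatureSpec(**manifest["feature"])
            config = ModelConfig(**manifest["config"])
            stats = None
            if manifest["stats"] is not None:
                s = manifest["stats"]
                stats = NormalizationStats(
                    float(s["median"]), float(s["p1"]), float(s["p99"])
                )
            net = cls(feature, config, stats)
            for name in net.params:
                net.params[name] = data[f"param/{name}"].copy()
            for name in net.buffers:
                net.buffers[name] = data[f"buffer/{name}"].copy()
        return net


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _acc(grads: dict, name: str, a: np.ndarray, d: np.ndarray) -> None:
    """grads[name] += a^T . d with (batch, nodes) axes flattened."""
    F1, F2 = a.shape[-1], d.shape[-1]
    grads[name] += a.reshape(-1, F1).T @ d.reshape(-1, F2)


def receptive_radius(
    net: ShapeNet,
    depth: int | None = None,
    n_probe_seqs: int = 4,
    seed: int = 0,
    tol: float = 1e-10,
) -> int:
    """Perturbation-probed receptive radius, in base pairs.

    Measures the largest bp distance at which a single-nucleotide
    substitution changes the prediction at a center position, probing random
    sequences and all alternative bases on both sides.  By construction each
    shape layer extends the field by one node, so the radius equals ``depth``
    for per-bp features; on step graphs a substitution touches two step
    nodes, so the bp radius is ``depth + 1``.
    """
    depth = net._check_depth(depth)
    L = 2 * (net.config.n_shape_layers + 3) + 1
    center = L // 2
    node = center if net.feature.node_kind == "per-bp" else center
    rng = np.random.default_rng(seed)
    max_d = net.config.n_shape_layers + 3
    radius = 0
    for _ in range(n_probe_seqs):
        seq = "".join(rng.choice(list("ACGT"), size=L))
        variants = [seq]
        coords = [None]
        for d in range(1, max_d + 1):
            for pos in (center - d, center + d):
                for alt in "ACGT":
                    if alt == seq[pos]:
                        continue
                    variants.append(seq[:pos] + alt + seq[pos + 1:])
                    coords.append(d)
        mats = np.stack(
            [add_caps(encode_for(s, net.feature.node_kind)).matrix for s in variants]
        )
        head = net.forward(mats, training=False)[depth - 1]
        ref = head[0, 1 + node]
        for i, d in enumerate(coords[1:], start=1):
            if abs(head[i, 1 + node] - ref) > tol:
                radius = max(radius, d)
    return radius
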