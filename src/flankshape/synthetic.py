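"""Synthetic shape-data generator with flank influence decaying by distance.

Real training corpora for shape prediction come from ensemble simulations of
short duplexes: variable-length sequences, per-position real values, and
NA-masked terminal positions for groove features.  This module emulates that
with an explicit, fully known ground truth so that every other component can
be trained and validated without external data, and so that parameter
recovery can be checked against an exact oracle.

The ground truth encodes the central modelling assumption: the shape value at
a position is a base-composition effect of its own unit (base or step) plus
additive contributions from flanking bases that shrink geometrically with
distance,

    value(i) = center[unit_i] + sum_{d=1..R} contrib(d, side, base at i -/+ d)

with |contrib(d, ., .)| <= A * gamma^(d-1).  A radius-R truth is therefore
exactly representable by a (2R+1)-mer query table, and beyond-R edits provably
do nothing — both properties are exploited by the tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .features import ShapeFeatureSpec
from .training import TrainingExample, write_training_file

__all__ = [
    "GroundTruthModel",
    "GroundTruthPredictor",
    "SyntheticRecord",
    "SyntheticCorpus",
    "make_ground_truth",
    "true_shape",
    "sample_corpus",
]

_BASES = "ACGT"
_BASE_IDX = {b: i for i, b in enumerate(_BASES)}

#: Default study conditions: sized like the simulation corpora this emulates.
DEFAULT_N_SEQS = 2121
DEFAULT_LENGTH_RANGE = (15, 25)
DEFAULT_RADIUS = 4
DEFAULT_DECAY = 0.6
DEFAULT_AMPLITUDE = 0.5


@dataclass
class GroundTruthModel:
    """Known flank-decay shape function used for data generation.

    ``center_table`` has one value per central unit (4 bases or 16 steps);
    ``contribution`` is indexed ``[d-1, side, base]`` with side 0 = 5' and
    side 1 = 3', already scaled by ``decay**(d-1)``.  ``fluctuation`` selects
    a softplus squashing so that emitted values are strictly positive, as an
    ensemble spread must be.
    """

    node_kind: str
    radius: int
    decay: float
    center_table: np.ndarray
    contribution: np.ndarray
    noise_sd: float
    terminal_mask_margin: int = 0
    fluctuation: bool = False
    seed: int | None = None

    @property
    def feature_spec(self) -> ShapeFeatureSpec:
        """A registry-style spec describing the synthetic feature."""
        return ShapeFeatureSpec(
            name="synthetic" + ("-FL" if self.fluctuation else ""),
            node_kind=self.node_kind,
            units="arbitrary",
            rc_class="invariant",
            terminal_mask_margin=self.terminal_mask_margin,
            is_fluctuation=self.fluctuation,
        )

    def manifest(self) -> dict:
        return {
            "node_kind": self.node_kind,
            "radius": self.radius,
            "decay": self.decay,
            "noise_sd": self.noise_sd,
            "terminal_mask_margin": self.terminal_mask_margin,
            "fluctuation": self.fluctuation,
            "seed": self.seed,
            "center_table": self.center_table.tolist(),
            "contribution": self.contribution.tolist(),
        }

    @classmethod
    def from_manifest(cls, d: dict) -> "GroundTruthModel":
        return cls(
            node_kind=d["node_kind"],
            radius=d["radius"],
            decay=d["decay"],
            center_table=np.asarray(d["center_table"]),
            contribution=np.asarray(d["contribution"]),
            noise_sd=d["noise_sd"],
            terminal_mask_margin=d["terminal_mask_margin"],
            fluctuation=d["fluctuation"],
            seed=d["seed"],
        )


def make_ground_truth(
    seed: int,
    radius: int = DEFAULT_RADIUS,
    decay: float = DEFAULT_DECAY,
    noise_sd: float | None = None,
    node_kind: str = "per-bp",
    amplitude: float = DEFAULT_AMPLITUDE,
    center_loc: float = 5.0,
    center_spread: float = 1.5,
    terminal_mask_margin: int = 2,
    fluctuation: bool = False,
) -> GroundTruthModel:
    """Draw a seeded ground truth with geometric flank decay.

    Center values are spread around ``center_loc`` (think groove-width-like
    magnitudes in arbitrary units); flank contributions at distance d are
    uniform in +/- ``amplitude * decay**(d-1)``.  When ``noise_sd`` is None it
    defaults to 5% of the spread of noiseless values over random sequence
    (measured empirically from the tables).
    """
    if radius > 7:
        raise ValueError("radius must be <= 7")
    if not (0.0 <= decay < 1.0):
        raise ValueError("decay must be in [0, 1)")
    if node_kind not in ("per-bp", "per-step"):
        raise ValueError(f"unknown node_kind {node_kind!r}")
    rng = np.random.default_rng(seed)
    n_units = 4 if node_kind == "per-bp" else 16
    center = center_loc + rng.uniform(-center_spread, center_spread, size=n_units)
    contrib = np.zeros((max(radius, 1), 2, 4))
    for d in range(1, radius + 1):
        bound = amplitude * decay ** (d - 1)
        contrib[d - 1] = rng.uniform(-bound, bound, size=(2, 4))
    if radius == 0:
        contrib = np.zeros((0, 2, 4))
    gtm = GroundTruthModel(
        node_kind=node_kind,
        radius=radius,
        decay=decay,
        center_table=center,
        contribution=contrib[:radius],
        noise_sd=0.0,
        terminal_mask_margin=terminal_mask_margin,
        fluctuation=fluctuation,
        seed=seed,
    )
    if noise_sd is None:
        probe = rng.choice(list(_BASES), size=2000)
        vals, _ = true_shape("".join(probe), gtm)
        noise_sd = 0.05 * float(np.nanmax(vals) - np.nanmin(vals))
    gtm.noise_sd = float(noise_sd)
    return gtm


def _unit_index(seq: str, i: int, node_kind: str) -> int:
    if node_kind == "per-bp":
        return _BASE_IDX[seq[i]]
    return 4 * _BASE_IDX[seq[i]] + _BASE_IDX[seq[i + 1]]


def true_shape(seq: str, gtm: GroundTruthModel) -> tuple[np.ndarray, np.ndarray]:
    """Noiseless profile and defined-mask for one sequence.

    Flank contributions falling outside the sequence are truncated (the end
    of the molecule simply has no neighbour there); the first and last
    ``terminal_mask_margin`` nodes are masked as undefined.
    """
    seq = seq.upper()
    n_nodes = len(seq) - 1 if gtm.node_kind == "per-step" else len(seq)
    if n_nodes < 1:
        raise ValueError("sequence too short for node kind")
    values = np.empty(n_nodes)
    step = gtm.node_kind == "per-step"
    for i in range(n_nodes):
        v = gtm.center_table[_unit_index(seq, i, gtm.node_kind)]
        for d in range(1, gtm.radius + 1):
            j5 = i - d
            if j5 >= 0:
                v += gtm.contribution[d - 1, 0, _BASE_IDX[seq[j5]]]
            j3 = (i + 1 + d) if step else (i + d)
            if j3 < len(seq):
                v += gtm.contribution[d - 1, 1, _BASE_IDX[seq[j3]]]
        values[i] = v
    if gtm.fluctuation:
        values = np.log1p(np.exp(values - values.mean())) + 0.05
    mask = np.ones(n_nodes, dtype=bool)
    m = gtm.terminal_mask_margin
    if m > 0:
        mask[:m] = False
        mask[-m:] = False
    return values, mask


@dataclass
class SyntheticRecord:
    seq_id: str
    sequence: str
    true_values: np.ndarray
    noisy_values: np.ndarray
    mask: np.ndarray


@dataclass
class SyntheticCorpus:
    """Seeded synthetic training corpus plus its generating parameters."""

    records: list[SyntheticRecord]
    gtm: GroundTruthModel
    seed: int
    params: dict = field(default_factory=dict)

    def to_training_file(self, path: str | Path, noisy: bool = True) -> None:
        rows = []
        for r in self.records:
            vals = (r.noisy_values if noisy else r.true_values).copy()
            vals[~r.mask] = np.nan
            rows.append((r.seq_id, r.sequence, vals))
        write_training_file(path, rows)

    def to_examples(self, noisy: bool = True) -> list["TrainingExample"]:
        """In-memory raw examples (targets not yet normalized)."""
        out = []
        for r in self.records:
            vals = (r.noisy_values if noisy else r.true_values).copy()
            vals[~r.mask] = np.nan
            out.append(TrainingExample(r.seq_id, r.sequence, vals, r.mask.copy()))
        return out

    def save_manifest(self, path: str | Path) -> None:
        doc = {"seed": self.seed, "params": self.params,
               "ground_truth": self.gtm.manifest()}
        Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True))


class GroundTruthPredictor:
    """Exposes a ground truth through the shape-predictor interface.

    Useful as an exact oracle wherever a trained model is expected (e.g. in
    binding-regression experiments): ``predict`` returns the noiseless truth,
    ignoring ``depth`` (the truth has a fixed radius) and ``symmetrize``.
    """

    def __init__(self, gtm: GroundTruthModel) -> None:
        self.gtm = gtm
        self.feature = gtm.feature_spec

    def predict(self, seq: str, depth: int | None = None,
                symmetrize: bool = False) -> np.ndarray:
        values, _ = true_shape(seq, self.gtm)
        return values


def _random_sequence(rng: np.random.Generator, length: int,
                     probs: np.ndarray) -> str:
    return "".join(rng.choice(list(_BASES), size=length, p=probs))


def sample_corpus(
    gtm: GroundTruthModel,
    n_seqs: int = DEFAULT_N_SEQS,
    length_range: tuple[int, int] = DEFAULT_LENGTH_RANGE,
    composition_bias: Sequence[float] | None = None,
    constrained_context: tuple[str, str] | None = None,
    seed: int = 0,
) -> SyntheticCorpus:
    """Sample a corpus of i.i.d. random sequences with known shape values.

    ``composition_bias`` gives per-base probabilities (default uniform).
    ``constrained_context = (kmer, context)`` activates a biased-sampling
    mode for flank-bias experiments: the given k-mer occurs in the corpus
    *only* embedded inside ``context`` (which must contain the k-mer once);
    every sequence gets one planted copy of the context, and accidental bare
    occurrences of the k-mer are mutated away.
    """
    if n_seqs < 1:
        raise ValueError("need at least one sequence")
    lo, hi = length_range
    if lo > hi or lo < (2 if gtm.node_kind == "per-step" else 1):
        raise ValueError(f"degenerate length range {length_range}")
    probs = (np.full(4, 0.25) if composition_bias is None
             else np.asarray(composition_bias, dtype=float))
    if probs.shape != (4,) or abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError("composition_bias must be 4 probabilities summing to 1")
    kmer = context = None
    if constrained_context is not None:
        kmer, context = constrained_context
        if context.count(kmer) != 1:
            raise ValueError("context must contain the k-mer exactly once")
        if hi < len(context):
            raise ValueError("sequences too short for the context")
    rng = np.random.default_rng(seed)
    records: list[SyntheticRecord] = []
    for idx in range(n_seqs):
        length = int(rng.integers(lo, hi + 1))
        if context is not None:
            length = max(length, len(context))
        seq = _random_sequence(rng, length, probs)
        if context is not None:
            pos = int(rng.integers(0, length - len(context) + 1))
            seq = seq[:pos] + context + seq[pos + len(context):]
            seq = _scrub_bare_kmer(seq, kmer, context, rng)
        tv, mask = true_shape(seq, gtm)
        noisy = tv + rng.normal(0.0, gtm.noise_sd, size=tv.shape)
        records.append(SyntheticRecord(f"seq{idx:05d}", seq, tv, noisy, mask))
    params = dict(
        n_seqs=n_seqs, length_range=list(length_range),
        composition_bias=None if composition_bias is None else list(probs),
        constrained_context=None if constrained_context is None
        else list(constrained_context),
    )
    return SyntheticCorpus(records=records, gtm=gtm, seed=seed, params=params)


def _scrub_bare_kmer(seq: str, kmer: str, context: str,
                     rng: np.random.Generator) -> str:
    """Mutate occurrences of ``kmer`` that are not inside ``context``."""
    off = context.index(kmer)
    for _ in range(100):
        bad = None
        i = seq.find(kmer)
        while i >= 0:
            start = i - off
            if not (0 <= start and start + len(context) <= len(seq)
                    and seq[start:start + len(context)] == context):
                bad = i
                break
            i = seq.find(kmer, i + 1)
        if bad is None:
            return seq
        j = bad + int(rng.integers(0, len(kmer)))
        seq = seq[:j] + str(rng.choice(list(_BASES))) + seq[j + 1:]
    raise RuntimeError("could not scrub bare k-mer occurrences")
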