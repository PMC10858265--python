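"""One-hot sequence encodings as linked nodes, N handling, and N caps.

A sequence is modelled as a chain of nodes — one node per base for per-bp
features, one per dinucleotide step for per-step features.  ``N`` bases encode
as the uniform average over their compatible pure encodings, so every row of
an encoding matrix sums to one.  Before the network runs, an artificial ``N``
cap node is attached at each end; a cap's missing outer neighbour is the cap
itself (a self-link), which gives terminal bases the same neighbour degree as
interior ones and a boundary that is stable under arbitrarily deep message
passing.  Caps are stripped from returned profiles.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterator

import numpy as np
from Bio import SeqIO

__all__ = [
    "EncodedSequence",
    "MONO_ALPHABET",
    "DINUC_ALPHABET",
    "encode_mono",
    "encode_di",
    "encode_for",
    "add_caps",
    "strip_caps",
    "neighbor_indices",
    "reverse_complement",
    "read_fasta",
]

MONO_ALPHABET = ("A", "C", "G", "T")
#: Dinucleotide channels in alphabetical order AA, AC, ..., TT.
DINUC_ALPHABET = tuple(a + b for a in MONO_ALPHABET for b in MONO_ALPHABET)

_BASE_INDEX = {b: i for i, b in enumerate(MONO_ALPHABET)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# Per-base probability rows; N is the uniform average over A/C/G/T.
_BASE_ROWS = {b: np.eye(4)[i] for b, i in _BASE_INDEX.items()}
_BASE_ROWS["N"] = np.full(4, 0.25)


@dataclass(frozen=True)
class EncodedSequence:
    """A node-matrix encoding of one sequence.

    ``matrix`` has one row per node (4 channels for mono, 16 for di); every
    row sums to 1.  ``capped`` records whether uniform N-cap nodes have been
    attached at both ends.
    """

    node_kind: str
    matrix: np.ndarray
    capped: bool
    source_length: int

    @property
    def n_nodes(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_channels(self) -> int:
        return self.matrix.shape[1]


def _validate(seq: str) -> str:
    if not seq:
        raise ValueError("empty sequence")
    seq = seq.upper()
    for pos, ch in enumerate(seq):
        if ch not in "ACGTN":
            raise ValueError(f"invalid character {ch!r} at position {pos}")
    return seq


def encode_mono(seq: str) -> EncodedSequence:
    """Encode a sequence base-by-base: A,C,G,T one-hot; N uniform."""
    seq = _validate(seq)
    matrix = np.stack([_BASE_ROWS[b] for b in seq])
    return EncodedSequence("per-bp", matrix, capped=False, source_length=len(seq))


def encode_di(seq: str) -> EncodedSequence:
    """Encode a sequence step-by-step over the 16 dinucleotide channels.

    Node ``i`` encodes positions ``(i, i+1)``.  A step containing N averages
    uniformly over its compatible pure dinucleotides, computed as the outer
    product of the two per-base probability rows.
    """
    seq = _validate(seq)
    if len(seq) < 2:
        raise ValueError("per-step encoding needs length >= 2")
    rows = [
        np.outer(_BASE_ROWS[a], _BASE_ROWS[b]).ravel()
        for a, b in zip(seq[:-1], seq[1:])
    ]
    return EncodedSequence("per-step", np.stack(rows), capped=False,
                           source_length=len(seq))


def encode_for(seq: str, node_kind: str) -> EncodedSequence:
    """Dispatch to mono or dinucleotide encoding by node kind."""
    if node_kind == "per-bp":
        return encode_mono(seq)
    if node_kind == "per-step":
        return encode_di(seq)
    raise ValueError(f"unknown node_kind {node_kind!r}")


def _uniform_row(n_channels: int) -> np.ndarray:
    return np.full((1, n_channels), 1.0 / n_channels)


def add_caps(enc: EncodedSequence) -> EncodedSequence:
    """Attach one uniform N-cap node at each end.

    For per-step encodings the caps are "N-step" nodes (uniform 16-vectors).
    Cap nodes self-link on their outer side — see :func:`neighbor_indices`.
    """
    if enc.capped:
        raise ValueError("sequence is already capped")
    cap = _uniform_row(enc.n_channels)
    matrix = np.concatenate([cap, enc.matrix, cap], axis=0)
    return replace(enc, matrix=matrix, capped=True)


def strip_caps(enc: EncodedSequence) -> EncodedSequence:
    if not enc.capped:
        raise ValueError("sequence is not capped")
    return replace(enc, matrix=enc.matrix[1:-1].copy(), capped=False)


def neighbor_indices(n_nodes: int) -> tuple[np.ndarray, np.ndarray]:
    """5' and 3' neighbour index arrays for a capped node chain.

    Terminal (cap) nodes take themselves as their missing outer neighbour,
    so every node has exactly one 5' and one 3' neighbour.
    """
    idx = np.arange(n_nodes)
    left = np.maximum(idx - 1, 0)
    right = np.minimum(idx + 1, n_nodes - 1)
    return left, right


def reverse_complement(seq: str) -> str:
    return _validate(seq).translate(_COMPLEMENT)[::-1]


def read_fasta(path: str | Path) -> Iterator[tuple[str, str]]:
    """Yield ``(record_id, sequence)`` from a FASTA file.

    Sequences are upper-cased; RNA (``U``) and other non-ACGTN characters are
    rejected with the offending position named.
    """
    for record in SeqIO.parse(str(path), "fasta"):
        yield record.id, _validate(str(record.seq))
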