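"""The k-mer query-table baseline: sliding-window shape prediction.

The classical high-throughput approach assigns the shape value at a position
by looking up the mean simulated value of the k-mer window centred there
(a pentamer table for per-bp features).  The window bounds the usable flank
to (k-1)/2 bp, and any k-mer that never occurred in the training corpus has no
entry at all, so this module also ships the diagnostics that expose those two
failure modes: coverage gaps and flank-composition bias (a k-mer whose
occurrences all carry the same flanking bases inherits their influence as a
systematic offset).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .features import ShapeFeatureSpec, rc_transform_profile
from .encoding import reverse_complement
from .training import TrainingExample

__all__ = [
    "QueryTable",
    "build_table",
    "sliding_predict",
    "flank_bias_report",
    "compare_methods",
]

_BASES = "ACGT"


@dataclass
class QueryTable:
    """k-mer -> (mean value, occurrence count); missing k-mers are absent.

    Values are on the raw feature scale.  ``k`` counts nucleotides in the
    window: odd for per-bp features (window centred on a base) and even for
    per-step features (window centred on the middle step).
    """

    k: int
    feature: ShapeFeatureSpec
    entries: dict[str, tuple[float, int]] = field(default_factory=dict)

    @property
    def coverage(self) -> float:
        """Fraction of the 4^k possible k-mers present."""
        return len(self.entries) / 4 ** self.k

    def lookup(self, kmer: str) -> float:
        """Mean value for a k-mer; NaN when absent."""
        hit = self.entries.get(kmer)
        return np.nan if hit is None else hit[0]

    def center_offset(self) -> int:
        """Node index (within the window) whose value the entry stores."""
        if self.feature.node_kind == "per-bp":
            return self.k // 2
        return self.k // 2 - 1

    def write(self, path: str | Path) -> None:
        """TSV ``kmer<TAB>mean<TAB>count``, lexicographically sorted."""
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            for kmer in sorted(self.entries):
                mean, count = self.entries[kmer]
                fh.write(f"{kmer}\t{mean:.15g}\t{count}\n")

    @classmethod
    def read(cls, path: str | Path, feature: ShapeFeatureSpec) -> "QueryTable":
        entries: dict[str, tuple[float, int]] = {}
        k = None
        with open(path, "r", encoding="utf-8") as fh:
            for line in fh:
                kmer, mean, count = line.rstrip("\n").split("\t")
                k = len(kmer)
                entries[kmer] = (float(mean), int(count))
        if k is None:
            raise ValueError(f"empty table file {path}")
        return cls(k=k, feature=feature, entries=entries)


def _validate_k(k: int, feature: ShapeFeatureSpec) -> None:
    if feature.node_kind == "per-bp":
        if k < 3 or k % 2 == 0:
            raise ValueError("per-bp tables need odd k >= 3")
    else:
        if k < 2 or k % 2 == 1:
            raise ValueError("per-step tables need even k >= 2")


def build_table(
    examples: Sequence[TrainingExample],
    feature: ShapeFeatureSpec,
    k: int = 5,
    min_count: int = 1,
    merge_rc: bool = False,
) -> QueryTable:
    """Accumulate every defined central-node value under its k-mer window.

    ``merge_rc`` pools each window with its reverse complement, flipping the
    value's sign for sign-flip-class features (a window and its reverse
    complement describe the same physical stack read from opposite strands).
    Entries seen fewer than ``min_count`` times are dropped.
    """
    _validate_k(k, feature)
    center = k // 2 if feature.node_kind == "per-bp" else k // 2 - 1
    sums: dict[str, float] = {}
    counts: dict[str, int] = {}
    any_window = False
    sign = -1.0 if feature.rc_class == "sign-flip" else 1.0
    for ex in examples:
        seq = ex.sequence
        for start in range(0, len(seq) - k + 1):
            any_window = True
            node = start + center
            if not ex.mask[node]:
                continue
            window = seq[start:start + k]
            if "N" in window:
                continue
            value = float(ex.raw[node])
            if merge_rc:
                rc = reverse_complement(window)
                if rc < window:
                    window, value = rc, sign * value
            sums[window] = sums.get(window, 0.0) + value
            counts[window] = counts.get(window, 0) + 1
    if not any_window:
        raise ValueError(f"k={k} exceeds every sequence length")
    entries = {
        w: (sums[w] / c, c) for w, c in counts.items() if c >= min_count
    }
    return QueryTable(k=k, feature=feature, entries=entries)


def sliding_predict(seq: str, table: QueryTable) -> np.ndarray:
    """Profile over the sequence's nodes; NaN where undefined.

    Positions whose window would run off either end are undefined, as are
    positions whose window is absent from the table (no imputation).  As an
    opt-in fallback, :func:`sliding_predict_with_fallback` retries missing
    windows at k-2.
    """
    seq = seq.upper()
    k = table.k
    if len(seq) < k:
        raise ValueError(f"sequence shorter than k={k}")
    n_nodes = len(seq) - 1 if table.feature.node_kind == "per-step" else len(seq)
    out = np.full(n_nodes, np.nan)
    center = table.center_offset()
    for start in range(0, len(seq) - k + 1):
        out[start + center] = table.lookup(seq[start:start + k])
    return out


def sliding_predict_with_fallback(
    seq: str, table: QueryTable, fallback: QueryTable | None = None
) -> np.ndarray:
    """Sliding prediction that fills missing windows from a k-2 table."""
    out = sliding_predict(seq, table)
    if fallback is not None:
        if fallback.k != table.k - 2:
            raise ValueError("fallback table must have k-2 window")
        inner = sliding_predict(seq, fallback)
        missing = np.isnan(out) & ~np.isnan(inner)
        out[missing] = inner[missing]
    return out


def flank_bias_report(
    examples: Sequence[TrainingExample], k: int,
    node_kind: str = "per-bp",
) -> dict[str, dict]:
    """Observed flanking-base context distribution for every k-mer.

    For each k-mer occurrence with both neighbours present, tallies the pair
    of bases one position outside the window (16 combinations); occurrences
    at sequence ends are excluded.  The bias score is the total-variation
    distance of that empirical distribution from uniform: 0 for perfectly
    balanced flanks, 15/16 for a point mass (every occurrence inside one
    fixed context).
    """
    tallies: dict[str, np.ndarray] = {}
    for ex in examples:
        seq = ex.sequence
        for start in range(1, len(seq) - k):
            window = seq[start:start + k]
            if "N" in window:
                continue
            left, right = seq[start - 1], seq[start + k]
            if left == "N" or right == "N":
                continue
            t = tallies.setdefault(window, np.zeros((4, 4)))
            t[_BASES.index(left), _BASES.index(right)] += 1
    report = {}
    for window, t in tallies.items():
        total = t.sum()
        freq = t / total
        bias = 0.5 * float(np.abs(freq - 1.0 / 16.0).sum())
        report[window] = dict(
            count=int(total), context_freq=freq, bias_score=bias
        )
    return report


MAX_BIAS_SCORE = 15.0 / 16.0


def compare_methods(
    eval_set: Sequence[TrainingExample],
    net,
    table: QueryTable,
    depth: int | None = None,
    symmetrize: bool = False,
) -> dict[str, float]:
    """Raw-scale MAE of the network and the query table on shared positions.

    Only positions where the ground truth is defined *and* the table has a
    value count toward either method's error, so the comparison is apples to
    apples.  ``net`` is anything with a ``predict(seq, depth, symmetrize)``
    returning a raw-scale profile.
    """
    err_net = err_table = 0.0
    n = 0
    for ex in eval_set:
        p_table = sliding_predict(ex.sequence, table)
        p_net = np.asarray(net.predict(ex.sequence, depth=depth,
                                       symmetrize=symmetrize))
        ok = ex.mask & ~np.isnan(p_table) & ~np.isnan(p_net)
        if not ok.any():
            continue
        truth = ex.raw[ok]
        err_net += float(np.abs(p_net[ok] - truth).sum())
        err_table += float(np.abs(p_table[ok] - truth).sum())
        n += int(ok.sum())
    if n == 0:
        raise ValueError("no overlapping defined positions")
    return {"net_mae": err_net / n, "table_mae": err_table / n, "n_positions": n}
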