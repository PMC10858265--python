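"""DNA shape feature vocabulary, normalization, and strand-symmetry transforms.

The helical-parameter vocabulary follows the Curves convention: six inter-bp
(step) features describing translations/rotations between adjacent base pairs,
six intra-bp features describing the geometry within one base pair, and two
minor-groove features (groove width and the electrostatic potential at the
groove center).  Each feature may also carry a fluctuation ("-FL") variant
quantifying its spread across a conformational ensemble.

Shape values from simulation have feature-specific ranges and occasional
extreme outliers, so models are trained on a robust normalized scale

    S_hat = (S - median) / (p99 - p1)

where the median and the 1st/99th percentiles are pooled over the training
corpus.  The denominator uses the ascending percentile difference so that the
map is orientation-preserving and invertible; extreme raw values may map
outside [-1, 1], which is acceptable because the network's tanh output head
bounds predictions to (-1, 1) on the normalized scale.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "ShapeFeatureSpec",
    "NormalizationStats",
    "FeatureRegistry",
    "register_default_features",
    "compute_norm_stats",
    "normalize",
    "denormalize",
    "rc_transform_profile",
    "PER_STEP_FEATURES",
    "INTRA_BP_FEATURES",
    "GROOVE_FEATURES",
]

#: Inter-bp (step) parameters: defined between adjacent base pairs, n-1 values
#: for an n-mer.  Translations in Angstrom, rotations in degrees.
PER_STEP_FEATURES = ("Shift", "Slide", "Rise", "Tilt", "Roll", "HelT")

#: Intra-bp parameters: defined within a single base pair, n values.
INTRA_BP_FEATURES = ("Shear", "Stretch", "Stagger", "Buckle", "ProT", "Opening")

#: Minor-groove features: groove width (Angstrom) and electrostatic potential
#: at the groove center (kT/e); undefined near the termini.
GROOVE_FEATURES = ("MGW", "EP")

_UNITS = {
    "Shift": "Angstrom",
    "Slide": "Angstrom",
    "Rise": "Angstrom",
    "Tilt": "degrees",
    "Roll": "degrees",
    "HelT": "degrees",
    "Shear": "Angstrom",
    "Stretch": "Angstrom",
    "Stagger": "Angstrom",
    "Buckle": "degrees",
    "ProT": "degrees",
    "Opening": "degrees",
    "MGW": "Angstrom",
    "EP": "kT/e",
}

# Behavior under reverse complement, standard helical-parameter convention:
# Shift, Tilt (step) and Shear, Buckle (intra-bp) change sign when the strand
# is reversed; every other parameter is invariant.  Fluctuation variants are
# always invariant (a spread is sign-independent).  Overridable per spec.
_SIGN_FLIP = frozenset({"Shift", "Tilt", "Shear", "Buckle"})


@dataclass(frozen=True)
class ShapeFeatureSpec:
    """Registry entry for one shape feature.

    Attributes
    ----------
    name : feature identifier, e.g. ``"MGW"`` or ``"Roll-FL"``.
    node_kind : ``"per-bp"`` (n values per n-mer) or ``"per-step"`` (n-1).
    units : physical units of the raw values.
    rc_class : ``"invariant"`` or ``"sign-flip"`` under reverse complement.
    terminal_mask_margin : positions undefined at each sequence end in
        training data (groove geometry needs flanking base-pair levels).
    is_fluctuation : True for "-FL" ensemble-spread variants.
    """

    name: str
    node_kind: str
    units: str
    rc_class: str = "invariant"
    terminal_mask_margin: int = 0
    is_fluctuation: bool = False

    def __post_init__(self) -> None:
        if self.node_kind not in ("per-bp", "per-step"):
            raise ValueError(f"unknown node_kind {self.node_kind!r}")
        if self.rc_class not in ("invariant", "sign-flip"):
            raise ValueError(f"unknown rc_class {self.rc_class!r}")

    @property
    def n_channels(self) -> int:
        """Input channels for this feature's encoding (mono=4, di=16)."""
        return 16 if self.node_kind == "per-step" else 4

    def profile_length(self, seq_length: int) -> int:
        return seq_length - 1 if self.node_kind == "per-step" else seq_length


class FeatureRegistry:
    """Case-sensitive name -> :class:`ShapeFeatureSpec` map with presets."""

    def __init__(self) -> None:
        self._specs: dict[str, ShapeFeatureSpec] = {}
        self._presets: dict[str, tuple[str, ...]] = {}

    def add(self, spec: ShapeFeatureSpec) -> None:
        self._specs[spec.name] = spec

    def add_preset(self, name: str, members: Sequence[str]) -> None:
        for m in members:
            if m not in self._specs:
                raise KeyError(f"preset {name!r} references unknown feature {m!r}")
        self._presets[name] = tuple(members)

    def lookup(self, name: str) -> ShapeFeatureSpec:
        try:
            return self._specs[name]
        except KeyError:
            raise KeyError(f"unknown shape feature {name!r}") from None

    __getitem__ = lookup

    def __contains__(self, name: str) -> bool:
        return name in self._specs

    def preset(self, name: str) -> tuple[str, ...]:
        try:
            return self._presets[name]
        except KeyError:
            raise KeyError(f"unknown feature preset {name!r}") from None

    def names(self) -> tuple[str, ...]:
        return tuple(self._specs)

    def override_rc_class(self, name: str, rc_class: str) -> None:
        """Replace the reverse-complement class of a registered feature."""
        self._specs[name] = replace(self.lookup(name), rc_class=rc_class)


def register_default_features() -> FeatureRegistry:
    """Build the default registry: 14 features plus their "-FL" variants.

    Presets: ``"4shape"`` = {MGW, ProT, Roll, HelT}; ``"13shape"`` = MGW plus
    the six inter-bp and six intra-bp features; ``"13shape+FL"`` adds the 13
    matching fluctuation features.
    """
    reg = FeatureRegistry()
    for name in PER_STEP_FEATURES + INTRA_BP_FEATURES + GROOVE_FEATURES:
        node_kind = "per-step" if name in PER_STEP_FEATURES else "per-bp"
        margin = 2 if name in GROOVE_FEATURES else 0
        base = ShapeFeatureSpec(
            name=name,
            node_kind=node_kind,
            units=_UNITS[name],
            rc_class="sign-flip" if name in _SIGN_FLIP else "invariant",
            terminal_mask_margin=margin,
        )
        reg.add(base)
        reg.add(
            ShapeFeatureSpec(
                name=f"{name}-FL",
                node_kind=node_kind,
                units=_UNITS[name],
                rc_class="invariant",
                terminal_mask_margin=margin,
                is_fluctuation=True,
            )
        )

    thirteen = ("MGW",) + PER_STEP_FEATURES + INTRA_BP_FEATURES
    reg.add_preset("4shape", ("MGW", "ProT", "Roll", "HelT"))
    reg.add_preset("13shape", thirteen)
    reg.add_preset("13shape+FL", thirteen + tuple(f"{n}-FL" for n in thirteen))
    return reg


@dataclass(frozen=True)
class NormalizationStats:
    """Median and 1st/99th percentiles of a feature over a training corpus."""

    median: float
    p1: float
    p99: float

    def __post_init__(self) -> None:
        if not (self.p1 <= self.median <= self.p99):
            raise ValueError("require p1 <= median <= p99")

    @property
    def range(self) -> float:
        return self.p99 - self.p1

    def to_json(self) -> str:
        return json.dumps(
            {
                "median": repr(self.median),
                "p1": repr(self.p1),
                "p99": repr(self.p99),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "NormalizationStats":
        d = json.loads(text)
        return cls(float(d["median"]), float(d["p1"]), float(d["p99"]))


def compute_norm_stats(values: Iterable[float]) -> NormalizationStats:
    """Pool values and compute median and 1st/99th percentiles.

    Percentiles use the linear-interpolation convention between order
    statistics so that stats files are reproducible bit-exactly.  Degenerate
    inputs (fewer than two distinct finite values) are rejected: a zero range
    would make the normalization non-invertible.
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size < 2 or not np.all(np.isfinite(arr)):
        raise ValueError("need >= 2 finite values")
    med, p1, p99 = np.percentile(arr, [50.0, 1.0, 99.0], method="linear")
    if p99 - p1 <= 0.0:
        raise ValueError("degenerate stats: 1st and 99th percentiles coincide")
    return NormalizationStats(float(med), float(p1), float(p99))


def normalize(values, stats: NormalizationStats):
    """Map raw shape values to the robust normalized scale.

    Scalar in, scalar out; array in, array out.  NaN entries (masked
    positions) pass through unchanged.
    """
    _check_stats(stats)
    arr = np.asarray(values, dtype=float)
    if np.any(np.isinf(arr)):
        raise ValueError("non-finite shape value")
    out = (arr - stats.median) / stats.range
    return float(out) if np.isscalar(values) or arr.ndim == 0 else out


def denormalize(values, stats: NormalizationStats):
    """Exact inverse of :func:`normalize`."""
    _check_stats(stats)
    arr = np.asarray(values, dtype=float)
    if np.any(np.isinf(arr)):
        raise ValueError("non-finite normalized value")
    out = arr * stats.range + stats.median
    return float(out) if np.isscalar(values) or arr.ndim == 0 else out


def _check_stats(stats: NormalizationStats) -> None:
    if not math.isfinite(stats.range) or stats.range <= 0.0:
        raise ValueError("degenerate normalization stats")


def rc_transform_profile(profile, spec: ShapeFeatureSpec, seq_length: int | None = None):
    """Transform a per-position profile to the reverse-complement strand.

    Reverses position order and flips the sign for sign-flip-class features.
    Involution: applying it twice returns the input.  NaN (masked) entries
    reverse with the rest.  ``seq_length``, when given, validates that the
    profile length matches the feature's node kind.
    """
    arr = np.asarray(profile, dtype=float)
    if arr.ndim != 1:
        raise ValueError("profile must be one-dimensional")
    if seq_length is not None and arr.size != spec.profile_length(seq_length):
        raise ValueError(
            f"profile length {arr.size} does not match {spec.node_kind} "
            f"feature on a {seq_length}-mer"
        )
    out = arr[::-1].copy()
    if spec.rc_class == "sign-flip":
        out = -out
    return out
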