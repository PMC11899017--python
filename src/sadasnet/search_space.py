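"""Bounded hyperparameter search space and genome encoding.

A candidate CNN architecture is encoded as a fixed-length vector of reals in
[0, 1] (the *genome*, a particle position for the swarm optimizer).  Each gene
maps to one integer hyperparameter through a bounded denormalization rule

    V = round(L + (U - L) * P),    P in [0, 1],

where ``L``/``U`` are the inclusive integer bounds of that hyperparameter and
``round`` is round-half-away-from-zero.  Control genes select the layer
variant (standard vs multi-branch convolution) or layer presence (pooling,
fully connected); the remaining genes of an unselected variant travel silently
with the particle, which keeps the dimensionality fixed for PSO.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

__all__ = [
    "ParamRange",
    "SearchSpace",
    "Gene",
    "GenomeLayout",
    "DEFAULT_RANGES",
    "build_layout",
    "denormalize_gene",
    "normalize_value",
    "random_genome",
]


class ConfigurationError(ValueError):
    """Invalid search-space configuration."""


@dataclass(frozen=True)
class ParamRange:
    """Inclusive integer bounds for a single hyperparameter gene."""

    name: str
    lower: int
    upper: int
    role: str

    def __post_init__(self) -> None:
        if int(self.lower) != self.lower or int(self.upper) != self.upper:
            raise ConfigurationError(f"range {self.name!r}: bounds must be integers")
        if self.lower > self.upper:
            raise ConfigurationError(
                f"range {self.name!r}: lower ({self.lower}) > upper ({self.upper})"
            )

    @property
    def width(self) -> int:
        return self.upper - self.lower


#: Default bounds of the architecture search space: standard convolutions
#: (presence/variant control, filter size, filter count, stride), multi-branch
#: convolutions (branch count, filter size, filters per branch), pooling
#: (presence, type, filter size, stride) and fully connected layers
#: (presence, neuron count).
DEFAULT_RANGES: dict[str, ParamRange] = {
    "conv_control": ParamRange("conv_control", 1, 2, "conv_control"),
    "conv_fs": ParamRange("conv_fs", 2, 8, "filter_size"),
    "conv_nf": ParamRange("conv_nf", 8, 512, "filter_count"),
    "conv_s": ParamRange("conv_s", 1, 3, "stride"),
    "mb_nb": ParamRange("mb_nb", 2, 4, "branch_count"),
    "mb_fs": ParamRange("mb_fs", 2, 8, "filter_size"),
    "mb_nf": ParamRange("mb_nf", 4, 128, "filter_count"),
    "pool_control": ParamRange("pool_control", 0, 1, "pool_control"),
    "pool_type": ParamRange("pool_type", 1, 2, "pool_type"),
    "pool_fs": ParamRange("pool_fs", 1, 7, "filter_size"),
    "pool_s": ParamRange("pool_s", 1, 3, "stride"),
    "fc_control": ParamRange("fc_control", 0, 1, "fc_control"),
    "fc_nn": ParamRange("fc_nn", 10, 512, "neuron_count"),
}

#: Gene keys of one macro (feature-extraction) slot, in genome order.
MACRO_KEYS = (
    "conv_control",
    "conv_fs",
    "conv_nf",
    "conv_s",
    "mb_nb",
    "mb_fs",
    "mb_nf",
    "pool_control",
    "pool_type",
    "pool_fs",
    "pool_s",
)

#: Gene keys of one fully-connected slot.
FC_KEYS = ("fc_control", "fc_nn")


@dataclass(frozen=True)
class SearchSpace:
    """Search-space configuration: per-gene bounds plus slot counts.

    ``max_macro_layers`` bounds the number of feature-extraction slots (each
    slot decodes to one convolution or multi-branch block plus an optional
    pooling layer); ``fc_slots`` bounds the number of optional intermediate
    fully connected layers before the classifier head.
    """

    max_macro_layers: int = 13
    fc_slots: int = 1
    ranges: dict[str, ParamRange] = field(default_factory=lambda: dict(DEFAULT_RANGES))

    def __post_init__(self) -> None:
        if self.max_macro_layers < 1:
            raise ConfigurationError("max_macro_layers must be >= 1")
        if self.fc_slots < 0:
            raise ConfigurationError("fc_slots must be >= 0")
        missing = set(DEFAULT_RANGES) - set(self.ranges)
        if missing:
            raise ConfigurationError(f"missing ranges: {sorted(missing)}")

    @classmethod
    def with_overrides(
        cls,
        max_macro_layers: int = 13,
        fc_slots: int = 1,
        overrides: dict[str, tuple[int, int]] | None = None,
    ) -> "SearchSpace":
        ranges = dict(DEFAULT_RANGES)
        for key, (lo, hi) in (overrides or {}).items():
            if key not in ranges:
                raise ConfigurationError(f"unknown range {key!r}")
            ranges[key] = ParamRange(key, lo, hi, ranges[key].role)
        return cls(max_macro_layers=max_macro_layers, fc_slots=fc_slots, ranges=ranges)

    @classmethod
    def small(cls) -> "SearchSpace":
        """Desk-scale preset for CPU-sized experiments on tiny images.

        Shrinks filter counts and depth so that every candidate trains in
        seconds on a single CPU core while keeping the full structural
        variety (conv vs multi-branch, optional pooling, optional FC).
        """
        return cls.with_overrides(
            max_macro_layers=3,
            fc_slots=1,
            overrides={
                "conv_fs": (2, 5),
                "conv_nf": (8, 32),
                "mb_nf": (4, 16),
                "fc_nn": (10, 64),
            },
        )


@dataclass(frozen=True)
class Gene:
    """One genome position: which slot it belongs to and its bounds."""

    index: int
    slot: int
    key: str
    range: ParamRange


@dataclass(frozen=True)
class GenomeLayout:
    """Deterministic map from genome indices to (slot, hyperparameter)."""

    max_macro_layers: int
    fc_slots: int
    gene_map: tuple[Gene, ...]

    @property
    def dimension(self) -> int:
        return len(self.gene_map)

    def index_of(self, slot: int, key: str) -> int:
        for g in self.gene_map:
            if g.slot == slot and g.key == key:
                return g.index
        raise KeyError(f"no gene for slot {slot}, key {key!r}")

    def macro_slots(self) -> Iterator[int]:
        return iter(range(self.max_macro_layers))

    def fc_slot_ids(self) -> Iterator[int]:
        return iter(range(self.max_macro_layers, self.max_macro_layers + self.fc_slots))


def build_layout(space: SearchSpace) -> GenomeLayout:
    """Lay out the genome: one contiguous gene group per slot.

    Macro slots come first (conv/multi-branch genes then pooling genes),
    followed by the fully-connected slots.  The genome length is a pure
    function of the configuration.
    """
    genes: list[Gene] = []
    idx = 0
    for slot in range(space.max_macro_layers):
        for key in MACRO_KEYS:
            genes.append(Gene(idx, slot, key, space.ranges[key]))
            idx += 1
    for fc in range(space.fc_slots):
        slot = space.max_macro_layers + fc
        for key in FC_KEYS:
            genes.append(Gene(idx, slot, key, space.ranges[key]))
            idx += 1
    return GenomeLayout(space.max_macro_layers, space.fc_slots, tuple(genes))


def denormalize_gene(p: float, prange: ParamRange) -> int:
    """Map a normalized coordinate to an integer hyperparameter value.

    ``V = round(L + (U - L) * P)`` with round-half-away-from-zero; attains
    ``L`` at ``p = 0`` and ``U`` at ``p = 1`` and is monotone in between.
    """
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"normalized coordinate {p} outside [0, 1]; clamp first")
    v = prange.lower + prange.width * p
    return int(math.floor(v + 0.5))  # half-away-from-zero for nonneg bounds


def normalize_value(v: int, prange: ParamRange) -> float:
    """Inverse of :func:`denormalize_gene`; exact round trip for integers."""
    if not (prange.lower <= v <= prange.upper):
        raise ValueError(
            f"value {v} outside range {prange.name!r} [{prange.lower}, {prange.upper}]"
        )
    if prange.width == 0:
        return 0.0
    return (v - prange.lower) / prange.width


def random_genome(layout: GenomeLayout, rng: np.random.Generator) -> np.ndarray:
    """Uniform random genome in [0, 1]^D; reproducible for a given generator."""
    return rng.random(layout.dimension)
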