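"""Decoding genomes into concrete CNN macro-architectures.

A genome decodes slot by slot: the convolution control gene selects either a
standard convolution (filter size, filter count, stride) or an inception-style
multi-branch block (2-4 parallel branches with kernels 1, 3, 5, 7 and a shared
per-branch filter count, concatenated channel-wise); the pooling control gene
optionally appends a max or average pooling layer; fully-connected control
genes optionally insert hidden dense layers.  A classifier head — global
average pooling, a dense layer to ``num_classes`` and softmax — is always
appended.

Shape conventions: convolutions use SAME padding (output spatial extent =
ceil(in / stride)); pooling uses VALID padding (floor((in - FS) / S) + 1).  A
pooling layer whose filter exceeds the current spatial extent is infeasible
and is removed by :func:`repair`, mirroring the search's layer-removal rule.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np

from .search_space import GenomeLayout, denormalize_gene, normalize_value

__all__ = [
    "ConvBlockSpec",
    "MultiBranchSpec",
    "PoolSpec",
    "FCSpec",
    "ArchitectureSpec",
    "ShapeRow",
    "decode",
    "propagate_shapes",
    "repair",
    "feasibility_check",
    "count_parameters",
    "count_flops",
    "serialize",
    "deserialize",
]

SCHEMA_VERSION = 1


class DecodeError(ValueError):
    pass


class ParseError(ValueError):
    pass


@dataclass(frozen=True)
class ConvBlockSpec:
    kind = "conv"
    filter_size: int
    num_filters: int
    stride: int


@dataclass(frozen=True)
class MultiBranchSpec:
    """Parallel convolutions with kernels 1, 3, 5, 7 (branch i -> 2i-1),
    stride 1, SAME padding; outputs concatenated along channels."""

    kind = "multibranch"
    num_branches: int
    filters_per_branch: int

    @property
    def branch_kernels(self) -> tuple[int, ...]:
        return tuple(2 * i - 1 for i in range(1, self.num_branches + 1))

    @property
    def out_channels(self) -> int:
        return self.num_branches * self.filters_per_branch


@dataclass(frozen=True)
class PoolSpec:
    kind = "pool"
    pool_type: str  # "max" | "average"
    filter_size: int
    stride: int


@dataclass(frozen=True)
class FCSpec:
    kind = "fc"
    num_neurons: int


Layer = ConvBlockSpec | MultiBranchSpec | PoolSpec | FCSpec


@dataclass(frozen=True)
class ArchitectureSpec:
    """An ordered CNN macro-architecture plus its fixed classifier head."""

    input_shape: tuple[int, int, int]  # (H, W, C)
    layers: tuple[Layer, ...]
    num_classes: int
    provenance: dict[str, Any] = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if self.num_classes < 2:
            raise DecodeError("num_classes must be >= 2")
        h, w, c = self.input_shape
        if min(h, w, c) < 1:
            raise DecodeError(f"invalid input shape {self.input_shape}")


@dataclass(frozen=True)
class ShapeRow:
    index: int  # -1 for the classifier head entries
    kind: str
    out_h: int
    out_w: int
    out_c: int
    feasible: bool


def decode(
    genome: Sequence[float],
    layout: GenomeLayout,
    input_shape: tuple[int, int, int],
    num_classes: int,
) -> ArchitectureSpec:
    """Decode a genome into an architecture (deterministic).

    The multi-branch filter-size gene is decoded but unused: branch kernels
    are fixed at 1/3/5/7 by branch position. Its value is recorded in the
    provenance for audit.
    """
    g = np.asarray(genome, dtype=float)
    if g.ndim != 1 or g.shape[0] != layout.dimension:
        raise DecodeError(
            f"genome length {g.shape} does not match layout dimension {layout.dimension}"
        )

    def val(slot: int, key: str) -> int:
        gene = layout.gene_map[layout.index_of(slot, key)]
        return denormalize_gene(float(g[gene.index]), gene.range)

    layers: list[Layer] = []
    unused_mb_fs: list[int] = []
    for slot in layout.macro_slots():
        control = val(slot, "conv_control")
        if control == 1:
            layers.append(
                ConvBlockSpec(
                    filter_size=val(slot, "conv_fs"),
                    num_filters=val(slot, "conv_nf"),
                    stride=val(slot, "conv_s"),
                )
            )
        else:
            layers.append(
                MultiBranchSpec(
                    num_branches=val(slot, "mb_nb"),
                    filters_per_branch=val(slot, "mb_nf"),
                )
            )
            unused_mb_fs.append(val(slot, "mb_fs"))
        if val(slot, "pool_control") == 1:
            layers.append(
                PoolSpec(
                    pool_type="max" if val(slot, "pool_type") == 1 else "average",
                    filter_size=val(slot, "pool_fs"),
                    stride=val(slot, "pool_s"),
                )
            )
    for slot in layout.fc_slot_ids():
        if val(slot, "fc_control") == 1:
            layers.append(FCSpec(num_neurons=val(slot, "fc_nn")))

    digest = hashlib.sha256(np.ascontiguousarray(g).tobytes()).hexdigest()[:16]
    return ArchitectureSpec(
        input_shape=tuple(input_shape),
        layers=tuple(layers),
        num_classes=num_classes,
        provenance={"genome_sha256_16": digest, "unused_mb_fs_genes": unused_mb_fs},
    )


def _conv_out(extent: int, stride: int) -> int:
    return math.ceil(extent / stride)  # SAME padding


def _pool_out(extent: int, fs: int, stride: int) -> int:
    return (extent - fs) // stride + 1  # VALID padding


def propagate_shapes(arch: ArchitectureSpec) -> list[ShapeRow]:
    """Per-layer output shapes, including the classifier head.

    Rows with ``feasible=False`` mark layers that cannot be applied to the
    incoming feature map (pool filter larger than the spatial extent); they
    are left in place for :func:`repair` to consume, and shape propagation
    continues as if the layer were absent.
    """
    h, w, c = arch.input_shape
    rows: list[ShapeRow] = []
    for i, layer in enumerate(arch.layers):
        if isinstance(layer, ConvBlockSpec):
            h, w = _conv_out(h, layer.stride), _conv_out(w, layer.stride)
            c = layer.num_filters
            rows.append(ShapeRow(i, "conv", h, w, c, True))
        elif isinstance(layer, MultiBranchSpec):
            # all branches stride 1, SAME padding: spatial extent preserved
            c = layer.out_channels
            rows.append(ShapeRow(i, "multibranch", h, w, c, True))
        elif isinstance(layer, PoolSpec):
            oh = _pool_out(h, layer.filter_size, layer.stride)
            ow = _pool_out(w, layer.filter_size, layer.stride)
            if oh < 1 or ow < 1:
                rows.append(ShapeRow(i, "pool", h, w, c, False))
            else:
                h, w = oh, ow
                rows.append(ShapeRow(i, "pool", h, w, c, True))
        elif isinstance(layer, FCSpec):
            h = w = 1  # preceded by global average pooling
            c = layer.num_neurons
            rows.append(ShapeRow(i, "fc", 1, 1, c, True))
        else:  # pragma: no cover
            raise TypeError(f"unknown layer {layer!r}")
    rows.append(ShapeRow(-1, "head", 1, 1, arch.num_classes, True))
    return rows


def repair(arch: ArchitectureSpec) -> tuple[ArchitectureSpec, list[Layer]]:
    """Remove layers that cannot be applied to the current feature-map size.

    Returns the repaired architecture and the list of removed layers.  Always
    succeeds; an architecture reduced to its classifier head is still valid.
    Idempotent.
    """
    removed: list[Layer] = []
    current = arch
    while True:
        rows = propagate_shapes(current)
        bad = [r.index for r in rows if not r.feasible]
        if not bad:
            return current, removed
        first = bad[0]
        removed.append(current.layers[first])
        current = ArchitectureSpec(
            input_shape=current.input_shape,
            layers=current.layers[:first] + current.layers[first + 1 :],
            num_classes=current.num_classes,
            provenance=current.provenance,
        )


def feasibility_check(
    arch: ArchitectureSpec,
    max_parameters: int,
    max_activation_cells: int,
) -> dict[str, Any]:
    """Hardware-budget proxy: total learnable parameters and the peak
    per-sample activation cell count must both fit the budget.

    Candidates that fail receive worst-case fitness instead of being trained.
    """
    total = count_parameters(arch)["total"]
    rows = propagate_shapes(arch)
    h, w, c = arch.input_shape
    peak = h * w * c
    for r in rows:
        if r.feasible:
            peak = max(peak, r.out_h * r.out_w * r.out_c)
    violated = []
    if total > max_parameters:
        violated.append("max_parameters")
    if peak > max_activation_cells:
        violated.append("max_activation_cells")
    return {
        "feasible": not violated,
        "violated": violated,
        "total_parameters": total,
        "peak_activation_cells": peak,
    }


def _feasible_shape_seq(arch: ArchitectureSpec) -> list[tuple[int, str, int, int, int]]:
    rows = propagate_shapes(arch)
    if any(not r.feasible for r in rows):
        raise DecodeError("architecture has infeasible layers; repair first")
    return [(r.index, r.kind, r.out_h, r.out_w, r.out_c) for r in rows]


def count_parameters(arch: ArchitectureSpec) -> dict[str, Any]:
    """Per-layer learnable parameter counts (weights + biases) and total.

    Convolutions count ``FS^2 * Cin * NF + NF``; each multi-branch branch is
    counted as its own convolution; pooling carries no parameters; the head's
    dense layer counts ``Cin * K + K`` on the globally pooled 1x1 feature
    map.  Each multi-branch branch gets its own row, mirroring how such
    blocks are reported layer-by-layer.
    """
    h, w, cin = arch.input_shape
    rows: list[dict[str, Any]] = []
    total = 0
    features = None  # set once spatial part ends (first FC or head)
    shape_rows = _feasible_shape_seq(arch)
    for (i, kind, oh, ow, oc), layer in zip(shape_rows[:-1], arch.layers):
        if isinstance(layer, ConvBlockSpec):
            p = layer.filter_size**2 * cin * layer.num_filters + layer.num_filters
            rows.append(
                {
                    "index": i,
                    "name": f"conv_{i}",
                    "kind": "conv",
                    "activations": (oh, ow),
                    "num_filters": layer.num_filters,
                    "kernel": layer.filter_size,
                    "stride": layer.stride,
                    "parameters": p,
                }
            )
            total += p
            cin = oc
        elif isinstance(layer, MultiBranchSpec):
            for b, k in enumerate(layer.branch_kernels, start=1):
                p = k**2 * cin * layer.filters_per_branch + layer.filters_per_branch
                rows.append(
                    {
                        "index": i,
                        "name": f"multibranch_{i}_branch_{b}",
                        "kind": "multibranch_branch",
                        "activations": (oh, ow),
                        "num_filters": layer.filters_per_branch,
                        "kernel": k,
                        "stride": 1,
                        "parameters": p,
                    }
                )
                total += p
            cin = oc
        elif isinstance(layer, PoolSpec):
            rows.append(
                {
                    "index": i,
                    "name": f"pool_{i}",
                    "kind": f"{layer.pool_type}_pool",
                    "activations": (oh, ow),
                    "num_filters": cin,
                    "kernel": layer.filter_size,
                    "stride": layer.stride,
                    "parameters": 0,
                }
            )
        elif isinstance(layer, FCSpec):
            if features is None:
                features = cin  # global average pooling collapses H x W
            p = features * layer.num_neurons + layer.num_neurons
            rows.append(
                {
                    "index": i,
                    "name": f"fc_{i}",
                    "kind": "fc",
                    "activations": (1, 1),
                    "num_filters": layer.num_neurons,
                    "kernel": 1,
                    "stride": 1,
                    "parameters": p,
                }
            )
            total += p
            features = layer.num_neurons
    if features is None:
        features = cin
    head = features * arch.num_classes + arch.num_classes
    rows.append(
        {
            "index": -1,
            "name": "classifier",
            "kind": "fc",
            "activations": (1, 1),
            "num_filters": arch.num_classes,
            "kernel": 1,
            "stride": 1,
            "parameters": head,
        }
    )
    total += head
    return {"layers": rows, "total": total}


def count_flops(arch: ArchitectureSpec) -> dict[str, Any]:
    """Per-layer FLOPs under the multiply-plus-add convention.

    conv: ``2 * FS^2 * Cin * NF * Hout * Wout``; dense: ``2 * Cin * Cout``;
    pooling and elementwise activations are counted as zero.  The convention
    is stated in the output metadata because published FLOP figures vary by
    counting rule.
    """
    h, w, cin = arch.input_shape
    rows: list[dict[str, Any]] = []
    total = 0
    features = None
    shape_rows = _feasible_shape_seq(arch)
    for (i, kind, oh, ow, oc), layer in zip(shape_rows[:-1], arch.layers):
        if isinstance(layer, ConvBlockSpec):
            f = 2 * layer.filter_size**2 * cin * layer.num_filters * oh * ow
            rows.append({"index": i, "name": f"conv_{i}", "flops": f})
            total += f
            cin = oc
        elif isinstance(layer, MultiBranchSpec):
            for b, k in enumerate(layer.branch_kernels, start=1):
                f = 2 * k**2 * cin * layer.filters_per_branch * oh * ow
                rows.append(
                    {"index": i, "name": f"multibranch_{i}_branch_{b}", "flops": f}
                )
                total += f
            cin = oc
        elif isinstance(layer, PoolSpec):
            rows.append({"index": i, "name": f"pool_{i}", "flops": 0})
        elif isinstance(layer, FCSpec):
            if features is None:
                features = cin
            f = 2 * features * layer.num_neurons
            rows.append({"index": i, "name": f"fc_{i}", "flops": f})
            total += f
            features = layer.num_neurons
    if features is None:
        features = cin
    head = 2 * features * arch.num_classes
    rows.append({"index": -1, "name": "classifier", "flops": head})
    total += head
    return {
        "layers": rows,
        "total": total,
        "convention": "2*FS^2*Cin*NF*Hout*Wout per conv; 2*Cin*Cout per dense; pooling/activations zero",
    }


def _layer_to_doc(layer: Layer) -> dict[str, Any]:
    if isinstance(layer, ConvBlockSpec):
        return {
            "kind": "conv",
            "filter_size": layer.filter_size,
            "num_filters": layer.num_filters,
            "stride": layer.stride,
        }
    if isinstance(layer, MultiBranchSpec):
        return {
            "kind": "multibranch",
            "num_branches": layer.num_branches,
            "filters_per_branch": layer.filters_per_branch,
        }
    if isinstance(layer, PoolSpec):
        return {
            "kind": "pool",
            "pool_type": layer.pool_type,
            "filter_size": layer.filter_size,
            "stride": layer.stride,
        }
    if isinstance(layer, FCSpec):
        return {"kind": "fc", "num_neurons": layer.num_neurons}
    raise TypeError(f"unknown layer {layer!r}")  # pragma: no cover


def _layer_from_doc(doc: dict[str, Any], where: str) -> Layer:
    try:
        kind = doc["kind"]
        if kind == "conv":
            return ConvBlockSpec(doc["filter_size"], doc["num_filters"], doc["stride"])
        if kind == "multibranch":
            return MultiBranchSpec(doc["num_branches"], doc["filters_per_branch"])
        if kind == "pool":
            return PoolSpec(doc["pool_type"], doc["filter_size"], doc["stride"])
        if kind == "fc":
            return FCSpec(doc["num_neurons"])
    except KeyError as e:
        raise ParseError(f"{where}: missing field {e.args[0]!r}") from None
    raise ParseError(f"{where}: unknown layer kind {kind!r}")


def serialize(arch: ArchitectureSpec, include_derived: bool = True) -> str:
    """Human-readable JSON document; loss-free round trip via :func:`deserialize`."""
    doc: dict[str, Any] = {
        "schema_version": SCHEMA_VERSION,
        "input_shape": list(arch.input_shape),
        "num_classes": arch.num_classes,
        "layers": [_layer_to_doc(l) for l in arch.layers],
        "provenance": arch.provenance,
    }
    if include_derived:
        try:
            doc["derived"] = {
                "shapes": [
                    {"index": r.index, "kind": r.kind, "out": [r.out_h, r.out_w, r.out_c]}
                    for r in propagate_shapes(arch)
                ],
                "parameters": count_parameters(arch),
                "flops": count_flops(arch),
            }
        except DecodeError:
            doc["derived"] = None  # unrepaired architecture
    return json.dumps(doc, indent=2)


def deserialize(document: str) -> ArchitectureSpec:
    try:
        doc = json.loads(document)
    except json.JSONDecodeError as e:
        raise ParseError(f"invalid JSON at line {e.lineno}, column {e.colno}: {e.msg}")
    for key in ("input_shape", "num_classes", "layers"):
        if key not in doc:
            raise ParseError(f"document missing required field {key!r}")
    layers = tuple(
        _layer_from_doc(d, f"layers[{i}]") for i, d in enumerate(doc["layers"])
    )
    return ArchitectureSpec(
        input_shape=tuple(doc["input_shape"]),
        layers=layers,
        num_classes=int(doc["num_classes"]),
        provenance=doc.get("provenance", {}),
    )
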