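"""The published CNN224_5_40 reference model.

CNN224_5_40 is the best architecture found by the search on 224x224x3
dermoscopy images with a swarm of 5 particles over 40 iterations (the model
naming convention is ``CNN{image_size}_{population}_{iterations}``).  Its
printed layer table serves as the ground truth for decode and parameter
accounting: here the model is expressed as per-slot hyperparameters,
inverse-mapped into a genome with :func:`normalize_value`, and decoded back —
so the whole encode/decode/count pipeline is exercised, not just a hard-coded
layer list.

Macro-slot structure (6 slots):

====  =========================================  ==================
slot  feature extractor                          pooling
====  =========================================  ==================
1     multi-branch, 3 branches x 87 filters      max, FS 6, S 2
2     conv 6x6, 112 filters, stride 2            max, FS 4, S 2
3     multi-branch, 4 branches x 102 filters     max, FS 4, S 2
4     conv 6x6, 144 filters, stride 2            max, FS 4, S 2
5     multi-branch, 3 branches x 41 filters      (none)
6     multi-branch, 3 branches x 28 filters      (none)
====  =========================================  ==================

followed by the fixed classifier head (global average pooling -> dense to 7
lesion classes -> softmax).  The printed table shows a 1x1 pooling filter for
the first pooling layer, which cannot map 224 -> 110 under any standard
convention; FS 6 (VALID: floor((224-6)/2)+1 = 110) reproduces the printed
spatial extent and pooling filters carry no parameters either way.
"""

from __future__ import annotations

import numpy as np

from .architecture import ArchitectureSpec, decode
from .search_space import (
    GenomeLayout,
    SearchSpace,
    build_layout,
    normalize_value,
)

__all__ = [
    "INPUT_SHAPE",
    "NUM_CLASSES",
    "HAM10000_CLASSES",
    "HAM10000_CLASS_COUNTS",
    "reference_layout",
    "reference_genome",
    "reference_architecture",
]

INPUT_SHAPE = (224, 224, 3)
NUM_CLASSES = 7

#: The seven HAM10000 lesion classes, sorted (label order used throughout).
HAM10000_CLASSES = ("akiec", "bcc", "bkl", "df", "mel", "nv", "vasc")

#: Published per-class image counts of the HAM10000 dataset.
HAM10000_CLASS_COUNTS = {
    "nv": 6705,
    "mel": 1113,
    "bkl": 1099,
    "bcc": 514,
    "akiec": 327,
    "vasc": 142,
    "df": 115,
}

# per macro slot: {gene key: integer hyperparameter value}
_SLOTS: list[dict[str, int]] = [
    {"conv_control": 2, "mb_nb": 3, "mb_nf": 87,
     "pool_control": 1, "pool_type": 1, "pool_fs": 6, "pool_s": 2},
    {"conv_control": 1, "conv_fs": 6, "conv_nf": 112, "conv_s": 2,
     "pool_control": 1, "pool_type": 1, "pool_fs": 4, "pool_s": 2},
    {"conv_control": 2, "mb_nb": 4, "mb_nf": 102,
     "pool_control": 1, "pool_type": 1, "pool_fs": 4, "pool_s": 2},
    {"conv_control": 1, "conv_fs": 6, "conv_nf": 144, "conv_s": 2,
     "pool_control": 1, "pool_type": 1, "pool_fs": 4, "pool_s": 2},
    {"conv_control": 2, "mb_nb": 3, "mb_nf": 41, "pool_control": 0},
    {"conv_control": 2, "mb_nb": 3, "mb_nf": 28, "pool_control": 0},
]


def reference_layout() -> GenomeLayout:
    """Six macro slots, one FC slot (switched off in the reference genome)."""
    return build_layout(SearchSpace.with_overrides(max_macro_layers=6, fc_slots=1))


def reference_genome(layout: GenomeLayout | None = None) -> tuple[np.ndarray, GenomeLayout]:
    """Genome whose decode reproduces CNN224_5_40, via inverse mapping."""
    layout = layout or reference_layout()
    genome = np.zeros(layout.dimension)
    for slot, values in enumerate(_SLOTS):
        for key, v in values.items():
            gene = layout.gene_map[layout.index_of(slot, key)]
            genome[gene.index] = normalize_value(v, gene.range)
    # fc slot: control 0 -> no hidden dense layer (already zero)
    return genome, layout


def reference_architecture() -> ArchitectureSpec:
    genome, layout = reference_genome()
    return decode(genome, layout, INPUT_SHAPE, NUM_CLASSES)
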