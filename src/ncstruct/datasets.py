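"""Bookkeeping for a reference Rfam-derived benchmark composition.

The reference benchmark draws 13 ncRNA classes from Rfam: 500 training
sequences per class except IRES (only 320 non-redundant sequences
available), and an independent validation set of 200 sequences per class.
For the comparison against a reference tool lacking a scaRNA model, the
scaRNA validation sequences are excluded.  These helpers recompute the
dataset sizes from the per-class manifest rather than hard-coding totals.
"""

from __future__ import annotations

from itertools import product

__all__ = [
    "NCRNA_CLASSES",
    "TRAINING_CLASS_COUNTS",
    "VALIDATION_PER_CLASS",
    "training_dataset_size",
    "validation_dataset_size",
    "comparison_subset_size",
    "kernel_configuration_bound",
]

NCRNA_CLASSES = (
    "miRNA",
    "5S_rRNA",
    "5.8S_rRNA",
    "ribozyme",
    "CD-box",
    "HACA-box",
    "scaRNA",
    "tRNA",
    "Intron_gpI",
    "Intron_gpII",
    "IRES",
    "leader",
    "riboswitch",
)

TRAINING_CLASS_COUNTS = {name: (320 if name == "IRES" else 500) for name in NCRNA_CLASSES}

VALIDATION_PER_CLASS = 200


def training_dataset_size() -> int:
    """Total training sequences across the 13-class manifest."""
    return sum(TRAINING_CLASS_COUNTS.values())


def validation_dataset_size() -> int:
    """Total independent validation sequences (all 13 classes)."""
    return VALIDATION_PER_CLASS * len(NCRNA_CLASSES)


def comparison_subset_size(excluded: str = "scaRNA") -> int:
    """Validation sequences usable for the cross-tool comparison
    (one class removed because the reference tool was never trained on it)."""
    if excluded not in NCRNA_CLASSES:
        raise ValueError(f"unknown class {excluded!r}")
    return validation_dataset_size() - VALIDATION_PER_CLASS


def kernel_configuration_bound(k: int = 5) -> int:
    """Number of distinct nonzero binary patterns a width-k kernel can meet.

    Counted by enumeration; this bounds how many genuinely different
    first-layer kernels a binary input can support.
    """
    if k < 1:
        raise ValueError("k must be positive")
    return sum(1 for bits in product((0, 1), repeat=k) if any(bits))
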