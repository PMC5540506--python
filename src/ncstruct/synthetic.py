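"""Synthetic ncRNA-like datasets with class-specific structural motifs.

Each class is defined by a fixed hairpin signature: a stem of length
``3 + c`` (class index c) with a class-specific loop trinucleotide.  The
motif — sequence and its dot-bracket structure — is embedded at a seeded
random offset inside random unpaired flanking sequence, so a class's
records all share a characteristic sub-structure that the miner can
recover as a frequent fragment.  Mutation noise substitutes nucleotides
(sequence only; the structure string is kept), emulating mismatch between
a sequence and its predicted structure.

``toy_fold`` is a small base-pair-maximisation folder (Nussinov-style
dynamic programming over Watson-Crick + GU pairs, minimum hairpin loop of
three) used to exercise the FASTA-only code path where no structures are
provided; the generator itself emits ground-truth structures.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from pathlib import Path
from typing import Sequence

import numpy as np

from .records import (
    NcRnaRecord,
    write_fasta,
    write_labels,
    write_structures,
)

__all__ = ["SyntheticSpec", "generate_dataset", "toy_fold", "write_dataset", "class_motif"]

_BASES = "ACGU"
_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}
_PAIRABLE = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}
_LOOPS = ["".join(p) for p in product(_BASES, repeat=3)]
_STEM_POOL = "GCAUGGCUACGUAGCCAUGC"  # fixed per-class stem template source


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for one synthetic dataset."""

    n_classes: int = 5
    per_class: int = 40
    length_range: tuple[int, int] = (40, 60)
    mutation_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")
        if self.per_class < 1:
            raise ValueError("per_class must be >= 1")
        if not (0.0 <= self.mutation_rate <= 1.0):
            raise ValueError("mutation_rate must be in [0, 1]")
        lo, hi = self.length_range
        if lo > hi:
            raise ValueError("length_range min > max")
        longest = _motif_length(self.n_classes - 1)
        if lo < longest:
            raise ValueError(
                f"length_range min {lo} shorter than the longest class motif "
                f"({longest} nt)"
            )


def _motif_length(c: int) -> int:
    return 2 * (3 + c) + 3


def class_motif(c: int) -> tuple[str, str]:
    """(sequence, structure) of class c's hairpin signature.

    Stem length 3 + c drawn from a fixed template, loop = a class-specific
    trinucleotide; structure is the corresponding nested hairpin.
    """
    stem_len = 3 + c
    stem5 = "".join(
        _STEM_POOL[(c + i) % len(_STEM_POOL)] for i in range(stem_len)
    )
    loop = _LOOPS[(5 * c) % len(_LOOPS)]
    stem3 = "".join(_COMPLEMENT[b] for b in reversed(stem5))
    seq = stem5 + loop + stem3
    struct = "(" * stem_len + "..." + ")" * stem_len
    return seq, struct


def generate_dataset(spec: SyntheticSpec) -> list[NcRnaRecord]:
    """Deterministically generate labelled records with structures."""
    rng = np.random.default_rng(spec.seed)
    # mutations draw from their own stream so the same seed yields the same
    # records and structures at every mutation rate
    mut_rng = np.random.default_rng(spec.seed + 90001)
    lo, hi = spec.length_range
    records: list[NcRnaRecord] = []
    for c in range(spec.n_classes):
        motif_seq, motif_struct = class_motif(c)
        label = f"class{c:02d}"
        for i in range(spec.per_class):
            length = int(rng.integers(lo, hi + 1))
            offset = int(rng.integers(0, length - len(motif_seq) + 1))
            tail = length - offset - len(motif_seq)
            flank5 = "".join(_BASES[b] for b in rng.integers(0, 4, size=offset))
            flank3 = "".join(_BASES[b] for b in rng.integers(0, 4, size=tail))
            seq = list(flank5 + motif_seq + flank3)
            struct = "." * offset + motif_struct + "." * tail
            if spec.mutation_rate > 0:
                hits = mut_rng.random(length) < spec.mutation_rate
                for pos in np.flatnonzero(hits):
                    current = seq[pos]
                    choices = [b for b in _BASES if b != current]
                    seq[pos] = choices[int(mut_rng.integers(0, 3))]
            records.append(
                NcRnaRecord(
                    id=f"{label}_{i:04d}",
                    sequence="".join(seq),
                    structure=struct,
                    class_label=label,
                )
            )
    return records


def toy_fold(sequence: str) -> str:
    """Base-pair maximisation folding (nested structures only).

    Dynamic programming over Watson-Crick and GU wobble pairs with a
    minimum hairpin loop of 3 unpaired bases; the traceback is
    deterministic, preferring to pair the leftmost base with its smallest
    admissible partner.
    """
    if not sequence:
        raise ValueError("empty sequence")
    bad = set(sequence) - set(_BASES)
    if bad:
        raise ValueError(f"sequence contains non-ACGU characters: {sorted(bad)}")
    n = len(sequence)
    M = [[0] * n for _ in range(n)]
    for span in range(4, n):
        for i in range(0, n - span):
            j = i + span
            best = M[i + 1][j]
            for k in range(i + 4, j + 1):
                if (sequence[i], sequence[k]) in _PAIRABLE:
                    inner = M[i + 1][k - 1] if k - 1 >= i + 1 else 0
                    rest = M[k + 1][j] if k + 1 <= j else 0
                    best = max(best, inner + rest + 1)
            M[i][j] = best

    structure = ["."] * n

    def traceback(i: int, j: int) -> None:
        while i < j:
            target = M[i][j]
            paired = False
            for k in range(i + 4, j + 1):
                if (sequence[i], sequence[k]) in _PAIRABLE:
                    inner = M[i + 1][k - 1] if k - 1 >= i + 1 else 0
                    rest = M[k + 1][j] if k + 1 <= j else 0
                    if inner + rest + 1 == target:
                        structure[i] = "("
                        structure[k] = ")"
                        traceback(i + 1, k - 1)
                        i = k + 1
                        paired = True
                        break
            if not paired:
                i += 1

    traceback(0, n - 1)
    return "".join(structure)


def write_dataset(
    records: Sequence[NcRnaRecord], out_dir: str | Path
) -> dict[str, Path]:
    """Write FASTA + structure file + label manifest consumable end-to-end."""
    if not records:
        raise ValueError("no records to write")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": out / "sequences.fasta",
        "structures": out / "structures.txt",
        "labels": out / "labels.tsv",
    }
    write_fasta(records, paths["fasta"])
    write_structures(records, paths["structures"])
    write_labels(records, paths["labels"])
    return paths
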