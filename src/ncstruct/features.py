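"""Boolean fragment-containment features.

The mined fragments define a feature space: graph *i* gets a binary vector
whose *j*-th entry says whether fragment *j* embeds in it (the A(g, s)
matrix).  At training time the matrix follows directly from the miner's
per-fragment supporting ids; unseen graphs are *projected* into the frozen
feature space by exact sub-graph matching — no re-mining, absent fragments
simply score 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .graphs import StructureGraph
from .isomorphism import HostGraph, has_embedding
from .mining import Fragment

__all__ = [
    "FeatureMatrix",
    "contains_fragment",
    "build_feature_matrix",
    "feature_matrix_from_mining",
    "project",
    "write_matrix",
    "read_matrix",
]

_MATRIX_HEADER = "# ncstruct feature matrix v1"


@dataclass(frozen=True)
class FeatureMatrix:
    """Boolean graphs x fragments containment matrix with ordered axes."""

    graph_ids: tuple[str, ...]
    fragments: tuple[Fragment, ...]
    values: np.ndarray  # uint8, shape (len(graph_ids), len(fragments))

    def __post_init__(self) -> None:
        vals = np.asarray(self.values)
        if vals.shape != (len(self.graph_ids), len(self.fragments)):
            raise ValueError(
                f"matrix shape {vals.shape} does not match "
                f"({len(self.graph_ids)}, {len(self.fragments)})"
            )
        if vals.size and not np.isin(vals, (0, 1)).all():
            raise ValueError("feature matrix values must be 0/1")

    @property
    def fragment_codes(self) -> tuple[str, ...]:
        return tuple(f.canonical_code for f in self.fragments)


def contains_fragment(graph: StructureGraph, fragment: Fragment) -> bool:
    """True iff a label- and bond-preserving embedding of the fragment exists."""
    host = HostGraph.from_structure_graph(graph)
    return has_embedding(fragment.node_labels, fragment.edges, host)


def _check_graphs(graphs: Sequence[StructureGraph]) -> None:
    ids = [g.graph_id for g in graphs]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate graph ids")


def build_feature_matrix(
    graphs: Sequence[StructureGraph], fragments: Sequence[Fragment]
) -> FeatureMatrix:
    """Containment matrix computed by explicit sub-graph matching."""
    if not graphs:
        raise ValueError("empty graph list")
    if not fragments:
        raise ValueError("empty feature space")
    _check_graphs(graphs)
    values = np.zeros((len(graphs), len(fragments)), dtype=np.uint8)
    for i, g in enumerate(graphs):
        host = HostGraph.from_structure_graph(g)
        for j, f in enumerate(fragments):
            if has_embedding(f.node_labels, f.edges, host):
                values[i, j] = 1
    return FeatureMatrix(
        graph_ids=tuple(g.graph_id for g in graphs),
        fragments=tuple(fragments),
        values=values,
    )


def feature_matrix_from_mining(
    graphs: Sequence[StructureGraph], fragments: Sequence[Fragment]
) -> FeatureMatrix:
    """Training-time matrix read off the miner's supporting ids.

    Only valid when ``fragments`` were mined over exactly these ``graphs``;
    equals :func:`build_feature_matrix` there (a tested invariant), at a
    fraction of the cost.
    """
    if not graphs:
        raise ValueError("empty graph list")
    if not fragments:
        raise ValueError("empty feature space")
    _check_graphs(graphs)
    id_set = {g.graph_id for g in graphs}
    values = np.zeros((len(graphs), len(fragments)), dtype=np.uint8)
    row_of = {g.graph_id: i for i, g in enumerate(graphs)}
    for j, f in enumerate(fragments):
        if not f.supporting_ids:
            raise ValueError(
                f"fragment {f.canonical_code!r} carries no supporting ids; "
                f"use build_feature_matrix"
            )
        if not f.supporting_ids <= id_set:
            raise ValueError(
                f"fragment {f.canonical_code!r} supported by graphs outside "
                f"this collection; was it mined on these graphs?"
            )
        for gid in f.supporting_ids:
            values[row_of[gid], j] = 1
    return FeatureMatrix(
        graph_ids=tuple(g.graph_id for g in graphs),
        fragments=tuple(fragments),
        values=values,
    )


def project(
    graphs: Sequence[StructureGraph], frozen_fragments: Sequence[Fragment]
) -> FeatureMatrix:
    """Project unseen graphs into a frozen feature space (no re-mining).

    Column order is exactly the frozen fragment order; a graph list may be
    empty (yielding a 0-row matrix with the right column count).
    """
    if not frozen_fragments:
        raise ValueError("empty feature space")
    _check_graphs(graphs)
    values = np.zeros((len(graphs), len(frozen_fragments)), dtype=np.uint8)
    for i, g in enumerate(graphs):
        host = HostGraph.from_structure_graph(g)
        for j, f in enumerate(frozen_fragments):
            if has_embedding(f.node_labels, f.edges, host):
                values[i, j] = 1
    return FeatureMatrix(
        graph_ids=tuple(g.graph_id for g in graphs),
        fragments=tuple(frozen_fragments),
        values=values,
    )


def write_matrix(matrix: FeatureMatrix, path: str | Path) -> None:
    with open(path, "w") as handle:
        handle.write(_MATRIX_HEADER + "\n")
        handle.write("graph_id\t" + "\t".join(matrix.fragment_codes) + "\n")
        for gid, row in zip(matrix.graph_ids, matrix.values):
            handle.write(gid + "\t" + "\t".join(str(int(v)) for v in row) + "\n")


def read_matrix(path: str | Path) -> tuple[tuple[str, ...], tuple[str, ...], np.ndarray]:
    """Read a matrix TSV -> (graph_ids, fragment_codes, 0/1 array)."""
    with open(path) as handle:
        lines = handle.read().splitlines()
    if not lines or not lines[0].startswith("# ncstruct feature matrix"):
        raise ValueError(f"{path}: not an ncstruct matrix file")
    header = lines[1].split("\t")
    codes = tuple(header[1:])
    graph_ids = []
    rows = []
    for line in lines[2:]:
        if not line:
            continue
        parts = line.split("\t")
        graph_ids.append(parts[0])
        rows.append([int(v) for v in parts[1:]])
    values = np.asarray(rows, dtype=np.uint8).reshape(len(graph_ids), len(codes))
    return tuple(graph_ids), codes, values
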