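"""Labelled graphs over RNA secondary structures.

An RNA secondary structure in dot-bracket notation is converted into an
undirected labelled graph: one vertex per nucleotide (labelled with the
base), backbone edges between consecutive positions, and a ``pair`` edge for
every base pair.  Pseudoknots are supported through the extended bracket
alphabet ``() [] {} <>`` plus ``A-Z`` opening with ``a-z`` closing: each
family is matched with its own stack, and pairs from different families may
cross.
"""

from __future__ import annotations

from dataclasses import dataclass

from .records import NcRnaRecord

__all__ = [
    "BACKBONE",
    "PAIR",
    "StructureGraph",
    "StructureError",
    "parse_dot_bracket",
    "build_structure_graph",
]

BACKBONE = "backbone"
PAIR = "pair"

_OPEN_TO_CLOSE = {"(": ")", "[": "]", "{": "}", "<": ">"}
_OPEN_TO_CLOSE.update({chr(ord("A") + i): chr(ord("a") + i) for i in range(26)})
_CLOSE_TO_OPEN = {v: k for k, v in _OPEN_TO_CLOSE.items()}


class StructureError(ValueError):
    """Malformed dot-bracket structure."""


def parse_dot_bracket(structure: str) -> set[tuple[int, int]]:
    """Parse extended dot-bracket notation into a set of 0-based pairs (i, j), i<j.

    Each bracket family is matched independently with its own stack, so
    pairs from different families may cross (pseudoknots).  Dots contribute
    nothing.  Unbalanced families and illegal characters raise
    :class:`StructureError` naming the family and position.
    """
    stacks: dict[str, list[int]] = {}
    pairs: set[tuple[int, int]] = set()
    for pos, ch in enumerate(structure):
        if ch == ".":
            continue
        if ch in _OPEN_TO_CLOSE:
            stacks.setdefault(ch, []).append(pos)
        elif ch in _CLOSE_TO_OPEN:
            fam = _CLOSE_TO_OPEN[ch]
            stack = stacks.get(fam)
            if not stack:
                raise StructureError(
                    f"unbalanced {ch!r} at position {pos}: no open {fam!r}"
                )
            pairs.add((stack.pop(), pos))
        else:
            raise StructureError(f"illegal character {ch!r} at position {pos}")
    for fam, stack in stacks.items():
        if stack:
            raise StructureError(
                f"unbalanced {fam!r} at position {stack[-1]}: never closed"
            )
    return pairs


@dataclass(frozen=True)
class StructureGraph:
    """Undirected labelled graph of one RNA secondary structure.

    ``node_labels[i]`` is the base at 0-based sequence position ``i``;
    ``edges`` holds ``(i, j, bond)`` tuples with ``i < j`` and bond either
    :data:`BACKBONE` or :data:`PAIR`.
    """

    graph_id: str
    node_labels: tuple[str, ...]
    edges: frozenset[tuple[int, int, str]]

    def __post_init__(self) -> None:
        n = len(self.node_labels)
        expected_backbone = {(p, p + 1, BACKBONE) for p in range(n - 1)}
        backbone = {e for e in self.edges if e[2] == BACKBONE}
        if backbone != expected_backbone:
            raise ValueError(
                f"graph {self.graph_id!r}: backbone edges must be exactly the "
                f"sequence path"
            )
        pair_partners: dict[int, int] = {}
        for i, j, bond in self.edges:
            if not (0 <= i < j < n):
                raise ValueError(f"graph {self.graph_id!r}: edge ({i},{j}) out of range")
            if bond == PAIR:
                if j == i + 1:
                    raise ValueError(
                        f"graph {self.graph_id!r}: adjacent base pair ({i},{j})"
                    )
                for node in (i, j):
                    if node in pair_partners:
                        raise ValueError(
                            f"graph {self.graph_id!r}: node {node} has more "
                            f"than one pair edge"
                        )
                    pair_partners[node] = True
            elif bond != BACKBONE:
                raise ValueError(f"graph {self.graph_id!r}: unknown bond {bond!r}")

    @property
    def n_nodes(self) -> int:
        return len(self.node_labels)

    def pair_edges(self) -> set[tuple[int, int]]:
        return {(i, j) for i, j, bond in self.edges if bond == PAIR}

    def to_networkx(self):
        """Export as ``networkx.Graph`` with ``label`` node and ``bond`` edge attrs."""
        import networkx as nx

        g = nx.Graph()
        for i, lab in enumerate(self.node_labels):
            g.add_node(i, label=lab)
        for i, j, bond in self.edges:
            g.add_edge(i, j, bond=bond)
        return g


def build_structure_graph(record: NcRnaRecord) -> StructureGraph:
    """Convert a (sequence, structure) record into its labelled graph.

    Backbone edges connect consecutive positions; each matched bracket pair
    becomes a ``pair`` edge.  A pair between adjacent bases is geometrically
    impossible and rejected.
    """
    if record.structure is None:
        raise ValueError(f"record {record.id!r} has no structure")
    if len(record.structure) != len(record.sequence):
        raise ValueError(
            f"record {record.id!r}: structure length {len(record.structure)} "
            f"!= sequence length {len(record.sequence)}"
        )
    pairs = parse_dot_bracket(record.structure)
    for i, j in pairs:
        if j == i + 1:
            raise ValueError(f"record {record.id!r}: adjacent base pair ({i},{j})")
    n = len(record.sequence)
    edges = {(p, p + 1, BACKBONE) for p in range(n - 1)}
    edges |= {(i, j, PAIR) for i, j in pairs}
    return StructureGraph(
        graph_id=record.id,
        node_labels=tuple(record.sequence),
        edges=frozenset(edges),
    )
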