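"""Labelled sub-graph monomorphism: does a fragment embed in a host graph?

Matching is *sub-graph* (not induced-sub-graph) isomorphism: every fragment
edge must map onto a host edge with the same bond type, but the host may
have extra edges among the mapped nodes.  Node labels must match exactly
(``N`` matches only ``N``).  The matcher is a plain backtracking search over
a connectivity-respecting fragment node order, with label/degree candidate
pruning — ample for fragments of a handful of nodes.
"""

from __future__ import annotations

from collections import defaultdict
from typing import Sequence

__all__ = ["HostGraph", "find_embedding", "has_embedding"]

EdgeT = tuple[int, int, str]


class HostGraph:
    """Adjacency-indexed view of a labelled graph, built once per host."""

    __slots__ = ("labels", "adj", "edge_set", "nodes_by_label")

    def __init__(self, node_labels: Sequence[str], edges: Sequence[EdgeT] | frozenset):
        self.labels = tuple(node_labels)
        self.adj: dict[int, list[tuple[int, str]]] = defaultdict(list)
        self.edge_set: set[tuple[int, int, str]] = set()
        for i, j, bond in edges:
            self.adj[i].append((j, bond))
            self.adj[j].append((i, bond))
            self.edge_set.add((i, j, bond))
            self.edge_set.add((j, i, bond))
        self.nodes_by_label: dict[str, list[int]] = defaultdict(list)
        for idx, lab in enumerate(self.labels):
            self.nodes_by_label[lab].append(idx)

    @classmethod
    def from_structure_graph(cls, graph) -> "HostGraph":
        return cls(graph.node_labels, graph.edges)


def _match_order(n: int, edges: Sequence[EdgeT]) -> list[tuple[int, list[tuple[int, str]]]]:
    """Connectivity-respecting node order with, per node, its edges to
    already-ordered nodes.  Raises on a disconnected fragment."""
    adj: dict[int, list[tuple[int, str]]] = defaultdict(list)
    for i, j, bond in edges:
        adj[i].append((j, bond))
        adj[j].append((i, bond))
    order: list[int] = [0]
    placed = {0}
    while len(order) < n:
        nxt = None
        for v in range(n):
            if v not in placed and any(u in placed for u, _ in adj[v]):
                nxt = v
                break
        if nxt is None:
            raise ValueError("fragment graph is disconnected")
        order.append(nxt)
        placed.add(nxt)
    plan = []
    pos_of = {v: p for p, v in enumerate(order)}
    for p, v in enumerate(order):
        back = [(pos_of[u], bond) for u, bond in adj[v] if pos_of[u] < p]
        plan.append((v, back))
    return plan


def find_embedding(
    frag_labels: Sequence[str],
    frag_edges: Sequence[EdgeT] | frozenset,
    host: HostGraph,
) -> tuple[int, ...] | None:
    """Return one injective node map (fragment node -> host node) or None."""
    n = len(frag_labels)
    if n == 0:
        raise ValueError("empty fragment")
    plan = _match_order(n, list(frag_edges))
    assignment: list[int] = [-1] * n  # indexed by plan position
    used: set[int] = set()
    frag_node_at: list[int] = [v for v, _ in plan]

    def backtrack(pos: int) -> tuple[int, ...] | None:
        if pos == n:
            mapping = [0] * n
            for p, v in enumerate(frag_node_at):
                mapping[v] = assignment[p]
            return tuple(mapping)
        v, back = plan[pos]
        lab = frag_labels[v]
        if back:
            # candidates: host neighbours of the first constrained position
            anchor_pos, anchor_bond = back[0]
            anchor_host = assignment[anchor_pos]
            candidates = [
                h for h, bond in host.adj[anchor_host]
                if bond == anchor_bond and host.labels[h] == lab
            ]
        else:
            candidates = host.nodes_by_label.get(lab, [])
        for h in candidates:
            if h in used:
                continue
            ok = True
            for bpos, bond in back[1:]:
                if (assignment[bpos], h, bond) not in host.edge_set:
                    ok = False
                    break
            if not ok:
                continue
            assignment[pos] = h
            used.add(h)
            result = backtrack(pos + 1)
            if result is not None:
                return result
            used.remove(h)
        return None

    return backtrack(0)


def has_embedding(frag_labels, frag_edges, host: HostGraph) -> bool:
    return find_embedding(frag_labels, frag_edges, host) is not None
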