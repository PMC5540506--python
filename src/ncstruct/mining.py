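"""Closed frequent sub-graph mining over RNA structure graphs.

This is the feature-discovery stage of the classifier: given a collection of
labelled structure graphs, find every connected sub-graph (a *fragment*)
that

* occurs in at least ``support_pct`` percent of the graphs (support counts
  graphs, not embeddings),
* has between ``min_size`` and ``max_size`` nodes, and
* is *closed* within that size window: no one-edge extension occurring in
  the data (and still within the window) has the same support.

The search grows fragments depth-first from single-node seeds, carrying the
full embedding list of each fragment down the tree so that the support of
every extension is obtained by extending embeddings rather than by repeated
sub-graph isomorphism — the strategy of molecular sub-structure miners.
Duplicate fragments reached along different search paths are pruned with a
label-aware canonical code.  Matching is sub-graph (not induced) — a
fragment may omit edges that exist between its nodes in a host graph.

`oracle_mine` re-derives the same output by brute-force enumeration of all
connected sub-graphs; it is the test oracle and only feasible for tiny
graphs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from .graphs import StructureGraph
from .isomorphism import HostGraph, has_embedding

__all__ = [
    "MiningParams",
    "Fragment",
    "MiningError",
    "canonical_code",
    "mine_closed_fragments",
    "fragment_support",
    "oracle_mine",
    "write_fragments",
    "read_fragments",
]

EdgeT = tuple[int, int, str]

_BOND_CHAR = {"backbone": "-", "pair": "="}
_CHAR_BOND = {v: k for k, v in _BOND_CHAR.items()}


class MiningError(ValueError):
    pass


@dataclass(frozen=True)
class MiningParams:
    """Support threshold (percent of graphs) and fragment size window (nodes)."""

    support_pct: float = 10.0
    min_size: int = 4
    max_size: int = 6

    def __post_init__(self) -> None:
        if not (0 < self.support_pct <= 100):
            raise ValueError("support_pct must be in (0, 100]")
        if not (1 <= self.min_size <= self.max_size):
            raise ValueError("need 1 <= min_size <= max_size")

    def absolute_threshold(self, n_graphs: int) -> int:
        return math.ceil(self.support_pct / 100.0 * n_graphs)


@dataclass(frozen=True)
class Fragment:
    """One mined connected sub-graph with canonical code and support."""

    canonical_code: str
    node_labels: tuple[str, ...]
    edges: tuple[EdgeT, ...]
    support_count: int
    supporting_ids: frozenset[str] = field(default_factory=frozenset)

    @property
    def size(self) -> int:
        return len(self.node_labels)


# ---------------------------------------------------------------------------
# canonical codes
# ---------------------------------------------------------------------------

def _bond_token(bond: str) -> str:
    return _BOND_CHAR.get(bond, f"({bond})")


def _min_code(node_labels: Sequence[str], edges: Sequence[EdgeT]) -> tuple:
    """Lexicographically minimal connectivity-order code of a labelled graph.

    A code is the sequence, over an ordering of the nodes in which every
    node after the first is adjacent to an earlier one, of
    ``(label, ((earlier_position, bond), ...))`` columns.  The minimum over
    all such orderings is a canonical form: equal for isomorphic graphs,
    distinct otherwise.  Branch-and-bound: orderings whose code prefix
    already exceeds the best known full code are pruned.
    """
    n = len(node_labels)
    adj: list[list[tuple[int, str]]] = [[] for _ in range(n)]
    for i, j, bond in edges:
        adj[i].append((j, bond))
        adj[j].append((i, bond))
    if n == 1:
        return ((node_labels[0], ()),)

    best: list | None = None
    order_pos: list[int | None] = [None] * n
    code: list = []

    def extend() -> None:
        nonlocal best
        d = len(code)
        if best is not None and code > best[:d]:
            return
        if d == n:
            if best is None or code < best:
                best = list(code)
            return
        cands = []
        for v in range(n):
            if order_pos[v] is not None:
                continue
            links = sorted(
                (order_pos[u], bond) for u, bond in adj[v] if order_pos[u] is not None
            )
            if links:
                cands.append(((node_labels[v], tuple(links)), v))
        cands.sort(key=lambda cv: cv[0])
        for col, v in cands:
            code.append(col)
            order_pos[v] = d
            extend()
            order_pos[v] = None
            code.pop()

    min_label = min(node_labels)
    for s in range(n):
        if node_labels[s] != min_label:
            continue
        order_pos[s] = 0
        code.append((node_labels[s], ()))
        extend()
        code.pop()
        order_pos[s] = None
    assert best is not None  # connected graph with n >= 2 always yields a code
    return tuple(best)


def _check_connected(n: int, edges: Sequence[EdgeT]) -> None:
    if n == 0:
        raise ValueError("empty graph")
    adj: list[list[int]] = [[] for _ in range(n)]
    for i, j, _ in edges:
        adj[i].append(j)
        adj[j].append(i)
    seen = {0}
    stack = [0]
    while stack:
        v = stack.pop()
        for u in adj[v]:
            if u not in seen:
                seen.add(u)
                stack.append(u)
    if len(seen) != n:
        raise ValueError("fragment graph is disconnected")


def _serialize_code(code: tuple) -> str:
    parts = []
    for label, links in code:
        parts.append(label + "".join(f"{p}{_bond_token(b)}" for p, b in links))
    return ";".join(parts)


def canonical_code(node_labels: Sequence[str], edges: Sequence[EdgeT]) -> str:
    """Canonical string of a connected labelled graph (isomorphism invariant).

    Equal strings iff the graphs are isomorphic respecting node labels and
    bond types.  Disconnected input raises ``ValueError``.
    """
    _check_connected(len(node_labels), edges)
    return _serialize_code(_min_code(tuple(node_labels), list(edges)))


# ---------------------------------------------------------------------------
# the miner
# ---------------------------------------------------------------------------

def _sorted_edges(edges) -> tuple[EdgeT, ...]:
    return tuple(sorted(edges))


def mine_closed_fragments(
    graphs: Sequence[StructureGraph], params: MiningParams
) -> list[Fragment]:
    """Mine all closed frequent connected fragments within the size window.

    Output is sorted by (size, canonical_code) and therefore byte-stable
    across runs.  Each fragment carries the ids of the graphs containing it.
    """
    if not graphs:
        raise MiningError("empty graph list")
    ids = [g.graph_id for g in graphs]
    if len(set(ids)) != len(ids):
        raise MiningError("duplicate graph ids")
    threshold = params.absolute_threshold(len(graphs))
    if threshold <= 0:
        raise MiningError("support threshold computes to 0 graphs")

    hosts = [
        {
            "labels": g.node_labels,
            "adj": _adjacency(g),
        }
        for g in graphs
    ]

    results: dict[str, Fragment] = {}
    visited: set[str] = set()
    code_memo: dict[tuple, str] = {}

    def coded(labels: tuple[str, ...], edges: tuple[EdgeT, ...]) -> str:
        key = (labels, edges)
        code = code_memo.get(key)
        if code is None:
            code = _serialize_code(_min_code(labels, list(edges)))
            code_memo[key] = code
        return code

    def grow(
        labels: tuple[str, ...],
        edges: tuple[EdgeT, ...],
        code: str,
        embeddings: list[tuple[int, tuple[int, ...]]],
        supporting: frozenset[int],
    ) -> None:
        size = len(labels)
        edge_set = set(edges)
        # enumerate one-edge extensions actually present in the data
        ext: dict[tuple, set[tuple[int, tuple[int, ...]]]] = {}
        for gi, mp in embeddings:
            host = hosts[gi]
            mapped = {h: idx for idx, h in enumerate(mp)}
            for a, ha in enumerate(mp):
                for hb, bond in host["adj"][ha]:
                    b = mapped.get(hb)
                    if b is not None:
                        if a >= b:
                            continue
                        if (a, b, bond) in edge_set:
                            continue
                        ext.setdefault(("close", a, b, bond), set()).add((gi, mp))
                    else:
                        if size + 1 > params.max_size:
                            continue
                        key = ("grow", a, host["labels"][hb], bond)
                        ext.setdefault(key, set()).add((gi, mp + (hb,)))

        support = len(supporting)
        closed = True
        children = []
        for key, embs in ext.items():
            sup = frozenset(gi for gi, _ in embs)
            if len(sup) == support:
                closed = False
            if len(sup) < threshold:
                continue
            if key[0] == "close":
                _, a, b, bond = key
                nl, ne = labels, _sorted_edges(edges + ((a, b, bond),))
            else:
                _, a, lab, bond = key
                nl = labels + (lab,)
                ne = _sorted_edges(edges + ((a, size, bond),))
            children.append((nl, ne, sorted(embs), sup))

        if closed and params.min_size <= size <= params.max_size:
            results[code] = Fragment(
                canonical_code=code,
                node_labels=labels,
                edges=edges,
                support_count=support,
                supporting_ids=frozenset(ids[gi] for gi in supporting),
            )

        for nl, ne, embs, sup in children:
            ccode = coded(nl, ne)
            if ccode in visited:
                continue
            visited.add(ccode)
            grow(nl, ne, ccode, embs, sup)

    seed_labels = sorted({lab for h in hosts for lab in h["labels"]})
    for lab in seed_labels:
        embeddings = [
            (gi, (v,))
            for gi, h in enumerate(hosts)
            for v, l in enumerate(h["labels"])
            if l == lab
        ]
        supporting = frozenset(gi for gi, _ in embeddings)
        if len(supporting) < threshold:
            continue
        labels = (lab,)
        edges: tuple[EdgeT, ...] = ()
        code = coded(labels, edges)
        visited.add(code)
        grow(labels, edges, code, embeddings, supporting)

    return sorted(results.values(), key=lambda f: (f.size, f.canonical_code))


def _adjacency(g: StructureGraph) -> dict[int, list[tuple[int, str]]]:
    adj: dict[int, list[tuple[int, str]]] = {i: [] for i in range(g.n_nodes)}
    for i, j, bond in g.edges:
        adj[i].append((j, bond))
        adj[j].append((i, bond))
    return adj


def fragment_support(fragment: Fragment, graphs: Sequence[StructureGraph]) -> int:
    """Number of graphs containing >=1 embedding of the fragment (per-graph count)."""
    count = 0
    for g in graphs:
        host = HostGraph.from_structure_graph(g)
        if has_embedding(fragment.node_labels, fragment.edges, host):
            count += 1
    return count


# ---------------------------------------------------------------------------
# brute-force oracle (tests only)
# ---------------------------------------------------------------------------

def oracle_mine(
    graphs: Sequence[StructureGraph], params: MiningParams
) -> list[Fragment]:
    """Same contract as :func:`mine_closed_fragments`, by exhaustive
    enumeration of every connected sub-graph of every (<=10-node) graph."""
    if not graphs:
        raise MiningError("empty graph list")
    for g in graphs:
        if g.n_nodes > 10:
            raise MiningError(
                f"oracle_mine requires graphs of <= 10 nodes, got {g.n_nodes}"
            )
    threshold = params.absolute_threshold(len(graphs))
    if threshold <= 0:
        raise MiningError("support threshold computes to 0 graphs")

    # universe: canonical code -> (representative (labels, edges), graph ids)
    universe: dict[str, tuple[tuple[tuple[str, ...], tuple[EdgeT, ...]], set[str]]] = {}

    def register(code: str, rep, gid: str) -> None:
        if code not in universe:
            universe[code] = (rep, set())
        universe[code][1].add(gid)

    for g in graphs:
        codes_here: dict[str, tuple] = {}
        for v, lab in enumerate(g.node_labels):
            rep = ((lab,), ())
            codes_here[canonical_code(*rep)] = rep
        edge_list = sorted(g.edges)
        m = len(edge_list)
        for mask in range(1, 1 << m):
            sub = [edge_list[b] for b in range(m) if mask >> b & 1]
            nodes = sorted({x for i, j, _ in sub for x in (i, j)})
            if len(nodes) > params.max_size:
                continue
            if not _edges_connected(nodes, sub):
                continue
            relabel = {node: k for k, node in enumerate(nodes)}
            labels = tuple(g.node_labels[node] for node in nodes)
            edges = _sorted_edges(
                tuple(
                    (min(relabel[i], relabel[j]), max(relabel[i], relabel[j]), bond)
                    for i, j, bond in sub
                )
            )
            rep = (labels, edges)
            codes_here.setdefault(canonical_code(*rep), rep)
        for code, rep in codes_here.items():
            register(code, rep, g.graph_id)

    out = []
    for code, (rep, gids) in universe.items():
        labels, edges = rep
        size = len(labels)
        if not (params.min_size <= size <= params.max_size):
            continue
        if len(gids) < threshold:
            continue
        closed = True
        for code2, (rep2, gids2) in universe.items():
            labels2, edges2 = rep2
            if len(edges2) != len(edges) + 1:
                continue
            if len(labels2) > params.max_size:
                continue
            if len(gids2) != len(gids):
                continue
            host = HostGraph(labels2, edges2)
            if has_embedding(labels, edges, host):
                closed = False
                break
        if closed:
            out.append(
                Fragment(
                    canonical_code=code,
                    node_labels=labels,
                    edges=edges,
                    support_count=len(gids),
                    supporting_ids=frozenset(gids),
                )
            )
    return sorted(out, key=lambda f: (f.size, f.canonical_code))


def _edges_connected(nodes: list[int], edges: list[EdgeT]) -> bool:
    adj: dict[int, list[int]] = {v: [] for v in nodes}
    for i, j, _ in edges:
        adj[i].append(j)
        adj[j].append(i)
    seen = {nodes[0]}
    stack = [nodes[0]]
    while stack:
        v = stack.pop()
        for u in adj[v]:
            if u not in seen:
                seen.add(u)
                stack.append(u)
    return len(seen) == len(nodes)


# ---------------------------------------------------------------------------
# fragment files
# ---------------------------------------------------------------------------

_FRAGMENT_HEADER = "# ncstruct fragments v1"


def _edges_to_text(edges: Sequence[EdgeT]) -> str:
    return ";".join(f"{i}-{j}:{bond}" for i, j, bond in edges) or "-"


def _edges_from_text(text: str) -> tuple[EdgeT, ...]:
    if text == "-":
        return ()
    out = []
    for item in text.split(";"):
        ij, bond = item.split(":")
        i, j = ij.split("-")
        out.append((int(i), int(j), bond))
    return tuple(out)


def write_fragments(fragments: Sequence[Fragment], path: str | Path) -> None:
    """Write the deterministic fragment TSV (row order as given)."""
    with open(path, "w") as handle:
        handle.write(_FRAGMENT_HEADER + "\n")
        handle.write("canonical_code\tsize\tsupport_count\tnode_labels\tedges\n")
        for f in fragments:
            handle.write(
                f"{f.canonical_code}\t{f.size}\t{f.support_count}\t"
                f"{','.join(f.node_labels)}\t{_edges_to_text(f.edges)}\n"
            )


def read_fragments(path: str | Path) -> list[Fragment]:
    with open(path) as handle:
        lines = handle.read().splitlines()
    if not lines or not lines[0].startswith("# ncstruct fragments"):
        raise ValueError(f"{path}: not an ncstruct fragment file")
    out = []
    for line in lines[2:]:
        if not line:
            continue
        code, size, support, labels, edges = line.split("\t")
        out.append(
            Fragment(
                canonical_code=code,
                node_labels=tuple(labels.split(",")),
                edges=_edges_from_text(edges),
                support_count=int(support),
            )
        )
    return out
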