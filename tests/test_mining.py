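from itertools import permutations

import numpy as np
import pytest

from ncstruct.graphs import BACKBONE, PAIR, StructureGraph
from ncstruct.mining import (
    Fragment,
    MiningError,
    MiningParams,
    canonical_code,
    fragment_support,
    mine_closed_fragments,
    oracle_mine,
    read_fragments,
    write_fragments,
)

from conftest import backbone_path, random_structure_graph


def as_key_set(fragments):
    return {(f.canonical_code, f.support_count) for f in fragments}


class TestCanonicalCode:
    def test_node_order_is_irrelevant(self):
        a = canonical_code(("A", "C"), [(0, 1, BACKBONE)])
        b = canonical_code(("C", "A"), [(0, 1, BACKBONE)])
        assert a == b

    def test_bond_label_distinguishes(self):
        a = canonical_code(("A", "C"), [(0, 1, BACKBONE)])
        b = canonical_code(("A", "C"), [(0, 1, PAIR)])
        assert a != b

    def test_star_invariant_under_all_permutations(self):
        # centre C bonded to A, G, U: every node relabelling gives one code
        labels = ["C", "A", "G", "U"]
        edges = [(0, 1, BACKBONE), (0, 2, BACKBONE), (0, 3, BACKBONE)]
        codes = set()
        for perm in permutations(range(4)):
            relabelled = [labels[perm.index(i)] for i in range(4)]
            new_edges = [(perm[i], perm[j], b) for i, j, b in edges]
            codes.add(canonical_code(tuple(relabelled), new_edges))
        assert len(codes) == 1

    def test_non_isomorphic_graphs_differ(self):
        path = canonical_code(("A", "C", "G"), [(0, 1, BACKBONE), (1, 2, BACKBONE)])
        other = canonical_code(("A", "G", "C"), [(0, 1, BACKBONE), (1, 2, BACKBONE)])
        assert path != other

    def test_disconnected_rejected(self):
        with pytest.raises(ValueError):
            canonical_code(("A", "C"), [])


class TestWorkedExample:
    """The two-path mining example: {A-C-G, A-C-U} at 50% support, sizes 1-3."""

    def setup_method(self):
        self.graphs = [backbone_path("g1", "ACG"), backbone_path("g2", "ACU")]

    def test_exact_output(self):
        frags = mine_closed_fragments(self.graphs, MiningParams(50.0, 1, 3))
        by_labels = {tuple(sorted(f.node_labels)): f.support_count for f in frags}
        assert by_labels == {("A", "C"): 2, ("A", "C", "G"): 1, ("A", "C", "U"): 1}

    def test_full_support_window(self):
        frags = mine_closed_fragments(self.graphs, MiningParams(100.0, 2, 2))
        assert len(frags) == 1
        assert frags[0].support_count == 2
        assert sorted(frags[0].node_labels) == ["A", "C"]

    def test_disjoint_label_sets_yield_nothing(self):
        graphs = [backbone_path("g1", "AA"), backbone_path("g2", "GG")]
        assert mine_closed_fragments(graphs, MiningParams(100.0, 1, 2)) == []


class TestFragmentSupport:
    def test_per_graph_not_per_embedding(self):
        frag = Fragment("A", ("A",), (), 0)
        graphs = [backbone_path("g1", "ACA"), backbone_path("g2", "GG")]
        assert fragment_support(frag, graphs) == 1

    def test_path_fragment(self):
        frag = Fragment("x", ("A", "C"), ((0, 1, BACKBONE),), 0)
        graphs = [backbone_path("g1", "ACG"), backbone_path("g2", "ACU")]
        assert fragment_support(frag, graphs) == 2

    def test_bond_type_must_match(self):
        frag = Fragment("x", ("A", "C"), ((0, 1, PAIR),), 0)
        assert fragment_support(frag, [backbone_path("g", "AC")]) == 0


class TestMinerAgainstOracle:
    def test_equivalence_on_random_sets(self):
        """Miner output (codes + supports) is set-identical to brute force."""
        rng = np.random.default_rng(7)
        for _ in range(60):
            graphs = [
                random_structure_graph(rng, f"g{i}")
                for i in range(int(rng.integers(2, 7)))
            ]
            m = int(rng.integers(1, 4))
            params = MiningParams(
                support_pct=float(rng.choice([34.0, 50.0, 67.0, 100.0])),
                min_size=m,
                max_size=int(rng.integers(m, 7)),
            )
            assert as_key_set(mine_closed_fragments(graphs, params)) == as_key_set(
                oracle_mine(graphs, params)
            )

    def test_single_node_graph(self):
        g = StructureGraph("g", ("A",), frozenset())
        for miner in (mine_closed_fragments, oracle_mine):
            out = miner([g], MiningParams(100.0, 1, 1))
            assert len(out) == 1 and out[0].support_count == 1

    def test_oracle_size_guard(self):
        g = backbone_path("big", "ACGUACGUACG")  # 11 nodes
        with pytest.raises(MiningError):
            oracle_mine([g], MiningParams(100.0, 1, 2))


class TestMiningInvariants:
    def _random_case(self, rng):
        graphs = [
            random_structure_graph(rng, f"g{i}") for i in range(int(rng.integers(3, 6)))
        ]
        return graphs, MiningParams(50.0, 1, 5)

    def test_anti_monotone_support(self):
        """Support of a fragment never exceeds that of its sub-fragments."""
        rng = np.random.default_rng(21)
        from ncstruct.isomorphism import HostGraph, has_embedding

        for _ in range(20):
            graphs, params = self._random_case(rng)
            frags = mine_closed_fragments(graphs, params)
            for f in frags:
                for g in frags:
                    if g.size >= f.size or len(g.edges) >= len(f.edges):
                        continue
                    host = HostGraph(f.node_labels, f.edges)
                    if has_embedding(g.node_labels, g.edges, host):
                        assert g.support_count >= f.support_count

    def test_closedness_no_equal_support_extension(self):
        """Every one-edge extension present in the data has strictly lower
        support (exhaustive, via the oracle universe)."""
        rng = np.random.default_rng(22)
        from ncstruct.isomorphism import HostGraph, has_embedding

        for _ in range(10):
            graphs, params = self._random_case(rng)
            frags = mine_closed_fragments(graphs, params)
            # the oracle's closed set at threshold 1 covers every closed
            # sub-graph in the window; an equal-support one-edge extension of
            # f would extend (possibly repeatedly) to a closed super-graph of
            # f with the same support, so its absence proves closedness
            universe = oracle_mine(graphs, MiningParams(1.0, 1, params.max_size))
            for f in frags:
                for u in universe:
                    if len(u.edges) <= len(f.edges):
                        continue
                    if u.support_count != f.support_count:
                        continue
                    host = HostGraph(u.node_labels, u.edges)
                    assert not has_embedding(f.node_labels, f.edges, host)

    def test_raising_support_shrinks_output(self):
        rng = np.random.default_rng(23)
        graphs = [random_structure_graph(rng, f"g{i}") for i in range(6)]
        prev = None
        for pct in (17.0, 34.0, 50.0, 67.0, 100.0):
            frags = {
                f.canonical_code
                for f in mine_closed_fragments(graphs, MiningParams(pct, 1, 5))
            }
            if prev is not None:
                # closedness does not depend on the threshold, so the closed
                # frequent set at a higher threshold is a subset of the lower
                assert frags <= prev
            prev = frags

    def test_supporting_ids_match_support_count(self):
        rng = np.random.default_rng(24)
        graphs = [random_structure_graph(rng, f"g{i}") for i in range(5)]
        for f in mine_closed_fragments(graphs, MiningParams(40.0, 1, 4)):
            assert len(f.supporting_ids) == f.support_count
            assert f.supporting_ids <= {g.graph_id for g in graphs}


class TestDeterminismAndIO:
    def test_two_runs_byte_identical(self, tmp_path):
        rng = np.random.default_rng(31)
        graphs = [random_structure_graph(rng, f"g{i}") for i in range(5)]
        params = MiningParams(40.0, 1, 5)
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_fragments(mine_closed_fragments(graphs, params), p1)
        write_fragments(mine_closed_fragments(graphs, params), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_fragment_file_round_trip(self, tmp_path):
        graphs = [backbone_path("g1", "ACG"), backbone_path("g2", "ACU")]
        frags = mine_closed_fragments(graphs, MiningParams(50.0, 1, 3))
        p = tmp_path / "frags.tsv"
        write_fragments(frags, p)
        back = read_fragments(p)
        assert [(f.canonical_code, f.node_labels, f.edges, f.support_count) for f in back] == [
            (f.canonical_code, f.node_labels, f.edges, f.support_count) for f in frags
        ]

    def test_sorted_by_size_then_code(self):
        rng = np.random.default_rng(32)
        graphs = [random_structure_graph(rng, f"g{i}") for i in range(4)]
        frags = mine_closed_fragments(graphs, MiningParams(50.0, 1, 5))
        keys = [(f.size, f.canonical_code) for f in frags]
        assert keys == sorted(keys)


def test_error_cases():
    with pytest.raises(MiningError):
        mine_closed_fragments([], MiningParams(50.0, 1, 3))
    with pytest.raises(ValueError):
        MiningParams(0.0, 1, 3)
    with pytest.raises(ValueError):
        MiningParams(50.0, 3, 2)
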