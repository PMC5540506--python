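import numpy as np
import pytest

from ncstruct.graphs import BACKBONE, PAIR, StructureGraph


def backbone_path(gid: str, seq: str) -> StructureGraph:
    """A structure graph with backbone edges only (unpaired RNA)."""
    return StructureGraph(
        gid, tuple(seq), frozenset((p, p + 1, BACKBONE) for p in range(len(seq) - 1))
    )


def random_structure_graph(rng: np.random.Generator, gid: str, max_nodes: int = 8) -> StructureGraph:
    """Small random RNA-like graph: backbone path plus a few valid pair edges."""
    n = int(rng.integers(2, max_nodes + 1))
    labels = tuple("ACGU"[i] for i in rng.integers(0, 4, size=n))
    edges = {(p, p + 1, BACKBONE) for p in range(n - 1)}
    used: set[int] = set()
    for _ in range(int(rng.integers(0, 3))):
        i = int(rng.integers(0, n))
        j = int(rng.integers(0, n))
        i, j = min(i, j), max(i, j)
        if j - i < 2 or i in used or j in used:
            continue
        used |= {i, j}
        edges.add((i, j, PAIR))
    return StructureGraph(gid, labels, frozenset(edges))


@pytest.fixture(scope="session")
def small_synthetic_records():
    """A compact 3-class dataset reused by pipeline-level tests."""
    from ncstruct.synthetic import SyntheticSpec, generate_dataset

    return generate_dataset(
        SyntheticSpec(n_classes=3, per_class=8, length_range=(25, 35), seed=11)
    )
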