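"""Build the boolean containment matrix and project unseen sequences.

A synthetic 3-class dataset is mined for closed frequent fragments; the
training matrix has one row per sequence and one 0/1 column per fragment.
A held-out record is then projected into the *frozen* feature space — no
re-mining, just exact sub-graph matching against the frozen fragment list.
"""

from ncstruct import (
    MiningParams,
    SyntheticSpec,
    build_structure_graph,
    feature_matrix_from_mining,
    generate_dataset,
    mine_closed_fragments,
    project,
)

records = generate_dataset(
    SyntheticSpec(n_classes=3, per_class=10, length_range=(30, 40), seed=5)
)
train, held_out = records[:-1], records[-1:]

graphs = [build_structure_graph(r) for r in train]
fragments = mine_closed_fragments(graphs, MiningParams(25.0, 2, 5))
matrix = feature_matrix_from_mining(graphs, fragments)
print(f"training matrix: {matrix.values.shape[0]} sequences x "
      f"{matrix.values.shape[1]} fragments, density {matrix.values.mean():.2f}")

row = project([build_structure_graph(r) for r in held_out], fragments)
print(f"projected row for {held_out[0].id}: {int(row.values.sum())} of "
      f"{row.values.shape[1]} fragments present")
# column order equals the frozen fragment order, so this row can go straight
# into a model trained on the matrix above.
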