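"""Parse a dot-bracket structure and inspect its labelled graph.

The structure below is a pseudoknot: the () and [] families cross, which a
single bracket family could not express.
"""

from ncstruct import NcRnaRecord, build_structure_graph, parse_dot_bracket

sequence = "GGCAGAUCUGCC"
structure = "((([[[)))]]]"

pairs = parse_dot_bracket(structure)
print("pairs:", sorted(pairs))

record = NcRnaRecord(id="pk1", sequence=sequence, structure=structure)
graph = build_structure_graph(record)
backbone = sum(1 for e in graph.edges if e[2] == "backbone")
pair = sum(1 for e in graph.edges if e[2] == "pair")
print(f"{graph.n_nodes} nodes, {backbone} backbone edges, {pair} pair edges")

# Every nucleotide is one vertex; consecutive positions are covalently
# linked (backbone), and each matched bracket adds one hydrogen-bond (pair)
# edge. 12 nodes, 11 backbone edges and 6 pair edges here.
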