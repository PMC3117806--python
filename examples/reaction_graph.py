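"""Link preparations into a reactant→product graph.

Two preparations share starting material 5; the graph therefore has one
node of out-degree two, and each product node carries the physical state
extracted from its Yield phrase.
"""

from chemphrase import build_reaction_graph, parse_document
from chemphrase.action_roles import graph_to_tsv
from chemphrase.samples import PREPARATION

second = (
    "Product beta 9:\n"
    "The 2-nitrobenzene sulfonamide 50 (0.25 g, 0.65 mmol) was added to "
    "the solution and stirred for 4 h. Chromatography afforded the title "
    "compound 9 as a yellow oil (40 mg, 55%)."
)

docs = [
    parse_document(PREPARATION, source_id="prep82"),
    parse_document(second, source_id="prep9"),
]
graph = build_reaction_graph(docs)

nodes_tsv, edges_tsv = graph_to_tsv(graph)
print("nodes (id, state, colour):")
print(nodes_tsv)
print("edges (reactant -> product):")
print(edges_tsv)
print("out-degree of compound 50:", graph.out_degree(50))
# Compound 50 feeds both preparations; 82 was isolated as an oil, 9 as a
# yellow oil.
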