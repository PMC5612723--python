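"""High-confidence interaction networks among selected genes.

Plants three cliques (44, 8 and 6 genes — e.g. a repressive-complex hub, a
Mediator-like module and a remodelling module) with confidence scores >= 0.7,
adds sub-threshold noise edges, and recovers the components and hub degrees.
"""

import numpy as np

from funcdiv import filter_edges, components_above, degree_report
from funcdiv.simulate import simulate_edges

genes = [f"g{i:03d}" for i in range(120)]
rng = np.random.default_rng(8)
edges = simulate_edges(genes, clique_sizes=[44, 8, 6], noise_edge_rate=0.01, rng=rng)
print(f"edge list: {len(edges)} rows (cliques scored in [0.7, 1.0], noise below 0.7)")

graph = filter_edges(edges, selected=set(genes), min_score=0.700)
components = components_above(graph, min_size=3)
print(f"retained {len(graph.edges)} edges at confidence >= 0.700")
print("components of >= 3 genes:", [len(c) for c in components])

degrees = degree_report(graph)
top = degrees.iloc[0]
print(f"most connected gene: {top['gene']} ({top['degree']} connections)")
print(
    "\nNoise edges all score below the 0.700 threshold, so the three planted"
    "\nmodules are recovered exactly; within a clique of size s every member"
    "\nhas degree s - 1."
)
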