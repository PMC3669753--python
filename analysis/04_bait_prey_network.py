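"""Bait-prey network: the kinase/phosphatase baits against the remaining
Fe-responsive preys.

Thresholded edges are computed over baits + preys; every prey-prey edge
is discarded and every node left without an edge is dropped, so each
surviving node connects to at least one bait.  Checks both soundness
rules on the output.
"""

import pandas as pd

from ferronet.coexpression import NetworkConfig, bait_prey_network
from ferronet.de_analysis import DEFilterConfig, compute_ratio_records, filter_de
from ferronet.io_formats import read_annotation_table, read_expression_table, write_network

from _common import RESULTS, ensure_world

world = ensure_world()
expr = read_expression_table(world / "expression.tsv", scale="rpkm")
comp = read_expression_table(world / "compendium.tsv", scale="log2")
annot = read_annotation_table(world / "annotation.tsv")

de = filter_de(compute_ratio_records(expr, DEFilterConfig()), DEFilterConfig())
cls = dict(zip(annot.df["gene_id"], annot.df["class"]))
baits = {g for g in de.all_genes if cls.get(g) in ("kinase", "phosphatase", "both")}
preys = de.all_genes - baits

graph = bait_prey_network(comp, baits, preys, None, NetworkConfig())
write_network(graph, RESULTS / "04_baitprey.edges.tsv", dialect="edge_table")

prey_prey = sum(1 for u, v in graph.edges if u not in baits and v not in baits)
isolated = sum(1 for _, d in graph.degree() if d == 0)
rows = [
    ("baits", len(baits)),
    ("preys", len(preys)),
    ("nodes", graph.number_of_nodes()),
    ("edges", graph.number_of_edges()),
    ("prey_prey_edges", prey_prey),
    ("isolated_nodes", isolated),
]
out = pd.DataFrame(rows, columns=["quantity", "value"])
out.to_csv(RESULTS / "04_baitprey_summary.tsv", sep="\t", index=False)
print(out.to_string(index=False))
assert prey_prey == 0 and isolated == 0, "bait-prey soundness violated"
print("\nbait-prey rules hold: no prey-prey edges, no isolated nodes")
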