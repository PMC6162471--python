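"""Gene degree of centrality from a small hand-built network.

Builds the binary gene x miRNA adjacency matrix for a seven-edge toy
network and ranks genes by how many miRNAs converge on them.  The
'Sums' column is each gene's degree of centrality; the top-ranked gene
is the one most miRNAs converge on — a candidate key gene.
"""

from mirnetmapper import InteractionTable, build_adjacency, rank_genes_by_centrality

edges = InteractionTable(edges=(
    ("hsa-miR-107", "TCF4"), ("hsa-let-7e-5p", "TCF4"), ("hsa-miR-421", "TCF4"),
    ("hsa-miR-107", "FNDC3A"), ("hsa-let-7e-5p", "FNDC3A"),
    ("hsa-miR-107", "SRGN"), ("hsa-miR-421", "IGF1R"),
))

adj = build_adjacency(edges)
print("Adjacency matrix (1 = predicted interaction):\n")
print(adj.to_frame().to_string(index=False))

print("\nGenes ranked by degree of centrality:\n")
print(rank_genes_by_centrality(adj).to_string(index=False))
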