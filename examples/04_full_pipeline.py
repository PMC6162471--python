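"""One-call pipeline: two input files in, all five outputs out.

Writes a simulated interaction table and DE list to disk, then runs the
full analysis exactly as the command line would: adjacency matrix,
impact table, barplot, identity heatmap, dendrogram, distance matrix,
Newick tree and a JSON manifest, all into ./pipeline_output.  The
manifest records T, G, edge counts and every warning raised on the way.
"""

import json
from pathlib import Path

from mirnetmapper import FixtureSpec, RunConfig, generate_network, run_all, write_fixture

workdir = Path("pipeline_output")
fixture = generate_network(FixtureSpec(
    n_mirnas=8, n_genes=200, edge_density=0.02,
    n_clusters=2, within_cluster_overlap=0.8, cluster_target_count=25,
    n_hub_genes=1, hub_degree=8, rng_seed=11,
))
inputs = write_fixture(fixture, workdir / "inputs")

manifest = run_all(RunConfig(
    interactions_path=str(inputs["interactions"]),
    de_genes_path=str(inputs["de_genes"]),
    output_dir=str(workdir / "results"),
    force=True,
))

print(f"T = {manifest.T}, G = {manifest.G}, edges = {manifest.n_edges}")
print("Leaf order:", " ".join(manifest.leaf_order))
print("\nOutputs:")
print(json.dumps(manifest.outputs, indent=2))
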