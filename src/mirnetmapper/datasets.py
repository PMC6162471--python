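"""Bundled worked example: the top-10 upregulated-miRNA impact stratum.

A published bladder-cancer analysis of this kind (upregulated miRNAs
against downregulated transcripts, T24 vs. metastatic FL4 cell lines)
reports ten miRNAs by their number of predicted targets found, out of
T = 971 distinct targeted genes and G = 1277 differentially expressed
genes.  The full edge list behind those counts is not distributed, so
`worked_example_network` reconstructs a **synthetic** network realizing
exactly those marginals: each miRNA receives a consecutive cyclic block
of the 971 target genes of length equal to its target count, which
guarantees every gene is targeted at least once and every column sum is
exact.  All impact percentages computed from it are therefore identical
to the published ones, while the individual edges are synthetic.
"""

from __future__ import annotations

from .io import DEGeneList, InteractionTable

# (miRNA id, number of predicted target genes found)
TOP10_IMPACT: tuple[tuple[str, int], ...] = (
    ("hsa-miR-107", 373),
    ("hsa-miR-1290", 357),
    ("hsa-miR-421", 320),
    ("hsa-miR-1297", 310),
    ("hsa-miR-128", 309),
    ("hsa-miR-375", 281),
    ("hsa-let-7e-5p", 274),
    ("hsa-miR-194-5p", 205),
    ("hsa-miR-1246", 189),
    ("hsa-miR-190b", 156),
)

#: distinct genes targeted by at least one of the miRNAs
N_TARGET_GENES = 971
#: total differentially expressed genes in the stratum
N_DE_GENES = 1277


def worked_example_network() -> tuple[InteractionTable, DEGeneList]:
    """Synthetic edge list realizing the worked example's marginals.

    Deterministic: miRNA *i* targets the next ``t_i`` genes of the
    971-gene cycle, starting where miRNA *i - 1* stopped.  The total
    edge count (2774) exceeds 971, and consecutive blocks tile the
    cycle, so every gene is targeted and T = 971 emerges from the data
    rather than being asserted.  The DE list adds 306 never-targeted
    decoy genes so that G = 1277.
    """
    genes = [f"TGT{i + 1:04d}" for i in range(N_TARGET_GENES)]
    edges: list[tuple[str, str]] = []
    offset = 0
    for mirna, t in TOP10_IMPACT:
        if t > N_TARGET_GENES:
            raise AssertionError("target count exceeds gene cycle")
        for k in range(t):
            edges.append((mirna, genes[(offset + k) % N_TARGET_GENES]))
        offset = (offset + t) % N_TARGET_GENES
    decoys = [f"DECOY{i + 1:04d}" for i in range(N_DE_GENES - N_TARGET_GENES)]
    return (
        InteractionTable(edges=tuple(edges)),
        DEGeneList(genes=frozenset(genes) | frozenset(decoys)),
    )
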