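# Methods

## The model

`mirnetmapper` analyses a bipartite miRNA → mRNA interaction network
under the canonical-silencing assumption: miRNAs act predominantly by
degrading their target transcripts, so in a differential-expression (DE)
contrast an upregulated miRNA is paired with downregulated candidate
targets (and vice versa).  The tool takes the *post-DE* edge list as
given — it performs no differential-expression analysis and no target
prediction — and computes three topology metrics:

1. **Gene degree of centrality.**  The binary incidence matrix
   `A[g, m] ∈ {0, 1}` records whether miRNA *m* is predicted to target
   gene *g*; a gene's row sum is the number of distinct miRNAs
   converging on it.  Genes with high in-degree are candidate key genes
   of the system.

2. **miRNA impact.**  For miRNA *m* with *t* targets found,

   - `t / T` — share of the *T* distinct genes targeted by ≥1 miRNA in
     the network (centrality within the regulated set), and
   - `t / G` — share of all *G* DE genes in the stratum (overall impact
     on the transcriptional response),

   both reported ×100 as percentages.  *T* is defined operationally as
   the number of genes with degree ≥ 1 in the adjacency matrix — the
   only reading under which a single (T, G) pair reproduces every row
   of the bundled worked example.  When no DE list is supplied, *G*
   falls back to *T* (the second column then duplicates the first and
   is flagged as derived in the `ImpactTable`).

3. **Structural equivalence.**  Dissimilarity between miRNAs *i*, *j*
   with target sets `t_i`, `t_j` is the Jaccard distance
   `D_ij = 1 − |t_i ∩ t_j| / |t_i ∪ t_j|`, a metric on finite sets that
   counts only shared *presence* of targets.  Presence/absence
   coefficients that reward shared absences (simple matching,
   chi-square-style association) would rate two miRNAs similar merely
   for jointly ignoring most of the genome, which is meaningless in a
   sparse regulatory network and is why they are not offered.
   Agglomerative hierarchical clustering over `D` (complete, average or
   single linkage) yields the dendrogram and the identity heatmap of
   similarity `1 − D` with rows/columns in dendrogram leaf order.

## Inputs, units and defaults

| parameter | default | meaning |
|---|---|---|
| interaction table | required | headerless TSV, one `miRNA<TAB>gene` row per predicted interaction |
| DE gene list | optional | headerless, one gene symbol per line; defines *G* |
| `intersection_policy` | `strict` | `strict` drops edges whose gene is outside the DE list (the intersection rule for repository-derived edge lists); `warn` keeps and reports them |
| `id_case_policy` | `preserve` | HUGO symbols are case-sensitive by convention; `upper` available for messy inputs |
| `linkage` | `complete` | inter-cluster distance rule; the default of the mainstream `hclust`-style routine in the ecosystem this workflow originated in.  Dendrogram shape depends on it, so it is surfaced prominently |
| `decimals` | 1 | display rounding of percentages (half-even); underlying values stay full-precision |

Duplicate edges collapse to one (an interaction is binary), with the
count logged.  One sign stratum is analysed per run; the two-run
convention (up-miRNA/down-gene, then down-miRNA/up-gene) is the user's
responsibility.

## Numerical and algorithmic choices

- **Rounding** is banker's (half-even) on the decimal representation,
  applied only at rendering time.  Half-up rounding reproduces the same
  worked-example table at one decimal, so the choice is not observable
  there; half-even is the default because it is bias-free.
- **Clustering** is an in-package agglomerative loop using
  Lance–Williams updates, emitting a standard linkage matrix that
  scipy's `dendrogram`/`fcluster`/`leaves_list` consume.  The loop is
  written here rather than delegated so that exact ties in the minimal
  linkage value resolve by a fixed rule — merge the pair whose combined
  sorted leaf-name tuple is lexicographically smallest — making the
  tree independent of input row order.  Ties are common with Jaccard
  distances (small rational values), so this matters in practice.
  Merge heights are nondecreasing for all three supported linkages.
- **Zero-target miRNAs** (possible after strict intersection) are
  excluded from the distance matrix with a warning rather than being
  assigned distance 1, because their Jaccard distance is a 0/0 form.
  They are reported in the run manifest.  A miRNA with zero targets
  cannot appear in a pure edge list at all; an upstream DE-miRNA list
  can be reconciled against the impact table by the user to spot them.
- **Degenerate inputs**: an empty interaction file, an empty DE list,
  a strict intersection that leaves no edges, fewer than two miRNAs to
  cluster, and non-finite distances are all hard errors.
- **Newick export** places each internal node at half its merge height
  (leaves at zero), the usual dendrogram-to-phylogram convention, so a
  two-leaf tree merged at *h* serialises as `(a:h/2,b:h/2);`.
- **Ordering of written tables** (genes by descending degree then name,
  miRNAs by descending target count then name, impact rows by
  descending *t* then name) is deterministic presentation; every
  computation is order-invariant, and re-running with identical inputs
  reproduces tabular outputs byte-for-byte.
- **Plots** are pure functions of their inputs; SVG output suppresses
  timestamps and randomised element ids so identical inputs give
  byte-identical files.

## The synthetic-network generator

`simulate.generate_network` emulates the two topological features the
method is designed to surface:

- **hub genes**, each targeted by at least `hub_degree` miRNAs;
- **planted miRNA clusters**: each cluster owns a disjoint core of
  genes; every member targets the full core plus private genes, with
  `within_cluster_overlap` (w) the core's share of each member's
  target budget (`cluster_target_count`, default 20 — a realistic
  per-miRNA count for a filtered DE-stratum network of tens of
  miRNAs).  Pairwise within-cluster Jaccard similarity is then
  `w / (2 − w)`; between-cluster distance is exactly 1 while no
  background edges are added (`edge_density = 0`).

Bernoulli background edges at `edge_density` and a DE list padded with
`decoy_fraction` never-targeted decoys complete the picture.  A single
integer seed drives all sampling, and written fixtures carry a sidecar
JSON of their spec.

What the generator does **not** emulate: expression values, fold
changes, p-values, prediction-score noise, overlapping cluster
membership, or the heavy-tailed degree distributions of real target
databases.  Tests passing on these fixtures demonstrate correctness of
the computations and recoverability of planted structure, not
biological validity on any real dataset.

`recover_planted_structure` cuts the tree at the midpoint of the
largest jump in merge heights and compares the resulting partition with
the planted one; a gap below 0.25 is flagged as "no separation" and
recovery is reported but not asserted.

## Worked example and validation scale

The bundled worked example (`mirnetmapper.datasets`) reconstructs the
top-10 impact stratum of a published bladder-cancer analysis
(upregulated miRNAs vs. downregulated transcripts in the T24 /
metastatic-FL4 cell-line pair): ten miRNAs with published target counts
out of T = 971 targeted genes and G = 1277 DE genes.  The full edge
list behind those counts was never distributed, so the module builds a
**synthetic** edge assignment (consecutive cyclic blocks over the
971-gene cycle) that realises exactly those marginals; every impact
percentage computed from it therefore matches the published table,
while individual edges are synthetic.  The pair (T, G) = (971, 1277)
is itself validated in the test suite by brute-force search: T = 971
is the only universe size consistent with all ten per-target
percentages at one decimal, and the two-decimal top-miRNA values
(38.41% of targets, 29.21% of DE genes) single out G = 1277.

The *full* source analysis — 31 upregulated DE miRNAs of which 14
showed impact, and TCF4 as the top-centrality gene with degree 12 —
cannot be reproduced here: it requires the complete interaction table
derived from the E-MTAB-2610/E-MTAB-2611 expression data, which is not
printed anywhere and would require downloads and upstream DE/target-
prediction steps that are out of scope.  Those numbers are recorded as
out-of-scope reference points only; validation instead rests on the
worked-example table plus oracle checks (set-arithmetic Jaccard,
from-scratch agglomerative clustering) and planted-structure recovery
on generated networks — problem sizes of ≤20 miRNAs × ≤50 genes for
oracle comparisons, 6–10 leaves for clustering oracles, and 10 miRNAs ×
400 genes for recovery runs, sizes at which the brute-force references
are exact and fast.

## Known limitations

- Counting impact ignores interaction strength and fold change by
  design; a weighted variant is out of scope.
- The adjacency matrix is materialised densely (typical scale: tens of
  miRNAs × ~10³ genes); very large networks would need a sparse path.
- Dendrogram leaf order is deterministic given linkage and tie rule but
  is not comparable across tools that break ties differently.
- The Jaccard distance treats all targets equally; two miRNAs sharing
  a few high-confidence targets score as dissimilar as two sharing a
  few spurious ones.
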