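# Methods

This note documents the models and procedures implemented in `orthoweave`,
the parameters that matter, the choices made where the design was open, and
what the synthetic validation does and does not establish.

## Meta-gene harmonization

Orthology is taken as an input (a BioMart-style homolog table anchored on a
reference species), not inferred. Every reference gene seeds one candidate
meta-gene; homolog symbols of each species attach to it. A candidate is
retained when it is covered in at least `min_species` species (default: all
configured species, so the default table is directly comparable across all
of them). Groups in which every covered species contributes exactly one
symbol are classed `one2one_all`; groups where some species contributes
paralogs are classed `one_to_many`. Symbols are matched case-insensitively
(uppercased on both sides) because rodent symbols differ from human mostly
by case.

A homolog symbol claimed by two reference genes (a many-to-many homology)
would double-count reads if duplicated, so the default policy assigns it to
the lexicographically smallest reference gene and logs the conflict;
`duplicate` and `drop` policies are selectable. Under `duplicate`,
aggregation refuses to run when a matrix gene maps to two meta-genes —
per-cell count conservation is treated as non-negotiable.

Aggregation sums **raw UMI counts** over a meta-gene's members, before any
normalization, and preserves per-cell totals over mapped genes exactly
(integer equality, asserted in tests). Output rows follow the meta-gene
table order (reference-symbol lexicographic) in every species, so matrices
concatenate without reindexing; barcodes are suffixed with the species id.

## Preprocessing

- **QC.** A cell is kept iff it detects strictly more than `min_genes = 200`
  genes and its mitochondrial count fraction is at most `max_mito = 0.20`
  (boundary readings: a cell at exactly 200 genes is removed, a cell at
  exactly 20% mitochondrial is kept). Mitochondrial genes are recognized by
  the `MT-` prefix; if none are present the fraction is 0 and a warning is
  issued rather than an error.
- **Normalization.** `x = ln(1 + c·s/C)` with `s = 1e5`; for every cell with
  nonzero total, `sum(expm1(x)) = s` exactly (up to round-off) — this
  identity is the invariant the tests assert.
- **Variable genes.** Per-gene variance of the normalized values is divided
  by the median variance of its bin among 20 equal-occupancy bins of
  log10(mean); the top `n = 2000` genes by this standardized variance are
  selected, ties broken by symbol. The binned median trend replaces a loess
  fit: it is dependency-light, deterministic, and gives the same ranking
  behavior on synthetic data. The variable-gene count is not identifiable
  from the source workflow; 2000 is the ecosystem default and is exposed in
  config.
- **Embedding.** Expression of the selected genes is centered and scaled to
  unit variance **per species** (the package's transparent stand-in for
  anchor-based integration: it removes per-species location/scale shifts so
  shared cell types co-embed; reimplementing CCA anchors is out of scope),
  clipped at ±10 to bound extreme cells, and decomposed by exact full-SVD
  PCA into 30 components. Component signs are fixed (largest-magnitude
  loading positive) so runs are reproducible.

## Clustering and annotation

The neighbor graph is a shared-nearest-neighbor graph: each cell's neighbor
set is itself plus its `k = 20` nearest cells in PC space; edges between kNN
pairs carry the Jaccard similarity of the two neighbor sets, and edges with
weight below 1/15 are pruned (the convention of the neighbor-graph routine
this reimplements). Communities are found by seeded modularity optimization
(local moving with aggregation and refinement, via leidenalg's
RBConfiguration partition; `resolution = 0.8`, `seed = 0` by default —
resolution and k are not identifiable from the source workflow and are
exposed in config). Cluster ids are canonical: decreasing size, ties broken
by the smallest member index, so identical partitions always yield
identical labels.

Markers come from one-vs-rest two-sided Wilcoxon rank-sum tests. Groups of
at most 10 cells on both sides use exact enumeration of the rank-sum
permutation distribution with midranks; larger groups use the normal
approximation with midrank tie correction and a 0.5 continuity correction.
Genes are pre-filtered by detection (`min_pct = 0.1` in either group) and
fold change (`|log2FC| ≥ 0.25`, with
`log2FC = log2((mean(expm1 x)+1)/(mean(expm1 y)+1))` — explicit and
pseudocount-stabilized). **BH adjustment corrects over the full gene
universe of the matrix**, with untested genes entering at p = 1: under the
null, genes passing the fold-change pre-filter are exactly those with
extreme rank statistics, so adjusting only the survivors is
anti-conservative (measured ~6× tail inflation on null splits); correcting
across all features restores calibration (0 discoveries in ≥ 90% of null
splits) without costing planted-effect sensitivity.

Annotation is cluster-level: panel-gene expression is z-scored across all
cells, a cluster's score for a type is the mean z over its cells and the
type's panel genes, and the argmax type wins (ties broken by panel order).
Zero-variance panel genes carry no information and are excluded from
scoring; clusters whose best score is negative (or with no informative
panel signal at all) stay `unassigned`. Composition tables are proportions
over annotated cells per species.

## Cross-species comparisons

- **Pseudobulk** profiles are mean normalized expression per
  (species, cell type), groups under 10 cells dropped; their PCA uses
  centered profiles.
- **Cross-species DE** reuses the marker machinery between two species
  within one cell type (each needs ≥ 3 cells); swapping the species flips
  fold-change signs exactly.
- **Enrichment** is the one-sided hypergeometric upper tail
  P(X ≥ overlap), identical to one-sided Fisher on the 2×2 table (asserted
  against it), BH-adjusted across sets. Gene-set collections are user
  inputs (GMT, JSON or two-column TSV).
- **Family scores** are per-cell means (not sums) of normalized expression
  over a family's present members, so families of different sizes are
  comparable; group contrasts use the same rank-sum test. The per-cell mean
  and the joint-vs-separate grouping of T/B cells were open choices; the
  mean and caller-supplied cell groups are implemented.
- **Bulk DE** follows the FPKM rule: genes whose larger group-mean FPKM is
  below 1 are `unexpressed` and get no p-value; the rest are tested by
  two-sided Welch t on log2(FPKM+1) — the simplest defensible two-group
  test at n = 2 replicates, stated openly since the source pipeline's test
  is unnamed — and called `up`/`down` iff |log2FC| > 1 **and** p < 0.05.
- **Ligand–receptor strength** is a deliberately transparent mass-action
  stand-in for full cell-communication frameworks: pair score =
  mean(expm1 ligand in sender cells) × mean(expm1 receptor in receiver
  cells), summed over sender/receiver type combinations into a pathway
  score, normalized per species to sum 1 ("relative strength"). It is
  bilinear in the two means and carries no significance model of its own;
  an optional label-permutation null (default 100 shuffles) provides a
  per-pair p-value.

## Synthetic study design

The generator emulates a four-species antrum-epithelium experiment with
known truth. Defaults:

| parameter | value | rationale |
| --- | --- | --- |
| species | human (reference), pig, rat, mouse | the study design being emulated |
| reference genes | 1000 | desk-scale; ~860 retained meta-genes after coverage filtering |
| paralog rate | 0.10 per (gene, species) | 2–3 paralogs when drawn; matches the ~7% "1-many" share of curated ortholog sets |
| missing rate | 0.05 per (gene, species) | annotation gaps; marker/program genes exempt so panels resolve everywhere |
| cell types | 7 shared + pig-private F3⁺ | the annotated antral types; ~3930 cells total, composition biased (rodents pit/proliferative-rich, human/pig BGMC-rich, pig parietal-poor) |
| marker programs | named markers + 20 genes, 8× boost | strong, well-separated identity programs |
| immune program | 25 genes, 4× boost in pig only | the planted species-biased signal (includes RANKL ligand/receptor) |
| count model | NB, dispersion 0.1 | standard overdispersed scRNA-seq surrogate |
| library size | log-normal, median 5000, σ = 0.3 | realistic QC behavior around the 200-gene filter |
| mito fraction | Beta(2, 38) per cell (mean 0.05) | a small tail of cells exceeds the 20% QC cut |
| dropout | 0.10 Bernoulli | zero-inflation on top of NB sampling |
| bulk contrast | 50 genes, 4-fold, replicate σ = 0.1 (log2) | a low-noise two-replicate design where the FPKM rule should recover ≥ 90% |

Paralogous homologs split their reference gene's expectation uniformly, so
meta-gene aggregation inverts the split in expectation — the clean
conservation test. Baseline gene weights are log-normal, with program/
immune/pathway genes clamped to at least the median weight so planted
effects sit on detectable expression. The truth record (cell labels, gene
programs, meta-gene assignments, planted bulk DE genes, the planted
pathway) is emitted alongside the data and never read by any pipeline
operation.

What the generator does **not** emulate: doublets, ambient RNA, batch
chemistry effects, read-level structure (FASTQ), realistic gene–gene
correlation beyond the planted programs, and cross-species mean shifts
other than the immune program. Passing the recovery tests therefore shows
that the machinery is correct and calibrated under a faithful statistical
surrogate, not that annotations on real tissue would reach the same
accuracy.

## Numerical notes and limitations

- Determinism: all generators draw from seed-derived independent streams;
  identical config + seed reproduce byte-identical TSV/MTX outputs.
- Degenerate inputs: all-zero cells normalize to all-zero columns;
  zero-variance genes get unit scale (z = 0); single-cell clusters are
  skipped in marker detection with a warning; empty graphs, empty species
  lists and zero gene overlap raise informative errors.
- With a handful of genuinely ambiguous cells (~0.1% at default noise), the
  modularity step can place a non-owner cell in the species-private
  cluster; its purity stays ≥ 95% but pipeline-annotated compositions can
  show a sub-1% private-type proportion outside the owning species.
- The rank-sum exact path enumerates up to C(20,10) subsets per gene; it is
  intended for the ≤ 10-per-group regime only.
- Cross-species DE operates on normalized meta-gene expression; it does not
  model gene-length or annotation-quality differences between species
  beyond what meta-gene aggregation absorbs.
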