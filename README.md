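# orthoweave

Cross-species comparison of single-cell RNA-seq is blocked by a mundane
problem: every species has its own gene namespace, paralog expansions and
annotation gaps, so count matrices from different organisms do not share
rows. `orthoweave` implements the homology-anchored **meta-gene** approach
used in comparative studies of the gastric antrum epithelium: every gene of
a reference species (human) seeds one ortholog group, homolog symbols of the
other species (pig, rat, mouse) attach to it, and each species' raw UMI
counts are **summed over all manifestations of each meta-gene** before any
normalization. The harmonized matrices live in one shared gene space and can
be pooled, clustered and compared.

On top of the harmonization the package provides the full downstream
analysis chain, each step with explicit formulas:

- **QC** — keep cells with > 200 detected genes and mitochondrial count
  fraction ≤ 20%.
- **Normalization** — `x = ln(1 + c·s/C)` with scale factor `s = 1e5`,
  cell total `C`.
- **Variable genes** — variance standardized against a 20-bin median
  mean–variance trend.
- **Embedding** — per-species centering/scaling (a transparent stand-in for
  anchor-based integration), values clipped at ±10, exact 30-component PCA.
- **Clustering** — shared-nearest-neighbor graph (Jaccard weights, pruned at
  1/15) and seeded modularity community detection.
- **Markers / DE** — one-vs-rest and cross-species two-sided Wilcoxon
  rank-sum (tie-corrected normal approximation, exact enumeration for groups
  ≤ 10), `log2FC = log2((mean(expm1 x)+1)/(mean(expm1 y)+1))`, BH adjustment
  over the full gene universe.
- **Annotation** — curated marker panels (GKN1/MUC5AC pit mucous, AQP5
  BGMC, PGC chief, ATP4A/B parietal, CHGA/B endocrine, HCK/DCLK1 tuft,
  MKI67/BIRC5/MCM6/PCNA proliferative, F3/CLCA1/RRAD for the pig-private
  F3⁺ cluster) scored by mean z-scored expression per cluster.
- **Comparisons** — cell-type composition tables, pseudobulk PCA,
  hypergeometric gene-set enrichment, per-cell immune-family scores, the
  bulk FPKM DE rule (unexpressed below FPKM 1; DE iff |log2FC| > 1 and
  p < 0.05, Welch t on log2(FPKM+1)), and a mass-action ligand–receptor
  pathway strength (`mean(expm1 ligand in senders) × mean(expm1 receptor in
  receivers)`, summed per pathway, normalized per species).

A bundled synthetic-data generator emulates the four-species study design —
negative-binomial counts, marker programs, a pig-private cell type, an
immune program elevated in pig (including the RANKL ligand/receptor pair),
paralog splitting, mitochondrial fractions, dropout, and a TNFα-like bulk
contrast — and emits the planted truth alongside, so every stage can be
validated against known structure.

## Worked example

```python
import orthoweave as ow
from orthoweave.pipeline import run_synthetic_pipeline

res = run_synthetic_pipeline(ow.SimulationConfig(seed=0))
print(ow.classify_summary(res.metagenes))
print(res.qc_report.to_string(index=False))
print(res.ratios.round(3))
```

prints

```
{'one2one_all': 587, 'one_to_many': 274, 'total': 861}
 n_cells_in  n_cells_kept  removed_low_genes  removed_high_mito
       3930          3903                  0                 27
cell_type   BGMC  F3+ cell  chief cell  endocrine cell  parietal cell  pit mucous cell  proliferative cell  tuft cell
species
human      0.190     0.001       0.160           0.084          0.106            0.214               0.159      0.085
mouse      0.104     0.000       0.157           0.081          0.104            0.266               0.207      0.082
pig        0.168     0.150       0.144           0.078          0.049            0.193               0.143      0.075
rat        0.104     0.000       0.154           0.083          0.103            0.266               0.208      0.082
```

Of 1000 reference genes, 861 meta-genes are covered in all four species
(587 with exactly one member per species, 274 with at least one paralog
expansion); 27 of 3930 cells fail the mitochondrial filter; and the
composition table recovers the planted structure — the F3⁺ type appears
only in pig (15%), parietal cells are depleted in pig, pit mucous and
proliferative cells dominate the rodents. Cross-species DE within pit
mucous cells (pig vs human) then surfaces the planted immune program:

```python
de = ow.cross_species_de(res.norm, res.cells, "pit mucous cell", "pig", "human")
print(de.nsmallest(5, "p_adj")[["gene", "log2fc", "p_adj"]])
```

```
  gene   log2fc        p_adj
JCHAIN 1.886014 4.256731e-62
  CD74 1.914049 2.990808e-59
IMM010 2.031549 2.500215e-49
 CHID1 1.839374 4.497290e-48
 CD79A 1.828956 2.115701e-47
```

i.e. the immunoglobulin/antigen-presentation genes planted ~4× higher in
pig are recovered with log2 fold changes near the configured boost of 2.

The same stages are scriptable from the shell via the `orthoweave` CLI
(`simulate`, `metagenes`, `harmonize`, `preprocess`, `cluster`,
`composition`, `de`, `enrich`, `familyscore`, `lr`, `bulkde`); every stage
exchanges plain-text MTX/TSV/JSON artifacts.

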