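# sfmultiome

Multimodal single-cell regulatory analysis of synovial fibroblasts (SFs):
paired scRNA-seq / scATAC-seq machinery for mapping how arthritis rewires the
gene-regulatory landscape of the joint, exercised end-to-end on a synthetic
multiome generator with planted ground truth.

In TNF-driven inflammatory arthritis, distinct fibroblast states expand from a
repressed progenitor state in the sublining synovium. Resolving *which*
transcription factors drive that expansion, and *which* genes are already
epigenetically poised to respond, requires integrating chromatin accessibility
with expression at single-cell resolution. This package implements the
computational core of such a study for analysts who have cluster labels,
candidate peak calls, motif hits, and a latent-time ordering in hand and need
the downstream integration:

- **Gene activity scores** from a 500-bp tile matrix: for gene *g* and cell
  *c*,
  `raw(g,c) = L(g) · Σ_{|d|≤100kb} (e^(−|d|/5000) + e^(−1)) · tiles(t,c)`,
  where *d* is the tile-center-to-TSS distance and `L(g)` maps 1/gene-length
  linearly onto [1, 5]; columns are scaled to 10,000 and log2-transformed.
- **Fixed-width peak sets** by iterative overlap merging: candidates are
  ranked by score, the best peak is kept, overlapping candidates discarded,
  first within pseudo-bulk replicates per cluster and then across the dataset.
- **Motif deviations** (chromVAR-style): `raw(m,c) = obs(m,c)/exp(m,c) − 1`
  with a depth-matched expectation, z-scored against accessibility-matched
  background peak sets.
- **Positive TF regulators**: TFs whose motif deviation correlates with their
  own expression (Pearson r > 0, r² > 0.5, BH-adjusted p < 0.05).
- **Peak-to-gene links and the disease GRN**: Pearson correlation between peak
  accessibility and expression across pseudo-cell aggregates within a 250-kb
  window; TF→peak→gene links through motif annotation, filtered to
  disease-upregulated genes connected via disease-opened peaks
  (|log2FC| > 0.58, p < 0.01).
- **Driver genes and epigenetic priming**: cluster-and-disease-specific DE
  genes intersected with high driver-likelihood scores; phase assignment by
  hierarchical clustering along latent time; and the four-criterion primed
  call — silent in the root state, activated downstream, upregulated in
  disease, promoter already open in the root.
- **Regulons and cross-species modules**: SCENIC-style co-expression ranking
  pruned by motif evidence, rank-based per-cell AUC activity, homolog-mapped
  conservation between species, and module clustering of conserved TFs by
  deviation correlation.

Marker detection uses the two-sided Wilcoxon rank-sum test (exact enumeration
for small groups, tie-corrected normal approximation otherwise) with
Bonferroni correction over all features, Seurat-style avgLFC, and the
published thresholds (QC ≥ 500 genes and ≤ 10% mitochondrial reads; markers
p < 0.01, avgLFC ≥ 0.25, detected in ≥ 25% of one group).

The synthetic generator (`sfmultiome.simulate`) plants all of this structure —
cluster markers, TF regulons with motif-bearing enhancers, disease expansion,
a rooted lineage with latent time, and primed genes — so every stage is scored
against known truth. See `docs/methods.md` for the generative model and its
limits.

## Worked example

The analysis is organised as numbered drivers over the library:

```bash
python analysis/01_simulate.py            # write the dataset + ground truth
python analysis/02_expression_markers.py  # QC, normalization, markers
python analysis/03_atac_features.py       # peak merging, gene scores
python analysis/04_motif_regulators.py    # deviations, positive regulators
python analysis/05_grn_links.py           # links and the disease GRN
python analysis/06_trajectory_priming.py  # drivers, phases, primed genes
python analysis/07_cross_species_regulons.py  # regulons, conservation, modules
```

At the default design (2,400 cells in 6 clusters × healthy/disease, 2,000
genes, 5 TFs, 4,000 peaks, seed 1) the drivers print:

```
planted marker recovery: sensitivity 1.000, FDR 0.003
47797 candidate peak calls -> 4000 merged fixed-width peaks
gene activity vs planted promoter accessibility: rank correlation 0.807
positive regulators: 5 detected; 5/5 planted TFs recovered, 100% of 20 decoy motifs rejected
1820 peak-to-gene links (1281 shared, 228 disease-unique, 159 healthy-unique)
704 TF->peak->gene links through positive regulators; 102 pass the disease filter
planted disease-regulon edges: precision 1.000, recall 0.850
481 inter-cluster DE genes -> 136 cluster+disease specific -> 136 drivers (Jaccard with planted 0.971)
39 primed genes (sensitivity 0.975, FDR 0.000)
5 regulons inferred (target precision 0.953, recall 1.000)
5 regulons conserved across the two species replicates (median target Jaccard 0.909)
module clustering of conserved TFs: ARI vs planted programs 1.000
```

Reading these: every planted cluster marker is recovered at the published
thresholds with a 0.3% false-discovery rate; the merged peak set reproduces
the 4,000 planted regions; all five planted TFs pass the positive-regulator
rule while decoy motifs fail it; the disease-filtered GRN recovers 85% of the
planted disease-TF edges with no false edges; and the primed-gene caller finds
39 of the 40 planted primed genes with no false calls. The per-TF regulation
summary shows the planted disease regulator controlling ~90% of primed genes,
the pattern the priming analysis is designed to expose.

## Layout

```
src/sfmultiome/    core, config, io, simulate, markers, atac, motifs,
                   linkage, trajectory, regulons, pipeline
analysis/          numbered narrative drivers (the interface)
tests/             unit, property, and acceptance suites
scripts/           acceptance.py
docs/methods.md    model, assumptions, parameter choices, limitations
```
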