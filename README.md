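# leafdyn

Cell-type-resolved analysis of leaf-ageing transcriptional dynamics and
their dose-dependent response to drought, for single-nucleus RNA-seq
designs in which every nucleus is barcoded back to its leaf or shoot of
origin. The package is aimed at plant genomicists who want the full
inference chain — pseudobulk construction, gene-wise covariate models,
hormone-response overlap, dose-response trend classes and phenotype-linked
candidate ranking — as reusable, tested components rather than a one-off
analysis script.

## The models

Leaf stage (rosette position L1–L15) and sampling day are collinear
descriptors of leaf age and are combined into one composite covariate,

    leaf_age = 23 + day − 2 · leaf_stage,

and each gene *g* is modelled per cell type on log2 quantile-normalized
pseudobulk expression:

    y_g = β0 + β_age · leaf_age + β_drought · 1{drought} + ε

with Wald *t* inference and Benjamini–Hochberg adjustment per cell type and
coefficient. A gene is ageing-induced when `padj < 0.01` and
`β_age > 0.04`, repressed when `β_age < −0.04`, drought-responsive when the
drought term is significant at the same level.

On the hard-agar (HA) osmotic-stress grid (8 doses × 11 days) the model is
`y_g = β0 + β_time · day + β_dose · dose`, and significance/sign patterns
define three trend classes: dose-induced/time-flat, dose-and-time-induced,
and time-induced/dose-repressed — the class whose mean z-score trajectory
tracks shoot area most closely. Hormone responses are detected per cell
class with a negative-binomial GLM likelihood-ratio test against mock and
intersected directionally with ageing/drought sets by one-sided Fisher
exact tests. Candidate regulators are ranked by combining per-gene
expression–shoot-area correlation with independent drought responsiveness
in the rosette experiment.

A synthetic-data module generates all three study designs (negative-binomial
nucleus counts, nine cell types, planted gene archetypes with known effect
sizes and a coupled shoot-area phenotype) so every stage is testable without
any external download; `leafdyn.benchmarks` scores each stage against the
planted truth.

## Worked example

```python
from leafdyn import SimConfig, simulate_rosette, AgeingModel
from leafdyn.pipeline import prepare_celltype_matrix

cfg = SimConfig(seed=1, n_genes=2000)            # the default rosette design
nuclei, samples, truth = simulate_rosette(cfg)    # 270 leaves, 10,800 nuclei
pb = prepare_celltype_matrix(nuclei, samples, "mesophyll")  # UMI>=450, QN, log2
result = AgeingModel(pb, samples, "mesophyll").fit(alpha=0.01, min_coef=0.04)
print(result.summary())
```

```
Leaf-ageing model: cell type 'mesophyll', 2000 genes, 270 pseudobulk columns
  thresholds: padj < 0.01, |leaf-age coefficient| > 0.04
  ageing-induced:      403
  ageing-repressed:    201
  drought-responsive:  276 (up 58, down 218)
```

Of the 2,000 simulated genes, 604 are classified as ageing-associated —
the generator planted ~500 genes with nonzero age slopes (pure ageing
archetypes plus development-induced, drought-repressed and hormone-coupled
genes), and the surplus is controlled at the configured FDR. The 276
drought calls are dominated by repression (218 down), matching the planted
drought-repressed programme. `result.table` carries per-gene coefficients,
standard errors and adjusted p-values; `result.gene_sets()` exposes the
directional sets consumed by the hormone-overlap stage, and
`result.trend(gene_id)` returns a quadratic age trend with confidence bands
for plotting.

The same objects exist for the dose grid (`DoseResponseModel` →
trend classes, class trajectories, `area_correlations`) and the hormone
experiment (`HormoneDEModel` → DE sets, promiscuity filter, Fisher
overlaps). `leafdyn run --config cfg.yaml` executes the whole chain and
writes per-stage TSVs plus a manifest; rerunning the same configuration is
byte-identical.

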