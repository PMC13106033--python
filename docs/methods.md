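# Methods

`leafdyn` reconstructs, as a tested pipeline, an inference procedure for
cell-type-resolved leaf-ageing transcriptional programmes in *Arabidopsis
thaliana* and their dose-dependent response to water limitation. This note
records the statistical models, the synthetic study designs they are
validated on, and the numerical and design choices that were genuinely open.

## The composite leaf-age covariate

Rosette leaves are sampled as 15 stage positions (L1 oldest … L15 youngest)
over a 9-day time course. Stage and day are strongly collinear descriptors of
how old a leaf is (`AgeingModel.diagnostics()` reports VIFs and the design
condition number), so inference uses one composite covariate:

```
leaf_age = 23 + day − 2 × leaf_stage
```

computed in exact integer arithmetic. The constants encode that one stage
position corresponds to about two days of developmental separation; the
offset places the youngest sampled leaf near age zero mid-design.

## Gene-wise linear models

Pseudobulk profiles (summed UMI counts per cell type × sample, nuclei with
< 450 total UMI discarded) are gene-filtered (row total ≥ 10 and nonzero in
≥ 3 columns; these two thresholds are this package's own defaults),
quantile-normalized within each cell type's columns, and modelled on
`log2(QN + 1)`:

* **Ageing model** (per cell type): `expr ~ leaf_age + drought`, OLS with
  Wald *t* inference, drought a binary indicator. A gene is
  ageing-**induced** when BH-adjusted p < 0.01 *and* the leaf-age coefficient
  exceeds 0.04 (strict); **repressed** symmetrically below −0.04 (the
  absolute-value extension makes repressed genes classifiable);
  drought-responsive when the drought term has adjusted p < 0.01. The 0.04
  threshold is expressed in the engine's log2-normalized units and is a
  configurable parameter. BH families are per cell type and per coefficient.
* **Dose-response model** (hard-agar design, default cell type mesophyll):
  `expr ~ day + dose`, both quantitative, over the 88-condition pseudobulk
  (8 doses × 11 days; the ~7 shoots of a condition are pooled before
  normalization). Trend classes by sign and significance at adjusted
  p < 0.01: dose-induced/time-flat (dose significant positive, time *not*
  significant — non-significance operationalizes "unchanged over time",
  since no equivalence test is specified); dose-and-time-induced (both
  positive); time-induced/dose-repressed (time positive, dose negative);
  remaining significant patterns are "other".

A Gaussian OLS engine on log-QN values is used deliberately instead of a
negative-binomial count engine: quantile normalization destroys the
mean-variance relationship an NB model assumes, and the OLS route is exactly
testable against closed forms. "Advancement" of ageing programmes under
drought is read from the drought main effect of ageing-classified genes — no
age × drought interaction term is fitted.

Quadratic display trends (`fit_quadratic_trend`) are degree-2 least squares
with pointwise t-based confidence bands at 95% or 99%.

## Hormone differential expression and directional overlap

Hormone responses (8 treatments vs mock) are tested per cell class
(mesophyll; epidermal = epidermis + guard + trichome; vasculature = phloem +
xylem + bundle sheath + hydathode + myrosin idioblast) on raw class-level
pseudobulk with a negative-binomial GLM likelihood-ratio test written from
first principles: log link, log-library-size offset, full model intercept +
group, reduced model intercept only, LR ~ χ²(1), BH within each
hormone × class family at adjusted p < 0.05.

Dispersion is per-gene method-of-moments under the full model, floored at
1e-8. With six columns per group that raw estimator frequently collapses to
the floor and inflates the statistic for high-count genes, so by default each
gene's dispersion is additionally floored at the family median after a
J/(J−2) degrees-of-freedom correction — a light-touch analogue of the
dispersion moderation standard DE engines perform (`moderate_dispersion=False`
exposes the raw estimator, whose Poisson limit is tested exactly).

Genes DE under three or more hormones within a class are removed as
promiscuous (per class — a gene may survive elsewhere). Surviving sets are
intersected with ageing/drought sets of matching direction via a one-sided
Fisher exact test (hypergeometric enrichment tail) against a background of
genes with nonzero pseudobulk count in that class; overlaps with p < 0.05
are retained.

## Candidate prioritization

Two independent measures combine as a filter-then-sort, mirroring a
two-criterion candidate scatter: eligibility requires membership in the
time-induced/dose-repressed class, a significant negative drought
coefficient in the rosette mesophyll fits (adjusted p < 0.01), and a defined
per-gene Pearson correlation between z-scored expression and per-condition
mean shoot area; eligible genes are ranked by descending correlation (ties:
ascending drought p, then gene id). No composite score is formed — the two
axes stay interpretable, and both the drought coefficient and a signed
−log10 adjusted p are emitted for plotting.

## Phenotype statistics

`ancova_condition_effect` fits the parallel-slopes model
`response ~ day + condition` and F-tests the condition term by residual-sum
comparison (area untransformed by default; `log_response`/`--log` available
since the original transform choice is unstated). `welch_one_sided_t` is
Welch's unequal-variance t with Satterthwaite degrees of freedom, one-sided.

## The synthetic data generator

`simulate_rosette`, `simulate_hormone` and `simulate_hard_agar` emulate the
three study designs with planted, recoverable ground truth; they are the
package's validation substrate, not a model of any particular dataset.

**Count law.** Counts are gamma-Poisson (NB2, dispersion 0.15): a nucleus of
depth *s* (log-normal, median ≈ 1,300 UMI, capped to [150, 20,000]) expresses
gene *g* with mean `s · p_g`, where `p` is the softmax over genes of log2
baseline + design effects + biological noise. The softmax is deliberate: UMI
data measure relative abundance, so planted effects are planted on the scale
the pipeline can actually see. Random streams split hierarchically
(design → sample), so identical configurations are bit-identical and partial
regeneration is stable.

**Designs and effects** (all log2-scale defaults):

* Rosette: 15 stages × 9 days × {well-watered, drought}, 40 nuclei per leaf;
  drought water content falls linearly 100 → 21%. Ageing archetypes (5% + 5%
  of genes) carry slope ±0.1 per leaf-age day. Drought-advanced genes (5%)
  age with random sign and have their *effective* age advanced by 0.15 days
  per % water lost, which the main-effect model reads as a concordant-sign
  drought shift. Time-induced/dose-repressed genes double as
  photosynthesis-like rosette genes: age slope +0.1, drought shift −0.5.
* Hormone: 8 treatments + mock × 6 replicate samples. Hormone-responsive
  genes (5%) are assigned one (hormone, class) pair round-robin with one
  direction per pair (≈ 4 genes per coupling) and shift ±2.0 in that class;
  with coupling enabled they also age with the same sign, planting
  hormone-ageing couplings.
* Hard agar: 8 doses (default grid 1.0–3.33, an explicit assumption — the
  full dose ladder is configurable) × 11 days × 7 shoots. Planted classes at
  10% each: dose-only (+0.3/dose), dose-and-time (+0.3, +0.15/day),
  time-induced/dose-repressed (−0.3, +0.15). Shoot area is
  `A0·exp(0.19·day)·exp(−0.49·(dose−1))·exp(ε)`, ε ~ N(0, 0.1), calibrated
  so unstressed shoots grow ≈ 33 → 220 mm² and maximally stressed ≈ 20 → 71
  mm² over the course; setting the dose-decay to 0 decouples phenotype from
  dose.
* Gene 0 is an optional planted candidate: ageing-induced,
  drought-repressed (−0.75), strongly dose-repressed (−0.6) and time-induced
  (+0.3), at pinned median abundance.

**Composition structure.** Baselines are log-normal (sd 1.25 log2). The
stress/growth-programme archetypes are drawn from a band 1.5 log2 below the
genome average, and hormone-response genes from a slightly elevated band.
This is both biologically sensible (drought markers are induced from low
basal expression) and statistically load-bearing: quantile normalization
translates rank crossings into value changes, so where the moving genes sit
determines how cleanly unaffected genes stay flat.

**Biological noise.** Independent per-gene log2 noise (sd 0.2) is added per
sample (leaf or treated rosette); in the hard-agar design the 7 shoots of a
condition share one such component (their common plate/day
micro-environment) plus the count-level noise. Without it, pseudobulk counts
are so precise that negligible artifacts become statistically significant —
real designs are biology-noise-limited, not count-limited.

**What the generator does not emulate:** doublets, ambient RNA, batch or
capture-bias effects, gene length/GC bias, discrete developmental
transitions (heteroblasty), cell-type-specific ageing programmes (non-hormone
effects apply across cell types), and correlated gene modules. Passing
recovery tests therefore demonstrates that the inference machinery is
correct and calibrated under the stated generative assumptions — not that it
is robust to every artifact of real single-nucleus data.

## Known limitation: compositional drift under quantile normalization

With ~20% of genes genuinely induced over time, relative-abundance
measurement plus rank-based normalization necessarily pushes unaffected
genes slightly down (~−0.03 log2/day here). With 88 well-measured columns
that drift is often statistically significant, so roughly half of the
planted dose-only (time-flat) genes acquire a weak negative time trend and
land in "other" rather than their own class. The effect is conservative — no
gene is assigned to a *wrong named* class (cross-class confusion is ~0) —
but "time-flat" should be read as "time-flat on the normalized scale". The
dose-phenotype null check is therefore run on a design without time-induced
programmes, which isolates the coupling being tested from this drift.

## Validation problem sizes

Recovery benchmarks run the full default designs (2,000 genes; 270 rosette
samples; 616 shoots). The 20-replicate calibration checks (all-null
discovery, decoupled overlaps, dose-decoupled correlations, candidate
ranking) use reduced designs (500–1,000 genes, 16–30 nuclei per sample, 4
shoots per condition) — sizes chosen so each replicate still has the power
regime of the full design for the quantity being checked. `benchmarks.py`
records every such size, and `scripts/acceptance.py` reports them alongside
each metric.

## Numerical choices

* Quantile normalization: mean-of-sorted-columns reference; ties receive the
  mean of their tied reference values (deterministic; on tied data the
  "identical sorted multisets" property then holds only up to tie
  averaging). Idempotent on tie-free data.
* z-scores use the sample SD (n−1); constant genes map to all-zero rows.
* Zero-variance genes in OLS get coefficient 0 and p = 1; all-zero genes in
  the LR test are skipped with p = 1.
* NB group means are fitted by Newton iteration on log-mean (globally
  convergent; 25 iterations, step clamp ±4); genes at the dispersion floor
  are evaluated with the exact Poisson likelihood.
* p-values are clamped to (tiny, 1]; BH is the standard step-up, applied per
  family.
* The trailing "+ c" sometimes written after the leaf-age formula is an
  intercept annotation of the enclosing regression, not part of the
  covariate; `compute_leaf_age` omits it.
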