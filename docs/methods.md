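# Methods

This note documents the models and procedures `mspscreen` implements, the
choices made where the design was genuinely open, and what the synthetic
benchmark does and does not demonstrate.

## Quantification

The pipeline's abundance input is a gene-catalog read-count matrix
(genes × samples, non-negative integers) together with a gene-info table
assigning each catalog gene a length in bp, a metagenomic species
pan-genome (MSP), a core/accessory label, a core rank, and optionally an
accessory-module id and taxonomy.

Counts are length-normalized to transcripts-per-million:

    tpm_gs = (x_gs / len_g) / Σ_g' (x_g's / len_g') × 10^6

so every sample column with any mapped reads sums to 10^6 (checked to
1e−9 relative). Columns with no reads stay zero rather than propagating
NaN.

MSP abundance in a sample is the **median TPM of the MSP's 30
top-ranked representative core genes**. Two conventions needed fixing:

- Zeros count toward the median. The representative set is fixed, not
  "top-30 detected", so an MSP below the detection limit scores 0
  instead of being propped up by its few detected genes. (A
  `n_representatives` parameter exposes the set size.)
- MSPs with fewer than 30 core genes use all of their core genes.

Relative MSP abundance renormalizes the medians to sum 1 per sample;
this is the input for diversity, differential abundance, and taxon
aggregation (MSPs lacking an annotation at the requested level pool
under "unclassified", so column sums are conserved).

Named gene sets (e.g. the five cgr-locus homologs of *E. lenta*, or a
HypD homolog set) are aggregated by per-sample summation of counts (the
presence/absence signal) and of TPM (the combined relative-abundance
signal).

## Diversity and PERMANOVA

Alpha diversity is the Shannon index with natural log. Beta diversity is
Bray-Curtis dissimilarity d_ij = Σ|x_i − x_j| / Σ(x_i + x_j) on relative
MSP abundances; ordination is classical PCoA (eigendecomposition of the
Gower-centered squared-distance matrix, via scikit-bio).

The PERMANOVA is the distance-based sequential (Type I) partition of
McArdle & Anderson (2001): with G the Gower-centered matrix and H_j the
hat matrix of the design containing terms 1..j (plus intercept), the
j-th term's sum of squares is tr(H_j G) − tr(H_{j−1} G); pseudo-F uses
the residual mean square. Because the partition is order-dependent, a
model-selection step first fits each covariate alone and orders
covariates by their single-term partial R², descending (ties keep input
order; constant covariates are dropped with a warning). The single-term
R² table is reported alongside the sequential table so users can
re-order. p-values use free permutation of sample labels (no strata)
with the +1 correction, p = (1 + #{F* ≥ F}) / (1 + n_perm); default
n_perm = 1000. Seeded permutation streams make p-values bit-for-bit
reproducible.

## Differential abundance

Per-feature procedure on relative abundances:

1. **Prevalence filter.** Features present in < 20% of samples are
   dropped, unless their presence/absence pattern is specific to the
   control or the pooled disease cohorts: a two-sided Fisher exact test
   on the presence × disease-status table, BH-adjusted **across the
   low-prevalence candidates only**, rescues features at FDR < 0.05.
   (Adjusting over all features was the alternative; the candidate-only
   family is used because only candidates are tested.)
2. **Transform.** Zeros are replaced by half the smallest non-zero value
   of that feature, then log10.
3. **Model.** One OLS per feature: y ~ age + sex + cohort + treatment,
   with reference levels control (cohort), none (treatment, 6
   categories), male (sex). All features share one design matrix, so the
   fits are solved jointly as a multi-response least-squares problem;
   coefficients, standard errors, and two-sided t-tests are identical to
   per-feature OLS (verified against statsmodels in the tests).
4. **Contrasts and FDR.** Each non-reference cohort level yields one
   contrast (IgG4-RD vs control, SSc vs control); BH is applied across
   features **within each contrast**, matching per-comparison FDR
   reporting. SSc-subgroup analyses are supported by recoding the cohort
   column with the subgroup labels.

Treatment categories observed in only one cohort are reported as a
degenerate-cell table (confound transparency) rather than silently
dropped; with controls untreated by design, treatment effects are
identified from the within-disease mixture of categories.

## Accessory-module carriage

Absence of reads for a strain-variable locus is only evidence of absence
when the species is well covered. For each MSP × module the detection
model uses the proportionality between module reads and the reads of the
MSP's top-30 representative core genes among putative carriers:

- carriers for the fit = samples with ≥ 1 module read and ≥ 1 core read;
- β = median over carriers of (module reads / core reads). The median is
  robust to a few contaminating non-carriers with spurious reads; a
  regression-through-origin estimator could replace it, but the median
  needs no noise model. The mild circularity (carriers defined by ≥ 1
  read) only sets a conservative coverage floor, it does not bias calls;
- m\* = smallest integer with β·m ≥ 1, i.e. the minimal core-read count
  at which a carrier is expected to show at least one module read. Under
  the Poisson model a carrier at core reads = m\* shows ≥ 1 module read
  with probability ≥ 1 − e^(−1) ≈ 0.63.

Calls per sample: core reads < m\* → **undetermined** (discarded
unconditionally, even when module reads exist — low-coverage samples
cannot support a negative call and are excluded whole); otherwise
**positive** iff module reads ≥ 1. Undetermined samples never enter
contingency tables.

Enrichment in a disease cohort vs controls uses Fisher's exact test on
the carriage 2×2 table: one-sided ("greater in disease") for a targeted
hypothesis, two-sided for the microbiome-wide screen. The screen
includes an MSP × module only when the number of determined samples
exceeds 20 in every cohort present ("detected" = determined, i.e.
core reads ≥ m\*; the alternative reading, MSP abundance > 0, is
looser and not used). BH runs across all tested modules within each
disease contrast. Odds ratios are reported as sample ORs; the
Haldane–Anscombe +0.5 continuity correction is applied **only** to the
log2 OR and only when a cell is zero — significance always comes from
the exact test. β is fit per MSP × module, never transferred between
modules.

Carrier-vs-non-carrier abundance comparisons within a cohort use the
two-sample Wilcoxon rank-sum test (exact null distribution for small
tie-free samples, midranks otherwise).

## Synthetic-data generator

The generator emulates the **post-mapping count matrix**, not reads: no
FASTQ, no error model, no real taxonomies. It exists to give every
downstream stage a known ground truth.

- Metadata: cohorts control/IgG4-RD/SSc with default sizes 165/58/90;
  ages ~ Normal(57, 10) clipped to [18, 90]; sex ~ 30/70 male/female
  (autoimmune cohorts skew female); disease-cohort treatments drawn from
  the six categories (default mix 25/20/20/15/10/10% for
  none/RTX/prednisone/other/RTX+prednisone/prednisone+other); controls
  always untreated; SSc subgroups at 39:39:7:5 and IgG4-RD activity at
  13:45, the observed cohort compositions.
- Community: each MSP has ranked core genes (default 30) and accessory
  modules with per-cohort carriage probabilities; gene lengths
  log-uniform on [300, 3000] bp; base log10 abundances Normal(μ=0, σ=1).
- Sample s: depth D_s ~ LogNormal(ln depth_mean, σ=0.3); MSP
  log10-abundance = base + cohort effect + covariate effects +
  Normal(0, 0.25) noise, softmax-normalized to relative abundances
  (this defines the compositionality the downstream analyses assume).
  Modules are carried per sample with the cohort's probability.
- Counts: gene g of MSP m draws X ~ Poisson(D_s · a_m(s) · w_g) with
  w_g the gene's length share among the genes present in that sample's
  strain (reads land proportionally to template length, which is
  exactly what TPM inverts; absent modules contribute no genes, which
  also makes the accessory/core read ratio concentrate on the
  length ratio — the proportionality the detection model estimates).
  Poisson is the minimal model consistent with that proportionality; a
  gamma over-dispersion switch exists to stress robustness.

What passing tests on this generator do **not** show: robustness to
mapping artifacts (multi-mapping, homologous recruitment), compositional
biases of real extraction/sequencing, strain mixtures within a sample
(carriage is binary here), or real phylogenetic correlation structure.

## Benchmark design notes

- **Differential-abundance benchmark.** Spiked cohort effects are placed
  on a low-abundance stratum (base log10 ~ Normal(−1.0, 0.3) vs
  Normal(0, 1) for null features). Spiking abundant features changes the
  compositional denominator, which genuinely shifts every null feature's
  relative abundance; a model that detects those shifts is right, but a
  spiked-list "FDR" would count them as errors. Keeping spikes rare
  makes the ground-truth labels match the estimand. Sensitivity/FDR are
  evaluated at q < 0.05 over seeded replicates (500 features, 10%
  spiked at |log10 FC| 0.5–1.0, age/sex/treatment effects active on all
  features, 100 samples per cohort).
- **Carriage benchmark** mirrors the targeted comparison's design:
  107 controls at 50% carriage vs 81 patients at 75% (true OR = 3),
  deep coverage, one-sided test.
- **Null calibrations** use 200 modules × 100 samples/group for the
  screen and 40-sample structureless Bray-Curtis matrices for
  PERMANOVA (99 permutations per fit, 200 replicates).
- Problem sizes throughout (replicate counts, depths of 2–10×10^5
  expected reads, 20-MSP end-to-end communities) are chosen so the full
  benchmark runs on a laptop in minutes while keeping Monte-Carlo error
  well inside the asserted margins.

## Numerical choices and degenerate inputs

- TPM of an all-zero sample is all-zero; Shannon of an all-zero profile
  is an error; Bray-Curtis between two all-zero samples is an error
  (0/0); a single all-zero sample is at distance 1 from any non-empty
  sample.
- PCoA axes beyond the positive eigenvalues are truncated with a
  warning; negative eigenvalues (non-Euclidean Bray-Curtis) are
  reported, not clipped into the requested axes.
- Design-matrix rank is checked before fitting; aliased columns are
  named in the error. Hat matrices use rank-revealing QR.
- m\* is computed with an explicit integer search around ceil(1/β) so
  floating-point edge cases (β exactly 1/k) cannot shift the threshold.
- BH is the statsmodels step-up implementation; p-values outside [0, 1]
  are rejected, q is monotone and capped at 1.
- All randomness flows through `numpy.random.default_rng(seed)`; every
  simulation and permutation result is reproducible from its seed.

## Known limitations

- The screen's per-module detection models are fit on the same samples
  that are subsequently called; with very few carriers β is noisy and
  m\* conservative.
- Sequential PERMANOVA R² depends on covariate order by construction;
  the single-term table is provided, but marginal (Type III) tests are
  not implemented.
- The differential-abundance model is a fixed-effects OLS on log10
  relative abundance, as specified; it does not address compositional
  closure (no CLR/ALDEx-style transform) or longitudinal designs.
- Homolog discovery is out of scope: gene sets such as cgr or HypD
  homolog lists are inputs.
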