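# Methods

This note documents the models and procedures implemented in `spatialtme`,
the defaults and why they were chosen, what the synthetic-data generator
does and does not emulate, and the numerical choices that affect results.

## Data model and units

A dataset is an `AnnData`: `obs` holds the per-cell record (cell id, FOV,
sample, patient, compartment ∈ {tumor, stroma}, cohort, µm coordinates,
area, phenotype), `X` holds sparse raw integer counts, and
`layers["normalized"]` the variance-stabilized expression. Coordinates are
stored in µm throughout; instrument pixel coordinates are converted on read
with a configurable pixel size (default 0.18 µm/px, so the canonical
clustering radius of 150 px equals 27 µm). Gene symbols are matched
case-sensitively after whitespace trimming, with no alias resolution —
panel probes are fixed symbols.

## Quality control

Cells with total counts strictly below `min_counts = 20` are removed, as are
cells whose area exceeds `area_factor = 5` times the geometric mean area.
The geometric mean is computed globally (whole dataset) over cells that pass
the count filter: "abnormally large" is read as a dataset-level property,
and excluding about-to-be-dropped cells keeps a single segmentation blob
from inflating its own cutoff. FOVs retaining fewer than `min_cells = 5`
cells are treated as failed assays and dropped whole. The filters are
idempotent on realistic data; because the geometric mean is recomputed after
removal, pathological area distributions could in principle remove further
cells on a second pass — the property test uses representative lognormal
areas.

Normalization is the analytic negative-binomial Pearson residual
`(x − μ)/√(μ + μ²/θ)` with `μ = L_j p_g` (cell total × gene fraction of the
grand total), fixed `θ = 100`, residuals clipped to ±√n_cells, and all-zero
genes set to 0. This removes the technical depth variation that motivates
regularized-NB normalization while keeping a single interpretable tunable;
`θ → ∞` recovers the Poisson residual exactly. Residuals are stored as
float32 and computed in row chunks to bound memory.

## Phenotyping

Reference profiles are built by rescaling every reference cell to the
largest library size in the reference (configurable target) and averaging
gene expression per label. Assignment is supervised multinomial
naive-Bayes on raw counts: with profile fractions `π_gk`, cell *j* scores
`Σ_g x_gj log π_gk` per label (the library-size term is constant across
labels and drops out), posteriors are softmax-normalized likelihoods, ties
break to the lexicographically first label, and zero-count cells are
`unassigned` with a uniform posterior. A small pseudo-fraction (1e-10)
guards `log 0` for genes absent from a profile. This replaces a Bayesian
semi-supervised mixture whose internals (and fluorescence channels) are out
of scope; the acceptance surface — phenotype recovery — is preserved, with
> 90 % held-out accuracy on cohorts with NB dispersion θ = 5 and
~200 counts/cell.

Subset refinement (e.g. T cells) is PCA (50 components by default, reduced
with a warning for small subsets), a shared-nearest-neighbor graph
(k = 20, Jaccard edge weights, pruned below 1/15), and Louvain communities
(python-igraph `community_multilevel`, seeded RNG, resolution 1.0).
Graph k and resolution are configuration; exact cluster counts on real data
are reproducible only in distribution since the upstream tool's parameters
are unknown. Markers are one-vs-rest Wilcoxon rank-sum tests on the
normalized layer with LFC computed as
`log((mean(expm1(in)) + 1)/(mean(expm1(out)) + 1))` (pseudocount 1; the
input to `expm1` is capped at 80 to avoid float overflow on clipped
residuals); a gene is a marker when |LFC| > 0.25 and P < 0.004.

## Malignant-cell calling

Clear-cell RCC arises from the proximal tubule and is VEGFA-high. Seeding:
per-FOV mean VEGFA (normalized layer) over proximal-tubule cells is ranked
within each compartment; PT cells on tumor FOVs in the top tercile become
MALIGNANT seeds, PT cells on stroma FOVs in the bottom tercile NORMAL seeds
(the tercile rule is a deterministic proxy for a partly visual FOV
selection; terciles are configurable). A uniform marker across FOVs
triggers a weak-separation warning; fewer than 50 seeds per class is an
error.

Candidate markers come from the same Wilcoxon/LFC test between the seed
classes. The classifier is an L1-penalized logistic path
(`LogisticRegressionCV`, 10-fold stratified CV, penalty chosen at the
minimum cross-validated deviance; the grid is exposed so the one-standard-
error rule can be swapped in), followed by an unpenalized logistic refit on
the surviving genes. The positive class is NORMAL, so the fitted
probability follows the "< 0.5 ⇒ malignant, ≥ 0.5 ⇒ nontumor" convention
exactly; genes missing from an external panel are zero-imputed with a
warning. A post-hoc rule (default on) resets stromal cells phenotyped as
glomerular endothelium back to normal when the model calls them malignant,
flagging the override. External evaluation reports the rank-based
(Mann–Whitney) AUC — identical to the trapezoidal ROC area — and the
confusion at the 0.5 threshold.

## Spatial statistics

All spatial statistics are per-FOV. Weights are exact Euclidean k-nearest
neighbors (k = 3, binary weight 1, asymmetric as "3 nearest neighbors"
implies; symmetrization is a flag, default off), with distance ties broken
by ascending cell index; small FOVs use a stable full-matrix sort and large
ones a KD-tree with tie re-ordering.

Ripley's K is the plain pair-count statistic without analytic edge
correction: the DOCE difference `K(phenotype) − K(all cells)` uses the
FOV's own all-cells pattern as an empirical CSR reference, which absorbs
the FOV geometry (holes, edge effects, missing tissue) that an analytic
correction would model. DOCE of the whole population is identically 0, a
CSR-thinned subset is 0 in expectation, and rescaling units multiplies
DOCE by exactly the area factor c² (K carries units of area).

Gene-set scores are the mean over set genes of per-gene z-scores computed
across the FOV's cells (a scale-free choice that makes the mean + 1 SD
"high" threshold meaningful regardless of gene magnitude; raw-mean scoring
is a flag). The hotspot test sums pairwise Euclidean distances among the
high cells and compares against `n_perm = 1000` uniform draws of the same
number of cells, with `p = (1 + #{T_perm ≤ T_obs})/(n_perm + 1)` — small
sums mean aggregation, and the +1 correction keeps p > 0. FOVs with fewer
than `min_high = 5` high cells, or zero score variance, are reported as
missing with a reason. The p-value is invariant to rigid motions of the
coordinates.

Bivariate Moran's *I* uses the formula
`I = (n/S₀) Σ_i Σ_{j∈N(i)} (x_i−x̄)(y_j−ȳ) / √(Σ(x−x̄)²·Σ(y−ȳ)²)` with
binary kNN weights (S₀ = k·n unsymmetrized); with x = y it reduces exactly
to univariate Moran's *I*. Zero-variance genes, absent genes, and FOVs with
≤ k cells yield missing rows with reasons. Per-FOV results are emitted
per (FOV, ligand–receptor pair); when samples contribute one FOV per
compartment, per-sample and per-FOV summaries coincide, and the
sample-level aggregation for the hotspot counts uses the per-sample
minimum p.

## Differential statistics

- **Pseudobulk**: expression averaged over all cells of each FOV, then per
  gene a two-sample t-test between cohorts' FOV means — Welch by default
  (pooled by flag) since equal variances are not guaranteed. Degenerate
  genes (zero difference, zero variance) report t = 0, p = 1.
- **Mixed model**: per gene, cell-level expression ~ cohort with a random
  FOV intercept, fit by REML (statsmodels `MixedLM`). The Wald t uses
  between-FOV degrees of freedom (`n_FOV − 2`), recorded per row; this is
  exact for balanced designs and holds the type-I error near nominal under
  FOV-correlated noise (ICC 0.3), where a naive per-cell t-test is badly
  anticonservative. Singular fits reduce to OLS and are flagged.
- **Beta-binomial abundance**: positive-cell counts `y_i` of `n_i` per FOV
  follow `BetaBinomial(n_i, μ(group), ρ)` with `logit μ = β₀ + β₁·group`
  and shapes `a = μ(1−ρ)/ρ`, `b = (1−μ)(1−ρ)/ρ`. Fit by direct ML
  (Nelder–Mead over (β₀, β₁, logit ρ), multiple starts); inference is a
  Wald test from the numerical Hessian, with a likelihood-ratio test behind
  a flag. For ρ < 1e-6 the likelihood switches to its exact binomial limit
  (the beta-binomial pmf cancels catastrophically for huge shapes), and on
  that boundary the Wald SE comes from the analytic logistic information
  matrix. All-zero groups are flagged as boundary fits.
- **DOCE / Moran comparisons**: per phenotype, OLS of DOCE on the cohort
  indicator (the slope is the cohort mean difference); per pair, Welch
  t-test on per-FOV Moran's *I*. Hotspot evidence is summarized by counting
  samples with empirical p below α per cohort.
- **FDR**: Benjamini–Hochberg step-up within each result family
  (genes within a contrast, phenotypes, pairs), significance flagged at
  α = 0.1 by default.

## Synthetic-data generator

The generator emulates the study design: three cohorts (12 + 4 + 5
patients), one tumor and one stroma FOV per patient (42 FOVs), 900–6,100
cells per 0.9 × 0.7 mm FOV, a ~1,000-gene panel. Counts are negative
binomial (gamma–Poisson, dispersion θ = 5) with mean `L_j · p_g(phenotype) ·
m_gj`: library sizes are lognormal(5.5, 0.4) (median ≈ 250 counts/cell,
panel-scale magnitude), `p_g` comes from phenotype profiles (a shared
lognormal baseline with 8-fold marker boosts for each of eight
kidney-relevant phenotypes), and `m_gj` carries the planted effects. Two
percent of cells are "low-quality" (library size scaled to 2–12 %) and one
percent oversegmented (area ×8) so the QC filters act on realistic targets.

Planted structure, each independently switchable:

- **Spatial clustering**: per phenotype, CSR (uniform) or a Thomas cluster
  process (Poisson parents κ = 20/FOV, Gaussian offspring σ = 30 µm;
  offspring falling outside the FOV are redrawn). Thomas was chosen because
  it is the standard two-knob cluster model and only the existence of
  clustering, not a mechanism, is asserted.
- **Hotspots**: genes of a set multiplied by `effect` inside a disc
  (default radius 100 µm at the FOV center); the disc must lie inside the
  FOV.
- **Ligand–receptor coupling**: a latent Gaussian field with exponential
  covariance `exp(−d/ℓ)` (default range 100 µm) multiplies both genes'
  means by `exp(β·f)`; β = 0 leaves the count distribution unchanged and
  mean Moran's *I* is monotone in β. The field is drawn exactly (Cholesky)
  on a grid of spacing ≤ ℓ/3 and bilinearly interpolated to cells, which
  keeps cost linear in cells while resolving structure at the stated range.
- **Abundance shifts**: a phenotype's proportion moved by Δ on the log-odds
  scale in a cohort, other proportions rescaled.
- **Malignancy**: proximal-tubule cells on tumor FOVs carry a
  multiplicative malignant signature (VEGFA ×6, CA9 ×6, NDUFA4L2 ×5,
  EGFR ×3, MYC, YES1, COL4A1, ITGB5 up; WIF1 and the healthy PT markers
  down), emulating a VEGFA-high ccRCC profile against a healthy reference.

Everything is a pure function of (config, seed); identical seeds give
byte-identical on-disk output. What the generator does **not** emulate:
segmentation errors that misassign transcripts between neighboring cells,
negative-probe background, spatial gradients in capture efficiency,
cell-shape anisotropy, and inter-patient biological heterogeneity beyond
cohort-level effects. Passing recovery tests therefore demonstrates
statistical correctness of the pipeline under the stated generative model,
not robustness to those artifacts.

## Determinism and numerical choices

A single global seed fans out to per-stage seeds via SHA-256 of
`"{seed}:{stage}"` (31-bit), avoiding seed collisions while keeping each
stage independently reproducible; the pipeline writes a manifest (config
hash, package version, stage seeds) next to its outputs. Ties everywhere
(kNN distances, naive-Bayes posteriors, cluster relabeling) break by
ascending index or lexicographic label. Permutation p-values use the +1
correction. Missing results (too-few cells, zero variance, absent genes)
are emitted as rows with an explicit reason rather than dropped.

## Problem sizes used in the tests and acceptance script

The statistical tests run at reduced but adequately powered sizes chosen as
part of the package's test design: null calibrations use 200–500 replicate
FOVs of 120 cells with 199 permutations; power checks use 50–100 replicates
at the generator's planted effect sizes (hotspot effect 2×, coupling β = 1,
abundance Δ ≈ 0.8, β-binomial μ = 0.1 vs 0.3 with ρ = 0.05); the
acceptance script runs the full 42-FOV cohort at its default size. All
stated rates (type-I in [0.03, 0.08] at α = 0.05, power ≥ 0.8–0.9) are
asserted by the test suite, not quoted from elsewhere.

## Known limitations

- The naive-Bayes phenotyper assumes profile-proportional multinomial
  counts; heavy ambient contamination or doublets (not modeled) would
  degrade it before it would a mixture model with an explicit "other"
  class.
- DOCE values are area-scaled counts, not a calibrated clustering index;
  cross-dataset comparison requires a common radius and unit convention.
- The hotspot test conditions on the observed number of high cells;
  set-size-dependent score noise means power differs between small and
  large gene sets.
- The beta-binomial Wald test is boundary-flagged but not boundary-adjusted
  (the ρ = 0 mixture null would halve the LRT p); the LRT flag is provided
  for sensitivity analysis.
- The mixed model's between-FOV df is conservative for strongly unbalanced
  designs with weak FOV effects.
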