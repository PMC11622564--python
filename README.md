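# spatialtme

Spatial single-cell transcriptomics analysis of the tumor immune
microenvironment (TIME), built for CosMx-SMI-style data: ~1,000-gene panels,
cell-level coordinates, and tissue-microarray fields of view (FOVs) of tumor
and adjacent stroma from multiple patient cohorts (e.g. immunotherapy-naïve
vs. immunotherapy-exposed clear-cell renal-cell carcinoma).

The package covers the full analysis chain, each stage usable on its own:

* **Quality control** — remove cells with < 20 transcripts or area > 5× the
  geometric-mean cell area; drop FOVs with < 5 cells; variance-stabilize
  counts with analytic negative-binomial Pearson residuals
  `(x − μ)/√(μ + μ²/θ)`, `μ = L_j p_g`.
* **Phenotyping** — reference profiles built by rescaling every reference
  cell to the largest library size and averaging per label; supervised
  multinomial naive-Bayes assignment `argmax_k Σ_g x_gj log π_gk`; refinement
  by PCA → shared-nearest-neighbor graph → Louvain, with one-vs-rest
  Wilcoxon marker tests (|LFC| > 0.25, P < 0.004).
* **Malignant-cell calling** — proximal-tubule cells seeded malignant/normal
  by FOV-level VEGFA terciles (ccRCC is VEGFA-high), candidate markers
  between the seeds, an L1 logistic path with 10-fold cross-validation, and
  an unpenalized logistic refit whose score is P(normal): a cell scoring
  **< 0.5 is called malignant**, ≥ 0.5 nontumor.
* **Spatial statistics** — binary k-nearest-neighbor weights (k = 3);
  Ripley's K pair counts `K(r) = A/(m(m−1)) Σ_{i≠j} 1(d_ij ≤ r)` and the
  degree of clustering exact, **DOCE = K(phenotype) − K(all cells)**, at
  r = 27 µm (150 px), using the all-cells K as an empirical
  complete-spatial-randomness reference; a permutation test for spatial
  aggregation of cells scoring > mean + 1 SD on a gene set (summed pairwise
  distance vs. 1,000 random relabelings); and bivariate Moran's *I*
  `I = (n/S₀) Σ_i Σ_{j∈N(i)} (x_i−x̄)(y_j−ȳ) / √(Σ(x−x̄)² Σ(y−ȳ)²)`
  for ligand–receptor coupling (−1 inverse, +1 direct).
* **Differential statistics** — FOV-pseudobulk Welch t-tests; cell-level
  linear mixed models with a random FOV intercept; beta-binomial
  differential cell-type abundance fit by maximum likelihood; Wilcoxon
  utilities; linear-model and t-test comparisons of DOCE and Moran's *I*;
  Benjamini–Hochberg FDR (threshold 0.1).
* **Synthetic data** — a generator emulating CosMx-like cohorts (42 FOVs
  across three cohorts, 900–6,100 cells per 0.9 × 0.7 mm FOV,
  negative-binomial counts over phenotype profiles, Thomas-clustered or CSR
  positions, planted gene-set hotspots, latent-Gaussian-field
  ligand–receptor coupling, abundance shifts) with per-cell ground truth, so
  every stage has a recovery test.

## Worked example

Simulate two four-patient cohorts where only the exposed cohort carries a
planted COL4A1→ITGAV spatial coupling in the stroma, then ask whether the
pair's bivariate Moran's *I* differs between cohorts:

```python
import pandas as pd
from spatialtme import synthetic, qc, spatial, differential

cfg = synthetic.SimConfig(
    n_patients={"io_naive_nonsarc": 4, "io_naive_sarc": 0, "io_exposed": 4},
    n_cells_range=(800, 1200),
    couplings=[synthetic.CouplingSpec("COL4A1", "ITGAV", range_um=100.0, beta=1.0,
                                      compartment="stroma", cohorts=("io_exposed",))],
    seed=7,
)
adata, truth_cells, truth_fovs = synthetic.simulate_cohort(cfg)
adata, cell_report, fov_report = qc.run_qc(adata)

stroma = adata[adata.obs["compartment"] == "stroma"]
pairs = pd.DataFrame({"ligand": ["COL4A1", "TGFB1"], "receptor": ["ITGAV", "ITGB5"],
                      "source_set": "EMT"})
moran = spatial.moran_pair_scan(stroma, pairs, k=3)
groups = adata.obs.groupby("fov_id", observed=True)["cohort"].first()
table = differential.compare_moran(moran, groups, ("io_naive_nonsarc", "io_exposed"))
print(table[["unit", "mean_0", "mean_1", "p", "fdr"]].to_string(index=False))
```

Output:

```
16363 cells -> 16033 after QC (199 low-count, 131 oversized)
        unit   mean_0   mean_1        p      fdr
COL4A1-ITGAV 0.001837  0.14565 0.044885 0.089770
 TGFB1-ITGB5 0.004323 -0.00612 0.427978 0.427978
```

The planted pair's mean Moran's *I* rises from ≈ 0 in the naïve stroma to
0.15 after "exposure" and is the only pair flagged at FDR 0.1; the
uncoupled TGFB1–ITGB5 pair stays at the null.

A command-line interface mirrors the library
(`spatialtme simulate|qc|phenotype|malignancy|ripley|enrich|moran|de|abundance|compare|run-all`);
`spatialtme run-all --config run.yaml` executes every stage from one YAML
config and writes long-format TSV tables plus a reproducibility manifest.

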