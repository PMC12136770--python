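# sectormix

Sector-stratified missing-value imputation for mass-spectrometry-based
proteomics peptide matrices.

Wide peptide × sample abundance tables from bottom-up LC-MS/MS routinely
miss 20–60% of their cells, and the missingness is structured: peptide
missing rate correlates strongly and negatively with mean log2 intensity
(low-abundance peptides sit near the detection limit, MNAR), with a
residual abundance-independent component (MCAR). No single imputation
method fits both regimes, so `sectormix` stratifies before it imputes:

1. **Sectorize** — summarize each peptide by mean observed log2
   intensity and missing rate; cut intensity at its 25%/75% empirical
   quantiles and missing rate at fixed 25%/75% fractions (configurable),
   giving nine sectors (`HIHM` = **H**igh **I**ntensity **H**igh
   **M**issing rate, …).
2. **Mask and test** — hide a seeded 10% of the observed cells, impute
   with every registered method (kNN, iterative random forest, SVD-EM,
   Bayesian PCA, local least squares, multivariate-normal MLE,
   SGD matrix factorization; optional autoencoder plugins), and score
   each method per sector by the sample-wise normalized RMSE

       NRMSE = sqrt(Σᵢ (Sᵢ − Oᵢ)² / N) / sd(Oᵢ)

   over that sample's masked cells (Sᵢ imputed, Oᵢ held-back truth,
   sd with N−1).
3. **Mix the optima** — impute each sector with its lowest-NRMSE method,
   reassemble, and reuse the per-sector winners to fill the genuinely
   missing cells of the unmasked matrix.

Downstream, the package provides a moderated-t two-group differential
expression test (empirical-Bayes variance shrinkage, BH-FDR), ROC
benchmarking against spike-in labels, and reproducibility scoring
against the unmasked reference analysis — the metrics by which
imputation strategies are compared in this field. A seeded synthetic
generator reproduces the intensity-dependent missingness structure so
the whole pipeline is testable without downloading data.

It is intended for computational proteomics/metabolomics practitioners
working from FragPipe-style combined peptide reports (TSV/CSV, missing
cells empty, `NA`, or 0).

## Worked example

```python
from sectormix import SyntheticConfig, generate, peptide_summaries, \
    compute_thresholds, assign_sectors, mask_entries, \
    evaluate_sector_methods, select_optimal, assemble_mix, nrmse
from sectormix.imputers import default_registry

# proteomics-like matrix: 800 peptides x 12 samples, ~34% missing
dataset = generate(SyntheticConfig(n_peptides=800, n_samples=12, seed=0))
matrix = dataset.observed.drop_all_missing_peptides()

summaries = peptide_summaries(matrix)
grid = compute_thresholds(summaries)                  # 25%/75% quantiles
assignment = assign_sectors(summaries, grid)          # nine sectors

masked, mask = mask_entries(matrix, fraction=0.10, seed=0)
registry = {k: v for k, v in default_registry().items()
            if k in ("knn", "svd", "bpca", "lls")}
evaluation = evaluate_sector_methods(masked, assignment, mask, registry, seed=0)
plan = select_optimal(evaluation, fallback_method="knn")
mix = assemble_mix(masked, assignment, plan, registry,
                   evaluation=evaluation, fallback_method="knn")

print("chosen method per sector:", plan.choices)
print(f"mix NRMSE on masked cells: {nrmse(mask, mix.values).mean_nrmse:.3f}")
for name, spec in registry.items():
    out = spec.run(masked, seed=0)
    print(f"{name:>5s} NRMSE (whole matrix): "
          f"{nrmse(mask, out.values).mean_nrmse:.3f}")
```

prints

```
chosen method per sector: {'HIHM': 'knn', 'HILM': 'bpca', 'HIMM': 'bpca', 'LIHM': 'knn', 'LILM': 'bpca', 'LIMM': 'bpca', 'MIHM': 'knn', 'MILM': 'bpca', 'MIMM': 'bpca'}
mix NRMSE on masked cells: 0.282
  knn NRMSE (whole matrix): 0.486
  svd NRMSE (whole matrix): 0.304
 bpca NRMSE (whole matrix): 0.238
  lls NRMSE (whole matrix): 0.328
```

Reading down: Bayesian PCA wins the well-observed sectors and kNN the
sparse high-missing ones; the assembled mix (0.282) beats three of the
four single methods on the same mask. (On this draw whole-matrix BPCA
edges it out — sector winners are selected on sector sub-matrices, so
the mix is guaranteed optimal per sector, not against whole-matrix
fits; with the full seven-method registry the gap closes.) NRMSE is in
units of the per-sample truth standard deviation: 0.28 means the typical
imputation error is about a quarter of the natural spread of the masked
values in a sample.

The same pipeline runs from the shell:

```sh
sectormix simulate --out data --seed 0            # synthetic dataset
sectormix impute --input data/observed.tsv --out run --seed 0
sectormix evaluate --config run.yaml              # whole-matrix comparison
sectormix diffexp --config run.yaml               # DE + ROC + reproducibility
```

Every run writes a YAML manifest (thresholds, seeds, sector sizes,
chosen methods) sufficient to reproduce it byte-for-byte.

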