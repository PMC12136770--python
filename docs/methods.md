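# Methods

## The problem

Bottom-up LC-MS/MS peptide quantification tables are riddled with missing
values (MVs): anywhere from a fifth to two thirds of the cells of a wide
peptide × sample matrix can be empty. Missingness is not homogeneous —
low-abundance peptides sit near the instrument's detection limit and are
missed far more often than abundant ones (missing *not* at random, MNAR),
while stochastic precursor selection in DDA and processing failures add an
abundance-independent component (missing completely at random, MCAR). A
single imputation method applied uniformly therefore mixes regimes it was
not designed for.

`sectormix` implements a sector-stratified strategy:

1. **Sectorize.** Summarize each peptide by its mean observed log2
   intensity and its missing rate across samples. Cut the intensity axis
   at the 25% and 75% empirical quantiles of the per-peptide means and
   the missing-rate axis at fixed fractions (25%/75% by default,
   configurable to e.g. 35%/65% for very small sample sizes), yielding
   nine sectors coded LI/MI/HI × LM/MM/HM (e.g. `HIHM` = high intensity,
   high missing rate).
2. **Mask and test.** Hide a seeded random 10% (configurable) of the
   *observed* cells, impute with every registered method, and score each
   method in each sector by sample-wise NRMSE against the hidden truth.
3. **Mix the optima.** Impute each sector with its lowest-NRMSE method
   and reassemble the matrix; the per-sector winners are then reused to
   impute the genuinely missing cells of the unmasked matrix.

## The error metric

For each sample, over that sample's masked cells with imputed values
S_i and ground truth O_i:

    NRMSE = RMSE / σ = sqrt( Σ (S_i − O_i)² / N ) / sd(O_i)

with sd the N−1 sample standard deviation of that sample's masked truth
values. Samples with fewer than two masked cells in scope, or zero truth
variance, are undefined and excluded from the unweighted mean across
samples (logged); the reported uncertainty is the t-distribution 95%
confidence half-width of the per-sample values. NRMSE is invariant to a
common shift of truth and imputation within a sample and to a common
rescaling (σ scales with the RMSE).

Because the sums are only computable where imputed values exist, all
per-sample quantities (including σ and N) are taken over the masked
cells of that sample. Spearman's rank correlation between pooled masked
truth and imputed values complements NRMSE as a structure-preservation
check.

Selection reuses the evaluation mask itself (no second holdout), so the
reported Mix NRMSE on that mask is optimistically biased — it is, by
construction, the sector-wise minimum. The run manifest records this,
and `confirmation_mask: true` in the config scores the assembled plan on
a second, independent mask.

## Imputation methods

Seven classical methods ship in the default registry, all behind one
contract (observed cells pass through bit-identically; a method that
cannot model a given sector returns a typed not-applicable result that
selection skips):

| method | model | key defaults |
|---|---|---|
| `knn` | distance-weighted mean of the k nearest peptide rows (Euclidean over co-observed samples, rescaled by sqrt(n/n_co); weights 1/(d+1e−6)) | k=10 |
| `rf` | missForest-style iterative random forest over sample columns, increasing-missingness order, stop on rising change | 100 trees, mtry=sqrt, ≤10 sweeps |
| `svd` | EM on a rank-r truncated SVD, missing cells refilled from the reconstruction | rank=5, tol=1e−4 |
| `bpca` | variational Bayesian PCA with ARD precisions pruning components, posterior-mean refill | q=min(d−1,10) |
| `lls` | least-squares regression of each target peptide on its k most |corr| neighbours | k=20 |
| `mle` | EM for a multivariate normal over the sample dimension; conditional-mean imputation | tol=1e−4, ridge 1e−3 on Cholesky failure only |
| `cf` | biased matrix factorization μ + b_p + b_s + p·q fitted by seeded mini-batch SGD on observed cells | 8 factors, 200 epochs, lr 0.01, reg 0.02 |

Hyperparameters are not prescribed by the stratification strategy; the
defaults above are field-standard values, all exposed through
`method_params` in the run config. The sample dimension is the
multivariate axis for `mle` because n_samples ≪ n_peptides makes the
covariance estimable; the ridge is applied only when the updated
covariance fails a positive-definiteness check, since an unconditional
ridge would break EM's monotone-likelihood guarantee (which the test
suite asserts).

Two neural reference plugins (`dae`, `vae`: single-hidden-layer numpy
autoencoders trained by Adam on the masked reconstruction loss, with
input corruption or a KL-regularized stochastic latent) can be added via
`register_plugin_imputer`. They are excluded from the default registry:
with tens of samples they underfit and are routinely beaten by the
classical methods.

Ties in per-sector selection are broken deterministically by the
canonical method order `rf, bpca, lls, svd, cf, knn, mle, dae, vae`;
sectors with no applicable method fall back to the configured default
(`rf`), and if that too is inapplicable (sectors of fewer than five
peptides), to peptide-mean fill — both logged.

## Differential expression

After imputation, two-group contrasts use a moderated t statistic:
per-peptide residual variances s² on d degrees of freedom are shrunk
toward a prior s0² with d0 prior degrees of freedom,
s̃² = (d0·s0² + d·s²)/(d0 + d), t = logFC / (s̃·sqrt(1/n1+1/n2)) on
d0 + d degrees of freedom. The prior is fitted by the method of moments
on log s² (digamma/trigamma matching, Newton inversion of the trigamma);
when the variances are no more dispersed than chi-square sampling
explains, d0 → ∞ and all peptides share s0². Welch's t is available as
an `ordinary` fallback for singleton groups. P-values are two-sided and
BH-adjusted (step-up, implemented by definition); significance means
p_adj < 0.05 by default.

ROC curves against known labels rank peptides by raw p (a curve needs a
ranking; the binary p_adj < α rule defines a single operating point,
which is reported alongside). AUC equals the Mann–Whitney concordance of
the ranking, ties at half credit. Reproducibility of a method is the
fraction of the unmasked reference run's significant set recovered after
mask-and-impute, with full 2×2 overlap counts for UpSet-style reporting.

## Synthetic data

The generator emulates the structure this pipeline is sensitive to, not
raw spectra:

* per-peptide baselines μ_p ~ N(20, 2) on the log2 scale;
* a rank-3 latent-factor term (loadings and factors N(0, 0.8)) providing
  the between-peptide correlation that similarity- and structure-based
  imputers exploit — without it every method degenerates to the mean and
  ranking methods is meaningless;
* residual noise N(0, 0.3);
* missingness `p = mcar + (1−mcar)·logistic(−k(v − m − η_p))` with
  mcar = 0.05, steepness k = 0.8, midpoint m = 18 (≈1 sd below the
  typical abundance) and a per-peptide detectability offset
  η_p ~ N(0, 2.5). The logistic (rather than a hard censor) reflects
  that abundant peptides still go missing occasionally; the peptide
  offset reflects peptides that are systematically hard to ionize or
  digest, and is what populates the high-intensity/high-missing corner
  seen in real data — per-cell-independent missingness alone cannot put
  a >75%-missing peptide above the 75th intensity percentile at 24
  samples. Rows left fully missing get one seeded cell restored (logged).

Defaults (2000 peptides × 24 samples) give ≈34% missing cells — inside
the 22–63% range typical of DDA peptide reports — a Spearman correlation
of ≈ −0.45 between peptide mean intensity and missing rate, an OLS R² of
≈0.2, and all nine sectors non-empty; these signatures are asserted by
the test suite across seeds.

`spike_in_config()` emulates a two-proteome mixture benchmark: 3 vs 3
samples, 10% of peptides spiked at log2FC = log2 3 ≈ 1.585, factor sd
tightened to 0.5 (the benchmark design uses technical replicates, and
sample-level factor variability is shared biological noise that a 3v3
design cannot average away).

What the generator does **not** model: between-sample normalization
drift, batch effects, match-between-runs structure, retention-time
dependence, non-Gaussian heavy tails. Passing tests demonstrate the
machinery is correct and well-calibrated under the stated model, not
that any particular method ranking transfers to a given real dataset —
the whole point of the strategy is to re-derive the ranking per dataset.

## Numerical choices and edge cases

* Intensity thresholds use the linear-interpolation empirical quantile
  (numpy default). Boundary values fall in the *middle* band (MI/MM).
* Missing-rate thresholds are fractions of samples, not quantiles of the
  observed rate distribution.
* Masking draws uniformly without replacement from observed cells under
  the constraint that every peptide retains ≥1 observed value; any
  shortfall from round(f·n_observed) is logged as a deficit.
* Sector assignment is computed once on the pre-mask matrix and reused
  throughout; masking happens once on the whole matrix, sector scoping
  at evaluation time.
* Degenerate inputs: all-equal intensities collapse the middle intensity
  band (warned); a constant missing-rate vector returns slope 0, R² 0;
  constant vectors make Spearman undefined (NaN, logged).
* `rf` and `cf` consume the run seed; all stochastic steps flow from
  `numpy.random.default_rng(seed)`.

## Benchmark sizes

The packaged acceptance script runs the full pipeline at 1200 × 16
(main comparison) and 1000 × 6 (spike-in differential expression; the
spike run uses moderate ~25% missingness — the low end of the realistic
range — because a 3 vs 3 design on heavily imputed data sits at the
BH cliff, where the reference significant set can collapse to nothing
and reproducibility becomes uninformative), with
the test suite using 500 × 40 for imputer-quality checks and smaller
matrices for contract tests — sizes chosen as the package's own
fast-feedback benchmark scale; every operation accepts matrices of
arbitrary size.

## Known limitations

* Selection and reporting share one mask by default (bias noted above).
* The moderated test covers two-level designs only; no continuous
  covariates or multi-group contrasts.
* No between-sample normalization is applied before imputation; input
  is assumed normalized upstream.
* The autoencoder plugins are deliberately small reference
  implementations, not tuned deep-learning baselines.
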