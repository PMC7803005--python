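# Methods

## Model

Bulk expression is modelled as a non-negative linear mixture of cell
type-specific expression:

```
E = S · C,    E: genes × samples,  S: genes × cell types,  C: cell types × samples
```

Columns of `C` are per-sample compositions on the simplex (non-negative,
summing to 1); `C` is treated as known and the task is to estimate `S`.
Because the rows of `E` are independent under this model, each gene `g` is
a separate linear regression of its bulk vector `e_g ∈ R^n` on the design
`X = Cᵀ ∈ R^{n×T}`, with **no intercept**: a gene not expressed by any cell
type has zero bulk expression, so a constant term has no physical meaning
and would absorb signal.

Assumptions the estimators rely on:

- compositions vary across samples enough that `C` has full row rank
  (enforced at construction; a rank-deficient `C` makes `S` unidentifiable);
- at least as many samples as cell types per fitted gene
  (otherwise `UnderdeterminedError`);
- expression is additive across cell types on the measurement scale — the
  model is fitted on linear (not log) expression values;
- cell type-specific expression is the same in every sample up to noise;
  real regulatory variation across individuals appears to the model as
  outliers, which is exactly what the robust loss is for.

## The robust estimator

### Huber IRLS

For each gene, coefficients minimise `Σ_i ρ(r_i / σ)` with the Huber loss

```
ρ(x) = x²/2            for |x| ≤ k
ρ(x) = k·|x| − k²/2    for |x| > k
```

fitted by iteratively reweighted least squares with weights
`w_i = min(1, k·σ / |r_i|)`. Defaults (`HuberConfig`):

- `k = 1.345`: the standard tuning constant giving 95% asymptotic
  efficiency at the Gaussian while bounding the influence of any single
  sample. As `k → ∞` the fit converges to OLS (tested).
- Scale `σ` is the median absolute residual about **zero** divided by
  0.6745 (so σ estimates the standard deviation at the Gaussian),
  re-estimated every iteration. Zero-centring rather than
  median-centring matches the convention of the reference robust-regression
  implementations for regression residuals, which are already centred by
  the fit itself; `mad_scale(..., center=None)` gives the median-centred
  textbook variant for callers who want it.
- Initialisation: OLS via `numpy.linalg.lstsq`.
- Convergence: `max_i |Δβ_i| / max(1, |β_i|) < tol` with `tol = 1e-6`,
  `max_iter = 50`.
- Degenerate scale: if σ = 0 (more than half the residuals exactly zero,
  e.g. noise-free data), the current fit already interpolates the majority
  of samples; the fit is returned as converged with unit weights rather
  than dividing by zero.
- A rank-deficient design raises `RankDeficiencyError` naming the
  collinear columns (identified by pivoted QR) instead of silently
  returning one of infinitely many solutions.

### Non-negativity by exclusion

After a robust fit, any cell type with a negative coefficient is excluded
for that gene — its expression is fixed at 0 — and the model is refitted on
the remaining cell types. This repeats until all coefficients are
non-negative (or every cell type is excluded, yielding a zero row). All
negative coefficients in a round are excluded together. This differs from
NNLS: exclusion is applied to the *robust* fit, and an excluded cell type
is reported (`DeconvResult.excluded`) rather than merely landing on the
constraint boundary.

### Implementation note

Fitting 10,000 genes one at a time is slow in Python, so `rodeo()` batches
the IRLS across all genes that share an active set (the same non-excluded
cell types), solving the per-gene weighted normal equations with one
batched `numpy.linalg.solve` per iteration. Genes whose active set shrinks
are regrouped and continue with the matching batch. The batched path is
tested for exact agreement with the straightforward per-gene reference
implementation (`rodeo_fit_gene`).

### Baselines

- `ols_deconv`: per-gene no-intercept least squares; with
  `clip_negative=True` negatives are set to 0 *after* the fit (no refit,
  nothing marked excluded).
- `nnls_deconv`: per-gene non-negative least squares
  (`scipy.optimize.nnls`), the constrained-optimum baseline.

## Synthetic data generator

`simulate_dataset(SimConfig)` builds a ground-truthed pseudo-bulk dataset:

- 5 cell types (A–E) with mean proportions 0.5/0.2/0.15/0.09/0.06 —
  one dominant and two rare cell types, a typical shape for dissociated
  tissue.
- Per cell type base expression drawn log-normal (meanlog 4, sdlog 1) per
  gene, independently across cell types, so csGEPs are only weakly
  correlated and non-negative with a heavy right tail, like linear-scale
  expression data.
- Batch structure: `n_batch_genes` (default 200) genes have their means
  doubled in every cell type for the first half of the samples, a simple
  two-batch technical effect shared across cell types.
- Compositions drawn `Dirichlet(concentration × mean_proportions)` with
  concentration 50: samples vary realistically around the means without
  leaving the simplex.
- Measurement noise: multiplicative Gaussian with CV 0.15, truncated at 0,
  applied to the mixed signal — noise scales with expression level, as in
  intensity/count data.
- Outlier samples (`add_outlier_samples`): extra samples whose own
  signature has 10% of genes scaled ×3 before mixing with a fresh
  composition. These are outliers in *expression*, not merely unusual
  compositions.

All randomness descends from a single integer seed via
`numpy.random.SeedSequence.spawn`, so datasets are bit-reproducible and
independent components (signatures, compositions, noise, outliers) use
independent streams.

What the generator does **not** emulate: count-specific mean–variance
relationships (negative binomial overdispersion), gene–gene correlation
structure, dropout, cross-sample regulatory variation in `S`, or
compositional estimation error in `C` (the latter is studied separately by
`perturb_proportions`, which adds `Uniform(0, max)` noise to every entry
and renormalises columns).

## Evaluation

- `celltype_correlations` / `diagonal_correlations`: Pearson correlation
  over genes between each estimated csGEP and each true csGEP (at least 3
  shared genes required; zero-variance columns yield NaN and are flagged).
- `gene_correlations`: per-gene Pearson correlation over cell types
  (requires ≥ 3 cell types); genes whose true or estimated row is constant
  are excluded from the reported median and counted.
- `accuracy_metric`: Pearson, Euclidean distance, or RMSE
  (Euclidean / √n_genes).
- `sample_size_sweep`: simulates fresh replicate datasets at each size
  (default) or subsamples columns of one large pool, fits, and reports
  per-replicate and median scores. Sizes below the number of cell types
  are skipped with a warning.
- `noise_sweep`: perturbs the known `C` at each noise level, fits with the
  perturbed proportions, and scores against the clean truth.

Sweeps default to 10 replicates per grid point — enough to stabilise a
median at desk scale while keeping a full 10,000-gene sweep under a few
minutes; it is a pragmatic choice, not a statistical necessity.

## Limitations

- `C` must be supplied; the package does not estimate compositions or do
  unsupervised/reference-free deconvolution.
- One signature matrix is estimated for the whole cohort; per-group
  differential analysis must be done by fitting groups separately.
- No uncertainty quantification on `S` (no standard errors or tests);
  the Huber weights are diagnostics, not inference.
- The exclusion loop is greedy: excluding all negative coefficients at
  once does not guarantee the constrained-optimal active set that NNLS
  finds, by design — the point is robustness plus non-negativity, not
  exact constrained least squares.
- Robustness is per gene across samples; a sample that is an outlier in
  *composition* (wrong column of `C`) biases all genes and is not addressed
  by the Huber loss.
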