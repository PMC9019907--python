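# Methods

This note describes, in the package's own terms, the statistical procedures
implemented in `fatsig` and the synthetic data model used to exercise them.

## 1. Synthetic cohort model (`fatsig.simulate`)

Each cohort has `n_samples` patients and `n_genes` genes on a log2-like
expression scale. A latent binary risk group (HR with probability `frac_hr`,
default 0.6) drives everything the pipeline is later asked to recover:

- **Mutation.** The anchor gene is mutated with probability
  `mutation_rate_hr` (0.26) in the HR group and `mutation_rate_lr` (0.13) in
  the LR group.
- **Expression.** Gene g for sample i is
  `baseline_g + λ·u_i + effects + ε`, with `ε ~ N(0, noise_sd²)` and `u_i` a
  shared standard-normal latent factor loading on the anchor and on the
  `n_signature` planted signature genes. Signature genes additionally shift by
  `±delta_log2` (1.5) with mutation status and by `±group_delta_log2` (2.5)
  with the risk group; the anchor shifts by `anchor_mut_delta` (−0.8) with its
  own mutation. The loading λ is solved in closed form so that the
  sign-averaged Pearson correlation between a signature gene and the anchor
  equals `rho` (0.5): with A and B the non-shared variances of anchor and
  signature gene, λ² is the admissible root of
  `(1−ρ²)x² − ρ²(A+B)x − ρ²AB = 0`.
- **Survival.** Exponential proportional-hazards times: baseline hazard
  `baseline_hazard` (0.01/month), multiplied by `hr_hazard_ratio` (2.0) in the
  HR group and `rt_hazard_ratio` (0.7) under radiotherapy; independent
  exponential censoring at rate `censor_rate` plus administrative censoring at
  120 months. Recurrence-free survival uses the same structure with a 1.5×
  hazard. Clinical covariates (age group, sex, smoking, alcohol, T/N class,
  stage, HPV, radiotherapy) are drawn with fixed marginal frequencies; HPV
  positivity depends on the risk group.
- **Platform effects.** Cohorts beyond the first share all planted structure
  (same signature genes, signs, baselines) but add per-gene offsets
  `N(0, platform_shift_sd²)` and scales `exp(N(0, platform_scale_sd²))`,
  emulating a different measurement platform.

Determinism: all draws descend from `numpy.random.SeedSequence(seed)`;
cohort k uses spawn key (k+1) and the shared structure uses spawn key 0, so a
cohort's data is invariant to how many other cohorts are generated.

## 2. Signature derivation (`fatsig.signature`)

For every gene, with samples split by anchor-mutation status:

- **Fold change** `FC = 2^(m̄_mut − m̄_wt)` on the log2 scale; membership uses
  the direction-agnostic `max(FC, 1/FC) ≥ 1.5` (a flag restricts to
  up-regulated genes only).
- **Pooled-variance two-sample t-test**, two-sided p < 0.05 (Welch available
  as a flag).
- **Pearson correlation with anchor expression**, |r| > 0.2, with two-sided
  p < 0.05 from the exact t-transform `t = r√((n−2)/(1−r²))`.

All four criteria must hold simultaneously. P-values are unadjusted by
default, as is conventional for this signature-size regime; a
Benjamini–Hochberg option exists. Genes with zero within-group variance or
constant expression are flagged and excluded rather than given arbitrary
statistics. The anchor itself is never selected. Statistics are computed
vectorized in numpy and are cross-checked per-gene against scipy and against
exhaustive permutation nulls in the test suite.

## 3. Stratification (`fatsig.stratify`)

Samples are clustered on the signature-gene submatrix, after gene-wise
z-scoring (ddof = 1), with **centered correlation distance** `d = 1 − r`
(Pearson) and **complete linkage** (inter-cluster distance = maximum pairwise
leaf distance, Lance–Williams max update). The linkage is hand-implemented to
guarantee a deterministic tie-break — among equal-height merges, the pair with
the lexicographically smallest (min leaf ID, max leaf ID, sorted leaf IDs) key
merges first — and is verified against a from-definition brute-force oracle
and against `scipy.cluster.hierarchy` on tie-free inputs.

The dendrogram is cut at the root into two groups. The group with the higher
anchor-mutation rate is labeled **HR**; ties fall back to higher mean anchor
expression, then to larger size. The labeling basis is recorded.

## 4. Bayesian compound covariate predictor (`fatsig.bccp`)

Expression is standardized per cohort and per gene (subtract mean, divide by
SD, ddof = 1); standardization is idempotent and absorbs affine platform
effects. On the training cohort with clustered labels:

- **Weights** are pooled-variance t-statistics (HR − LR) per signature gene;
  the compound covariate is `c_i = Σ_j t_j·x_ij`.
- `c` is modeled as Gaussian within each class with **equal variance**
  (pooled within-class SD). The posterior
  `P(HR|c) = π_HR φ(c; μ_HR, σ) / Σ_k π_k φ(c; μ_k, σ)` reduces to a logistic
  function of c; the implementation computes it in log space and is verified
  against the closed form to 1e−10. Priors default to (0.5, 0.5);
  `"empirical"` uses training class frequencies. Classification thresholds
  the HR posterior at 0.5.
- **LOOCV**: each sample is predicted from weights and Gaussian parameters
  refit on the remaining n−1 samples; the gene set stays fixed (the selection
  step is not re-run inside the loop, so the reported error is optimistic with
  respect to selection — the standard caveat for this design).
- **Transfer**: a new cohort is standardized with its own per-gene moments and
  scored with the frozen model, restricted to shared genes.

## 5. Survival analysis (`fatsig.survival`)

- **Five-year horizon**: events after 60 months are administratively censored
  at 60 before five-year analyses.
- **Kaplan–Meier** estimates (with Greenwood standard errors) and the
  **log-rank test** use `lifelines`; both are verified against hand
  product-limit tables and a from-definition observed-minus-expected oracle.
- **Cox proportional hazards** (uni- and multivariate) uses `lifelines`'
  `CoxPHFitter` with Breslow tie handling (the only method lifelines
  implements; the API rejects anything else explicitly), complete-case rows,
  and dummy-coded categorical covariates. Reported per term: hazard ratio,
  95% Wald CI, p-value.
- **Interaction test**: for two two-level factors, a Cox model with both main
  effects and their product; the Wald p-value of the product term is reported.
  Empty design cells are an error, named in the message.
- **ROC/AUC**: `sklearn.metrics.roc_curve`; AUC equals the
  concordant-pair probability (verified exhaustively); the optimal cutpoint
  maximizes the Youden index (ties resolved toward higher sensitivity); the
  AUC confidence interval uses a hand-implemented DeLong variance.

## 6. Pipeline (`fatsig.pipeline`, `fatsig.cli`)

`discover` chains align → select → cluster → label → standardize → fit BCCP →
LOOCV → survival report and fails with a distinct `NoSignalError` (CLI exit
code 3) when fewer than two genes pass selection. `validate` standardizes a
new cohort, predicts labels and reports survival, optionally within clinical
subsets (e.g. HPV-negative patients). File wrappers write JSON/TSV artifacts
plus a manifest with SHA-256 digests of all inputs and outputs, so a rerun's
byte-identity is checkable.

## 7. Verification strategy

The suite (144 tests) is organized as: hand-computed and from-definition
oracles for every statistic; property-based invariants (affine invariance,
monotonicity, normalization, idempotence, label-swap symmetry); null
calibration (no planted effect ⇒ <1% selected genes, uniform log-rank and
interaction p-values, LOOCV at the majority-class baseline); and parameter
recovery at generator defaults (signature sensitivity ≥ 90%, false-discovery
proportion ≤ 10%, clustering ARI ≥ 0.8, cross-cohort balanced accuracy ≥ 0.9,
Cox hazard-ratio estimates covering the true value, HR subgroup with worse
Kaplan–Meier survival). The Cox precision check runs at n = 600 with
near-complete follow-up because the Wald interval at n = 300 is intrinsically
too wide for the stated hit-rate — a sample-size fact, not a property of the
implementation.
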