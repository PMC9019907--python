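# fatsig

Mutation-anchored gene-signature risk stratification for survival cohorts,
exercised end to end on a synthetic data generator.

## The problem

A recurrent design in cancer genomics: a driver gene (the *anchor*) is mutated
in a subset of tumors, and one wants an expression signature that captures the
downstream consequences of that mutation well enough to split patients into
prognostic subgroups — including on cohorts profiled on a different platform,
where the mutation calls may not even be available. This package implements
that full workflow:

1. **Signature derivation** — a gene enters the signature when it passes four
   criteria simultaneously: fold change ≥ 1.5 between anchor-mutant and
   wild-type tumors (direction-agnostic), pooled-variance two-sample t-test
   p < 0.05, |Pearson correlation| with anchor expression > 0.2, and
   correlation p < 0.05.
2. **Stratification** — hierarchical clustering of patients on the signature
   genes (centered-correlation distance, complete linkage), cut into two
   groups at the root; the group with the higher anchor-mutation rate is
   labeled high-risk (HR), the other low-risk (LR).
3. **Classifier transfer** — a Bayesian compound covariate predictor (BCCP):
   each sample is reduced to a scalar c = Σ tⱼ·xⱼ (t-statistic weights on
   z-score standardized expression), modeled as Gaussian within each class,
   and classified by the Bayes posterior. Per-cohort z-scoring absorbs
   platform shifts, so the model transfers across cohorts.
4. **Survival analysis** — five-year Kaplan–Meier curves, log-rank tests, Cox
   proportional-hazards models (uni- and multivariate), a subgroup ×
   treatment interaction test, and ROC/AUC with the Youden threshold.

Real patient data cannot ship with the package, so a **synthetic cohort
generator** plays the role of the population: it plants a latent LR/HR
structure (mutation-rate difference, signature-gene expression shifts, a
shared latent factor producing the anchor correlation, a true hazard ratio)
plus per-cohort platform shifts, and the test suite checks that every stage of
the pipeline recovers what was planted — and detects nothing when nothing was
planted.

## Worked example

The numbered scripts in `analysis/` run the whole study on simulated data
(each takes `--seed`, default 0; outputs land in `results/`):

```bash
python analysis/01_simulate_cohorts.py
python analysis/02_derive_signature.py
python analysis/03_stratify_patients.py
python analysis/04_train_validate_bccp.py
python analysis/05_survival_analysis.py
```

Actual output at seed 0 (two cohorts of 300 samples × 2000 genes, 25 planted
signature genes, true hazard ratio 2):

```
selected 25 signature genes (of 2000 tested) -> results/signature.json

labeling basis: mutation_rate
         n    pct  mutation_rate  anchor_mean
LR     112  37.33         0.1339        9.152
HR     188  62.67         0.2340        9.424

{ "loocv_misclassification": 0.0,
  "validation_balanced_accuracy": 0.9965,
  "n_signature_genes": 25 }

training five-year survival by subgroup:
          logrank_chi2  logrank_p  surv_lr_5y  surv_hr_5y
os             16.5551     0.0000      0.5955      0.3623
rfs             9.9754     0.0016      0.4455      0.2602
training multivariate Cox (n=300):
                hazard_ratio  ci_lower  ci_upper       p
risk_LR               0.4797    0.3528    0.6523  0.0000
...
validation_1 five-year survival by subgroup:
os             11.3323     0.0008      0.5906      0.3661
```

The signature recovers the planted genes, the clustering reproduces the latent
groups, the predictor transfers to the platform-shifted validation cohort
(balanced accuracy 0.997), and the HR subgroup shows the planted survival
disadvantage in both cohorts (`risk_LR` hazard ratio 0.48 ≈ 1/2, i.e. HR vs
LR ≈ 2, the generator's true value).

The same workflow is available as a CLI:

```bash
fatsig simulate --seed 0 --out data/
fatsig run-all --expr data/cohort0_expression.tsv \
               --clinical data/cohort0_clinical.tsv \
               --mut data/cohort0_mutation.tsv \
               --anchor ANCHOR --out run/
fatsig validate --model run/model.json --expr data/cohort1_expression.tsv \
                --clinical data/cohort1_clinical.tsv --out run/ --name c1
```

and as a library (`fatsig.pipeline.discover` / `validate`); see
`docs/methods.md` for the statistical details of every stage.

## Reproduction

```bash
pip install --no-build-isolation -e '.[test]'
python -m pytest -q tests/                    # full suite, ~2 min
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

`scripts/acceptance.py` reruns the pipeline on a seeded cohort pair and prints
its headline quantities (signature sensitivity/FDP, clustering agreement,
LOOCV error, cross-cohort balanced accuracy, log-rank p-values, the Cox
hazard-ratio estimate) plus the recomputed percentages of the published
patient-composition table the package models. All randomness derives from
`--seed`; runs are bit-reproducible.

## Layout

```
src/fatsig/        library (simulate, io, signature, stratify, bccp,
                   survival, pipeline, cli)
analysis/          numbered study scripts (the worked example above)
scripts/           acceptance report
tests/             pytest suite incl. oracle, null-calibration and
                   parameter-recovery acceptance tests
docs/methods.md    methods note
```
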