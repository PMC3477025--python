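# biosig

Sparse logistic regression with bootstrap stability selection for
identifying multi-modality biosignatures of MCI-to-AD conversion, with a
leave-one-out SVM/AUC evaluation protocol and a synthetic cohort generator
for end-to-end validation.

## The problem

Patients with mild cognitive impairment (MCI) convert to Alzheimer's
dementia at ~10–15% per year. Baseline measurements — MRI-derived regional
volumes and thicknesses, cognitive test scores, APOE genotype, demographics,
lab panels, CSF biomarkers — carry complementary signal about who will
convert. The statistical task is to select a *small* panel of predictors
from a few hundred correlated candidates at a few hundred subjects, where
univariate rankings ignore correlation and a single L1 fit is hypersensitive
to the choice of penalty.

## The method

For labels y ∈ {−1, +1} and features x ∈ ℝᵖ, the package fits

  min_{w,c}  (1/n) Σᵢ log(1 + exp(−yᵢ(wᵀxᵢ + c))) + λ‖w‖₁

by accelerated proximal gradient (KKT-certified to 10⁻⁸), and wraps it in
**stability selection**: draw N bootstrap resamples, fit the path over a
grid Λ of M penalties, and record for each feature j the selection
frequency Π_j^λ. The *stability score* max_{λ∈Λ} Π_j^λ ranks features; the
stable set keeps those with score ≥ τ (defaults N = 1000, M = 60, τ = 0.5).
Panels are evaluated by leave-one-out AUC: a linear SVM trained on n − 1
subjects scores the held-out subject, and one Mann–Whitney AUC is computed
from the pooled scores. A univariate t-test ranking serves as the baseline,
and DeLong's paired test compares correlated AUCs.

The clinical cohort that motivates this design is access-restricted, so the
package includes a generator for synthetic cohorts with the same statistical
shape (177/142 group split, 285 features in six modalities, correlated
MRI-like block, class-dependent APOE allele count, half-observed CSF panel)
and *known* planted support, so selection quality is measurable. See
`docs/methods.md` for the full model description and design choices.

## Worked example

```python
from biosig import (default_cohort_spec, generate_cohort, loo_scores,
                    compare_auc, two_sample_t)

# t-test directly from printed group summaries (age row of a baseline table)
t, df, p = two_sample_t(177, 74.90, 7.39, 142, 74.49, 6.94)
# -> t = 0.506, df = 317, p = 0.6133: age does not separate the groups
#    (the published table prints p = 0.6150 from the unrounded data)

table, truth = generate_cohort(default_cohort_spec(seed=0))
panel = sorted(truth.support)                 # the 15 planted features
print(loo_scores(table, panel).auc)           # 0.8704
print(loo_scores(table, ["ADAS_Q4"]).auc)     # 0.6803
print(loo_scores(table, ["lab_RCT00"]).auc)   # 0.4419
```

The planted 15-feature panel reaches a pooled leave-one-out AUC of 0.87,
a single strong cognitive subscore 0.68, and a null lab test sits at
chance — the integration gain over the best single feature is what the
method exists to deliver (DeLong p ≈ 3 × 10⁻¹⁰ for the first comparison).

The `examples/` directory has one narrative script per capability
(cohort simulation, baseline tables, regularization paths, stability
selection, LOO evaluation); each prints its numbers with a line on what
they mean. A thin CLI mirrors the library:

```bash
biosig simulate --seed 1 --out cohort.csv
biosig select cohort.csv --n-bootstrap 200 --out profile.tsv
biosig run --seed 1 --out report/
```

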