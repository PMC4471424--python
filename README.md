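# warfdose

Two-phase prediction of the weekly warfarin maintenance dose from clinical and
demographic covariates.

Warfarin has a narrow therapeutic index and a several-fold inter-patient
spread in the weekly dose needed to hold the INR in range, so a good initial
dose matters. `warfdose` implements a two-stage clinical (non-genotype)
dosing methodology:

1. **Classification.** Patients are assigned to a high-required-dose class
   (HRD, therapeutic dose > 30 mg/wk) or low-required-dose class (LRD,
   ≤ 30 mg/wk) by a from-scratch **relevance vector machine** — a sparse
   Bayesian logistic classifier with one Gaussian prior precision αᵢ per
   basis function, fitted by alternating a Laplace (IRLS) MAP step with
   MacKay evidence updates αᵢ ← γᵢ/wᵢ², γᵢ = 1 − αᵢΣᵢᵢ. Most precisions
   diverge, pruning their basis functions; the survivors are the relevance
   vectors. The 30 mg/wk cut-off is itself selected on the learning set by
   validation accuracy over a candidate grid {15, 20, 30, 35, 40, 45, 50}.
2. **Regression.** Each class routes to its own log-link linear dose model,
   `dose = exp(β₀ + Σ βᵥxᵥ)` mg/wk. The two published clinical equations are
   bundled (Model I, baseline exp(2.85332) ≈ 17.35 mg/wk, routed to LRD;
   Model II, baseline exp(3.44056) ≈ 31.20 mg/wk, routed to HRD), and both
   can be refitted per class by OLS on ln(dose). A fixed-dose comparator
   (35 mg/wk, i.e. 5 mg/day) and user-supplied coefficient files round out
   model comparisons by RMSE/MAE.

The package also ships the supporting machinery: cohort reading/validation,
k-nearest-neighbour imputation over a Gower-style mixed-type distance,
seeded learning/testing splits, confusion-matrix metrics, and a synthetic
cohort generator that reproduces the published marginal distributions of a
multiethnic warfarin cohort (truncated-normal target INR and BSA; categorical
frequencies for race, age decade, comorbidities and co-medications) with a
calibratable log-linear dose mechanism.

## Worked example

```python
import numpy as np
import warfdose as wd

# a synthetic cohort whose dose classes are separable from the covariates
learning = wd.generate_cohort(wd.synthetic.separable_cohort_spec(n=800, seed=11))
testing  = wd.generate_cohort(wd.synthetic.separable_cohort_spec(n=1000, seed=1011))

tau = wd.select_threshold(learning, seed=11)
model = wd.train_two_phase(learning, tau, refit=True)
cls, predicted = wd.predict_two_phase_cohort(model, testing)

actual = testing.data["dose_mg_wk"].to_numpy()
print("threshold:", tau)
print("two-phase RMSE:", round(wd.rmse(actual, predicted), 2))
print("fixed 35 mg/wk RMSE:", round(wd.rmse(actual, np.full(len(actual), 35.0)), 2))
```

prints

```
threshold: 30.0
two-phase RMSE: 5.26
fixed 35 mg/wk RMSE: 15.83
```

i.e. the grid search recovers the 30 mg/wk cut-off built into the generator,
and routing each patient to a class-specific dose model reduces the
prediction error by a factor of three relative to giving everyone 35 mg/wk.

The same workflow is available from the shell:

```bash
warfdose simulate --n 800 --seed 11 --out learn.csv
warfdose train --train-file learn.csv --out model/
warfdose predict --model model/ --in test.csv --out predictions.csv
warfdose evaluate --model model/ --test-file test.csv
```

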