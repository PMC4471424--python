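# Methods

## The two-phase dosing model

The package predicts a patient's therapeutic weekly warfarin dose (mg/wk)
from clinical and demographic covariates in two stages. First a binary
classifier estimates whether the patient belongs to the high-required-dose
class (HRD, dose > τ) or the low-required-dose class (LRD, dose ≤ τ), with
τ = 30 mg/wk by default. Second, the patient is routed to a class-specific
log-link linear model, dose = exp(β₀ + Σᵥ βᵥ xᵥ). The rationale is that a
single global dose equation must compromise between systematically different
dosing regimes; conditioning on the class lets each equation specialize.

The classification threshold is not assumed: `select_threshold` splits the
learning cohort 50/50 into inner training and validation halves (seeded),
labels doses at each candidate τ in {15, 20, 30, 35, 40, 45, 50} mg/wk, fits
the classifier per candidate, and keeps the candidate with the highest
validation accuracy. Candidates whose labeling is single-class on the inner
training half are skipped with a warning. Exact accuracy ties go first to
the candidate whose label split on the full learning set is most balanced,
then to the smaller τ — both tie-breaks are deterministic and documented
rather than implied.

### Routing of the bundled equations

The two bundled clinical equations are printed with identical class captions
in their source, which is an evident typo. Their baselines disambiguate:
at zero covariates Model I gives exp(2.85332) ≈ 17.35 mg/wk and Model II
exp(3.44056) ≈ 31.20 mg/wk, and at typical covariate values roughly 17–21
versus 31–36 mg/wk. The default routing is therefore LRD → Model I and
HRD → Model II; `train_two_phase(..., routing=...)` overrides it. Race
(codes 1–3) and age (decade codes 1–9) enter the equations numerically,
exactly as printed — no dummy coding is applied, and whether the original
fit used one is unknowable from the printed form.

With `refit=True`, each class's model is re-estimated by ordinary least
squares of ln(dose) on that class's learning records, using the routed
equation's term list. Terms that are constant within a class (rare
co-medication indicators are often all-zero in a class of a few hundred
records) are dropped with a warning; a genuinely collinear design raises an
error naming the offending terms.

## The relevance vector machine

The classifier is logistic: p(z = 1 | x) = σ(wᵀφ(x)), with independent
zero-mean Gaussian priors wᵢ ~ N(0, αᵢ⁻¹), one precision per basis function.
Training alternates two steps until the precisions stabilize
(max |Δ ln α| < `outer_tol`):

1. **MAP / Laplace step** (`irls_map`): damped Newton (IRLS) maximization of
   the Bernoulli log-likelihood minus ½Σαᵢwᵢ², giving the mode w* and
   posterior covariance Σ = (ΦᵀBΦ + A + jitter·I)⁻¹, where B is the
   diagonal of σ(1−σ) at the mode and A = diag(α). The line search enforces
   ascent; iteration stops when the Newton decrement falls below objective
   round-off or max |Δw| < `irls_tol`.
2. **Evidence step** (`update_alpha`): the MacKay fixed point
   αᵢ ← γᵢ/wᵢ² with γᵢ = 1 − αᵢΣᵢᵢ, which approximately maximizes the
   Laplace marginal likelihood. Basis functions with αᵢ > `prune_threshold`
   are removed; the survivors are the relevance vectors.

A per-iteration trace of the Laplace log marginal likelihood,
ln p(Z | X, w*) + ln p(w* | α) + (M/2)·ln 2π + ½·ln det Σ, is recorded. The
MacKay update is not provably monotone in this quantity, so decreases are
logged rather than raised; on the bundled test fixtures the trace is
non-decreasing within 1e-6 per step.

**Numerical pruning rule.** γᵢ is the difference of two nearly equal numbers
once αᵢ is large: resolving γᵢ ≈ 10⁻⁷ requires Σᵢᵢ to ~14 significant
digits, which double precision cannot deliver. Without intervention the
precision of a dead basis function executes a random walk in the 10⁵–10⁸
range and never stably crosses a 10⁹ threshold — no pruning ever happens.
Since γᵢ → 0 is itself the signature of an irrelevant basis function, any
γᵢ < `gamma_prune_tol` (default 1e-5), like wᵢ = 0 exactly, forces pruning.
The bias column is never pruned (its α is frozen if flagged), keeping the
model proper even if every covariate is discarded.

**Bases.** The default basis is linear over standardized covariates plus a
bias — appropriate for tabular clinical data and interpretable. A Gaussian
kernel basis (`BasisSpec(kind="rbf", rbf_width=...)`, one basis function per
training point) is available; standardization statistics are always frozen
on the training rows. Zero-variance features are excluded with a warning.
Known limitation: with many near-duplicate kernel columns and a saturated
(separable) likelihood, the evidence surface is extremely flat and the
simultaneous MacKay updates shed redundant kernels slowly; on noisy data the
usual sharp sparsity appears (3 relevance vectors of 100 on the bundled
overlapping-blobs fixture). At small n the evidence maximum can also
legitimately retain a spuriously correlated basis function.

**Prediction.** The predictive probability marginalizes the Gaussian
posterior: with μ = w*ᵀφ(x) and s² = φ(x)ᵀΣφ(x), the default "moderated"
output is σ(μ/√(1 + πs²/8)), the standard probit approximation to
∫σ(y)N(y; μ, s²)dy (accurate to < 0.02 against quadrature); a plug-in σ(μ)
is selectable. Class 1 is declared when the probability reaches the cutoff
(0.5 by default, boundary inclusive).

Defaults: `alpha_init=1.0`, `prune_threshold=1e9`, `gamma_prune_tol=1e-5`,
`outer_tol=1e-3` on max |Δ ln α|, `outer_max_iter=1000`, `irls_tol=1e-6`,
`irls_max_iter=100`, `jitter=1e-8` — conservative, standard values, all
configurable through `RVMConfig`.

## Cohort preparation

Cohorts are comma-separated text with a header row; names are matched
case-insensitively with punctuation stripped, and empty cells or `NA` mark
missing values. Variables whose missing fraction exceeds 0.5 are dropped
("more than half missing", so exactly half survives); the dose column may
never be dropped.

Imputation is k-nearest-neighbour (k = 1 by default) with a Gower-style
mixed-type distance: standardized absolute difference for continuous
coordinates (scale = the variable's SD over observed values), 0/1 mismatch
for categorical ones, averaged over the coordinates observed in both
records. The dose column is excluded from the distance so the response
cannot leak into covariate reconstruction; donors must observe the target
variable; distance ties go to the lower record index; for k > 1 continuous
cells take the donor mean and categorical cells the donor mode. Donor values
are always original observations, which makes imputation idempotent.

Learning/testing splits are seeded permutations; the first part receives
round(frac·n) records under round-half-up, so sizes are a deterministic
contract.

## Synthetic cohorts

`default_cohort_spec()` transcribes the published marginal description of a
multiethnic warfarin cohort: target INR ~ truncated-normal(2.5, 0.1²) on
[1.8, 3.5], BSA ~ truncated-normal(1.94, 0.3²) on [1.2, 3.4] (truncation
shifts the realized BSA mean up by ≈ 0.006), and printed percentage
frequencies for every categorical variable, age included as decade codes
1–9. Percentages are normalized to probabilities at load (the printed age
rows sum to 99.99%). Continuous draws use rejection sampling inside the
bounds; a truncation window carrying < 1e-12 mass is rejected as impossible.

Covariates are sampled independently because only marginals are published;
inventing a dependence structure would fabricate information. Consequently
the default cohorts cannot exhibit realistic covariate correlations
(e.g. BSA–gender), and passing tests on them demonstrates mechanical
correctness of the pipeline, not clinical transportability.

Doses come from a two-component log-linear mechanism: a latent class
(Bernoulli with the published HRD prevalence 50.18%, or optionally an
indicator on a covariate), the class's dose equation (defaults: Model I for
LRD, Model II for HRD), a shared calibration offset, and log-normal noise
(default SD 0.25 on the log scale, chosen to give dose spreads of the same
order as published model errors; configurable). `calibrate_offset` bisects
the offset until the Monte-Carlo fraction of doses above 30 mg/wk matches a
target prevalence within ±0.01, using common random numbers across offsets
so the objective is monotone and bisection is exact. The mechanism is a
testing device: true covariate–dose effect sizes in the real cohort are not
recoverable from published marginals.

`separable_cohort_spec()` builds the pipeline test fixture: the latent class
is tied to BSA (class 1 iff BSA > its population mean) and the two dose
clusters concentrate at 16.5 and 45 mg/wk (log-scale noise 0.15), leaving a
gap around 30 mg/wk. Labelings at thresholds inside the gap coincide with
the covariate-determined class, while thresholds cutting through a cluster
flip labels by noise no covariate explains — so validation accuracy is
maximized at 30 mg/wk and threshold selection is testable end to end. The
problem sizes used in tests and in the acceptance script (cohorts of
800–20 000, verification draws of 10 000–20 000) keep every check
comfortably deterministic relative to its tolerance.

## Evaluation conventions

The positive class is HRD. Accuracy, sensitivity, specificity and the two
precisions follow the standard confusion-matrix definitions, with
precision⁺ = TP/(TP+FP); some published confusion-matrix layouts place the
"FN" name in the predicted-positive/actual-negative cell, under which the
standard formula computes exactly the row-wise quantity such tables intend.
Zero-denominator ratios are reported as NaN with a warning rather than
silently as 0. Dose errors are RMSE (root applied) and MAE in mg/wk; percent
improvements are 100·(baseline − proposed)/baseline, reported rounded
half-up to whole percent with the raw value alongside.

## Known limitations

- Covariate independence in the generator (above).
- The RVM's simultaneous evidence updates can be slow to shed redundant
  kernel basis functions under separable data (above); the sequential
  marginal-likelihood algorithm would address this but is out of scope.
- Comparator dose models (published clinical equations from other groups)
  are not bundled — their coefficients are supplied by the user as
  `DoseModelSpec` text files.
- No pharmacogenetic (CYP2C9/VKORC1) covariates, pediatric models, or
  INR-feedback dose revision.
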