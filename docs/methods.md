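# Methods

`psapredict` implements an individualized treatment-response prediction
pipeline for a four-arm psoriatic-arthritis (PsA) trial design: DMARD-naïve
(DN) patients randomized 1:1 to methotrexate (MTX) or tofacitinib, and
csDMARD-failure (DF) patients randomized 1:1 to add-on etanercept (ETN) or
tofacitinib, 20 patients per arm at trial scale (n = 80). This note records
the model, the numerical choices, and the design decisions that were
genuinely open.

## Outcome: minimal disease activity at week 16

Treatment response is Minimal Disease Activity (MDA): at least 5 of 7
criteria met, with inclusive thresholds — TJC68 ≤ 1, SJC66 ≤ 1, psoriasis
BSA ≤ 3 %, pain VAS ≤ 15 mm, patient global VAS ≤ 20 mm, HAQ ≤ 0.5, and ≤ 1
tender entheseal point (Leeds Enthesitis Index). VAS thresholds assume the
0–100 mm dialect; both thresholds and dialect are overridable. The skin
criterion uses BSA (not PASI) and the enthesitis criterion uses the LEI
count directly. When the week-16 physical examination is missing (e.g. a
pandemic-era skipped visit), `compute_mda_with_fallback` merges week-16
patient-reported components (HAQ, pain VAS, patient global VAS) with the
examination components of the first subsequent visit and flags the result
as imputed.

## Penalized logistic core

All models minimize

  f(b₀, β) = (1/n) Σᵢ [log(1 + e^{ηᵢ}) − yᵢ ηᵢ] + λ [α‖β_P‖₁ + ((1−α)/2)‖β_P‖₂²]

with η = b₀ + Xβ, the intercept unpenalized, and a per-column penalty mask
(β_P) so design variables can be forced into a model. α = 0 is Ridge
(estimation), α = 0.5 is the elastic-net default used for selection — the
analysis contrasts elastic-net *selection* with Ridge *estimation*, and the
mixing weight is deliberately mid-way and configurable because neither
extreme is implied by that contrast.

Solvers: a damped Newton iteration for α = 0 and, for α > 0, IRLS with an
exact weighted least-squares step for the intercept + forced block plus
cyclic soft-thresholded coordinate descent over the penalized columns. The
block solve is not an optimization nicety: forced blocks (treatment
dummies, main effects in the interaction-selection fit) are strongly
correlated, where plain cyclic descent converges impractically slowly.
Convergence requires both a relative objective change below 10⁻¹² and an
exact first-order (KKT) residual below 10⁻¹², with a stagnation guard for
the saturated-probability regime near λ = 0 where the residual reaches its
numerical floor. Unit tests pin both solvers to independent oracles
(statsmodels ML fits at λ → 0, scikit-learn's saga solver via
C = 1/(nλ)). A numba-compiled kernel accelerates the path refits; a pure
numpy fallback implements the identical algorithm.

The λ grid holds 100 log-spaced values from λ_max (the smallest λ giving
the null model on the penalized columns, computed after fitting the forced
block) down to 10⁻⁴·λ_max for Ridge estimation; for α = 0, where λ_max is
unbounded, the grid is capped at 100× the gradient bound. The α > 0
*selection* grids stop higher, at 10⁻²·λ_max — the usual convention when
the column count is comparable to n: below that the elastic net saturates
the small fold subsets outright (quasi-separation), coordinate descent
converges only glacially there, and λ_1se never lands in that region.
Both ratios are configurable. Cross-validation is leave-one-out on the
per-patient binomial deviance; the SE of the mean deviance is taken across
the n held-out deviances. λ_1se — the largest λ within one SE of the
minimum — is used everywhere, preferring stronger regularisation at n = 80.
`loocv_path` refits every fold's path from scratch (warm-started along λ
only), and a test pins its per-λ mean deviance to a brute-force per-fold
refit loop at 10⁻¹⁰.

## Predictor handling

Sixteen baseline covariates are candidates: HAQ, TJC68, SJC66, LEI,
physician/pain/patient VAS, BSA, CRP, BMI, age, sex, disease duration, TNFi
history, nail psoriasis, dactylitis. Continuous predictors with |sample
skewness| > 1.0 (a common rule of thumb; the flag is configurable) are
screened univariably on the identity, natural-log and square-root scales;
the lowest-deviance candidate wins (equal one-parameter models, so this is
an AIC comparison). The log uses log(x+1) for variables with legitimate
zeros (counts, CRP, BSA, VAS). Continuous predictors are standardized
(mean 0, SD 1 on training rows) before penalized fitting because penalties
are scale-sensitive; binary predictors and treatment dummies stay on 0/1
for interpretability. Whether to standardize at all was an open choice;
standardization is recorded as this package's assumption. Treatment enters
as three dummies against the MTX-DN reference arm and is penalized by
default (a flag exempts it); this default affects the absolute size of
reported treatment coefficients and is therefore stated prominently.

## Selection by union

Elastic-net selection runs four times: full cohort (n = 80, with treatment
dummies), all tofacitinib patients (n = 40, with a DN/DF stratum indicator
— the two tofacitinib arms differ by background therapy; the adjustment is
this package's assumption), the MTX arm (n = 20) and the ETN arm (n = 20).
A predictor is selected when its coefficient is non-zero at λ_1se; the
relevant set is the union, with provenance per fit. Design variables are
never eligible for selection. Candidates that are structurally constant in
a subgroup (TNFi history among DMARD-naïve patients) are dropped from that
fit only. An empty union is a hard error by default, since downstream
models require at least one predictor; the pipeline can instead be told to
keep the full candidate list under Ridge shrinkage
(`on_empty_selection="all_candidates"`), the pragmatic fallback when a
cohort carries too little signal for the λ_1se rule to keep anything.

## Three treatment-effect strategies

**Homogeneous** — Ridge on selected predictors + treatment dummies;
constant log-odds treatment effect, so counterfactual deltas share one sign
within a stratum while their magnitude still varies with baseline risk
(largest near probability 0.5).

**Risk modelling** — stage 1 fits a Ridge response model on tofacitinib
patients only (selected predictors + stratum indicator, own LOOCV λ_1se).
The linear predictor LP = Σ β̂ⱼxⱼ is computed for all patients, excluding
the intercept and the stratum term (grouped with treatment, which is also
excluded). Stage 2 regresses the outcome on treatment dummies, LP and
LP×treatment (7 columns), Ridge with its own LOOCV λ_1se by default; an
unpenalized stage 2 is available behind a flag since penalization of that
small second stage was an open choice. Adding any constant to the stage-1
intercept changes no patient's LP.

**Effect modelling** — all predictor×arm interaction columns (products of
the standardized predictor and the arm dummy; none for the reference arm)
are offered to an elastic net in which main effects and treatment are
forced and only interactions are selectable (hierarchy principle); the
final Ridge model keeps the selected interactions. With an empty selection
the model is structurally identical to the homogeneous model, and a test
pins their predictions to within 10⁻⁶.

Counterfactual prediction evaluates a fitted model under the
stratum-consistent tofacitinib arm and under the stratum comparator (MTX
for DN, ETN for DF), holding covariates — and the LP — fixed; cross-stratum
counterfactuals are rejected. Exact ties (delta = 0) are reported as "tie"
and excluded from preference percentages; ties are measure-zero and the
rule is stated rather than silently resolved.

## Nested leave-one-out evaluation

An outer LOO loop leaves each patient out and reruns the entire fitting
recipe (for the risk model: stage-1 refit, LP recomputation, stage-2 refit)
on the remaining patients; each rerun tunes λ by its own inner LOOCV. AUC
over the held-out predictions is the Mann–Whitney concordance probability
with ties counting 0.5, so it is invariant under monotone transforms of the
probabilities. By default predictor selection is done once on the full data
and only λ is retuned per outer fold, matching the two-phase structure of
the analysis; `reselect_in_outer_loop=True` repeats screening and selection
per fold for a fully honest estimate, and the two modes can be compared.
The λ reported for the final model is the λ_1se of an inner-style LOOCV on
the full data; the per-outer-fold λs are reported alongside (the "resulting
nested λ" is ambiguous; this is the recorded interpretation). ROC curves
use one point per distinct threshold; their trapezoidal area equals the
tie-corrected AUC exactly.

Pooled leave-one-out predictions carry a known *pessimistic* artifact: the
fitted intercept tracks the training prevalence, which moves by ∓1/(n−1)
with the left-out outcome, so a heavily shrunk (near-null) model ranks each
held-out responder slightly *below* the non-responders and the pooled AUC
of a pure-noise model falls below 0.5 (to ≈0 in the exactly-null limit)
rather than centring on it. `nested_loocv` therefore reports two outer
estimates: `auc_outer`, the standard pooled Mann–Whitney AUC of the
held-out probabilities (the primary, conservative figure), and
`auc_outer_centered`, which ranks the held-out log-odds minus the logit of
each fold's training prevalence — removing exactly the prevalence coupling,
so an exactly-null model scores 0.5 by construction. On noise the centered
estimate calibrates to 0.5 while the pooled estimate sits at or below it;
both sit below the resubstitution AUC of the tuned model.

## Synthetic cohorts

The trial data are not public, so a generator emulates the design: per-arm
covariate draws from stratum-specific distributions (which makes arm
assignment independent of covariates within stratum by construction), a
logistic outcome model

  logit P(MDA) = b₀ + Σ βⱼxⱼ + τ(arm) + Σ γ_{j,arm} xⱼ,

and week-16 MDA components from a latent improvement model (baseline ×
arm-dependent shrinkage × lognormal noise) rejection-adjusted so that the
7-criterion MDA evaluation of the generated components reproduces the drawn
responder flag exactly — the outcome stays exactly logistic while the
components stay internally consistent.

Default distributions are plausible values for an early (DN) / established
(DF) PsA outpatient population, not facts about any particular trial: HAQ ~
3·Beta(2, 3.5); TJC68/SJC66 ~ 2 + negative binomial (the eligibility floor
of two tender and two swollen joints is enforced by truncation); LEI ~
Bin(6, 0.25); VAS ~ clipped normals; BSA and CRP lognormal (skewed, so the
transformation screen has something to find); disease duration lognormal
with a longer-duration DF stratum; TNFi history Bernoulli(0.35) in DF and
structurally 0 in DN. The five predictors relevant to response carry
non-zero effects (HAQ −0.9, LEI −0.35, TJC68 −0.07 per unit, physician
global VAS +0.02 per mm, TNFi history −0.9 on the log-odds scale), arm
effects are 0 / 0 / +0.4 / −0.4 (MTX-DN, TOFA-DN, ETN-DF, TOFA-DF), no
generative interactions, and the intercept is set from the analytic
covariate means so the overall response rate calibrates to ≈50 %.

What the generator does **not** emulate: measurement error and visit-window
jitter, correlation between baseline covariates (they are drawn
independently given stratum), informative missingness, site effects, and
any longitudinal structure beyond baseline → week 16. Passing tests
therefore demonstrate that the pipeline recovers what it assumes —
correctly computed outcomes, honest cross-validation, recoverable effects
under a correctly specified logistic model — not that the fitted models
transfer to real cohorts.

## Problem sizes used in the test suite

Simulation-based checks run at the size that makes their property visible
rather than at the largest size conceivable: parameter-recovery and
collapse checks use 500 patients per arm over 20 seeds; selection-behaviour
checks use 250 per arm; noise-floor checks for nested CV use n = 60.
Trial-scale analyses (n = 80) always use leave-one-out CV as the analysis
prescribes; large simulated cohorts use 10-fold CV for the selection steps,
where leave-one-out adds nothing but n-fold cost to a property that does
not depend on the CV flavour.

## Known limitations

- LOOCV deviance curves at n = 20 subgroups are noisy; λ_1se occasionally
  sits at the grid boundary (a warning suggests extending the grid).
- The elastic-net mixing α for selection is fixed (default 0.5), not tuned.
- No stability selection, bootstrap selection frequencies, calibration
  assessment, or AUC confidence intervals.
- Counterfactuals are within-stratum only; no cross-stratum recommendations
  and no risk–benefit weighting.
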