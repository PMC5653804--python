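# Methods

This note documents the models implemented in `rtrisk`, the assumptions
behind them, the design choices made where conventions diverge, and what
the synthetic-data generator does and does not emulate.

## Dose-volume histograms

A DVH is stored on strictly increasing bin edges starting at 0 Gy, in
either cumulative form (percent of organ volume receiving at least each
edge dose, anchored at 100% at 0 Gy) or differential form (percent of
volume per bin, summing to 100%).  The two forms convert exactly into one
another, and all metrics are defined on whichever form is natural: V_x by
linear interpolation of the cumulative curve (doses beyond the last edge
return 0), the mean dose as the volume-weighted bin-midpoint average of
the differential form.  For piecewise-linear cumulative curves the
midpoint mean equals ∫V(x)dx/100 identically.  Bin width is arbitrary;
nothing assumes the 1-cGy grid of any particular planning system.  Files
are long-format CSV (`organ,mode,dose_Gy,volume`); no DICOM-RT parsing is
attempted.

## Propensity matching

The propensity model is a maximum-likelihood logistic regression
(Newton iterations via statsmodels) of treatment arm on age (continuous,
years), AJCC stage (ordinal 1–3), supraclavicular irradiation and
chemotherapy (binary).  Single covariates that perfectly separate the
arms are detected up front and reported by name; diverging coefficients
(|β| > 30) are treated the same way.

Matching is greedy 1:1 nearest neighbour on the **logit** of the score,
without replacement, treated units processed in descending propensity
order, with a caliper of 0.2 × the standard deviation of the logit scores
pooled over both arms.  Distance ties break on the smaller control id so
results are independent of input file order.  Greedy-with-caliper was
chosen over optimal (network-flow) matching as the conventional reading
of the 1:1 caliper recipe; the caliper multiplier and treated-arm label
are configurable.  Balance is reported as standardised mean differences
(pooled-variance denominator) and two-sided tests (chi-square for binary,
rank-sum otherwise), before and after matching.

## Dominant-factor selection

Candidates are the mean lung dose plus V_x of the ipsilateral lung at
5-Gy steps (MD, IV5, …, IV50 — an 11-column default; the threshold list
is configurable).  The selector solves the L1-penalised binomial
likelihood on internally standardised predictors (intercept unpenalised)
with a proximal-Newton / coordinate-descent scheme, warm-started down a
100-point log-spaced lambda grid from the closed-form null-model maximum
to 10⁻³ of it.  Convergence is declared on the Karush–Kuhn–Tucker
conditions of the true penalised likelihood (violation < 10⁻⁸, well
inside the 10⁻⁶ contract asserted in tests).  The inner kernel is
numba-compiled for the cross-validation workload.

Penalty choice: stratified 10-fold cross-validation, per-lambda mean and
standard error of the validation loss, and the one-standard-error rule
(largest lambda within one SE of the minimising mean loss).  The
validation loss is the **binomial deviance** by default — the
statistically coherent choice for a binary endpoint — with squared error
on the predicted probability available (`loss="mse"`) for parity with
software that reports cross-validated MSE.  The dominant factor is the
active factor at the chosen lambda that entered the path first, ties
broken by larger standardised coefficient; if the 1-SE model is empty the
first factor ever to enter the path is reported.

## LKB dose-response

With the volume parameter fixed at n = 1 the LKB model needs no gEUD
reduction: the model variable is the selected dosimetric factor itself
(a percent volume, so TV50 carries percent units):

    NTCP(x) = Φ((x − TV50)/(m·TV50)),  x = selected factor (e.g. IV40).

Fitting maximises the Bernoulli log-likelihood over TV50 ∈ (0, 10·max x]
and m ∈ (0.01, 10] by bounded L-BFGS-B from six seeded starts (median-x
plus five random draws); probabilities are clamped to [10⁻¹², 1−10⁻¹²]
inside the likelihood.  Confidence intervals are profile-likelihood at
Δ2lnL = 3.84, found by bracket expansion and Brent root-finding on the
profile deviance; profile likelihood was preferred over Wald intervals
because the slope's sampling distribution is visibly asymmetric at
cohort sizes of interest.  Degenerate designs (constant factor, single
outcome class) are rejected; fits that touch a parameter bound warn
about possible separation.

Validation metrics: AUC (Mann–Whitney with half-credit ties);
Hosmer–Lemeshow on risk-quantile groups (default 10, ties kept together,
statistic Σ(O−E)²/(E(1−E/n_g)), df = groups − 2 — calibrated for
predictions estimated on the same data); scaled Brier score
1 − BS/(p̄(1−p̄)); and the calibration slope/intercept from a logistic
refit of the outcome on logit(prediction).  The Hosmer–Lemeshow report
exposes the statistic, df and p-value separately.

## Carcinoma-induction model

For a dose bin with total dose D delivered in fractions of d Gy, the
fractionation-corrected cell-kill parameter is α′ = α(1 + d/(α/β)) with
α/β = 3 Gy; d defaults to D divided by 30 fractions (the 63 Gy / 2.1 Gy
and 51 Gy / 1.7 Gy prescription patterns both give 30).  The
risk-equivalent dose of the full model,

    RED(D) = e^{−α′D}/(α′R) · [1 − 2R + R²e^{α′D}
             − (1−R)² e^{−(α′R/(1−R))D}],

interpolates between the bell-shaped full-kill limit R→0
(RED = D·e^{−α′D}) and the plateau full-repopulation limit R→1
(RED = (1−e^{−α′D})/α′).  The closed-form limits are evaluated within
10⁻⁷ of the R boundaries: the general expression differs from its limit
by O(ε·RED) at a switch point ε from the boundary, so a 10⁻⁷ window
keeps the branch discontinuity below 10⁻⁵ Gy for plateau values up to
~100 Gy while staying clear of catastrophic cancellation.  RED(0) = 0
exactly and RED has unit slope at the origin, hence OED — the
volume-weighted average of RED over the differential DVH — reduces to
the mean dose in the linear-response limit α′→0.

EAR scales OED by the organ's risk slope β (excess cases per 10,000
person-years per Gy, defined at exposure age 30 and attained age 70) and
the age modifier exp(γₑ(age_x−30) + γₐ ln(age_a/70)).  Cohort-level SCR
excludes patients older than 65 at treatment, computes OED/EAR per
patient × organ at attained age 70, and contrasts arms by rank-sum test
(Welch t-test via config).  An "accumulated EAR" — the sum of yearly
EARs over attained ages from exposure (+ optional latency, default 0) to
70 — is provided as a separate output alongside the point value at 70,
since either reading of a lifetime-accumulated risk is defensible.

Organ parameters (α, R, β, γₑ, γₐ, α/β) are **inputs** loaded from YAML
keyed by organ; the packaged template is synthetic (plausible magnitudes
only) and must be replaced with published organ-specific fits for any
real analysis.  Tests use synthetic parameter sets throughout.

## Synthetic cohort generator

The generator emulates a two-arm breast-radiotherapy cohort:

* **Covariates** from the pooled baseline marginals of the emulated
  90-patient cohort (age ≈ N(52, 11²) truncated to 25–80; AJCC
  0.59/0.17/0.24; SCF 41%; chemotherapy 57%; T and N stages drawn
  independently from their marginals).
* **Treatment assignment** by a logistic model on the covariates (VMAT
  patients younger, lower stage, less SCF irradiation and chemotherapy),
  producing the pre-matching imbalance a matched analysis exists to fix;
  a `confounding` multiplier of 0 yields a randomised cohort.
* **Ipsilateral-lung DVHs** from lognormal band masses (σ = 0.9) around
  a modality template over 5-Gy bands: a weakly varying unirradiated
  bulk, a decaying low-dose bath (scaled 0.8 for VMAT) and a high-dose
  shoulder (scaled 0.68 for VMAT), normalised to 100% and spread over
  1-Gy bins.  Band-level independence is deliberate: it produces the
  ragged differential DVHs seen in practice, nearest-neighbour V_x
  correlations ≈ 0.87, and — critically — an identifiable ground truth,
  so that a factor-selection method can in principle recover the
  generating factor.  Under a smooth two-parameter DVH family the V_x
  candidates are ≥ 0.98 correlated and no selector could do so.  The
  resulting arm-specific event rates (≈ 0.53 IMRT / 0.42 VMAT) match the
  emulated matched cohort's 18/32 and 13/32.
* **Other organs** from a smooth renormalised-sigmoid cumulative family
  with modality-dependent location (VMAT slightly higher contralateral
  lung/breast dose, lower cord dose).
* **Outcome**: the RP event is Bernoulli with probability given by the
  LKB model on IV40 (defaults TV50 = 15.07, m = 0.62; any factor name is
  accepted so selection can be stress-tested against alternative
  truths); event grades 1–3 follow a fixed 20:9:2 split echoing the
  emulated cohort's grade distribution.

What the generator does **not** emulate: joint covariate structure
(marginals are independent), T/N–AJCC consistency, anatomical coupling
between organs' DVHs, inter-fraction dose variation, and any link
between covariates (age, chemotherapy) and RP risk beyond the dosimetric
factor.  Passing recovery tests therefore demonstrate correctness of the
estimators under the stated generative model, not clinical validity on
real data.

## Pipeline, seeds and problem sizes

One global seed fans out to per-stage seeds by fixed offsets (kept below
2³¹), so any stage can be re-run in isolation reproducibly; every run
writes a `run_log.json` with the full configuration.  Partial failure is
contained: missing organ parameters skip only the SCR stage, an NTCP
failure does not block SCR.  Between-arm RP incidence uses a chi-square
test without continuity correction (exact test via config); NTCP/EAR arm
contrasts use the same rank-sum default as the SCR stage.

Test problem sizes are chosen to give each check real statistical power
at interactive runtimes: parameter recovery and interval coverage use
cohorts of 2000 (100 replicates for coverage), selection stability uses
50 replicates of 300-patient cohorts, and the matching/balance checks
use 400–4000 patients.  The pipeline demo mirrors the emulated study's
32 + 32 scale.
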