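# Methods

This note documents the statistical models, the synthetic-data
generator, the numerical choices and the known limitations of the
package. It states no empirical claim that the test suite or
`scripts/acceptance.py` does not itself compute.

## The trial design being emulated

A three-arm, 1:1:1 randomised superiority trial of daily iron syrup,
iron-containing micronutrient powders (MNPs) and placebo in children
around 8–10 months old, with a 90-day intervention and follow-up to one
year. Outcomes are measured at baseline, month 3 (the primary
time-point) and month 12: developmental composites (cognitive,
language, motor; population scale mean 100, SD 15), haemoglobin,
ferritin and C-reactive protein, anthropometric z-scores, and behaviour
/ temperament scales. Morbidity is reported weekly during the
intervention (13 reports, the last on day 90) and monthly thereafter
(9 reports to day 365). Randomisation uses permuted blocks within
union × sex strata. The design arithmetic — detectable difference 2
points, SD 15, two-sided 2.5% per primary comparison, 80% power, 20%
attrition — reconstructs 883 analysed and 1100 recruited per arm (3300
total) with critical value 1.96. The stated 2.5% two-sided level
strictly implies 2.241, which does not reproduce those printed numbers;
1.96 is therefore the reconstruction default and 2.241 is selectable
via `critical_value` in `opchar`.

## Constrained longitudinal data analysis

Model: `y_i ~ N(X_i β, Σ)` over the three visits, with mean columns
intercept (shared baseline mean), visit indicators, treatment-by-visit
interactions for the two active arms (identically zero at baseline —
the constraint), union and sex dummies, and optional continuous or
categorical covariates. The constraint encodes that randomised arms
have equal baseline means; it buys efficiency and lets baseline-only
children contribute.

Estimation is observed-data maximum likelihood: children are grouped by
missingness pattern, and per pattern the sufficient statistics
Σᵢ XᵢᵀWXᵢ, Σᵢ XᵢᵀWyᵢ, Σᵢ yᵢᵀWyᵢ are precomputed so that each
evaluation of the profile likelihood (mean parameters solved by
generalised least squares in closed form) costs O(k²p²). The covariance
is parameterised unconstrained — log-Cholesky for unstructured; log-SD
plus tanh / scaled-logistic correlation transforms for AR(1), Toeplitz
and compound symmetry (the compound-symmetry correlation is kept in
(−1/2, 1), its positive-definite range for three visits) — and
optimised by L-BFGS-B with analytic gradients obtained via the envelope
theorem. Convergence requires optimizer success or a gradient norm
below 1e-4; ftol is 1e-14, so complete-data fits agree with the
closed-form ANCOVA solution to ~1e-8 (the test suite asserts 1e-6). ML
is the default for cross-structure likelihood comparability (the
nesting invariant "unstructured log-likelihood ≥ structured" is
tested); REML is available by flag. On non-convergence the structures
are tried in the order unstructured → AR(1) → Toeplitz → compound
symmetry and the winning structure is recorded on the fit.

Inference is Wald with the normal reference, appropriate at the
design's scale (n ≈ 3300); model-based covariance (XᵀWX)⁻¹. Treatment
effects are contrasts of the interaction coefficients; for
log-transformed outcomes (ferritin) estimate and CI are exponentiated
and labelled ratio-scale. Confidence levels follow the multiplicity
engine's assigned alphas.

Subgroup analysis adds subgroup main effect (omitted when the subgroup
is itself a stratification factor, whose main effect is already
present), subgroup-by-visit, and subgroup-by-treatment-by-visit
columns. Because treatment enters the constrained model only through
treatment-by-visit terms, a separate subgroup-by-treatment block does
not exist; the homogeneity test is the Wald chi-square on the full
subgroup-by-treatment-by-visit block ((L−1)·2·2 degrees of freedom for
L levels), whose null p-value is verified approximately uniform by
simulation.

## Binary, safety and complier models

Repeated binary endpoints use a binomial model with child-level random
intercept, fitted by adaptive Gauss–Hermite quadrature (15 nodes;
per-child mode and curvature re-centre the rule). The baseline value of
the indicator enters as a covariate — the shared-baseline constraint
does not transfer cleanly to a nonlinear link. The log link (prevalence
ratios) is primary; non-convergence or fitted probabilities at 1
trigger a logit refit (odds ratios) with the reason recorded. With the
random-intercept variance pinned to zero the model reduces to an
ordinary GLM and is delegated to statsmodels.

Safety: incidence-rate ratios come from Poisson regression with
log person-time offset; "time at risk" is observed participation days
within the period (intervention days 0–90, extended 91–365, study
0–365, with person-time measured on half-open intervals so the two
sub-periods partition the study period exactly). Per-child binary
safety outcomes use log-binomial regression; at boundary failure the
fallback is a Poisson working model with HC1 sandwich variance,
labelled as such. Comparisons with zero events on both sides are
reported non-estimable, never as a crash.

CACE uses randomisation as the instrument with the placebo arm's access
to active treatment fixed at zero, so the estimator is ITT effect
divided by the active-arm complier proportion, with a delta-method CI
treating numerator and denominator as independent; complier-proportion
differences ≤ 0.05 are flagged weak-instrument.

## Multiplicity

The gatekeeping tree is implemented exactly as specified, parameterised
by the overall α (default 0.05). Rejection uses p ≤ assigned α (the
published text says strictly `<`; the ≤ convention makes "rejected at
α" and "adjusted p ≤ α" coincide for every α, which the tests verify on
a grid, and differs only on a measure-zero set). Adjusted p-values are
smallest-rejecting alphas in closed form: primaries min(1, 2p); the
head-to-head value is the minimum over the exactly-one-gate regime
(max(min(2p₁,2p₂), 2p₃), valid below max(2p₁,2p₂)) and the both-gates
regime (max(max(2p₁,2p₂), p₃)). The key-secondary family (language,
motor, LAZ change, WAZ change, haemoglobin change, log-ferritin) runs
one Hochberg step-up family per pairwise comparison at that
comparison's assigned level, only when its primary gate opened; family
composition is configurable since the source text is ambiguous.
Month-3 and month-12 procedures run independently with no alpha
sharing. Secondary and exploratory endpoints are reported as estimates
with 95% CIs and empty p-value cells, enforced in the table builder.

## Multiple imputation

Wide-format chained equations, separately by arm: each visit's
measurement is its own column; incomplete columns are visited in
chronological order for 10 sweeps (configurable). Continuous variables
use Bayesian linear regression (σ² from the scaled inverse-chi-square,
β from its conditional normal, plus residual noise); binary variables
use logistic regression with a normal approximation to the coefficient
posterior. Ferritin is imputed on the natural-log scale and
back-transformed. Predictors are union, sex, family-care score and
maternal education by default, plus the other visit columns of the same
outcome; in wide format each column is already visit-specific, so no
additional visit factor enters the imputation models. m defaults to
max(5, ceil(percent missing)). Pooling follows Rubin's rules with
Barnard–Rubin degrees of freedom when a complete-data df is supplied
and the classical large-sample formula otherwise.

## Synthetic-data generator

The generator's defaults encode the design: 1100 children per arm
(reduced in simulation studies, below), six equal union × sex strata,
permuted blocks of 6 (the block size is not published; 6 is the package
default and configurable), common baseline means across arms with
additive arm effects at follow-up visits only, exchangeable 3×3
within-child covariance with SD 15 and correlation 0.4 for the
developmental composites (the baseline–follow-up correlation is not
published; 0.4 is a mid-range value for repeated developmental scores),
log-normal ferritin and CRP so the log-transform and the CRP > 5 rule
are exercised, Poisson morbidity counts per reporting occasion with an
optional negative-binomial dispersion knob, per-child Beta(8, 2) daily
intake probabilities with a 2% point mass of children with no intake
data, 20% dropout, and rare registry events (consent withdrawal 0.3%,
never-dosed 1%, improper unblinding 0.2%, eligibility violation 0.5%,
death 0.4%). Assessment days jitter around the nominal visit days with
~1% gross outliers so the visit-window filter has work to do. A `light`
flag skips morbidity/adherence generation for large simulation studies.

MCAR dropout blanks the month-3 visit with the configured probability;
monotone dropout makes month-12 missing whenever month 3 is, plus an
independent month-12-only draw. MAR dropout is logistic in standardised
observed baseline quantities with the intercept calibrated by
root-finding so the marginal rate is exact. One deliberate design
choice: demonstrations of complete-case bias use an arm-by-baseline
interaction in the dropout model (e.g. low-baseline placebo children
drop out more). Selection that depends on baseline alone shifts both
arms' completer distributions identically under randomisation, so the
between-arm change-score contrast would remain unbiased and there would
be nothing to demonstrate; the interaction mechanism is still MAR
(all predictors observed) and produces the textbook contrast between
the biased complete-case estimator and the consistent
likelihood/imputation estimators.

What the generator does not emulate: real covariate–outcome
correlation structure (covariate effects on outcomes default to zero),
instrument floor/ceiling effects, seasonality, site/rater drift, or any
fitted resemblance to a real population's reference data. Passing tests
therefore certify the statistical machinery under the stated
distributional assumptions, not performance on real field data.

## Problem sizes and numerical conventions

Simulation studies are sized to run comfortably on one CPU: the
family-wise-error certification uses 2000 replicates of 150 children
per arm through the full generator → cLDA → gatekeeper pipeline;
parameter recovery uses 500 replicates at 500/arm; the MI-versus-
complete-case comparison uses 200 replicates at 400/arm with m = 5 and
5 chained sweeps — sized so the complete-case bias under the
demonstration mechanism (~3.3 points) is roughly 2.5 estimator standard
deviations, enough for the ordering of the two estimators to be
resolvable above Monte-Carlo noise; the full-size 1100/arm scenario is
available through the same API. Seeds: every stochastic component takes an explicit
integer seed; replicate seeds derive from a `SeedSequence` and stay
below 2³¹. Ties in Hochberg ordering break by original index. Degenerate
inputs (zero-event comparisons, single-level outcomes, all-missing
columns within an arm, windows that overlap, reports after death) raise
explicit errors or produce labelled non-estimable results rather than
silent output.

## Repository shape

The package is a library: the importable API plus `examples/` scripts
are the interface, and the pipeline driver (`report.run_pipeline`)
covers the orchestration a command-line wrapper would otherwise
provide. No console script is installed.

## Known limitations

- The binomial GLMM's covariance comes from a numerically differenced
  Hessian; extremely flat likelihoods can flag non-convergence and fall
  back to the logit link even when the log-link point estimate is
  reasonable.
- The Toeplitz parameterisation is not constrained to the exact
  positive-definite region; invalid proposals are rejected with an
  infinite objective, which L-BFGS-B handles but which can slow
  convergence near the boundary.
- Small-sample t inference (between-within df) is not implemented; at
  the design's n the normal reference is adequate, and the Rubin
  pooling path supplies t-based intervals where m is small.
- The wealth index is generated directly as quintiles; no PCA
  construction is attempted, and the LMS growth reference shipped for
  tests is synthetic — real analyses must supply an official table.
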