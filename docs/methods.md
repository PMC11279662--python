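# Methods

## Scope and model

`salbupop` analyses single-dose concentration-time data for inhaled
salbutamol (600 ug via dry-powder inhaler) with a population
(nonlinear mixed-effects) approach.  The structural model is a
two-compartment disposition with first-order absorption from a depot and
linear elimination, parameterized as (ka, Cl, V1, Q, V2).  Closed-form
tri-exponential solutions are used for prediction; one- and
three-compartment and absorption-lag variants are available through the
model registry for structure selection.  Bioavailability is not separated:
all clearances and volumes are apparent (Cl/F convention).  The internal
unit canon is micrograms, litres and hours (concentrations ug/L); the
readers convert ug/mL files on import.  The dose is encoded as a single
600 ug depot bolus at t = 0 (the three successive 200 ug inhalations have
no stated spacing and inhalation is effectively instantaneous on the
sampling scale).

Hierarchy: individual log-parameters are Gaussian around covariate-adjusted
typical values, `phi_i = log theta(c_i) + eta_i`, `eta_i ~ N(0, Omega)` —
i.e. parameters are log-normal across subjects.  Omega is structured:
per-parameter variances plus named correlation entries (default: a ka-Q
correlation).  Residual error is "combined-1": the residual *standard
deviation* is affine in the prediction, `g = a + b f`, with a single
standard-normal noise term per observation (`y = f + g eps`).  Continuous
covariates enter as power terms on the ratio to a reference value
(`theta (cov/ref)^beta`), categorical ones as multiplicative shifts
(`theta e^beta`, reference level beta = 0) — the conventional forms of the
major popPK estimation tools.

## Reference generating model

The default simulator uses published population estimates for this drug and
formulation: ka = 3.71 /h, Cl = 24.33 L/h, Q = 10.59 L/h, V2 = 0.0066 L,
IIV standard deviations 0.062 / 0.082 / 0.045 / 0.032 (log scale), ka-Q
correlation 0.89, combined error a = 0.05 ug/L, b = 0.10.  The reported
central volume (2e-11 L) and its IIV (10.09) are numerically degenerate —
both carry undefined standard errors in the source — so the generating
model substitutes V1 = 1 L and omega(V1) = 0.1, and all recovery analyses
exclude V1.

Two consequences of these values shape everything downstream:

* **Flip-flop kinetics.**  The terminal slope equals ka (3.71 /h), which is
  slower than the elimination micro-rate Cl/V1 (24.3 /h) — standard for
  inhaled depots, where absorption is rate-limiting.  A bi-exponential
  profile is symmetric under swapping the two rates (with a compensating
  volume), so the data cannot resolve the assignment.  The initializer
  builds both assignments, refines each against the median profile, and
  keeps the better fit; on a tie it prefers the absorption-limited
  assignment.  A forced policy is available
  (`nca_informed_initials(..., flip_flop=...)`).
* **A nearly invisible peripheral compartment.**  With V1 = 1 L and
  V2 = 0.0066 L the peripheral return rate is Q/V2 ~ 1600 /h: the
  peripheral compartment equilibrates instantly and holds ~0.7% of the
  central amount.  Numerically, the observable profile is a bi-exponential
  `~108 (e^{-3.71 t} - e^{-24.2 t})` ug/L; the marginal -2LL changes by
  less than 0.1 units across two decades of Q and is exactly flat in the
  ka-Q correlation.  Q, V2, their IIVs and the correlation therefore sit on
  a likelihood ridge: estimates of those quantities reflect initialization
  plus stochastic drift, their reported RSEs are honest (hundreds of
  percent or undefined), and a one-compartment model fits the simulated
  data equivalently — the corrected-BIC structure selection prefers it,
  since the two extra parameters buy ~1 unit of -2LL against a ~17-unit
  penalty.  ka, Cl, V1 and omega(Cl), by contrast, are well identified and
  are recovered tightly.

## Synthetic cohorts

`default_virtual_cohort()` is a deterministic 32-subject table matching the
study margins: 18 male / 14 female; 12 American Indian / Alaskan Native and
20 East Asian (10 Japanese, 10 Chinese); ages from the design set
{5, 10, 20, 30, 65} years with median 20.0; BMI spanning the normal,
overweight and obese adult bands (median ~21).  Heights and weights are
deterministic module constants by age, gender and race — the source
publishes only the margins, not per-subject anthropometrics.
`sample_cohort()` draws randomized cohorts from configurable composition
rules; subject i uses a stream keyed by (seed, i), so growing a cohort
never reshuffles earlier subjects.

The generator emulates the *design* of the study — cohort composition,
sampling grid (0, 0.08, 0.17, 0.33, 0.5, 0.75, 1, 1.5, 2, 4, 6, 8, 10,
12 h), dose, hierarchical parameter variation and combined residual error.
It does not emulate assay quantification limits (negative draws are
truncated at zero and flagged instead of censored), absorption-phase
irregularities of real inhalation (breath-to-breath variation, swallowed
fraction kinetics), or dropout/missingness patterns; passing tests
demonstrate internal consistency of estimator and simulator under the
stated design, not robustness to those real-data features.  Because
censoring likelihoods are out of scope, the additive error component `a` is
re-estimated low on designs where many samples sit at the truncated noise
floor (about 30% low on the default grid); on designs whose observations
stay above the floor, a and b are recovered within sampling error.

No covariate coefficients are published for this drug, so the covariate-bearing
demonstration model (`demo_popmodel()`) uses module constants chosen to
reproduce the qualitative stratification orderings (children absorb and
clear faster with higher peak concentrations; heavier subjects lower Cl, Q
and V2; females lower ka and Cl; East Asians lower Cl).  These are
documented defaults, not estimates.

## Estimation

SAEM follows the standard two-phase schedule: 500 exploratory iterations
with constant step (gamma = 1) and simulated-annealing caps that keep
variances from collapsing faster than 5% per iteration, then 200 smoothing
iterations with gamma_k = (k - 500)^-0.7 (both configurable).  The E-step
is one sweep of three Metropolis-within-Gibbs kernels per subject —
independent prior proposal, adaptive joint random walk, adaptive
componentwise random walk — with per-subject random streams keyed by
(seed, subject id), which makes fits invariant to the order of subjects in
the file.  M-steps: generalized least squares for the fixed effects and
covariate coefficients, structured projection (variances + named
correlations, SD floor 1e-6 with a boundary flag, correlations clipped to
|rho| <= 0.95) for Omega, and a damped two-parameter likelihood
maximization over (a, b) on smoothed per-observation statistics for the
residual model.  If every IIV SD collapses below 0.02 the latent draws can
no longer move the means (the model has degenerated to nonlinear
regression), and the fixed effects are finished by direct likelihood
maximization.

Starting values are NCA-informed: Cl from dose/AUC (structure-free under
linear kinetics), the two observable rates from the terminal slope of the
median profile (restricted to concentrations above 2% of the peak, away
from the noise floor) and the peak-time relation, V1 from Cl and the fast
rate, Q = Cl/2, V2 from a coarse log-spaced grid, all polished by a cheap
weighted least-squares fit of the median profile under both flip-flop
assignments.

Empirical Bayes modes are found per subject by multi-start Nelder-Mead +
Powell (from the chain state and from the prior mean — the conditional
density is bimodal under flip-flop).  The marginal likelihood is estimated
by importance sampling with a multivariate-t (df = 5) proposal centered at
each subject's mode with curvature-based scale (default 5000 draws;
subjects with effective sample size < 50 are flagged); with no IIV the
computation collapses to the closed-form residual likelihood.  Standard
errors come from a numerical Hessian of the FOCE-style linearized marginal
likelihood in unconstrained coordinates (log theta, beta, log omega,
atanh rho, log a, log b), delta-methoded back to the reporting scale;
non-invertible blocks yield per-parameter NaN flags rather than a failed
table.  A score-based alternative (`method="score"`) approximates the
information by the empirical covariance of per-subject score vectors.

Information criteria: AIC = -2LL + 2p, BIC penalizes all parameters by
log(N subjects), and the corrected BIC (BICc) penalizes subject-level
parameters (fixed effects, betas, Omega entries) by log(N) and
residual-error parameters by log(n observations).

## Covariate selection

Screening draws L = 10 conditional-distribution samples per subject
(reducing the shrinkage bias of mode-based screening) and tests each
(random effect, covariate) pair — Pearson correlation for continuous
covariates (age, height, weight; BMI is excluded as a deterministic
function of the other two, with a config switch), one-way ANOVA for
categorical (gender; race collapsed to two levels with American Indian /
Alaskan Native as reference) — taking the median p over samples and
sorting ascending.  Forward steps add the smallest-p untried candidate
below alpha_add = 0.05 and keep it only if the refit strictly lowers BICc;
backward steps drop the retained effect with the largest Wald p above
alpha_remove = 0.05; the loop runs to a fixed point with bounded revisits.
Wald, Shapiro-Wilk (random-effect normality) and a signed-rank symmetry
test on IWRES provide the confirmatory report.

## Diagnostics

IWRES uses conditional-mode predictions and the fitted error model.  PWRES
and NPDE are simulation-based (default 500 replicates): each subject's
observation vector is decorrelated by the symmetric inverse square root of
its simulated covariance (symmetric, not Cholesky, so the result does not
depend on observation ordering); NPDE ranks the decorrelated observation
among the decorrelated replicates with mid-ranks on ties, clamps to
(1/(2K), 1 - 1/(2K)) and applies the normal quantile.  The outlier
proportion counts observations outside `IPRED ± z g(IPRED)` at the 90%
level; because conditional modes track the data, this empirical fraction
sits at or somewhat below the nominal 10% on well-specified data (~5% on
the reference fixture — the same order as the source's reported 4.6%).
The VPC bins by nominal time (the design is a fixed grid; bins under 3
observations merge leftward with a log entry) and compares observed
10th/50th/90th percentiles with percentile-of-percentile prediction
intervals at the 90% level.  Stratified summaries report geometric mean and
(n-1) geometric SD of individual parameters for the default strata (age
5-22 vs 23-65 years, weight <= 75 vs > 75 kg, gender, race), flagging
empty and singleton strata.

## Problem sizes used in the shipped analyses

The recovery experiment uses the full study design (32 subjects x 14
samples) with the full SAEM schedule.  Structure selection runs the same
data at 300 + 150 iterations per candidate model.  Replicated statistical
suites run at reduced counts chosen to keep the whole suite quick while
still resolving the property under test: 24 replicates for the SE
calibration, 5 seeded replicates each for planted-effect recovery and null
false-inclusion in stepwise selection, 300-400 replicates for the
screening-calibration and rank-based checks that need no refitting.

## Known limitations

* No censoring/BQL likelihood: values below the noise floor are truncated
  zeros, which biases the additive error term low on designs dominated by
  the floor.
* Omega supports named correlation pairs, not full unstructured blocks;
  inter-occasion variability and multiple-dose designs are not modeled.
* Under the reference generating values Q, V2 and the ka-Q correlation are
  structurally non-identifiable (see above); the package reports them with
  honest uncertainty rather than stabilizing them artificially.
* The importance-sampling -2LL carries Monte-Carlo noise (~0.1-0.5 units at
  the default draw count); BICc comparisons across models separated by less
  than ~1 unit are not meaningful.
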