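# Methods

This note documents the models implemented in `thyropop`, the assumptions
behind them, the choices made where the design was genuinely open, and what
the synthetic-data experiments do and do not demonstrate.

## Structural PK model

T4 kinetics are described by a linear two-state system: an absorption
compartment `A_B` receiving once-daily oral boluses of
`F * 1.29 * dose` (the factor 1.29 converts mcg/day of levothyroxine to
nmol/day via the molecular weight 776.9 g/mol; the printed two-decimal
constant is used rather than the exact 1.2872 so that reported amounts
match the published arithmetic — the difference is under 0.3%), and a
central compartment `A_C` with first-order elimination `kel` and a
zero-order endogenous production `kendo` representing residual gland
function.  The initial condition `A_C(0) = kendo/kel` places the untreated
patient at the endogenous equilibrium; this neglects residual maternal
hormone shortly after birth but guarantees the physiologically required
return to equilibrium when dosing stops.

The observed quantity is the free fraction, `C_FT4 = 0.3 * A_C / V(W)`
(0.3 = 0.03% free fraction x 1000 pmol/nmol), with the allometric volume
`V = fV * (W/WRef)^betaW`.  Body weight enters only the observation — the
elimination acts on amounts — so growth dilutes FT4 without altering
kinetic rates.  `WRef` defaults to the median observed weight of the
dataset being fitted and is overridable for cross-dataset comparability.

Because the system is linear and `ka`, `kel`, `F` are fixed (`ka = 20 /day`,
giving a central-compartment peak at `ln(ka/kel)/(ka-kel) ~ 0.27 day`
after a bolus; `kel = 0.1 /day` from the ~7-day plasma half-life of T4;
`F = 0.6` mid-range of reported oral bioavailability), the solution is an
exact exponential superposition over dose events.  The dose-driven part of
each subject's profile is therefore precomputed once per fit, making a
single prediction a handful of vector operations.  A regimen row holds
until the next row (last observation carried forward) and is expanded to
one bolus per day starting at the row's time exactly.  The degenerate case
`ka = kel` uses the analytic limit `amt * ka * tau * exp(-ka * tau)`
rather than erroring, since samplers may propose near-equal rates.  An
independent Runge–Kutta integrator (`pk_numeric`), sharing no
superposition code, verifies the solver to ~1e-13 relative error; the test
suite pins agreement at 1e-6 on randomized regimens.

Time-varying production (used by the TSH feedback) is handled by a
piecewise-constant daily production series whose convolution with the
elimination kernel is again available in closed form.

## Reference-range normalization

Each FT4 measurement carries the reference range of the assay that
produced it.  Measurements are mapped onto a postnatal-age bracketed
target range (brackets 0–1 months = [0, 30] d, 1–12 months = (30, 365] d,
1–5 years = (365, 1826] d; the month/year labels do not prescribe day
counts, and the closed-above convention avoids double assignment).  The
age used is the postnatal age at the measurement, `pna_start + t`.

Three formulas are provided: scale (valid for right-skewed data, never
negative), location-scale (valid for normal data, can go negative when a
measurement falls below its assay lower limit — preserved and flagged by
default, floored at 0 only when `clamp_negative` is set), and the blended
formula that moves linearly from scale to location-scale over treatment
time up to the threshold `ts`.  `ts` defaults to 150 days — the time by
which the treated FT4 distribution has transitioned to approximate
normality — but remains a setting because it is a data-driven choice, not
a constant of nature.  Rows lacking a complete assay range are skipped
with a warning rather than imputed, mirroring how incomplete TSH ranges
are handled in practice (TSH is never normalized here).  The skewness
diagnostic (adjusted Fisher–Pearson skewness plus Shapiro–Wilk per time
window) is what justifies `ts` on a given dataset; Shapiro–Wilk was chosen
as the normality test because the sample sizes per window (tens of values)
are in its sweet spot.

## Population model and estimation

`kendo`, `fV` and `betaW` carry log-normal inter-individual variability
(`theta_i = theta_pop * exp(eta_i)`, diagonal covariance — correlations
are not identifiable at this data density); `ka` and `kel` have no IIV.
The log-normal choice makes `betaW > 0` structural.  The residual model is
proportional, `y = f * (1 + sigma * eps)`.

Estimation is stochastic-approximation EM: per iteration, a
Metropolis–Hastings kernel (an independent proposal from the current
population prior plus componentwise random walks with acceptance-rate
adaptation during burn-in) refreshes the individual log-parameters, and
the sufficient statistics of the complete-data model — which is
exponential-family in `(mu, Omega, sigma)` — are updated with step size 1
during burn-in (default 400 iterations) and `1/k` during smoothing
(default 200).  Omega is kept from collapsing during early burn-in by a
0.9-per-iteration floor relative to its previous value.

Feedback/covariate coefficients without IIV have no closed-form update;
they are refreshed by a damped numerical argmax of the complete-data
likelihood.  These updates start only after the first third of burn-in and
are damped (factor 0.3) before smoothing: an undamped per-iteration argmax
chases Monte-Carlo noise and can drag the population parameters into a
biased quasi-mode, which shows up as a *negative* likelihood-ratio
statistic for nested models.  For the same reason the covariate-testing
workflow warm-starts the full model from the reduced fit's estimates.

The marginal -2 log-likelihood is computed by importance sampling around
each subject's conditional mode (multivariate-t proposal, df 4, covariance
from a finite-difference Hessian; 5000 draws per subject by default,
seeded and reproducible).  A deterministic Laplace approximation is
available as a fallback and is used for the finite-difference Fisher
standard errors (a nonparametric bootstrap over subjects would be the
robust alternative; RSEs here are linearization-style).  With all omegas
at zero the integral degenerates and the closed-form Gaussian sum is
returned.  On small instances the importance-sampling value agrees with a
brute-force Monte-Carlo marginalization over the prior to well under 0.1
on the -2LL scale (asserted in the test suite at 1e5 oracle draws).

Empirical Bayes estimates are conditional modes; shrinkage is
`(1 - sd(eta_hat)/omega) * 100` with the population (ddof 0) standard
deviation, capped into [0, 100] for reporting and undefined (NaN) when
omega is 0.  Model comparison uses `delta OFV = -2LL_reduced - -2LL_full`
against a chi-square whose degrees of freedom default to the number of
extra coefficients; a negative delta beyond numerical tolerance is flagged
as an approximation/convergence artifact and never declared significant.
The retention level alpha defaults to 0.05.

## TSH feedback and covariates

TSH may modulate the endogenous production as a time-varying covariate
(never a state variable — the final model of record contains no feedback,
and modeling the full hypothalamic–pituitary–thyroid loop is out of
scope).  Four couplings are implemented: two categorical groupings (cut
point 3 mU/l; cut points 1 and 10 mU/l, both right-continuous at the cut),
a multiplicative coupling `kendo * f(TSH)` and an additive coupling
`kendo + beta3 * f(TSH)`, with `f` the identity, a power of `TSH/TSH_Ref`,
`log(TSH)` or a power of `log(TSH)/log(TSH_Ref)`.  Every form reduces to
plain `kendo` at zero coefficients, so the models are properly nested for
likelihood-ratio testing.  `TSH_Ref` has no canonical value and must be
supplied.  The logarithm is natural by default and configurable; TSH is
clamped at the 0.005 mU/l quantification floor before any log.  A negative
modulated production is floored at 0 with a warning.  Continuous
covariates on other parameters use the power model
`theta_pop * (Cov/Cov_Ref)^beta`; categorical covariates act as
`exp(beta)` on the log-normal parameter with the reference category at 0.

Daily body-weight and TSH series are imputed from sparse visit values by
monotone shape-preserving piecewise-cubic (PCHIP) interpolation with
constant extrapolation: it passes through every support, never overshoots
(so growth curves stay monotone and positive), and degrades gracefully to
a constant with a warning when only one support exists.  Linear
interpolation would also be defensible; PCHIP was preferred for the
no-overshoot guarantee.

## Synthetic cohort generator

The generator emulates the statistical structure of a retrospective
multi-center CH cohort: 61 subjects, 4–14 FT4 visits each (mean ~8) over a
600–770-day horizon with front-loaded visit density; birth weights around
a 3.3 kg median growing along saturating-exponential curves to ~11.3 kg by
day 600; postnatal age at treatment start around 7 days with a long right
tail; starting LT4 doses around 9 mcg/kg/day rounded to 12.5-mcg tablet
steps and titrated at visits against the age-dependent target range
(double steps for gross deviations, step-up already when FT4 falls into
the lowest 30% of the range — clinicians aim mid-to-upper range);
diagnostic TSH around a median of 267 mU/l, severity-correlated,
normalizing exponentially into the treated range with a 0.005 mU/l floor;
and a pool of 34 assay reference ranges across 4 centers and several
assay eras, jittered around the target range with a slight upward bias of
the upper limits and a fraction of inflated first-month "anomaly" ranges.
Missingness switches (5 missing baseline FT4 values, occasional missing
weights and reference ranges) default on so the skip/flag code paths are
exercised.

Disease severity is encoded entirely through `kendo`: individual values
are drawn log-normally at the declared truth (defaults: the published
final-model estimates), and the severity label *emerges* from classifying
the simulated baseline FT4 (severe < 5, moderate 5–10, mild >= 10 pmol/l;
missing baseline -> unknown).  A `severity_mix` option instead draws
class-stratified truncated values to reproduce a prescribed label mix;
this distorts the marginal distribution and is therefore not the default.

Three deliberate departures from naive iid sampling serve the generator's
role as ground truth for recovery experiments:

1. *CH inclusion rule* — parameter vectors whose untreated equilibrium FT4
   at a typical one-year size (10 kg) would exceed the 1–12-month target
   upper limit are resampled.  Congenital hypothyroidism means reduced
   production; an unbounded log-normal tail would create "patients" with
   above-healthy endogenous FT4 that no dose reduction can correct.
2. *Moment standardization* — the cohort's eta sample is standardized to
   mean 0 and standard deviation exactly omega per effect, and the
   measurement-noise deviates (clipped at ±2.5 sd) are standardized to
   mean 0 / sd 1.  The realized cohort then carries the declared truth
   exactly, so recovery error reflects the estimator, not the draw.
3. *Titration realism* — see the dosing policy above.

All randomness flows from one seed through named substreams (subjects /
pk / visits / assays / tsh / noise); identical config and seed give
bit-identical output.

**What passing tests show — and what they do not.**  Recovery of the
published values from these cohorts shows that the estimation machinery is
unbiased and precise *under the model's own assumptions at this design
density*.  It does not validate the structural model against real
patients: the generator has no assay-specific bias structure beyond
multiplicative range jitter, no model misspecification (the fitted model
is the generating model), no dropout or informative visit timing, and the
eta standardization removes the cohort-level sampling noise a real study
would carry.  Conversely, the visual-predictive-check calibration
experiment must be read with the adaptive-design caveat: because doses are
titrated to each subject's own realized FT4, re-simulating with fresh
random effects at the *observed* doses widens the predictive bands beyond
what the observed percentiles show.  The VPC self-consistency test
therefore uses non-adaptive dosing (`titrate=False`); on titrated cohorts
the VPC remains a diagnostic to be interpreted, not a calibration
guarantee.

## Numerical conventions

Quantile/percentile computations use linear interpolation (numpy default,
"type 7").  VPC bins are equal-count in time (default 8) because visit
density is front-loaded; empty bins are dropped with a warning.  CSV I/O
round-trips decimal text up to 10 significant digits bit-identically;
missing cells are empty fields, never 0 or textual NaN.  Problem sizes in
the test suite are the package's own choices: the recovery experiment uses
one n = 61 cohort; the likelihood-validation instance uses 3 subjects; the
feedback operating-characteristics study uses 20 + 20 replicates at
n = 30 with an injected additive-identity feedback of 0.02 nmol/day per
mU/l.

## Known limitations

* No T3, no protein-binding kinetics, no mechanistic HPT-axis feedback,
  no clearance-parameterized allometry — deliberate scope choices for
  clinical applicability.
* Units are fixed (pmol/l, mU/l, kg, mcg/day); no automatic conversion.
* Diagonal random-effect covariance; correlations are not estimated.
* The importance-sampling -2LL is stochastic (seeded); the Laplace value
  is deterministic but biased by ~0.1–1% of the -2LL scale on sparse
  subjects.
* Standard errors by finite-difference Fisher information assume a
  locally quadratic likelihood; use the bootstrap for small cohorts.
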