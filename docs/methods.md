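# Methods

## Structural models

**Absorption.** Oral enalapril must be absorbed and hydrolysed to
enalaprilat before it appears in serum, producing a pronounced delay
that a first-order model cannot capture.  The default absorption input
is a continuous transit chain: the dose enters the absorption
compartment as a gamma-density flow

    rate(t) = dose · k_tr · (k_tr t)^n · e^(−k_tr t) / Γ(n + 1),
    n = k_tr · Mtt − 1,

parameterised by the transit rate constant `k_tr` (1/h) and the mean
transit time `Mtt` (h).  This mirrors the (k_tr, Mtt, k_a) triple of
the published adult model without committing to an integer compartment
count; an explicit integer chain (`transit_chain_profile`) is provided
for cross-validation, and both the `n = k_tr·Mtt − 1` and
`n = k_tr·Mtt` stage conventions are selectable because tools differ by
one stage in this mapping.  `k_tr·Mtt ≤ 1` is rejected as a
parameterisation error (the implied stage count would be non-positive);
samplers treat that region as zero likelihood, and the study
generators redraw the far tail of the random-effect distribution that
would land there (≈0.1% of draws at the published variability).

**Disposition and effect link.** One- or two-compartment linear
kinetics with apparent parameters (oral bioavailability F is not
identifiable, so CL/F, V1/F, Q/F, V2/F absorb it), plus an optional
effect compartment dCe/dt = k_e0(C − Ce).  The full system is linear,
so it is solved semi-analytically: the compartment matrix is
eigendecomposed once per parameter set, making the impulse response an
explicit sum of exponentials, and the transit input is convolved with
it by 40-node Gauss–Legendre quadrature restricted to the support of
the gamma flow (truncated at the 1−1e−13 quantile).  Agreement with a
DOP853 reference solution at rtol 1e−11 is ~1e−11 relative — far
inside the 0.1% the test suite demands — and a batched 40-subject
evaluation costs ~5 ms, which the stochastic estimation loop relies
on.  Repeated doses superpose linearly.  A lag-time variant and a
plain first-order variant are selectable so the absorption-model
comparison can be exercised, not just its winner.

**Pharmacodynamics.** The ANG II/ANG I ratio follows an inhibitory
sigmoid Imax model, ratio = E0·(1 − Imax·Ce^γ/(Ce^γ + IC50^γ)).  Full
inhibition (Imax = 1) is the default; a partial-inhibition variant is
selectable.  The paediatric model is the direct, Hill-free special
case (γ = 1, effect site = measured concentration) and reduces
numerically to the adult model as k_e0 → ∞ with γ = 1.

## Statistical layer

Inter-individual variability is lognormal: subject parameters are
`theta_pop · exp(eta)` with `eta ~ N(0, Ω)`.  Magnitudes are reported
as CV% using the exact transform `omega = sqrt(ln(1 + (CV/100)^2))`
(at the adult baseline-ratio magnitude of 141.9 CV% the popular
approximation CV ≈ omega is off by ~26%, so the exact form matters).
Ω is block-structured: declared correlations (here V1/F–CL/F) form
blocks, everything else is diagonal; positive definiteness is checked
loudly at construction.  Covariates enter multiplicatively — power
models `(cov/ref)^beta` centred at the observation-count-weighted mean
(plain mean or fixed reference selectable; the choice is recorded in
fit metadata) and `exp(beta·I[female])` for sex.

Residual errors are proportional (sd = b·f) or combined additive +
proportional.  The combined form is sd = a + b·f; the quadrature form
sqrt(a² + b²f²) is selectable for sensitivity analyses.  A
concentration below the LLOQ contributes the unconditional interval
probability P(0 < Y < LLOQ) under the Gaussian residual model — the
censored-with-lower-bound treatment — computed in log space via
`log_ndtr` so deep tails (predictions far above the LLOQ) stay finite.

## Estimation

**SAEM.**  The expectation step runs a Markov chain per subject on the
log-scale individual parameters with three kernels per sweep: an
independence sampler proposing from the population prior (global
moves), an adaptive full-vector random walk scaled by chol(Ω), and an
adaptive componentwise random walk.  The third kernel is essential
here: the random-effect scales span 0.29–1.05 on the log scale, and
with a single full-vector kernel the chains under-explored the wide
baseline-ratio and IC50 directions, settling at a self-consistent but
sub-maximum-likelihood point (the generating parameters beat such fits
by hundreds of OFV units at n = 200).  With the three-kernel sweep the
fitted point matches the generating parameters' likelihood.

The maximisation step is closed-form on stochastically averaged
sufficient statistics: per-parameter regression of the smoothed
log-parameters on the covariate design gives the fixed effects and
covariate coefficients, and blockwise smoothed covariances give Ω.
Exploration (default 300 iterations, step size 1) anneals the Ω
diagonal and the error coefficients — each bounded below by 0.95 of
its previous value — to prevent premature collapse; smoothing (default
100 iterations) uses step sizes 1/k.  Residual-error coefficients are
updated by a small Nelder–Mead against the cached current predictions,
annealed and smoothed the same way.

Fixed effects without inter-individual variability (k_a, Q/F, V2/F,
k_e0, γ in the adult final model) are shared across subjects and
updated every third iteration by a damped diagonal-Newton profile step
on the complete-data likelihood, with steps clipped to ±0.25 on the
log scale.  An alternative — giving such parameters a small artificial
variability so they ride the same machinery — was evaluated and
rejected: with a 7% proportional residual error, even 5% artificial
parameter wiggle measurably distorts the likelihood (~550 OFV units at
the generating values on a 200-subject study) and inflates the error
estimates.

All positive parameters are estimated on the log scale; γ is bounded
below at 0.1.  Runs are deterministic given (dataset, settings, seed).
Convergence is flagged from the smoothing-phase trace; a model with
more random effects than subjects triggers a warning, not a silent
fit.

**Gauss–Hermite route.**  The paediatric direct model has two fixed
effects, one random effect and one error coefficient, so SAEM is
overkill: the marginal likelihood is computed exactly (30-node
Gauss–Hermite over the IC50 random effect) and maximised by
Nelder–Mead.  This deterministic route is the default for that model;
SAEM remains available and the test suite cross-checks the two.

**OFV.**  −2·log marginal likelihood is estimated by importance
sampling: a short batched MCMC locates each subject's conditional
distribution, then a moment-matched multivariate-t proposal (df 5,
covariance inflated 1.5×) supplies the draws; the Monte-Carlo standard
error is reported alongside.  With no random effects the integral
collapses to the direct sum.  The prior-scale Gaussian proposal used
first was abandoned — rich per-subject data make posteriors far
narrower than the prior, and the resulting estimator bias differed
between specs by hundreds of units, which would have corrupted every
model comparison.

**Covariate search.**  A simplified conditional-sampling stepwise
search: candidate (parameter, covariate) pairs are ordered by
EBE-association tests (Pearson for continuous covariates, t-test for
sex), the top pairs (default 3, screening p < 0.2) are scored, and
forward inclusion/backward elimination use the chi-square 1-df
threshold at p = 0.01 (6.635).  The score is a *paired profile* OFV
change: one set of conditional importance samples is drawn from the
current fit, the data likelihoods are cached, and the link coefficient
plus the linked parameter's omega are profiled through the prior term
alone, so both hypotheses are evaluated on identical draws and the
Monte-Carlo error cancels in the difference (1 df, since the null also
profiles omega).  Scoring candidates by refitting instead was
evaluated and rejected at desk scale: replicate SAEM fits of the same
model differ by tens of OFV units, swamping a 6.6-unit criterion and
selecting spurious covariates on covariate-free data.  Accepted links
trigger one full SAEM refit so reported coefficients are genuine
estimates.

Because the screen examines every (parameter, covariate) pair and
forwards the strongest, testing that maximum against the per-test
quantile would retain something on roughly a fifth of covariate-free
studies (4 covariates × 6 random-effect parameters ≈ 24 chances).  The
forward threshold is therefore Bonferroni-adjusted over the screened
candidate space by default (12.36 instead of 6.63 for 24 pairs at
p = 0.01), making the *search-level* false-selection rate the nominal
p; `family_control=False` restores the literal per-test rule.
Backward elimination tests specific, already-included links and keeps
the per-test threshold.  The exact internals of the commercial search this
simplifies are unpublished; equivalence is claimed at the level of
decisions (threshold, ordering heuristic, forward/backward structure),
not internals.

**Uncertainty.**  Relative standard errors come from a per-subject
score outer product (BHHH) on the importance-sampled marginal
likelihood (fast default) or from a case bootstrap (resample subjects,
refit, SD across replicates); the two agree within a factor of two on
the paediatric model in the test suite.

## Synthetic studies

The generators define the study conditions; the packaged final-model
configs are their default truths.

**Adult** (default 9 subjects): one 20,000 µg oral dose; 34 scheduled
concentration samples per subject *including* predose — every 10 min
to 3 h, every 20 min to 6 h, every 30 min to 7.5 h, then 24/48/72 h —
and 13 ratio samples (predose, 0.5–8 h hourly-ish, 24/48/72 h).  The
literal protocol enumeration would give 35 samples; the published
accounting (9×34 − 9 missing − 9 predose = 288 analysed
concentrations) is only consistent with 34 including predose, so the
default schedule ends the 30-min block at 7.5 h.  Nine samples are
removed across two subjects (5 + 4 by default, configurable — only
the total is documented).  Parameters are drawn with the published
variability including the 0.84 V1/F–CL/F correlation; concentrations
get combined error and interval censoring below 0.70 µg/L; ratios get
proportional error, redrawn on the rare negative draw (0.7% per
observation).  Demographics are uniform over the published adult
ranges with a 2:1 male:female split.

**Paediatric** (default 27 subjects): ages 0.07–2.24 y and weights
3.2–13 kg (correlated), first dose 0.03–0.08 mg/kg, maintenance
0.06–0.27 mg/kg/day twice daily (one random subject once daily).  The
27-subject default reproduces the study's record accounting exactly:
54 analysable simultaneous (concentration, ratio) records in classes
16 predose-first / 12 post-first / 26 post-repeated, plus 33 tagged
excluded records (10/10/8/2/1/2 across the six documented categories).
Any other subject count switches to a dense recovery plan (predose +
three post-dose visits per subject, no exclusion injection).

Enalaprilat concentrations are *input data* for the paediatric
analysis, so they are generated directly — lognormal (median 3 µg/L,
geometric SD 2.5) scaled by a unimodal time-since-dose template
peaking at 3.5 h and capped at 18.3 µg/L, the highest concentration
observed in that population — rather than from any pharmacokinetic
model.  Raw angiotensins are reconstructed around the noisy model
ratio: ANG I is lognormal with baseline median 250 pg/mL and a
feedback rise (E0/ratio)^0.5 as inhibition deepens (ACE inhibition
removes ANG II's negative feedback on renin, raising ANG I), with
geometric SD 1.85.  These values are anchored to three documented
facts: post-dose ANG I frequently approached the 1594.2 pg/mL upper
calibration limit (10/87 records excluded for exceeding it), 55.6% of
included ANG II values fell below the 22.3 pg/mL LLOQ, and included
records lie inside the calibration range, which bounds their
dispersion.  ANG II below its LLOQ is replaced by LLOQ/2 before the
ratio is recorded, exactly as the analysis prescribes — so roughly
half of the post-dose ratios in a default run carry the substitution
flag, and fits consume the substituted values, as the real analysis
did.

**What the generators do not emulate**: assay drift, haemolysis,
inter-site differences, enalapril adherence patterns, or any
concentration–ANG I mechanistic coupling beyond the feedback factor.
Passing recovery tests therefore show that the estimation machinery
inverts the stated observation model at the stated designs — not that
the published estimates are correct for the real populations.

## Numerical choices and edge cases

* Quadrature: 40-node Gauss–Legendre for the transit convolution;
  30-node Gauss–Hermite for the paediatric marginal likelihood.
* Degenerate compartment spectra (coinciding rates) get a
  deterministic 1e−9 diagonal nudge and retry.
* Censored-likelihood tails are computed via `log_ndtr` and
  `log1p(−exp(·))`.
* The EBE search is a seeded batched stochastic hill-climb with a
  geometrically shrinking step (250 iterations); deterministic given
  the spec.
* VPC percentiles use linear-interpolation (type 7) quantiles —
  recorded in the output metadata because percentile conventions shift
  band edges; bins with fewer than 3 observations merge into their
  left neighbour with a log entry.  The adult VPC bins on scheduled
  nominal times; the paediatric VPC bins on quantiles of the measured
  concentration, its natural regressor axis; the adult-vs-paediatric
  overlay uses time since last dose, with true first-dose predose
  records (which have no prior dose) placed at t = 0 under their own
  symbol class.
* The hysteresis loop closes last-to-first point; |area| below
  1e−9 × (range product) classifies as "none".  Clockwise (negative
  shoelace area with concentration on x) means the effect lags
  concentration.

## Problem sizes used by the tests and the acceptance script

Parameter recovery runs ten seeded replicates per population: 200
subjects (sparse design, Gauss–Hermite fits) for the paediatric model
and 40 subjects (rich design, simultaneous SAEM fits at 300+100
iterations from neutral round-number inits) for the adult model, with
medians reported.  The covariate-search replication uses the
9-subject published design over ten seeds.  These sizes were chosen so
the whole suite runs on a single core in well under half an hour while
keeping the recovery tolerances (±10% paediatric, ±25% adult fixed
effects, ±0.15 on the correlation) comfortably testable.

## Known limitations

* The SAEM defaults are desk-scale; very skewed designs or models with
  many more random effects may need more iterations and transitions.
* The FIM-based RSEs ignore the uncertainty of the variance parameters
  (fixed-effect block only); use the bootstrap when those matter.
* The paired-profile covariate score holds the non-linked parameters
  at the current fit while profiling; a covariate effect that would
  substantially shift *other* parameters is scored conservatively
  (accepted links are refit in full, so the final model is unaffected).
* No inter-occasion variability and no parent-drug (enalapril)
  compartment, by design.
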