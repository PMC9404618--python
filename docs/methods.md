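# Methods

## Scope and estimands

`krtbayes` reanalyzes a two-arm randomized comparison of accelerated
versus standard kidney-replacement-therapy (KRT) initiation. The primary
estimand is the treatment odds ratio for 90-day all-cause mortality,
reported both conditionally (the posterior of exp(θ) from the adjusted
model) and marginally (the g-computation absolute risk difference,
averaging inverse-logit predictions over the observed covariate rows with
the arm toggled and random effects excluded). Secondary estimands are
between-arm differences in expected "days alive and free" of KRT and of
hospitalization, and odds ratios for KRT dependence, rehospitalization and
the death/KRT composite.

## Priors and thresholds

Priors on the treatment log odds ratio are normal. The adopted theoretical
constants are the *printed* consensus values — neutral N(0, 0.355),
optimistic N(−0.257, 0.249), pessimistic N(0.257, 0.249) — stored verbatim
so downstream numbers match the published analysis. The elicitation
utilities compute the exact counterparts: `sd_from_interval(0.5, 2.0,
0.95)` gives 0.3537, not 0.355, and `or_from_risks(0.40, 0.36)` implies a
MCID log OR of −0.1699 where the printed magnitude is 0.175. Both
discrepancies are inherited rounding in the source constants; we keep the
exact functions for general use and the printed constants for
reproduction, and we do not attempt to reconcile them.

Thresholds:

- **ROPE**: |log OR| < 0.1 · π/√3 = 0.18138 (Cohen's d of 0.1 mapped
  through the logistic standardized-difference conversion), i.e. OR
  0.8341–1.1989, displayed as 0.83–1.19.
- **MCID**: a 4-point absolute mortality reduction over a 40% baseline.
  The exact implied OR (0.84375) is stored; the probability column
  P(OR < 0.84) uses the printed 2-decimal threshold
  (`ThresholdSet.mcid_or_reporting`), mirroring how the large-effect
  margin below uses the printed 0.175.
- **Large effect**: |log OR| > 1.5 × 0.175 = 0.2625, i.e. OR below 0.77
  or above 1.30. The printed MCID magnitude is used because the published
  0.77/1.30 bounds follow from it.
- **Day endpoints**: ±1 day for practical equivalence, ±3 days for the
  MCID.

Data-derived priors are built from a source trial's 2×2 mortality table
as N(log OR, Woolf SE); zero cells are a domain error so any continuity
correction is an explicit caller decision. Source tables are user input,
not package constants.

## Binary-endpoint model

Hierarchical logistic regression with site random intercepts,
non-centered (u_s = τ·z_s, z_s ~ N(0,1)) to avoid funnel geometry at
small τ. Adjusters (sepsis, surgical admission, CKD) are coded 0/1
uncentered with N(0, 1) priors; the intercept has a Student-t(3, 0, 2.5)
prior and τ a half-Student-t(3, 0, 2.5) — the conventional
weakly-informative defaults that "default random-intercept priors" denotes
in the R regression ecosystem. Secondary binary endpoints reuse the same
operation: the composite on all patients, KRT dependence and
rehospitalization on the survivor subset, all under the neutral prior
only.

## Day-endpoint model

Outcomes are scaled by 90 to [0, 1]; values exactly 0 or 1 after scaling
are boundary observations (no epsilon-squeezing — boundaries are
modelled, not nudged). The zero–one-inflated beta likelihood is

- zoi = P(boundary), logit-linear in treatment;
- coi = P(upper boundary | boundary), logit-linear in treatment;
- interior ~ Beta(μφ, (1−μ)φ), with logit μ linear in treatment, the
  three adjusters and a site random intercept, and φ constant (log link).

Treatment on all three components with adjusters and site effects on μ
only is the most parsimonious structure that lets treatment move both
boundary mass and interior location while remaining identifiable at
trial-sized n; φ constant across arms keeps the beta component
identifiable, with between-arm spread differences absorbed by the
mixture. Expected days per arm use the mixture identity
E = zoi·coi + (1 − zoi)·μ̄, with μ̄ averaged over observed covariate rows
(random effects zero), so the reported day difference is
covariate-marginalized rather than at reference covariates — a declared
choice; the source analyses do not state which they used.

## Posterior computation

No probabilistic-programming framework is used: both models have
closed-form gradients, sampled with an internal No-U-Turn sampler
(multinomial variant, Stan-style windowed adaptation of a diagonal mass
matrix, dual-averaging step size, divergence threshold ΔH > 1000, max
tree depth 10, capped at 6 during the initial step-size buffer).
Gradients are verified against finite differences in the test suite, and
the sampler is validated against a dense-grid integration of the exact
two-parameter posterior on one-site, no-covariate data
(Kolmogorov–Smirnov distance < 0.05 at 4000 draws) and against the
posterior-equals-prior identity when the treatment column is constant.

Defaults: 4 chains, 1000 warmup, 1000 kept draws per chain,
target acceptance 0.9 (0.95 for ZOIB fits, whose mixture posteriors are
stiffer). Diagnostics are rank-normalized split R-hat and bulk ESS
(ArviZ), gated exactly at R-hat < 1.01 and ESS > 1000 per parameter —
including every site intercept. A failed gate is a warning state, never a
silent success: pipeline runs mark the fragment incomplete and keep the
draws, and the summary layer refuses non-converged draws unless forced.

The HDI is the shortest contiguous window over the sorted draws
containing ⌈mass·N⌉ draws, ties broken by the lowest start. The
probability of direction uses the sample median's side of zero (positive
side if the median is exactly zero). ROPE membership is strict
inequality; boundary draws have probability ~0 for continuous
posteriors. The "probability of significance by ROPE" is reported two
ways: the %ROPE fraction (the headline number) and an optional 95%
HDI-versus-ROPE decision rule, labelled `rope_decision`.

## Synthetic-trial generator

The real patient-level data are not publicly deposited, so the generator
emulates the design's statistical structure: 2927 patients in 168 sites
(site sizes multinomial with symmetric Dirichlet(5) weights — realistic
imbalance from one parameter), 1:1 allocation, adjuster prevalences 0.57
/ 0.33 / 0.44, mortality from the hierarchical logistic law with
defaults θ = 0, adjuster log ORs (0.35, −0.30, 0.10), τ = 0.30 (a
moderate ICC ≈ 0.027), and the intercept solved deterministically
(Gauss–Hermite quadrature over the random intercept, enumeration over
covariate cells, Brent root-finding) so marginal control-arm mortality
hits 0.44. One root seed drives every sub-stream, so a single integer
fixes the dataset byte for byte.

Day endpoints are drawn per arm from configurable ZOIB processes; because
the endpoints count days *alive* and free, each decedent's value is
forced to zero with probability `death_zero_link` (default 0.8) — a
configurable zero-inflation boost, the simplest mechanism reproducing the
published zero-heavy quartiles, chosen over an explicit survival-time
model. The per-arm ZOIB defaults (KRT-free: zoi 0.12, coi 0.30/0.45, μ
0.63/0.68, φ 2; hospital-free: zoi 0.15, coi 0.05, μ 0.30, φ 1.2) were
set once to reproduce the published medians/IQRs and the ≈3.5-day
KRT-free deficit in the accelerated arm. Survivor-only binary endpoints
are per-arm Bernoulli at the published rates (KRT dependence
10.44%/6.01%; rehospitalization 20.27%/16.77%). Missingness is MCAR
within arm (default: KRT-free days missing at 27/1465 in the accelerated
arm, zero in standard); only counts, not a mechanism, are published, so
MCAR is an assumption.

What the generator does **not** emulate: the joint dependence of death,
KRT-free and hospital-free days beyond the zero-coupling (the real joint
law is unknown); KRT receipt and time-to-KRT; eligibility criteria;
per-country structure; informative missingness. Passing tests therefore
demonstrate that the pipeline recovers the truth of *this* generative
family at trial-like sizes — not that the original data satisfy these
assumptions.

## Problem sizes in the test and acceptance runs

Monte-Carlo margin checks use n = 20 000; logistic parameter recovery
uses 5 replicate simulations of n = 1500 (2 chains × 500 kept); ZOIB
recovery n = 2000 with 2 × 400 kept; the reconstructed-margins fit uses
the full n = 2927 with 4 × 2500 kept draws in the test suite and
4 × 4000 in the acceptance script. These sizes keep Monte-Carlo error
small relative to each assertion's tolerance.

## Known limitations

- The margins-reconstruction fit reproduces only quantities determined by
  the per-arm outcome margins; covariate-conditional structure of the
  original data is not recoverable.
- The ZOIB component structure (which components carry covariates and
  random effects) in the original analysis is unpublished; ours is
  declared above, not inferred.
- Ordinal, hurdle, or joint mortality–days models are out of scope, as
  are Bayes factors, multiplicity adjustment, and missing-data
  imputation (complete-case analysis throughout).
- The internal NUTS engine assumes a single CPU; chains run sequentially.
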