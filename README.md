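# krtbayes

Bayesian reanalysis of two-arm trials of kidney-replacement-therapy (KRT)
timing in critically ill patients with acute kidney injury.

Large randomized trials of *accelerated* versus *standard* KRT initiation
report neutral frequentist results for 90-day all-cause mortality. A
Bayesian reanalysis asks sharper questions: what is the posterior
probability of any benefit, of a clinically important benefit, of the
effect being practically null? `krtbayes` implements that full workflow —
prior elicitation on the odds-ratio scale, hierarchical logistic modelling
of mortality, zero–one-inflated beta modelling of bounded "days alive and
free" endpoints, and a probabilistic summary layer — together with a
seeded synthetic-trial generator so the whole pipeline is testable without
access to patient-level data.

## Models

**Binary endpoints** (90-day mortality; KRT dependence, rehospitalization,
death/KRT composite). A hierarchical logistic regression:

```
logit P(y_i = 1) = β₀ + θ·arm_i + β_sepsis·x₁ᵢ + β_surgical·x₂ᵢ + β_ckd·x₃ᵢ + u_s(i)
u_s ~ Normal(0, τ)
```

θ is the treatment log odds ratio and carries the elicited prior; the
binary adjusters get Normal(0, 1) regularizing priors; the intercept a
Student-t(3, 0, 2.5) and τ a half-Student-t(3, 0, 2.5). Three theoretical
priors span the plausibility spectrum:

| prior       | N(μ, σ) on log OR | meaning                                        |
|-------------|-------------------|------------------------------------------------|
| neutral     | N(0, 0.355)       | 95% prior mass between OR 0.5 and 2.0          |
| optimistic  | N(−0.257, 0.249)  | centered on the 40%→34% design effect (OR 0.77), 0.15 prior probability of harm |
| pessimistic | N(+0.257, 0.249)  | mirror image: harm expected, 0.15 probability of benefit |

Data-derived priors from earlier trials' 2×2 margins are built with
`prior_from_2x2` (log OR mean, Woolf standard error).

**Day-count endpoints** (days alive and KRT-free / hospital-free through
day 90). After scaling to [0, 1], a zero–one-inflated beta (ZOIB) mixture:
P(boundary) = zoi, P(upper | boundary) = coi, interior ~ Beta(μφ, (1−μ)φ),
with treatment on all three components (logit links) and adjusters plus a
site intercept on μ. Expected days marginalized over the observed
covariate rows give the between-arm difference in days.

**Summary layer.** For each endpoint/prior combination: posterior median
OR, 95% highest-density interval, P(benefit) = P(OR < 1), probability of
direction, the fraction of the posterior inside a region of practical
equivalence (OR 0.83–1.19, from a Cohen's d of 0.1 via the logistic
conversion π/√3), P(effect not large) (within OR 0.77–1.30), MCID
probabilities (P(OR < 0.84) and P(absolute risk reduction > 4 points)),
and the g-computation marginal risk difference. Convergence is gated at
rank-normalized split R-hat < 1.01 and bulk ESS > 1000 per parameter.

Posterior sampling uses an internal No-U-Turn sampler with analytic
gradients for both model families (`krtbayes._nuts`); diagnostics come
from ArviZ.

## Worked example

Rebuild a 2927-patient dataset from published margins (643/1465 deaths
accelerated vs 639/1462 standard, 168 sites), fit mortality under the
neutral prior, and summarize:

```python
import krtbayes as kb
from krtbayes.synthetic_trial import from_margins

priors = kb.build_theoretical_priors()
th = kb.build_thresholds()
print(priors["optimistic"])
print(f"ROPE on the OR scale: {th.rope_or[0]:.2f}-{th.rope_or[1]:.2f}")

data = from_margins(643, 1465, 639, 1462)
draws = kb.fit_binary_model(
    data, kb.BinaryModelSpec("death90", priors["neutral"]),
    kb.SamplerConfig(chains=4, warmup_draws=800, kept_draws_per_chain=1500, seed=1))
s = kb.summarize_effect(draws, data, th)
print(f"median OR {s.median_or:.2f}, 95% HDI {s.hdi95_or[0]:.2f}-{s.hdi95_or[1]:.2f}")
print(f"P(benefit) {s.p_benefit:.2f}, %ROPE {s.pct_in_rope:.2f}, "
      f"P(effect not large) {s.p_not_large:.2f}, P(OR < 0.84) {s.p_or_below_mcid:.2f}")
print(f"absolute risk difference {s.absdiff_median:.2f}% "
      f"(95% HDI {s.absdiff_hdi95[0]:.2f}% to {s.absdiff_hdi95[1]:.2f}%)")
```

Output:

```
NormalPrior(label='optimistic', mean=-0.257, sd=0.249)
ROPE on the OR scale: 0.83-1.20
median OR 1.01, 95% HDI 0.87-1.16
P(benefit) 0.46, %ROPE 0.99, P(effect not large) 1.00, P(OR < 0.84) 0.01
absolute risk difference 0.18% (95% HDI -3.33% to 3.59%)
```

Read: the treatment effect on mortality is almost certainly not clinically
important — 99% of the posterior lies inside the equivalence region and
the probability of reaching the consensus minimal clinically important
difference (a 4-point absolute reduction, OR < 0.84) is about 1%.

The same workflow runs from the shell:

```sh
krtbayes simulate --out trial.csv --seed 1       # synthetic 2927-patient trial
krtbayes all --seed 1 --out results/             # fit everything, write report.json/.txt
krtbayes fit-primary --prior optimistic --seed 1 --out results/
```

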