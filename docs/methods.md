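# Methods

`famstates` reconstructs, from longitudinal village-registry tables, how
the marital state of a child's biological parents in each year of
childhood relates to four outcomes — annual survival, height, weight (for
height) and completed years of schooling — using Bayesian hierarchical
models with Gaussian-process-smoothed age-specific effects.

## The child-year panel

The observational unit is a **child-year**: child *i* at completed age
*a* ∈ {0, …, 18} in calendar year *t*. Rows exist only while the child is
at risk and observed: from birth to min(age 18, age at death, age at the
last data year covering the child). A child born in 2009 with data ending
in 2014 contributes ages 0–5 only; a child who died at age 2 contributes
ages 0–2 with the survival indicator set to 0 on the final row.

Each year, each biological parent is classified into one leaf of a
branching tree, walked in fixed order:

1. **external** — the parent's vital/marital history is unknown to the
   study (never lived in, or left, the community); modelled as its own
   state rather than dropped, because these children are plausibly the
   most marginalized and deletion would bias the sample;
2. **deceased**;
3. **unmarried**;
4. married, and the current spouse set includes the child's other
   biological parent → **bio-monogamous** / **bio-polygynous**;
   otherwise **step-monogamous** / **step-polygynous**.

Polygyny is an *overlap of marriage spells*: a man with two or more
concurrent wives. A mother is "in polygyny" whenever her current husband
has ≥ 2 concurrent wives, whether he is the biological father or a
step-father.

Annual resolution conventions (family structure is only resolved
annually): the state in force at the **end** of the calendar year is
assigned; a parent who dies in year *y* is deceased from year *y* onward;
when a woman holds overlapping spells in a transition year, the spell with
the latest start year identifies her current husband.

Leaves map deterministically to model indicators. Mother-perspective:
F (father deceased), X (mother deceased), W (mother unmarried), Z (mother
married to a step-father), P (mother in polygyny; Z and P are both 1 for a
step-father with a co-wife), U (either parent external). Father-perspective
adds V (father unmarried), SM (step-mother), PB (father polygynous with
the biological mother), PN (father polygynous without her). Two
monogamously married biological parents are the all-zero base case. An
external parent contributes U only; the co-parent's indicators are still
coded. No two leaves share an indicator vector within a perspective.

Birth order is capped at a configurable maximum category (default 10+):
the GP over sparse high orders is otherwise unstable.

## Outcome models

All four outcomes share the linear predictor

θ[i,t] = α + γ[O_i] + ε[Y_t] + κ[Q_i] + η[J_i] + Σ_e β[e, A_it] · x_e[i,t]

with birth-order (γ), calendar-year (ε), mother-identity (κ) and
father-identity (η) effects, and age-specific coefficient vectors β[e,·]
for the intercept, male, twin and parental-state indicators. External
parents contribute 0 to κ/η. Outcome distributions:

* **survival** — discrete-time hazard: S ~ Bernoulli(logistic(θ)),
  conditional on surviving the previous year (rows after death do not
  exist);
* **height** — log(H cm) ~ Normal(θ, λ);
* **weight** — log(K kg) ~ Normal(θ + b[A]·(log H − c[A]), λ), where b is
  an age-specific coefficient on log-height and c[A] is the per-age mean
  of observed log-height (centering improves identifiability of the
  age intercepts);
* **schooling** — zero-inflated Poisson: never-attended probability
  logistic(θ) and attendee rate exp(η̃), with θ and η̃ built from two
  independent parameter sets over the same predictors.

Children of unknown sex (common for infants who died long before the
surveys) are retained: their likelihood is a per-child two-component
mixture over male/female with the observed male fraction among sexed
children as the weight. Dropping them would bias early-mortality
estimates downward.

## Priors and smoothing

γ, ε and each row of β get non-centered Gaussian-process priors over their
ordered index (birth-order category, calendar year, age):
effect = amp · L(ls) z, z ~ N(0, I), where L is the Cholesky factor of the
squared-exponential correlation kernel k(i,j) = exp(−(i−j)²/(2·ls²)) plus
1e-6 jitter. This yields partial pooling across neighbouring categories
without a fixed functional form; the kernel is the minimal standard choice
with those properties and is pluggable. κ and η are exchangeable
zero-mean normals with estimated scales (identity effects have no
ordering to smooth over).

Default priors, declared in `FitConfig` and echoed into every report:
α ~ Normal(0, 1); amplitudes and identity scales ~ half-Normal(1);
lengthscales ~ log-Normal(log 3, 0.5) in category units (mass on smoothing
over a few neighbouring ages/years); residual scales λ ~ half-Normal(1);
all innovations standard normal. These are weakly regularizing on the
logit/log scales where effects of magnitude 1 are large.

## Inference

The joint log-density is compiled to flat arrays with analytic gradients
(including forward-mode differentiation through the GP Cholesky factor for
lengthscale gradients: dL = L·Φ(L⁻¹ dK L⁻ᵀ)). Sampling is Hamiltonian
Monte Carlo with dual-averaging step-size adaptation (target acceptance
0.8), a diagonal mass matrix estimated during warmup, and a jittered
number of leapfrog steps (uniform on 1..24 by default). Trajectories with
energy error > 1000 count as divergent and are rejected. Default desk
scale is 2 chains × 500 warmup × 500 kept draws; per-chain seeds derive
deterministically from the fit seed, so fits are bit-reproducible given
(seed, config, input). Split-R̂ and bulk ESS are computed for every
retained scalar via arviz; warnings fire at R̂ > 1.01 or any divergence.
Desk-scale fits of this model family typically show max split-R̂ around
1.05–1.2 — adequate for posterior means and contrast curves; production
inference should raise warmup/samples.

Numerical edge handling: positions with non-finite density or gradient,
failed factorizations, or degenerate lengthscales evaluate to −∞ and the
trajectory is rejected; the ls → 0 limit of the kernel derivative is taken
as 0 explicitly.

## Predictions and contrasts

Predicted outcome curves are for a population-typical child: identity
effects at 0, birth order at its first category, calendar year at the GP
prior mean, twin = 0. Focal parental states are held constant across ages
(death is absorbing; profiles violating that are rejected). Natural-unit
transforms: logistic for annual survival (cumulative survival to age 19 is
the product over ages 0–18); the log-normal **mean** exp(θ + λ²/2) for
height and weight (flagged in curve metadata — "cm" means the distribution
mean, not the median); the mixture mean (1 − p_never)·rate for schooling,
with p_never also reported. Contrasts are draw-wise focal-minus-base
differences, preserving posterior dependence; summaries report per-age
posterior means with 90% highest-posterior-density intervals computed by
the narrowest-sorted-window algorithm (ties broken toward the lowest lower
bound).

## Synthetic populations

The generator produces the data structure the analysis assumes, with known
truth, so the whole pipeline is testable without any external download.
Mothers enter at staggered years; their marital state evolves by an annual
Markov kernel over {unmarried, monogamous, polygynous}; husbands and
co-wives are explicit individuals, so polygyny in the generated spell
table really is an overlap of spells and the state engine's classifier
reproduces the simulated states. Default conditions: marriage 0.28/yr,
divorce 0.05/yr, co-wife acquisition 0.012/yr (≈ 8% of married-years
polygynous at stationarity, matching the ~1-in-10 marriages the study
setting reports), adult mortality 0.01/yr, external fathers 7.5% and
external mothers 2% of births (≈ 79% of external parents are fathers),
unknown sex 7.5%, twins 2%, survey years 1995–2014 in the study's ten
field years, births 1960–2014. Outcomes are drawn from the exact model
likelihoods: the age-0 annual survival of ~0.92 declining hazard, growth
curves through reference heights/weights with λ = 0.045 / 0.08, and
schooling starting around age 6.

What the generator does **not** emulate: within-family correlation beyond
the shared linear predictor, measurement error in anthropometry,
age-heaping in retrospective reports, fertility–marital-state feedback
beyond different birth rates, or migration. Passing tests therefore show
the estimator recovers the model's own data-generating process, not that
the model is correct for any real registry.

The hand-built 12-child fixture covers every classifier leaf in both
perspectives, censoring, a twin pair, an unknown-sex child and external
parents; its panel is frozen as a golden file.

## Effect-recovery power study

The desk-scale recovery suite injects a −1.0 logit effect of maternal
death on survival at ages 0–2 into 500-child populations and refits the
full survival model (2 × 500 + 500 draws) across 20 replicates. The study
design raises maternal mortality to 0.05/yr — a power design must place
events where the studied effect acts; at the default 0.01/yr almost no
child-years with a deceased mother occur at ages 0–2 in a cohort this
size. Two properties are checked: the posterior mean of the age 0–2
effect carries the injected sign in ≥ 95% of replicates, and 90% HPDI
coverage of the true age-specific effect vectors (all effects, pooled
across replicates) sits in the nominal 80–98% band. Coverage of the three
injected cells alone is expected to run *below* nominal (observed ≈ 60%):
the GP prior pools a step-shaped, prior-atypical truth toward zero — the
familiar bias–variance price of partial pooling, worth knowing when
reading the real-data analyses this mirrors.

## Problem sizes

Default test and acceptance runs use 120–1,500 simulated children and
2 × 500 + 500 MCMC draws, chosen as the smallest sizes at which the
sampler diagnostics and recovery checks are informative; all sizes are
configuration, not code.

## Known limitations

* Jittered-trajectory HMC mixes less efficiently than adaptive-tree
  samplers; desk-scale R̂ of ~1.1 on the survival model reflects that.
* The same-year mortality/dissolution diagnostic counts calendar-year
  coincidences only; sub-annual ordering is out of scope.
* The weight model conditions on observed height; rows with weight but no
  height are rejected rather than imputed.
* One-lag (previous-year state) models and external reference growth
  standards are out of scope.
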