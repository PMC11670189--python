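# famstates

Family structure and child outcomes in longitudinal village registries:
person-year panels of parental marriage states, and Bayesian hierarchical
models of child survival, growth and schooling.

## The problem

In many rural settings — the motivating case is a small East African
farming village with two decades of demographic interviews — marriages are
fluid: divorce, remarriage, widowhood and polygyny continually reshape the
families children grow up in. Whether these transitions matter for child
well-being is an empirical question that requires following each child
year by year while their parents' marital states change, handling children
whose parent is simply *unknown to the study* (an "external" parent),
children of unknown sex who died in infancy decades before the surveys,
and outcomes observed only in scattered survey years.

`famstates` provides that full pipeline for demographers and
biostatisticians:

1. **Panel construction** — reconstruct per-parent marriage timelines from
   spell tables, classify every child-year into a branching tree of
   parental states (external / deceased / unmarried / married to a
   step-parent or to the other biological parent, in monogamy or
   polygyny), and emit a validated child-year panel with indicator
   covariates and censoring.
2. **Models** — four outcomes sharing one predictor skeleton
   θ[i,t] = α + γ[O_i] + ε[Y_t] + κ[Q_i] + η[J_i] + Σ_e β[e, A_it]·x_e[i,t]:
   discrete-time survival S ~ Bernoulli(logistic θ); log-normal height and
   weight-for-height, log(H) ~ Normal(θ, λ); zero-inflated Poisson years
   of schooling E ~ ZIPoisson(logistic θ, exp η̃). Age-, birth-order- and
   year-indexed effects get Gaussian-process priors (partial pooling, no
   fixed functional form); mother/father identities get exchangeable
   random effects against parental selection.
3. **Inference** — Hamiltonian Monte Carlo with analytic gradients,
   non-centered parameterizations, split-R̂/ESS diagnostics, and
   bit-reproducible seeding.
4. **Contrasts** — age-specific predicted outcomes per parental state in
   natural units (probability, cm, kg, years), differences against the
   two-monogamously-married-parents base case, cumulative survival curves,
   and 90% highest-posterior-density intervals.
5. **Synthetic populations** — a Markov family-history simulator with
   known true parameters, so the whole loop (simulate → build panel →
   fit → recover) is testable end to end without any external data.

See `docs/methods.md` for the model, priors, conventions and limitations.

## Worked example

```python
from famstates import (
    FitConfig, StateProfile, ParentState,
    assemble_model, run_mcmc, contrast_curve, summarize_contrast,
)
from famstates.simulate import SimConfig, default_true_params, simulate_population

# a 500-child village with known generating parameters
cfg = SimConfig(n_children=500, seed=7)
records, spells, vitals, panel = simulate_population(cfg, default_true_params())

fit = FitConfig(outcome="survival", perspective="mother",
                chains=2, warmup=500, samples=500, seed=7)
draws = run_mcmc(assemble_model(panel, fit))
print(f"max split-R-hat {draws.max_rhat():.2f}, "
      f"divergences {draws.divergences}")

curve = contrast_curve(draws.flat_dict(), "female",
                       StateProfile(mother=ParentState.DECEASED),
                       "survival", draws.effect_names)
print(summarize_contrast(curve.cumulative).iloc[[0, 5, 18]])
```

Output from this exact script:

```
max split-R-hat 1.17, divergences 1
    age      mean  hpdi_lower  hpdi_upper
0     0 -0.067236   -0.185673    0.034870
5     5 -0.122547   -0.373704    0.054650
18   18 -0.104757   -0.330752    0.055155
```

Read: a girl whose mother is deceased from her birth is predicted to lose
about 7 percentage points of cumulative survival probability in her first
year, deepening to roughly 12 points by age 6 — the generating truth puts
the maternal-death penalty at early ages, so the cumulative deficit stops
growing once that window closes. The 90% HPDIs brush zero at this
desk-scale sample size, and a split-R-hat of 1.17 is typical for these
short chains; raise `warmup`/`samples` for production inference.

The same pipeline is available from a shell:

```bash
famstates simulate --outdir sim --seed 7 --n-children 500
famstates build-panel --children sim/children.csv --marriages sim/marriages.csv \
    --vitals sim/vitals.csv --measurements sim/measurements.csv --outdir panel
famstates fit --panel panel/panel.csv --outdir fit --outcome survival --seed 7
famstates contrast --posterior fit/posterior_survival_mother --outdir contrasts
famstates report --posterior fit/posterior_survival_mother --outdir report
```

Fitting real registry tables with different headers goes through a YAML
column mapping (`famstates build-panel --column-mapping map.yaml ...`);
see `famstates.io` for the native schema.

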