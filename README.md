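# rrtvar

Finite-population **variance estimation for sensitive variables** under
scrambled randomized-response (RRT) models, with two non-sensitive
auxiliary variables.

The package implements:

* **Two scrambling models** — the multiplicative-additive model
  `Z = T·Y + S` (mean-1 multiplier, mean-0 additive noise) and a combined
  model `Z = g(Y + aS) + (1−g)R(Y + aS)` mixing additive, multiplicative
  and subtractive perturbation — plus the privacy measure
  `Δ = E(Z − Y)²` for both (`rrtvar.scrambling`).
* **Point estimators** of the population variance `σ_y²` from one SRSWOR
  sample of scrambled responses: the basic decoded estimator, ratio and
  generalized-ratio adjustments, and a generalized exponential
  two-auxiliary class with closed-form optimum constants
  (`rrtvar.estimators`).
* **First-order bias/MSE theory** for every estimator, the intermediate
  A/B/D terms, closed-form optimum constants, efficiency comparisons, and
  a generic **delta-method oracle** that assembles the sampling covariance
  of `(s_z², s_x1², s_x2², z̄)` and numerically validates every printed
  closed form (`rrtvar.theory`).
* **Synthetic finite populations** (trivariate normal with configurable
  covariance/means), central and standardized cross-moments, SRSWOR
  sampling (`rrtvar.population`).
* A seeded **Monte-Carlo engine** reproducing the benchmark simulation
  design: repeated SRSWOR draws with fresh response noise, empirical
  Mean/MSE per estimator, percent relative efficiency (PRE), the unified
  privacy-efficiency measure ϑ = MSE/Δ, and published-table-shaped output
  (`rrtvar.simulation`).

Where the source material's printed algebra is typographically
inconsistent, the package implements the dimensionally consistent reading
(validated against the delta-method oracle and Monte Carlo); literal
variants are retained behind `strict_paper=True` flags where well defined.

## Library quick start

```python
import rrtvar as rv

pop = rv.generate_population(rv.POPULATION_I_COV, (3, 3, 3), 100_000, seed=1)
params = rv.DPModelParams(var_s=0.5, var_t=0.5)

z = rv.scramble_dp(pop.y_values, params, seed=2)          # respondents answer
idx = rv.draw_srswor(pop.size, 500, seed=3)               # SRSWOR sample
s = rv.summarize_sample(z[idx], pop.x1_values[idx], pop.x2_values[idx])

moments = rv.compute_population_moments(pop, z).with_theta(500)
const = rv.optimum_constants_t1d(moments, params, lambda1=1, lambda2=1, n=500)

print(rv.t0_dp(s, params))                                # basic estimator
print(rv.t1d(s, params, pop.var_x1, pop.var_x2, const))   # generalized class
print(rv.mse_t0_theory(moments, params, 500))             # closed-form MSE
```

## Command line

```sh
rrtvar simulate --config examples/simulation.toml --out results.csv
rrtvar tables   --results results.csv --layout table4
rrtvar theory   --config examples/simulation.toml     # closed form vs oracle
rrtvar privacy  --config examples/simulation.toml     # privacy levels
```

Set `[model] kind = "np"` (with `g`, `a`, `var_r`, `mode`) in the config
to run the combined scrambling model instead.

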