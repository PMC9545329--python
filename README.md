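# serialjm

Joint modelling of two *serially linked* longitudinal outcomes and two
competing time-to-event outcomes, with a latent mediation decomposition of
the intervention effect.  The motivating use case is long-term trials in
slowly progressing diseases (e.g. prodromal Alzheimer's disease) where a
brain-imaging outcome is hypothesised to drive a cognitive outcome, both
processes drive the risks of starting open-label medication and of dropping
out, and follow-up ends at whichever comes first.

## Model

For subject *i* and time *t* (years):

```
y_i1(t) = m_i1(t) + e_i1(t),   m_i1(t) = x_i1(t)'β1 + z_i1(t)'b_i1
y_i2(t) = m_i2(t) + e_i2(t),   m_i2(t) = x_i2(t)'β2 + z_i2(t)'b_i2 + ξ·m_i1(t)
h_ik(t) = h0k(t)·exp{γ_k'w_i + α_k1·m_i1(t) + α_k2·m_i2(t)},   k = 1, 2
```

with random intercepts and slopes z(t) = (1, t), independent b_i1 ⟂ b_i2,
and B-spline log-baseline hazards.  The first outcome's *latent* trajectory
enters the second outcome's mixed model as a time-varying covariate (ξ), and
both latent trajectories enter the two cause-specific hazards (α_kj).  This
is a serial multiple-mediator structure: with ℬ_j(t) the time-varying
intervention effect in longitudinal submodel j, the intervention's total
(conditional) log hazard ratio for event k splits exactly into

```
log 𝒯(t) = γ_k1  +  α_k1·ℬ1(t)  +  α_k2·ℬ2(t)  +  ξ·α_k2·ℬ1(t)
           direct    via outcome 1   via outcome 2   via both, serially
```

a product-of-coefficients mediation estimator computed per posterior draw.
Estimation is Bayesian MCMC (blocked adaptive Metropolis-within-Gibbs with
conjugate random-effects proposals; see `docs/methods.md`).

## Worked example

Simulate a 300-subject trial from the built-in `study1` scenario
(ξ = −0.5), fit the joint model, and decompose the intervention effect:

```python
import numpy as np
from serialjm import (McmcConfig, decompose, fit, get_scenario,
                      simulate_dataset, summarize)

scenario = get_scenario("study1").replace(n_subjects=300)
data = simulate_dataset(scenario, seed=1)
draws = fit(data, scenario.params_truth.spec,
            mcmc=McmcConfig(n_iterations=3000, n_burnin=1000,
                            n_chains=2, seed=1))
summary = summarize(draws)
print(summary.table.loc[["beta1[time]", "xi", "alpha_11", "alpha_12",
                         "gamma1[intervention]"]].round(3))
```

```
                       mean     sd   q2.5  q97.5   rhat      ess
beta1[time]          -0.283  0.051 -0.381 -0.175  1.029   90.964
xi                   -0.507  0.073 -0.653 -0.366  1.040  162.080
alpha_11             -0.396  0.184 -0.731 -0.006  1.022  136.867
alpha_12              0.309  0.160  0.003  0.643  1.289   11.633
gamma1[intervention] -0.014  0.183 -0.368  0.340  1.085   62.924
```

The generating values (−0.25, −0.5, −0.6, 0.4, −0.2) all lie inside the 95%
credible intervals.  `xi` is the coupling between the outcomes: a one-unit
increase in the first latent process shifts the second by −0.51 (truth
−0.5).  `alpha_11` < 0 means a higher first outcome lowers the risk of
event 1.  The mediation decomposition:

```python
curves = decompose(draws, np.arange(0, 3.01, 0.05))
print(curves.summary().query("time == 1.0").round(3))
```

```
     time              component   mean  lower  upper
20    1.0                 direct  1.003  0.692  1.405
81    1.0             indirect_1  0.931  0.840  1.002
142   1.0             indirect_2  1.004  0.953  1.049
203   1.0             indirect_3  0.973  0.932  1.001
264   1.0  combined_via_outcome1  0.905  0.802  0.988
325   1.0                  total  0.909  0.640  1.265
```

At one year the estimated overall intervention hazard ratio for event 1 is
0.91 with a wide band that covers the generating truth (0.71 at these
values).  `indirect_1` is mediation through the first latent outcome only,
`indirect_3` the serial path through both outcomes, and
`combined_via_outcome1` combines the two paths that start at the first
outcome.  On this dataset the mediated paths, not the direct one, carry the
estimated risk reduction.

The same pipeline is available from the shell:

```sh
serialjm simulate --scenario study1 --seed 1 --out-dir data/
serialjm fit --longitudinal data/longitudinal.csv --subjects data/subjects.csv \
             --seed 1 --out-dir fit/
serialjm mediate --draws fit/draws.csv --meta fit/draws_meta.json --out-dir med/
serialjm simstudy --scenario study2_IV --model univariate --replicates 25 \
                  --seed 0 --out-dir study/
```

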