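# trophocc

Multi-trophic dynamic occupancy modeling of post-fire forests: black-backed
woodpeckers (*Picoides arcticus*) and the accumulated sign of their
woodboring-beetle prey (Buprestidae, Cerambycidae).

In the decade after a conifer-forest wildfire, dead trees attract
woodboring beetles whose larvae are the woodpeckers' main food; both
groups surge and then decline on different clocks.  `trophocc` implements
a joint hierarchical Bayesian model that links repeated
detection/non-detection point-count surveys of woodpeckers (with imperfect
detection and a removal protocol) to a latent index of cumulative beetle
sign measured once, in the final study year, from bark samples on up to
six snags per survey point.  The package is aimed at quantitative
ecologists who want to fit, probe, or extend this model class: every piece
— the generative simulator, the exactly marginalized likelihood, the MCMC
sampler, and the posterior summaries and prediction curves — runs without
any external data.

## The model

For survey interval *k* at point *j* in year *t* (years indexed so the
final, beetle-surveyed year is *t = T = 10*):

```
y_jkt ~ Bernoulli(z_jt * p_jkt)            observation (removal design)
logit(p_jkt)  = alpha_0 + alpha_type * type_k        type: 0 passive, 1 broadcast
z_jt  ~ Bernoulli(psi_jt)                  latent occurrence
logit(psi_jt) = beta_0,f(j) + beta_elev elev_j + beta_lat lat_j
              + beta_snag snag_jt + beta_beetle intensity_jt
              + beta_ageXbeetle age_jt intensity_jt
              + phi z_j,t-1                (autologistic term; absent in the
                                            first post-fire year)
logit(intensity_jt) = gamma_0 + gamma_age age_jt + gamma_pine pine_j
                    + gamma_ageXpine age_jt pine_j
activity_j ~ Binomial(numTrees_j * 8, intensity_j,T)   beetle observation
```

Fire-level intercepts `beta_0,f ~ Normal(mu_beta0, tau_beta0)`; all fixed
effects carry vague Normal(0, precision 0.1) priors, with a Gamma(0.1, 0.1)
hyperprior on `tau_beta0`.  Beetle-sign intensity is a deterministic
logit-linear function of fire age and pine proportion — uncertainty flows
through the gammas, which are informed simultaneously by the binomial
beetle scores and by the occupancy histories.  The latent occurrence
series `z` is marginalized exactly by a two-state forward recursion, so
the sampler (adaptive Metropolis-within-Gibbs with conjugate updates for
the intercept hyperparameters) works on a deterministic likelihood.
See `docs/methods.md` for conventions, defaults, and design choices.

## Worked example

Simulate the 22-fire, 128-point study layout from the model's own
generative process at the reported posterior-mean parameter values, then
refit the beetle-sign submodel to the simulated activity scores:

```python
import numpy as np
from trophocc import (
    GeneratorConfig, MCMCConfig, field_study_params, make_table1_design,
    sample_posterior, simulate_dataset, summarize_posterior,
    predict_intensity_curve,
)

truths = field_study_params()
dataset, truth = simulate_dataset(
    GeneratorConfig(design=make_table1_design(), true_params=truths, seed=42)
)
config = MCMCConfig(n_chains=3, n_iter=4000, n_burnin=2000, thin=4, seed=0)
draws = sample_posterior(dataset, config, submodel="beetle")
print(summarize_posterior(draws).round(3))
```

```
                   mean  lower_95  upper_95   rhat  evidence
parameter
gamma0           -0.136    -0.263    -0.008  1.002      True
gamma_age         0.330     0.235     0.433  1.002      True
gamma_pine        0.403     0.158     0.643  1.002      True
gamma_age_x_pine -0.739    -0.930    -0.562  1.004      True
```

At only 128 points the intervals are wide, but each generating value
(0.26 for the age slope, 0.36 for pine, −0.62 for their interaction) sits
inside its 95% credible interval, and every interval excludes zero —
`evidence` flags the same coefficients the field study flagged.  The
fitted surface reproduces the signature crossing pattern of beetle sign:

```python
curves = predict_intensity_curve(draws, np.arange(1.0, 11.0), [0.0, 1.0])
```

gives a predicted intensity rising from 0.372 (year 1) to 0.642 (year 10)
in pine-free stands, but falling from 0.678 to 0.349 in pure-pine stands,
where fast bark decay erases accumulated sign.

The same workflow is available from the shell:

```sh
trophocc simulate --config gen.yaml --out-dir data/
trophocc fit --data-dir data/ --out draws.csv --submodel joint
trophocc summarize --draws draws.csv
trophocc predict --draws draws.csv --kind occupancy --out curves.csv
trophocc check          # reduced-scale marginalization + recovery checks
```

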