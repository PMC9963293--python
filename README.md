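# streamcom

Community dynamics under intentional release: simulation and hierarchical
Bayesian inference for stream-fish monitoring designs.

## The problem

Hatchery programs release millions of captive-bred fish into rivers every
year.  Because the number released is set by managers — not by the density
dependence that regulates wild populations — theory predicts that release
can disrupt the balance of competition that lets many species coexist, and
with it the *stability* of the whole community: the coefficient of
variation (CV = SD / mean) of total community density over time.

`streamcom` is for quantitative ecologists who want to study that
mechanism end to end:

* a stochastic **multi-species Ricker simulator** in which an enhanced
  species receives `R` released individuals per time step, entering both
  reproduction (with relative fitness `f_R`) and competition;
* a **synthetic monitoring-data generator** that mimics a long-term
  electrofishing survey (sites nested in watersheds, Poisson counts over
  sampled areas, irregular 1-3 year revisit gaps, watershed-aggregated
  release records);
* three **hierarchical Bayesian models** fitted by a built-in adaptive
  Metropolis-within-Gibbs sampler: a density-reconstruction state-space
  model (Poisson observation, geometric-lag AR process), a regression of
  site-level CV / mean / SD / richness on a *latent* effective release
  (a Dirichlet simplex splits each watershed's total across its sites),
  and a sparse spike-and-slab multi-species Ricker fit that estimates
  pairwise competition coefficients with latent-factor process noise.

The core model is

    N_{i,t+1} = (N_{i,t} + phi_i R) exp[ r_i (1 - (alpha_{i1} R
                + sum_j alpha_{ij} N_{j,t}) / K_i) ] exp(eps_{i,t})

with `phi_i = f_R` for the enhanced species and 0 otherwise, `alpha_ii = 1`
and `eps ~ Normal(0, sigma_eps^2)`.  See `docs/methods.md` for the full
model descriptions, priors, sampler design and known limitations.

## Worked example

Simulate the destabilizing regime (small carrying capacity, full hatchery
fitness) at three release levels and summarise community stability:

```python
import numpy as np
import pandas as pd
from streamcom import SimProtocol, run_sweep
from streamcom.theory_experiments import ScenarioGrid

grid = ScenarioGrid(
    axes={},
    scenarios=pd.DataFrame([{
        "scenario_id": "low-K", "r1": 1.5, "abar": 0.25, "K": 100.0,
        "f_R": 1.0, "S": 10, "r_max": 2.5, "sigma_eps": 0.5,
    }]),
    kind="n_species",
)
protocol = SimProtocol(T_total=600, T_init=150, T_burn=150, T_save=300,
                       init_density=5.0, reseed_every=10,
                       extinction_threshold=0.01)
res = run_sweep(grid, np.array([0.0, 250.0, 500.0]), protocol,
                n_rep=100, seed=42, paired=True)
print(res[~res.diverged].groupby("R")[
    ["cv_whole", "mu_whole", "n_persist"]].mean().round(3))
```

which prints

```
       cv_whole  mu_whole  n_persist
R
0.0       0.300   320.029       6.91
250.0     0.341   204.272       4.99
500.0     0.417   146.861       4.06
```

Reading the table: as the release level `R` rises from 0 to 500 fish per
step, the whole-community CV climbs from 0.30 to 0.42 (less stable), mean
total density falls by more than half, and on average three of the ten
species are lost — release destabilises the community by suppressing both
the enhanced species' natural recruitment and its competitors.

The inference half runs the same way from Python (`fit_statespace`,
`fit_release_models`, `fit_interaction` on `generate_*` data) or from the
command line:

```bash
streamcom make-synthetic --seed 1 --out data/
streamcom fit-statespace --data data/ --group enhanced --seed 1 --out post.csv
streamcom run-all --seed 1 --out run/
```

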