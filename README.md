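# tcnet

Longitudinal dyadic network models of peer feedback in therapeutic
communities (TCs).

TCs are residential substance-abuse treatment programs in which mutual
aid between peers is the primary clinical method: residents hand in
written *affirmations* rewarding prosocial behaviour and written
*corrections* sanctioning norm violations, producing two longitudinal
directed networks over the unit's residents.  `tcnet` is a pipeline for
analysing such event logs and for studying the analysis itself by
simulation:

* **event_data** — parse and validate event-log/roster CSVs, build the
  day-by-day presence grid that defines the dyadic risk set, and the
  binary tie outcomes per ordered co-present dyad, day, and network.
* **covariates** — compute, for every dyad-day observation, the
  temporal-structural predictors of tie formation from history strictly
  before that day: reciprocity, transitive closure and three-cycles,
  indegree/outdegree activity and popularity, out-isolation, same-peer
  concentration, tenure categories, attribute (age, race, LSI-R) activity,
  popularity and homophily terms, staff-differential terms, and
  head-turning (HT) terms.
* **latent_probit** — fit the dyadic probit GLMM

  `P(y_ijt = 1) = Φ(x_ijt'β + a_i + b_j + c_t + u_i·v_j)`

  with sender, receiver, and day random effects and a low-dimensional
  latent factor term absorbing residual dyadic dependence, by Gibbs
  sampling with truncated-normal data augmentation; summaries report
  posterior mean, 95% interval, and a significance flag per coefficient
  plus the three variance components.
* **synthetic_data** — simulate complete synthetic units (bed-constrained
  roster turnover, attributes, exogenous staff feedback, and day-by-day
  resident ties drawn from the model with known coefficients), calibrate
  intercepts to target event volumes, and run parameter-recovery
  experiments.
* **cli** — a thin command line (`tcnet simulate|covariates|fit|report|recover`)
  over the library.

The package ships reference estimates from an observed 16-bed women's
unit (611 days, 6,108 affirmations, 1,945 corrections); the simulator's
defaults emulate that unit and the recovery experiments use those
estimates as ground truth.

## Worked example

```python
from tcnet import (SimConfig, simulate_roster, simulate_unit,
                   assemble_design, ModelSpec, fit, summarize)

truth = {"affirmation": {"intercept": -1.8, "aff_reciprocity": 0.3},
         "correction": {"intercept": -2.2}}
cfg = SimConfig(bed_capacity=8, horizon_days=120, true_beta=truth, seed=7)
roster, grid = simulate_roster(cfg)
events = simulate_unit(cfg, roster, grid)

cols = ["intercept", "aff_reciprocity"]
design = assemble_design(events, grid, roster, columns=cols)["affirmation"]
draws = fit(design, ModelSpec(covariates=cols, iterations=800, burn_in=300, seed=7))
print(summarize(draws)[["variable", "mean", "lower", "upper", "sig"]])
```

prints (values from this exact run):

```
            variable      mean     lower     upper   sig
0          intercept -2.326397 -2.508768 -2.101911  True
1    aff_reciprocity  0.319119  0.054345  0.553922  True
2    sender_variance  0.398838  0.177461  0.760918  True
3  receiver_variance  0.268774  0.117748  0.566841  True
4       day_variance  0.546116  0.376031  0.760156  True
```

The reciprocity coefficient is on the probit scale: a directed
affirmation yesterday from j to i raises the propensity of an i→j
affirmation today by about 0.32 standard-normal units, its 95% interval
excludes zero, and it recovers the generating value 0.3 within posterior
uncertainty (the small 8-bed, 120-day unit leaves the intercept and
variance components noisy).  More narrative walk-throughs live in
`examples/`.

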