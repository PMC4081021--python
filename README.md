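# odemix

**ODE-constrained mixture modelling of single-cell snapshot data.**

Snapshot assays -- quantitative microscopy, flow cytometry -- measure a
readout in thousands of single cells at a handful of time points and
stimulus levels, destroying the cells as they go.  Heterogeneous tissues
such as primary sensory neurones split into subpopulations that respond
very differently to the same stimulus, and the interesting questions are
mechanistic: how many subpopulations are there, *which* molecular property
differs between them, how large is the responsive fraction, and what are
the kinetic rates?

`odemix` answers these questions by combining mixture models with ODE
pathway models.  Each mixture component represents one subpopulation; its
location parameter is not free but pinned to the observable of a reaction
rate equation describing that subpopulation's average dynamics,

    p(y | t, u) = sum_s  w_s * phi( y | m_s(t, u; psi_s), sigma ),
    dx_s/dt = f(x_s, u, psi_s),   m_s = h(x_s, psi_s),

and one joint likelihood couples every time point and experimental
condition.  Competing hypotheses about the source of cell-to-cell
variability (which kinetic parameter or protein abundance is
subpopulation-specific) become competing models, fitted by multi-start
maximum likelihood and ranked by BIC; a model more than 10 BIC units worse
than the best is rejected.  Parameter uncertainty comes from profile
likelihoods with chi-square(1) confidence intervals.

The package ships two pathway models -- a reversible conversion process
(A <-> B with stimulus-dependent conversion) and a two-state model of
NGF-induced Erk1/2 phosphorylation in sensory neurones (TrkA binding +
Erk phosphorylation, parameterised by the identifiable products of rates
and total protein abundances) -- plus an ensemble single-cell simulator
that generates realistic synthetic snapshot data with known ground truth,
a plain 2-D normal-mixture EM fitter for co-labelling validation data, and
a command-line workflow.

It is written for systems biologists analysing snapshot data who want
mechanistic subpopulation inference, and for methodologists who want a
tested, reproducible reference implementation.

## Worked example

Generate a synthetic two-subpopulation study (70% of cells barely respond
to the stimulus, 30% respond strongly; the subpopulations differ 100-fold
in the stimulus-dependent rate k1), then let model selection find the
source of the variability:

```python
import odemix as ox
from odemix.studies import run_selection_study

cfg = ox.get_preset("conversion-scenario1", seed=1)
data, truth = ox.generate_snapshots(cfg)      # 6 snapshots x 1,000 cells
table = run_selection_study(data, "conversion", n_starts=20, seed=1)
print(table.report())
```

```
 m distribution ODE_const variability  n_par   loglik       BIC  rank delta_BIC     decision
 2   log-normal      mean          k1     17 1.5023e4 -2.9899e4     1     0.000      optimal
 2   log-normal    median          k1     17 1.5023e4 -2.9899e4     2     0.214 not rejected
 2       normal      mean          k1     17 1.5022e4 -2.9896e4     3     2.899 not rejected
 2   log-normal      mean          k3     17 1.3231e4 -2.6315e4     4       >10     rejected
 ...
 1       normal      mean           -      9 0.2700e4 -0.5322e4    12       >10     rejected
```

All twelve candidate models were fitted jointly to all six snapshots; the
three models in which k1 is subpopulation-specific occupy ranks 1-3 and
every model with the wrong variability source (no subpopulations, or k2-
or k3-specific) is rejected at delta-BIC > 10 -- the selection recovered
the true cause of the heterogeneity without ever seeing the labels.

The best model's parameters recover the generating truth:

```python
spec = ox.build_spec("conversion", ox.VariabilityHypothesis(2, ("k1",)),
                     ox.DistributionAssumption("log-normal", "median"),
                     cfg.design)
fit = ox.fit_multistart(spec, data, n_starts=20, seed=1)
per_sub, weights, scales = spec.unpack(fit.theta)
print(weights)                     # [0.699 0.301]   (true 0.7 / 0.3)
print([q["k1"] for q in per_sub])  # [0.0199 2.0003] (true 0.02 / 2.0)

prof = ox.profile_parameter(spec, data, fit, "v1")
print(ox.confidence_interval(prof, 0.95))
# ProfileInterval(lower=0.683, upper=0.709, ...)  -- contains 0.7
```

An sklearn-style estimator wraps the same machinery
(`ox.OdeMixtureModel(...).fit(data)`, fitted attributes `theta_`,
`log_likelihood_`, `weights_`; `score(X)` returns the average per-cell
log-likelihood), and a CLI drives full studies from files:

```bash
odemix simulate --preset conversion-scenario1 --seed 1 --out work/
odemix select --data work/conversion-scenario1.tsv --n-starts 20 --seed 1
odemix profile --data work/conversion-scenario1.tsv --specific k1 --param v1
odemix report --data work/conversion-scenario1.tsv --specific k1 --out work/report
```

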