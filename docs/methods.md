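# Methods

## The model

Population snapshot assays (quantitative microscopy, flow cytometry)
measure a fluorescence-like readout in many single cells at a few time
points and stimulus levels, destroying the cells in the process.  When the
population splits into subpopulations -- clusters of cells with similar
mechanistic parameters -- the measured distribution at each snapshot is
naturally described by a mixture

    p(y | t, condition) = sum_s  w_s * phi( y | theta_s(t, condition) ),

but a plain mixture fitted per snapshot says nothing about mechanism and
requires error-prone matching of components across snapshots.  An
ODE-constrained mixture model (ODE-MM) removes both problems: each
component's location parameter is pinned to the observable of a reaction
rate equation (RRE) describing that subpopulation's average dynamics,

    dx_s/dt = f(x_s, u(t), psi_s),   x_s(0) = steady state at u = 0,
    m_s(t, condition) = h(x_s(t), psi_s),

and one likelihood couples *all* snapshots: cells are independent, so

    l(theta) = sum over snapshots k, cells j  log sum_s w_s *
               phi( y_jk | m_s(t_k, cond_k), sigma_{k,s} ).

The kinetic parameters psi_s split into shared parameters (identical in
all subpopulations) and subpopulation-specific parameters; *which*
parameters are specific is the variability hypothesis under test.
Information criteria computed from the maximised likelihoods of a grid of
hypotheses then identify the mechanistic source of the heterogeneity.

### Component families

Three family / constrained-statistic combinations are implemented
(`DistributionAssumption`):

| family     | constrained statistic | native parameters                        |
|------------|----------------------|-------------------------------------------|
| normal     | mean                 | mu = m, sd = sigma                         |
| log-normal | median               | logLoc = ln m, logSd = sigma               |
| log-normal | mean                 | logLoc = ln m - sigma^2/2, logSd = sigma   |

The log-normal+mean mapping is chosen so the component's *mean* equals the
ODE observable exactly.  Scale parameters are free per snapshot *and* per
component: within-subpopulation spread may change over time and between
conditions.  This scale layout is what makes the free-parameter count

    |shared| + |specific| * n_subpop + (n_subpop - 1) + n_snapshots * n_subpop

equal 9/17 for the conversion study designs and 17/30 for the NGF designs.
A non-positive ODE location under a log-normal family is treated as an
infeasible parameter point (log-likelihood -inf), not an exception, so
multistart optimisation simply walks out of such regions.

### Pathway models

`conversion` -- reversible conversion A <-> B with stimulus-driven forward
rate k1*u, basal forward rate k2 and back rate k3; total concentration
fixed at 1.  The RRE is linear, so the trajectory and its parameter
gradient are evaluated in closed form; the numerical path (LSODA,
rtol 1e-8, atol 1e-10) exists for cross-checking and for user-defined
models.

`ngf_a` -- NGF binds TrkA (NGF in excess, free NGF held at the dose);
the TrkA:NGF complex activates Erk phosphorylation on top of a basal rate,
opposed by dephosphorylation.  Absolute TrkA and Erk abundances are
structurally non-identifiable from relative intensities, so the model uses
the identifiable products `kact_T` (activation rate x total TrkA) and
`sErk` (intensity scale x total Erk).  Receptor occupancy is linear with
constant coefficients and is evaluated in closed form; the pErk equation
and its six forward sensitivities are integrated with LSODA in one packed
block-diagonal call per likelihood evaluation.

Hypotheses about protein-abundance differences between subpopulations
(total Erk, total TrkA) are expressed through these products.

## Estimation

* **Transformed parameter space.**  Rates and scales are optimised in
  log10, mixture weights through stick-breaking fractions in logit space:
  positivity and the simplex constraint hold exactly, and steps are
  scale-free.
* **Multi-start L-BFGS-B.**  Latin-hypercube starts across the transformed
  box; bounded L-BFGS-B (`ftol` 1e-11, `gtol` 1e-5, memory 40) from each;
  the best converged start wins, and the fraction of starts within 1e-4 of
  the best log-likelihood is reported as a convergence diagnostic.  For
  large model grids an optional two-stage schedule (`refine_top`) runs a
  short optimisation from every start and polishes only the best few
  endpoints; the selection studies shipped here use 20 starts with the top
  5 polished.
* **Gradients.**  Analytic end to end: trajectory sensitivities (closed
  form or forward sensitivities) chained through the mixture
  responsibilities and the stick-breaking/ log transforms.  A
  finite-difference fallback covers pathway models that provide no
  sensitivities; agreement between the two is a unit-tested invariant
  (relative 1e-4).
* **Default bounds** (configurable): rates 1e-3 .. 1e3 (1/time), weight
  fractions 1e-3 .. 1-1e-3, normal sd 1e-4 .. 10 x data range, log-sd
  1e-3 .. 10.
* **Label switching.**  Subpopulations are only identifiable up to
  permutation; fitted vectors are canonicalised so subpopulation 1 carries
  the smaller value of the first specific parameter.

## Uncertainty: profile likelihoods

The profile of a parameter re-maximises the likelihood over all other
parameters while stepping the parameter away from its MLE in the
transformed space, warm-starting each re-optimisation from its neighbour.
The step adapts to a target profile drop of 0.1 per step (clipped to
[1e-4, 0.5] log10 units, with retry-and-halve on overshoot) and the walk
stops beyond the 99% chi-square(1) threshold or at a bound.  Confidence
intervals collect the region where 2*(l_hat - PL) stays below the
chi-square quantile; endpoints are interpolated on the sqrt(2*delta)
scale, which is exact for quadratic profiles.  A side that reaches its
bound before crossing the threshold is flagged unbounded -- the
operational definition of practical non-identifiability.

## Model selection

BIC = -2 l + n_par * ln(n_obs) with n_obs the total number of single-cell
measurements pooled over snapshots (this convention reproduces the
reference tables of both studies exactly); AIC analogously with penalty
2 * n_par.  Models are ranked by BIC; the best is "optimal", a model more
than 10 BIC units worse is "rejected" (decisive evidence on the
Kass-Raftery scale), anything between is "not rejected".  The threshold is
configurable.

## Synthetic data: the ensemble generator

The generator implements the hierarchical single-cell model the inference
is meant to approximate: each cell draws kinetic parameters from its
subpopulation's log-normal distributions (given per-parameter median and
CV), starts at the pre-stimulus steady state, receives a step stimulus at
t = 0 and is integrated individually; fresh cells are drawn at every
snapshot (destructive measurement, no tracking).  True labels, weights and
median trajectories go to a manifest used only for evaluation.

Shipped presets (package conventions, fixed once):

* `conversion-scenario1` / `-scenario2`: times {0, 0.5, 1, 2, 3, 4} at
  u = 1, 1,000 cells per snapshot; medians k2 = 0.05, k3 = 0.1 in both
  subpopulations; k1 median 0.02 (70% of cells) vs 2.0 (30%); parameter
  CV 5% (scenario 1: homogeneous, separating subpopulations) or 40%
  (scenario 2: heterogeneous, strongly overlapping).
* `ngf-two-subpop`: model `ngf_a`, kinetic times {0, 1, 5, 15, 30, 60} min
  at 1 nM plus doses {0.05, 0.2, 0.8, 5, 25} nM at 30 min (11 snapshots,
  500 cells each); shared medians kon = 0.2 /(nM min), koff = 0.2 /min,
  kbasal = 0.01 /min, kdephos = 0.1 /min, sErk = 10; kact_T median
  0.005 /min (70%) vs 0.15 /min (30%) -- a 30-fold receptor-abundance
  difference; CV 15% throughout.  Rates were chosen so the responsive
  subpopulation rises ~5-fold with a ~10-15 min rise time and the dose
  response saturates above ~1 nM.

What the generator does *not* emulate: intrinsic (molecule-number) noise,
cell-cycle or size covariates, replicate-to-replicate normalisation
artefacts, cell-type transitions, and measurement background.  Passing
recovery tests on these data therefore demonstrates correctness of the
inference machinery under parameter-heterogeneity-driven variability, not
robustness to every noise source in real microscopy data.

## What the estimates mean

The component location tracks the *distribution* of the observable across
cells, so fitted kinetic parameters estimate effective subpopulation
averages, not any single cell's rates.  On scenario-1-style data the
subpopulation-average parameters lie inside the 95% profile CIs in ~95% of
replicates per parameter; with strongly overlapping subpopulations
(scenario 2) the weight estimate degrades gracefully (a few percentage
points at 1,000 cells per snapshot) while the hypothesis ranking remains
correct.

A deliberately exposed phenomenon: on two-subpopulation data the
*more complex* two-subpopulation model has better-determined kinetic
parameters than the one-subpopulation model, because only the flexible
model can exploit the distribution shape; the rigid model leaves receptor
kinetics (kon, koff) practically non-identifiable.

## Numerical choices

* LSODA everywhere (stiff-capable); rtol 1e-8 / atol 1e-10.
* Likelihood evaluation pools all cells into one flat vector; per-snapshot
  aggregation of the gradient uses bincount.  One evaluation with gradient
  on 6,000 cells costs ~1.5 ms (conversion) / ~4 ms (NGF).
* Infeasible points (ODE failure, non-positive log-normal location) yield
  -inf, mapped to a large finite penalty inside the optimiser.
* BIC ties at rank 1 keep stable input order and emit a warning.
* EM for the unconstrained 2-D co-labelling mixture: k-means seeding from
  a fixed seed, full covariances with a small diagonal ridge on
  degeneracy, monotone log-likelihood trajectory recorded per iteration.

## Problem sizes used in the shipped studies

Selection studies run 12 (conversion) or 9 (NGF) models at 20 starts per
model with the top 5 polished; recovery studies use 20 replicates of 1,000
cells x 6 snapshots; the NGF-like study uses 500 cells x 11 snapshots with
8 starts (top 3 polished).  These sizes reproduce the qualitative and
quantitative behaviour stably and are the package's default
recommendations for comparable data volumes.

## Limitations

* Constraints link the ODE to component means/medians only; variance
  constraints (linear-noise approximation, moment equations) are not
  implemented.
* Subpopulation weights are constant over time and conditions; systems
  with stimulus-induced subpopulation transitions are out of scope.
* Skew-normal/t families are not implemented; `DistributionAssumption`
  is the extension point.
* The MATLAB `.mat` snapshot reader is a best-effort convenience for one
  common struct layout; TSV/CSV is the supported format.
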