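"""Joint ODE-MM log-likelihood and multi-start maximum-likelihood fitting.

All snapshots -- every time point of every experimental condition -- enter
one joint log-likelihood: for each condition the subpopulation ODEs are
simulated once over the times measured there, the resulting observables pin
the mixture component locations, and every cell contributes the log of the
mixture density at its measured value.  Maximisation uses multi-start local
optimisation: Latin-hypercube starting points in the optimiser's
transformed space (log10 for rates and scales, logit for the
stick-breaking weight fractions), gradient-based bounded L-BFGS-B from each
start, results sorted by log-likelihood.

Gradients are analytic end to end when the pathway model provides
trajectory sensitivities (both shipped models do: closed form for the
conversion process, forward sensitivities for the NGF model); otherwise
L-BFGS-B falls back to finite differences.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, logit
from scipy.stats import qmc

from .data import SnapshotDataset
from .factory import OdemmSpec
from .pathway import SimulationError, ngfA_solution_batch, simulate

__all__ = [
    "LikelihoodContext",
    "FitResult",
    "StartRecord",
    "log_likelihood",
    "fit_multistart",
    "OdeMixtureModel",
]

_LOG_2PI = float(np.log(2.0 * np.pi))
_PENALTY = 1e12


# ---------------------------------------------------------------------------
# transforms between natural and optimiser space
# ---------------------------------------------------------------------------


def to_internal(theta, transforms):
    theta = np.asarray(theta, dtype=float)
    z = np.empty_like(theta)
    for i, tr in enumerate(transforms):
        z[i] = logit(theta[i]) if tr == "logit" else np.log10(theta[i])
    return z


def from_internal(z, transforms):
    z = np.asarray(z, dtype=float)
    theta = np.empty_like(z)
    for i, tr in enumerate(transforms):
        theta[i] = expit(z[i]) if tr == "logit" else 10.0 ** z[i]
    return theta


def _dtheta_dz(theta, transforms):
    theta = np.asarray(theta, dtype=float)
    out = np.empty_like(theta)
    for i, tr in enumerate(transforms):
        out[i] = theta[i] * (1.0 - theta[i]) if tr == "logit" else theta[i] * np.log(10.0)
    return out


# ---------------------------------------------------------------------------
# likelihood context: data layout precomputed once per (spec, data)
# ---------------------------------------------------------------------------


class LikelihoodContext:
    """Precomputed pairing of an :class:`OdemmSpec` with a dataset."""

    def __init__(self, spec: OdemmSpec, data: SnapshotDataset):
        data.check_design(spec.design)
        if spec.assumption.family == "log-normal":
            data.check_positive()
        self.spec = spec
        self.model = spec.pathway
        design = spec.design
        self.y = [data.values(c, t) for c, t in design.snapshots]
        self.logy = ([np.log(y) for y in self.y]
                     if spec.assumption.family == "log-normal" else None)
        snap_index = {s: k for k, s in enumerate(design.snapshots)}
        self.groups = []
        for cond_id, times in design.by_condition().items():
            idx = np.array([snap_index[(cond_id, t)] for t in times])
            self.groups.append((cond_id, design.conditions[cond_id], times, idx))
        self.n_obs = int(sum(y.size for y in self.y))
        rng = data.all_values()
        self.data_range = float(rng.max() - rng.min()) or 1.0
        # pooled layout: one flat cell vector with its snapshot index, so a
        # likelihood evaluation is a handful of large array operations
        self.ally = np.concatenate(self.y)
        self.snap_of_cell = np.concatenate(
            [np.full(y.size, k, dtype=np.intp) for k, y in enumerate(self.y)])
        self.ally_log = (np.log(self.ally)
                         if spec.assumption.family == "log-normal" else None)

    # -- ODE layer ---------------------------------------------------------
    def locations(self, per_sub, with_grad: bool = False):
        """Component locations per (snapshot, subpopulation).

        Returns ``loc`` of shape (S, n) and, with ``with_grad``, also
        ``dloc`` of shape (S, n, K) where K is the number of kinetic
        parameters in the pathway model's order.
        """
        spec = self.spec
        S, n = spec.design.n_snapshots, spec.n_subpop
        K = len(self.model.kinetic_param_names)
        loc = np.empty((S, n))
        dloc = np.empty((S, n, K)) if with_grad else None

        if self.model.name == "ngf_a":
            param_sets, doses, place = [], [], []
            union = np.unique(np.concatenate([g[2] for g in self.groups]))
            for cond_id, cond, times, idx in self.groups:
                tpos = np.searchsorted(union, times)
                for j in range(n):
                    param_sets.append(per_sub[j])
                    doses.append(float(cond[self.model.stimulus_key]))
                    place.append((idx, j, tpos))
            if with_grad:
                e, de = ngfA_solution_batch(param_sets, doses, union, sens=True)
            else:
                e = ngfA_solution_batch(param_sets, doses, union)
            for row, (idx, j, tpos) in enumerate(place):
                loc[idx, j] = e[row, tpos]
                if with_grad:
                    dloc[idx, j, :] = de[row, tpos, :]
            return (loc, dloc) if with_grad else loc

        for cond_id, cond, times, idx in self.groups:
            for j in range(n):
                if with_grad and self.model.solution_grad is not None:
                    traj, g = self.model.solution_grad(per_sub[j], cond, times)
                    loc[idx, j] = traj
                    dloc[idx, j, :] = g
                else:
                    loc[idx, j] = simulate(self.model, per_sub[j], cond, times,
                                           use_solution=True)
        return (loc, dloc) if with_grad else loc

    # -- mixture layer -----------------------------------------------------
    def _component_stats(self, loc, scales):
        """Per-snapshot component log densities and score factors."""
        spec = self.spec
        fam, stat = spec.assumption.family, spec.assumption.constrained_stat
        if fam == "log-normal" and np.any(loc <= 0):
            return None
        out = []
        for k, y in enumerate(self.y):
            m, s = loc[k], scales[k]
            if fam == "normal":
                z = (y[:, None] - m[None, :]) / s[None, :]
                L = -0.5 * z**2 - np.log(s)[None, :] - 0.5 * _LOG_2PI
            else:
                mu = np.log(m)
                if stat == "mean":
                    mu = mu - 0.5 * s**2
                ly = self.logy[k]
                z = (ly[:, None] - mu[None, :]) / s[None, :]
                L = (-0.5 * z**2 - np.log(s)[None, :] - 0.5 * _LOG_2PI
                     - ly[:, None])
            out.append((L, z))
        return out

    def loglik(self, theta, with_grad: bool = False):
        """Joint log-likelihood (and its gradient w.r.t. packed theta).

        Infeasible points (failed integration, non-finite or non-positive
        locations under a log-normal family) yield -inf, never an
        exception, so optimisers treat them as out of bounds.
        """
        spec = self.spec
        per_sub, weights, scales = spec.unpack(theta)
        n = spec.n_subpop
        try:
            res = self.locations(per_sub, with_grad=with_grad)
        except (SimulationError, ValueError, FloatingPointError, OverflowError):
            return (-np.inf, None) if with_grad else -np.inf
        loc, dloc = res if with_grad else (res, None)
        if not np.all(np.isfinite(loc)):
            return (-np.inf, None) if with_grad else -np.inf
        if spec.assumption.family == "log-normal" and np.any(loc <= 0):
            return (-np.inf, None) if with_grad else -np.inf

        logw = np.log(weights)
        fam, stat = spec.assumption.family, spec.assumption.constrained_stat
        S = spec.design.n_snapshots
        ix = self.snap_of_cell
        logsc = np.log(scales)
        if fam == "normal":
            M = loc[ix]
            SC, LS = scales[ix], logsc[ix]
            z = (self.ally[:, None] - M) / SC
        else:
            mu = np.log(loc)
            if stat == "mean":
                mu = mu - 0.5 * scales**2
            M = mu[ix]
            SC, LS = scales[ix], logsc[ix]
            z = (self.ally_log[:, None] - M) / SC
        L = -0.5 * z**2 - LS - 0.5 * _LOG_2PI
        if fam == "log-normal":
            L = L - self.ally_log[:, None]
        A = L + logw[None, :]
        amax = A.max(axis=1)
        with np.errstate(over="ignore"):
            R = np.exp(A - amax[:, None])
        norm = R.sum(axis=1)
        total = float(amax.sum() + np.log(norm).sum())
        if with_grad:
            R /= norm[:, None]  # responsibilities
            if fam == "normal":
                dm = z / SC                         # dlogphi/dm
                dsig = (z**2 - 1.0) / SC            # dlogphi/dsigma
            else:
                dm = z / (SC * loc[ix])
                dsig = (z**2 - 1.0) / SC
                if stat == "mean":
                    dsig = dsig - z  # extra term from mu = ln m - s^2/2
            gloc = np.empty_like(loc)
            gscale = np.empty_like(scales)
            for j in range(n):
                gloc[:, j] = np.bincount(ix, weights=R[:, j] * dm[:, j],
                                         minlength=S)
                gscale[:, j] = np.bincount(ix, weights=R[:, j] * dsig[:, j],
                                           minlength=S)
            gw = R.sum(axis=0) / weights

        if not np.isfinite(total):
            return (-np.inf, None) if with_grad else -np.inf
        if not with_grad:
            return total

        # chain ODE locations into kinetic-parameter gradients
        names = self.model.kinetic_param_names
        kidx = {p: i for i, p in enumerate(names)}
        grad = np.zeros(spec.n_parameters)
        i = 0
        for p in spec.shared_names:
            grad[i] = float(np.sum(gloc * dloc[:, :, kidx[p]]))
            i += 1
        for p in spec.specific_names:
            for j in range(n):
                grad[i] = float(np.sum(gloc[:, j] * dloc[:, j, kidx[p]]))
                i += 1
        # stick-breaking jacobian: w_j = v_j prod_{i<j}(1 - v_i)
        v = np.asarray(theta[i:i + n - 1], dtype=float)
        for jv in range(n - 1):
            g = gw[jv] * weights[jv] / v[jv]
            g -= np.sum(gw[jv + 1:] * weights[jv + 1:] / (1.0 - v[jv]))
            grad[i] = g
            i += 1
        grad[i:] = gscale.reshape(-1)
        return total, grad


def log_likelihood(spec: OdemmSpec, theta, data: SnapshotDataset) -> float:
    """Joint log-likelihood of a packed parameter vector (Eq.-level API)."""
    return LikelihoodContext(spec, data).loglik(np.asarray(theta, dtype=float))


# ---------------------------------------------------------------------------
# multi-start maximum likelihood
# ---------------------------------------------------------------------------


@dataclass
class StartRecord:
    start: np.ndarray          # starting point, natural space
    theta: np.ndarray | None   # converged point, natural space (canonical)
    loglik: float
    converged: bool
    n_iter: int
    message: str = ""


@dataclass
class FitResult:
    """Best parameter vector with multistart diagnostics."""

    spec_label: str
    theta: np.ndarray
    loglik: float
    starts: list
    seed: int
    bounds: tuple
    convergence_fraction: float
    n_obs: int

    @property
    def n_starts(self) -> int:
        return len(self.starts)

    def to_dict(self) -> dict:
        return {
            "spec": self.spec_label,
            "loglik": float(self.loglik),
            "theta": [float(x) for x in self.theta],
            "seed": int(self.seed),
            "n_starts": self.n_starts,
            "convergence_fraction": float(self.convergence_fraction),
            "n_obs": int(self.n_obs),
            "start_logliks": [float(s.loglik) for s in self.starts],
        }


def _objective(ctx, transforms, analytic):
    if analytic:
        def fun(z):
            theta = from_internal(z, transforms)
            ll, g = ctx.loglik(theta, with_grad=True)
            if not np.isfinite(ll) or g is None or not np.all(np.isfinite(g)):
                return _PENALTY, np.zeros_like(z)
            return -ll, -g * _dtheta_dz(theta, transforms)
        return fun, True

    def fun(z):
        ll = ctx.loglik(from_internal(z, transforms))
        return _PENALTY if not np.isfinite(ll) else -ll
    return fun, None


def minimize_local(ctx, z0, zlb, zub, fixed: Mapping[int, float] | None = None,
                   options: Mapping | None = None):
    """Bounded local optimisation in transformed space.

    ``fixed`` pins coordinates (used by profile likelihoods).  Returns
    ``(z_full, loglik, converged, n_iter, message)``.
    """
    transforms = ctx.spec.transforms()
    analytic = (ctx.model.solution_grad is not None
                or ctx.model.name == "ngf_a")
    fun, jac = _objective(ctx, transforms, analytic)
    opts = {"maxiter": 500, "maxfun": 50000, "ftol": 1e-11, "gtol": 1e-5,
            "maxcor": 40}
    if options:
        opts.update(options)

    fixed = dict(fixed or {})
    free = np.array([i for i in range(z0.size) if i not in fixed], dtype=int)
    z_full = np.array(z0, dtype=float)
    for i, val in fixed.items():
        z_full[i] = val

    if free.size == 0:
        f = fun(z_full)
        ll = -(f[0] if analytic else f)
        return z_full, ll, True, 0, "all parameters fixed"

    def red_fun(zf):
        z = z_full.copy()
        z[free] = zf
        out = fun(z)
        if analytic:
            return out[0], out[1][free]
        return out

    res = minimize(
        red_fun, z_full[free], method="L-BFGS-B",
        jac=True if analytic else None,
        bounds=list(zip(zlb[free], zub[free])), options=opts,
    )
    z_full[free] = res.x
    return (z_full, -float(res.fun), bool(res.success),
            int(getattr(res, "nit", 0)), str(res.message))


def fit_multistart(spec: OdemmSpec, data: SnapshotDataset, n_starts: int = 100,
                   bounds: tuple | None = None, seed: int = 0,
                   local_options: Mapping | None = None,
                   refine_top: int | None = None) -> FitResult:
    """Multi-start MLE: LHS starts, bounded L-BFGS-B, best of all starts.

    ``bounds`` is a ``(lower, upper)`` pair in natural parameter space;
    by default the spec's bounds (scales relative to the data range).  The
    fraction of converged starts within 1e-4 of the best log-likelihood is
    reported as a convergence diagnostic.

    ``refine_top`` enables a two-stage schedule for large model grids: all
    starts first run a short local optimisation, then the ``refine_top``
    best endpoints are polished to full tolerance.  The default (``None``)
    optimises every start to full tolerance.
    """
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    ctx = LikelihoodContext(spec, data)
    if bounds is None:
        bounds = spec.default_bounds(data_range=ctx.data_range)
    lb, ub = (np.asarray(b, dtype=float) for b in bounds)
    transforms = spec.transforms()
    zlb, zub = to_internal(lb, transforms), to_internal(ub, transforms)
    if not (np.all(np.isfinite(zlb)) and np.all(np.isfinite(zub))):
        raise ValueError("bounds must be finite in transformed space")

    sampler = qmc.LatinHypercube(d=spec.n_parameters, seed=seed)
    z_starts = list(zlb + sampler.random(n_starts) * (zub - zlb))

    if refine_top:
        coarse_opts = dict(local_options or {})
        coarse_opts.setdefault("maxiter", 60)
        coarse = []
        for z0 in z_starts:
            try:
                z, ll, *_ = minimize_local(ctx, z0, zlb, zub,
                                           options=coarse_opts)
            except Exception:
                continue
            coarse.append((ll, z, z0))
        coarse.sort(key=lambda p: -p[0] if np.isfinite(p[0]) else np.inf)
        z_starts = [z for _, z, _ in coarse[:max(refine_top, 1)]]

    starts = []
    for z0 in z_starts:
        start_nat = from_internal(z0, transforms)
        try:
            z, ll, ok, nit, msg = minimize_local(ctx, z0, zlb, zub,
                                                 options=local_options)
            theta = spec.canonicalize(from_internal(z, transforms))
        except Exception as exc:  # defensive: a start must never kill the fit
            starts.append(StartRecord(start_nat, None, -np.inf, False, 0, str(exc)))
            continue
        if ll <= -_PENALTY / 2:
            ll, ok = -np.inf, False
        starts.append(StartRecord(start_nat, theta, ll, ok, nit, msg))

    usable = [s for s in starts if s.theta is not None and np.isfinite(s.loglik)]
    if not usable:
        raise RuntimeError(
            "all optimisation starts failed; per-start diagnostics: "
            + "; ".join(s.message for s in starts)
        )
    converged = [s for s in usable if s.converged] or usable
    best = max(converged, key=lambda s: s.loglik)
    n_close = sum(1 for s in converged if best.loglik - s.loglik < 1e-4)
    starts.sort(key=lambda s: -s.loglik if np.isfinite(s.loglik) else np.inf)
    return FitResult(
        spec_label=spec.label,
        theta=best.theta,
        loglik=float(best.loglik),
        starts=starts,
        seed=seed,
        bounds=(lb, ub),
        convergence_fraction=n_close / len(converged),
        n_obs=ctx.n_obs,
    )


# ---------------------------------------------------------------------------
# sklearn-style estimator facade
# ---------------------------------------------------------------------------

from sklearn.base import BaseEstimator  # noqa: E402  (kept near its user)


class OdeMixtureModel(BaseEstimator):
    """ODE-constrained mixture model as a scikit-learn style estimator.

    Parameters mirror :func:`fit_multistart`; ``X`` passed to :meth:`fit`
    may be a :class:`SnapshotDataset` or a tidy DataFrame with columns
    ``condition``, ``time``, a stimulus column and ``value``.  If no
    explicit design is given, it is inferred from the data.

    Fitted attributes: ``spec_``, ``theta_``, ``log_likelihood_``,
    ``result_``, ``weights_``, ``subpopulation_params_``, ``scales_``,
    ``n_parameters_``.
    """

    def __init__(self, pathway="conversion", hypothesis=None, assumption=None,
                 design=None, n_starts: int = 20, seed: int = 0,
                 bounds=None, local_options=None):
        self.pathway = pathway
        self.hypothesis = hypothesis
        self.assumption = assumption
        self.design = design
        self.n_starts = n_starts
        self.seed = seed
        self.bounds = bounds
        self.local_options = local_options

    def _as_dataset(self, X) -> SnapshotDataset:
        if isinstance(X, SnapshotDataset):
            return X
        return SnapshotDataset.from_dataframe(X)

    def _build_spec(self, data: SnapshotDataset) -> OdemmSpec:
        from .factory import ExperimentDesign, build_spec
        from .mixtures import DistributionAssumption
        from .factory import VariabilityHypothesis

        hypothesis = self.hypothesis or VariabilityHypothesis(1)
        assumption = self.assumption or DistributionAssumption("normal", "mean")
        design = self.design
        if design is None:
            design = ExperimentDesign(
                snapshots=tuple(sorted(data.snapshots)),
                conditions=data.conditions,
            )
        return build_spec(self.pathway, hypothesis, assumption, design)

    def fit(self, X, y=None):
        data = self._as_dataset(X)
        self.spec_ = self._build_spec(data)
        self.result_ = fit_multistart(
            self.spec_, data, n_starts=self.n_starts, bounds=self.bounds,
            seed=self.seed, local_options=self.local_options,
        )
        self.theta_ = self.result_.theta
        self.log_likelihood_ = self.result_.loglik
        per_sub, self.weights_, self.scales_ = self.spec_.unpack(self.theta_)
        self.subpopulation_params_ = per_sub
        self.n_parameters_ = self.spec_.n_parameters
        return self

    def score(self, X, y=None):
        """Average per-cell log-likelihood (sklearn convention)."""
        data = self._as_dataset(X)
        ctx = LikelihoodContext(self.spec_, data)
        return ctx.loglik(self.theta_) / ctx.n_obs

    def responsibilities(self, X) -> dict:
        """Per-snapshot posterior subpopulation membership per cell."""
        data = self._as_dataset(X)
        ctx = LikelihoodContext(self.spec_, data)
        per_sub, weights, scales = self.spec_.unpack(self.theta_)
        loc = ctx.locations(per_sub)
        stats = ctx._component_stats(loc, scales)
        out = {}
        for k, (cond, t) in enumerate(self.spec_.design.snapshots):
            A = stats[k][0] + np.log(weights)[None, :]
            A = A - A.max(axis=1, keepdims=True)
            R = np.exp(A)
            out[(cond, t)] = R / R.sum(axis=1, keepdims=True)
        return out
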