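"""Profile likelihoods and likelihood-ratio confidence intervals.

The profile of parameter ``theta_i`` is the log-likelihood re-maximised
over all other parameters while ``theta_i`` is stepped away from its MLE.
Confidence intervals at level ``alpha`` collect the values where twice the
profile drop stays below the chi-square(1 df) quantile.  Profiles are
walked in the optimiser's transformed space (log10/logit) with an adaptive
step targeting a fixed likelihood decrease per step, warm-starting each
re-optimisation from its neighbour, and are reported in natural units.

A profile that reaches a parameter bound before crossing the 99% threshold
marks that side as unbounded: the parameter is practically non-identifiable
in that direction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import chi2

from .likelihood import (FitResult, LikelihoodContext, from_internal,
                         minimize_local, to_internal)

__all__ = ["ProfileResult", "ProfileInterval", "profile_parameter",
           "confidence_interval"]

#: default profile-walking controls
STEP_INIT = 0.05
STEP_MIN, STEP_MAX = 1e-4, 0.5
TARGET_DROP = 0.1
STOP_LEVEL = 0.99
MAX_STEPS = 200


@dataclass
class ProfileInterval:
    lower: float
    upper: float
    lower_unbounded: bool = False
    upper_unbounded: bool = False

    def contains(self, x: float) -> bool:
        lo = -np.inf if self.lower_unbounded else self.lower
        hi = np.inf if self.upper_unbounded else self.upper
        return lo <= x <= hi

    @property
    def bounded(self) -> bool:
        return not (self.lower_unbounded or self.upper_unbounded)


@dataclass
class ProfileResult:
    """Profile grid for one parameter, sorted by parameter value."""

    param: str
    values: np.ndarray          # natural units
    loglik: np.ndarray          # profile log-likelihood at each value
    loglik_hat: float           # global maximum
    mle: float                  # parameter MLE, natural units
    z_values: np.ndarray        # transformed-space grid (for interpolation)
    bound_hit: tuple = (False, False)   # (lower side, upper side)
    flagged: list = field(default_factory=list)  # grid points whose re-opt failed
    nuisance: list = field(default_factory=list)  # re-optimised theta per point

    def two_delta(self) -> np.ndarray:
        return 2.0 * (self.loglik_hat - self.loglik)


def _resolve_param(spec, param):
    if isinstance(param, str):
        try:
            return spec.param_names.index(param)
        except ValueError:
            raise ValueError(
                f"unknown parameter {param!r}; layout: {list(spec.param_names)}"
            ) from None
    return int(param)


def profile_parameter(spec, data, fit: FitResult, param, options=None) -> ProfileResult:
    """Walk the profile likelihood of ``param`` outward from the MLE.

    ``options`` may override ``step_init``, ``max_steps``, ``stop_level``,
    ``target_drop`` and the local optimiser options (``local_options``).
    """
    opts = dict(options or {})
    step_init = float(opts.get("step_init", STEP_INIT))
    max_steps = int(opts.get("max_steps", MAX_STEPS))
    stop_level = float(opts.get("stop_level", STOP_LEVEL))
    target = float(opts.get("target_drop", TARGET_DROP))
    local_options = opts.get("local_options",
                             {"maxiter": 200, "ftol": 1e-12, "gtol": 1e-6})

    ctx = LikelihoodContext(spec, data)
    transforms = spec.transforms()
    lb, ub = fit.bounds
    zlb, zub = to_internal(lb, transforms), to_internal(ub, transforms)
    i = _resolve_param(spec, param)
    z_hat = to_internal(fit.theta, transforms)
    ll_hat = float(fit.loglik)
    stop_2delta = chi2.ppf(stop_level, df=1)

    grid_z, grid_ll, grid_theta, flagged = [z_hat[i]], [ll_hat], [fit.theta.copy()], []

    overshoot = max(5.0 * target, 0.5)
    for direction in (-1.0, +1.0):
        z_curr = z_hat.copy()
        ll_prev = ll_hat
        step = step_init
        for _ in range(max_steps):
            zi = z_curr[i] + direction * step
            hit_bound = False
            if zi <= zlb[i]:
                zi, hit_bound = zlb[i], True
            elif zi >= zub[i]:
                zi, hit_bound = zub[i], True
            z_new, ll, ok, _, msg = minimize_local(
                ctx, z_curr, zlb, zub, fixed={i: zi}, options=local_options)
            if not np.isfinite(ll):
                flagged.append(float(from_internal(np.array([zi]), (transforms[i],))[0]))
                z_curr = z_curr.copy()
                z_curr[i] = zi
                if hit_bound:
                    break
                continue
            drop = ll_prev - ll
            if drop > overshoot and step > STEP_MIN and not hit_bound:
                # too coarse for reliable interpolation: retry shorter step
                step = max(step * 0.25, STEP_MIN)
                continue
            grid_z.append(zi)
            grid_ll.append(ll)
            grid_theta.append(from_internal(z_new, transforms))
            if not ok:
                flagged.append(float(from_internal(np.array([zi]), (transforms[i],))[0]))
            ll_prev = ll
            z_curr = z_new
            if 2.0 * (ll_hat - ll) > stop_2delta or hit_bound:
                break
            # adaptive step: aim for `target` decrease in PL per step
            if drop > 2.0 * target:
                step = max(step * 0.5, STEP_MIN)
            elif drop < 0.5 * target:
                step = min(step * 2.0, STEP_MAX)

    order = np.argsort(grid_z)
    grid_z = np.asarray(grid_z)[order]
    grid_ll = np.asarray(grid_ll)[order]
    thetas = [grid_theta[k] for k in order]
    values = np.array([from_internal(np.array([z]), (transforms[i],))[0]
                       for z in grid_z])
    bound_hit = (
        bool(np.isclose(grid_z[0], zlb[i])
             and 2.0 * (ll_hat - grid_ll[0]) <= stop_2delta),
        bool(np.isclose(grid_z[-1], zub[i])
             and 2.0 * (ll_hat - grid_ll[-1]) <= stop_2delta),
    )
    return ProfileResult(
        param=spec.param_names[i], values=values, loglik=grid_ll,
        loglik_hat=ll_hat, mle=float(fit.theta[i]), z_values=grid_z,
        bound_hit=bound_hit, flagged=flagged, nuisance=thetas,
    )


def confidence_interval(profile: ProfileResult, level: float) -> ProfileInterval:
    """Likelihood-ratio interval {theta_i : 2(l_hat - PL) <= chi2_1(level)}.

    Endpoints are located by linear interpolation of the profile (in the
    transformed space of the grid); a side whose profile never crosses the
    threshold is reported as unbounded there.
    """
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    thr = chi2.ppf(level, df=1)
    td = profile.two_delta()
    z = profile.z_values
    v = profile.values
    k_hat = int(np.argmin(td))

    def _side(idx_range, bound_side):
        """Scan outward; return (endpoint value, unbounded flag)."""
        prev = k_hat
        for k in idx_range:
            if td[k] > thr:
                # interpolate on sqrt(2*delta), which is locally linear in
                # the walked coordinate (exact for quadratic profiles)
                r_prev, r_k = np.sqrt(max(td[prev], 0.0)), np.sqrt(td[k])
                f = (np.sqrt(thr) - r_prev) / (r_k - r_prev)
                z_cross = z[prev] + f * (z[k] - z[prev])
                # back to natural units via the grid's monotone map
                val = np.interp(z_cross, z, v)
                return float(val), False
            prev = k
        return float(v[idx_range[-1]] if len(idx_range) else v[k_hat]), True

    lo_range = list(range(k_hat - 1, -1, -1))
    hi_range = list(range(k_hat + 1, len(td)))
    lower, lo_unb = _side(lo_range, 0)
    upper, hi_unb = _side(hi_range, 1)
    return ProfileInterval(lower=lower, upper=upper,
                           lower_unbounded=lo_unb, upper_unbounded=hi_unb)


def profile_table(profile: ProfileResult):
    """Tidy per-grid-point table (parameter value, PL, 2*(l_hat-PL))."""
    import pandas as pd

    return pd.DataFrame({
        "parameter": profile.param,
        "value": profile.values,
        "profile_loglik": profile.loglik,
        "two_delta": profile.two_delta(),
    })
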