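"""Mixture component families, ODE-constraint mappings and a plain EM fitter.

In an ODE-constrained mixture model the location of each component is not a
free parameter: it is pinned to the observable of a subpopulation's ODE
trajectory.  The ``constraint_map`` translates an ODE observable ``m`` and a
free scale parameter into the native parameters of the chosen family.
Three family/statistic combinations are supported, the ones used in the
shipped selection studies:

* normal, mean constrained: N(mu = m, sd = sigma)
* log-normal, median constrained: logLocation = ln m, logSd = sigma
* log-normal, mean constrained: logLocation = ln m - sigma^2 / 2, so the
  distribution's mean equals m exactly

The scale parameter is the standard deviation for normal components and the
log-standard deviation for log-normal components.

``NormalMixtureEM`` is a small, self-contained EM fitter for unconstrained
1-D/2-D normal mixtures, used to analyse co-labelling data (e.g. pErk vs
total Erk after log transformation) and to assign cells to subpopulations
via responsibilities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp
from sklearn.base import BaseEstimator
from sklearn.cluster import KMeans

__all__ = [
    "DistributionAssumption",
    "ASSUMPTIONS",
    "MixtureDensity",
    "constraint_map",
    "component_logpdf",
    "mixture_logpdf",
    "NormalMixtureEM",
    "em_fit_normal_mixture",
]

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass(frozen=True)
class DistributionAssumption:
    """Component family plus which statistic the ODE constrains."""

    family: str  # "normal" | "log-normal"
    constrained_stat: str  # "mean" | "median"

    _ALLOWED = (("normal", "mean"), ("log-normal", "mean"), ("log-normal", "median"))

    def __post_init__(self):
        if (self.family, self.constrained_stat) not in self._ALLOWED:
            raise ValueError(
                f"unsupported assumption {self.family}+{self.constrained_stat}; "
                f"allowed: {self._ALLOWED}"
            )

    @property
    def label(self) -> str:
        return f"{self.family} {self.constrained_stat}"


#: the three assumptions used throughout the selection studies
ASSUMPTIONS = (
    DistributionAssumption("normal", "mean"),
    DistributionAssumption("log-normal", "mean"),
    DistributionAssumption("log-normal", "median"),
)


def constraint_map(assumption: DistributionAssumption, location, scale):
    """Map (ODE observable, scale) to the family's native parameters.

    Returns ``(loc, scale)`` in the family's native parameterisation:
    (mu, sd) for normal, (log-location, log-sd) for log-normal.  A
    non-positive location under a log-normal family raises ``ValueError``
    (the likelihood converts this into a -inf contribution so optimisers
    treat such parameter points as infeasible).
    """
    location = np.asarray(location, dtype=float)
    scale = np.asarray(scale, dtype=float)
    if np.any(scale <= 0):
        raise ValueError("scale parameter must be positive")
    if assumption.family == "normal":
        return location, scale
    if np.any(location <= 0):
        raise ValueError("log-normal components require a positive location")
    log_loc = np.log(location)
    if assumption.constrained_stat == "mean":
        log_loc = log_loc - 0.5 * scale**2
    return log_loc, scale


def component_logpdf(assumption: DistributionAssumption, location, scale, y):
    """Log density of one constrained component at measurements ``y``.

    Broadcasts over ``y`` and over (location, scale); infeasible
    location/measurement combinations yield -inf instead of raising.
    """
    y = np.asarray(y, dtype=float)
    location = np.asarray(location, dtype=float)
    scale = np.asarray(scale, dtype=float)
    if assumption.family == "normal":
        z = (y - location) / scale
        return -0.5 * z**2 - np.log(scale) - 0.5 * _LOG_2PI
    # log-normal
    out_shape = np.broadcast_shapes(y.shape, location.shape, scale.shape)
    out = np.full(out_shape, -np.inf)
    ok = np.broadcast_to(location > 0, out_shape) & np.broadcast_to(y > 0, out_shape)
    if not np.any(ok):
        return out
    with np.errstate(divide="ignore", invalid="ignore"):
        log_loc = np.where(location > 0, np.log(np.where(location > 0, location, 1.0)), 0.0)
        if assumption.constrained_stat == "mean":
            log_loc = log_loc - 0.5 * scale**2
        ly = np.where(y > 0, np.log(np.where(y > 0, y, 1.0)), 0.0)
        z = (ly - log_loc) / scale
        val = -0.5 * z**2 - np.log(scale) - 0.5 * _LOG_2PI - ly
    out[ok] = np.broadcast_to(val, out_shape)[ok]
    return out


@dataclass
class MixtureDensity:
    """A fully specified mixture: weights plus constrained components."""

    weights: np.ndarray
    components: list  # of (DistributionAssumption, location, scale)

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-12:
            raise ValueError("weights must be non-negative and sum to 1")
        if len(self.components) != w.size:
            raise ValueError("one weight per component required")
        for assumption, loc, scale in self.components:
            if scale <= 0:
                raise ValueError("scale parameters must be positive")
            if assumption.family == "log-normal" and loc <= 0:
                raise ValueError("log-normal component requires positive location")
        self.weights = w

    def logpdf(self, y):
        return mixture_logpdf(self, y)

    def pdf(self, y):
        return np.exp(self.logpdf(y))


def mixture_logpdf(mix: MixtureDensity, y):
    """log sum_s w_s phi_s(y), evaluated with log-sum-exp for stability."""
    y = np.asarray(y, dtype=float)
    comp = np.stack(
        [
            component_logpdf(a, loc, scale, y)
            for (a, loc, scale) in mix.components
        ],
        axis=-1,
    )
    with np.errstate(divide="ignore"):
        logw = np.log(mix.weights)
    return logsumexp(comp + logw, axis=-1)


# ---------------------------------------------------------------------------
# Plain EM for 1-D/2-D normal mixtures (co-labelling validation)
# ---------------------------------------------------------------------------


class NormalMixtureEM(BaseEstimator):
    """EM fitter for an unconstrained mixture of (multivariate) normals.

    Supports 1-D and 2-D data with free (full) covariances per component.
    Initial means come from a k-means seeding with a fixed RNG seed; ties
    are broken by lowest component index.  The per-iteration log-likelihood
    trajectory is stored so the EM monotonicity guarantee can be verified.

    Attributes set by :meth:`fit` carry a trailing underscore:
    ``weights_``, ``means_``, ``covariances_``, ``responsibilities_``,
    ``log_likelihoods_`` (one value per iteration), ``n_iter_``,
    ``converged_``.
    """

    def __init__(self, n_components: int = 2, max_iter: int = 500,
                 tol: float = 1e-8, seed: int = 0, ridge: float = 1e-8):
        self.n_components = n_components
        self.max_iter = max_iter
        self.tol = tol
        self.seed = seed
        self.ridge = ridge

    # -- internals ---------------------------------------------------------
    def _log_gauss(self, X, mean, cov):
        d = X.shape[1]
        try:
            chol = np.linalg.cholesky(cov)
        except np.linalg.LinAlgError:
            warnings.warn("singular covariance regularised with a diagonal ridge")
            cov = cov + (self.ridge + 1e-10) * np.trace(cov) / d * np.eye(d)
            chol = np.linalg.cholesky(cov)
        sol = np.linalg.solve(chol, (X - mean).T)
        maha = np.sum(sol**2, axis=0)
        logdet = 2.0 * np.sum(np.log(np.diag(chol)))
        return -0.5 * (maha + logdet + d * _LOG_2PI)

    def _e_step(self, X):
        logp = np.stack(
            [
                np.log(self.weights_[k]) + self._log_gauss(X, self.means_[k],
                                                           self.covariances_[k])
                for k in range(self.n_components)
            ],
            axis=1,
        )
        norm = logsumexp(logp, axis=1, keepdims=True)
        return np.exp(logp - norm), float(norm.sum())

    # -- sklearn API -------------------------------------------------------
    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        n, d = X.shape
        if d not in (1, 2):
            raise ValueError("only 1-D and 2-D data are supported")
        if n <= self.n_components * d:
            raise ValueError("not enough data points for the requested mixture")

        km = KMeans(n_clusters=self.n_components, n_init=5,
                    random_state=self.seed).fit(X)
        # deterministic component order: lowest index = smallest first coord
        order = np.argsort(km.cluster_centers_[:, 0], kind="stable")
        self.means_ = km.cluster_centers_[order].copy()
        labels = np.argsort(order)[km.labels_]
        self.weights_ = np.bincount(labels, minlength=self.n_components) / n
        self.weights_ = np.clip(self.weights_, 1e-6, None)
        self.weights_ /= self.weights_.sum()
        base_cov = np.cov(X.T).reshape(d, d) + self.ridge * np.eye(d)
        self.covariances_ = np.array([base_cov.copy()
                                      for _ in range(self.n_components)])

        self.log_likelihoods_ = []
        self.converged_ = False
        prev = -np.inf
        for it in range(self.max_iter):
            resp, ll = self._e_step(X)
            self.log_likelihoods_.append(ll)
            if ll - prev < self.tol and it > 0:
                self.converged_ = True
                break
            prev = ll
            nk = resp.sum(axis=0)
            self.weights_ = nk / n
            self.means_ = (resp.T @ X) / nk[:, None]
            for k in range(self.n_components):
                diff = X - self.means_[k]
                cov = (resp[:, k][:, None] * diff).T @ diff / nk[k]
                cov += self.ridge * np.trace(base_cov) / d * np.eye(d)
                self.covariances_[k] = cov
        self.responsibilities_, self.log_likelihood_ = self._e_step(X)
        self.n_iter_ = len(self.log_likelihoods_)
        return self

    def predict_proba(self, X):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        return self._e_step(X)[0]

    def predict(self, X):
        return np.argmax(self.predict_proba(X), axis=1)

    def score(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        return self._e_step(X)[1] / X.shape[0]


def em_fit_normal_mixture(data, n_components: int, seed: int = 0,
                          max_iter: int = 500, tol: float = 1e-8):
    """Functional wrapper around :class:`NormalMixtureEM`.

    Returns ``(weights, means, covariances, responsibilities)``.  Use the
    estimator class directly when diagnostics such as the per-iteration
    log-likelihood trajectory are needed.
    """
    est = NormalMixtureEM(n_components=n_components, max_iter=max_iter,
                          tol=tol, seed=seed).fit(data)
    return est.weights_, est.means_, est.covariances_, est.responsibilities_
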