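"""Subpopulation-level ODE pathway models and their measurement maps.

Each subpopulation of cells is described by a reaction rate equation (RRE)
for its average state, a steady-state initial condition at the pre-stimulus
input, a step stimulus applied at t = 0, and an observation map onto the
measured (fluorescence-like) readout.  Two concrete systems ship with the
package:

``conversion``
    A reversible two-species conversion A <-> B with a stimulus-dependent
    forward rate ``k1*u``, a basal forward rate ``k2`` and a back rate
    ``k3``; the total concentration [A] + [B] is conserved (fixed to 1).
    The RRE is linear, so a closed-form solution is available and used as
    the default integration path.

``ngf_a``
    A two-state model of NGF-induced Erk1/2 phosphorylation in sensory
    neurones: NGF binds the receptor TrkA (NGF in excess, so the free NGF
    concentration stays at the applied dose), and the TrkA:NGF complex
    drives Erk phosphorylation on top of a basal rate, opposed by
    dephosphorylation.  Absolute TrkA and Erk abundances are structurally
    non-identifiable, so the model is parameterised by the identifiable
    products ``kact_T`` (induced-phosphorylation rate x total TrkA) and
    ``sErk`` (observation scale x total Erk).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.integrate import odeint, solve_ivp

__all__ = [
    "PathwayModel",
    "ConversionParams",
    "NgfAParams",
    "conversion_rre",
    "conversion_solution",
    "ngfA_rre",
    "ngfA_steady_state",
    "simulate",
    "get_model",
    "MODEL_REGISTRY",
    "SimulationError",
]

#: default integration tolerances (stiff-capable LSODA everywhere)
RTOL = 1e-8
ATOL = 1e-10


class SimulationError(RuntimeError):
    """Raised when the ODE solver fails; carries the offending parameters."""

    def __init__(self, message: str, params=None):
        super().__init__(message)
        self.params = params


@dataclass(frozen=True)
class PathwayModel:
    """Vector field, initial-condition map, input and observation map.

    ``vector_field(x, u, p)`` returns dx/dt for state ``x`` under stimulus
    level ``u`` with kinetic parameters ``p`` (a name -> value mapping).
    ``initial_state(p, condition)`` returns the state at t = 0 (here always
    the pre-stimulus steady state).  ``input_fn(condition, t)`` is the step
    stimulus: 0 for t < 0, the condition's level for t >= 0.
    ``observe(x, p)`` maps a state (or an array of states, last axis =
    state dimension) to the measured scalar.  ``solution``, when present,
    is a closed-form or fast-path trajectory evaluator used by the
    likelihood; it must agree with numerical integration.
    """

    name: str
    state_names: tuple
    kinetic_param_names: tuple
    vector_field: Callable
    initial_state: Callable
    input_fn: Callable
    observe: Callable
    stimulus_key: str = "stimulus"
    solution: Callable | None = None
    solution_grad: Callable | None = None
    default_bounds: Mapping[str, tuple] = field(default_factory=dict)

    @property
    def n_states(self) -> int:
        return len(self.state_names)

    def stimulus_level(self, condition: Mapping) -> float:
        return float(condition[self.stimulus_key])


# ---------------------------------------------------------------------------
# Conversion process A <-> B
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConversionParams:
    """Rates of the reversible conversion; total [A]+[B] conserved."""

    k1: float
    k2: float
    k3: float
    total: float = 1.0

    def __post_init__(self):
        for name in ("k1", "k2", "k3", "total"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")

    def as_dict(self) -> dict:
        return {"k1": self.k1, "k2": self.k2, "k3": self.k3}


def _pdict(p) -> Mapping:
    return p.as_dict() if hasattr(p, "as_dict") else p


def conversion_rre(b, u, p):
    """d[B]/dt = (k1*u + k2) * (total - [B]) - k3 * [B]."""
    q = _pdict(p)
    total = getattr(p, "total", 1.0)
    return (q["k1"] * u + q["k2"]) * (total - b) - q["k3"] * b


def conversion_solution(p, u, b0, t):
    """Closed-form [B](t) under constant stimulus ``u``.

    B(t) = Bss + (B0 - Bss) * exp(-lambda t) with lambda = k1*u + k2 + k3
    and Bss = (k1*u + k2) * total / lambda.
    """
    q = _pdict(p)
    total = getattr(p, "total", 1.0)
    lam = q["k1"] * u + q["k2"] + q["k3"]
    lam = np.asarray(lam, dtype=float)
    if np.any(lam <= 0):
        raise ValueError("k1*u + k2 + k3 must be positive")
    bss = (q["k1"] * u + q["k2"]) * total / lam
    return bss + (np.asarray(b0) - bss) * np.exp(-lam * np.asarray(t, dtype=float))


def _conversion_initial(p, condition):
    q = _pdict(p)
    total = getattr(p, "total", 1.0)
    # steady state at u = 0
    return np.array([q["k2"] * total / (q["k2"] + q["k3"])])


def _conversion_traj(p, condition, times):
    u = float(condition["stimulus"])
    b0 = _conversion_initial(p, condition)[0]
    t = np.asarray(times, dtype=float)
    return conversion_solution(p, u, b0, t)


def _conversion_traj_grad(p, condition, times):
    """Trajectory and its gradient w.r.t. (k1, k2, k3), all closed form."""
    q = _pdict(p)
    u = float(condition["stimulus"])
    k1, k2, k3 = q["k1"], q["k2"], q["k3"]
    total = getattr(p, "total", 1.0)
    t = np.asarray(times, dtype=float)
    lam = k1 * u + k2 + k3
    nu = k1 * u + k2
    bss = nu * total / lam
    b0 = k2 * total / (k2 + k3)
    E = np.exp(-lam * t)
    traj = bss + (b0 - bss) * E

    dlam = np.array([u, 1.0, 1.0])
    dbss = np.array([
        u * (total - bss) / lam,
        (total - bss) / lam,
        -bss / lam,
    ])
    db0 = np.array([
        0.0,
        k3 * total / (k2 + k3) ** 2,
        -k2 * total / (k2 + k3) ** 2,
    ])
    dE = -t[:, None] * E[:, None] * dlam[None, :]
    grad = (dbss[None, :] * (1.0 - E)[:, None]
            + db0[None, :] * E[:, None]
            + (b0 - bss) * dE)
    return traj, grad


CONVERSION = PathwayModel(
    name="conversion",
    state_names=("B",),
    kinetic_param_names=("k1", "k2", "k3"),
    vector_field=lambda x, u, p: np.atleast_1d(conversion_rre(x[0], u, p)),
    initial_state=_conversion_initial,
    input_fn=lambda condition, t: float(condition["stimulus"]) if t >= 0 else 0.0,
    observe=lambda x, p: np.asarray(x)[..., 0],
    stimulus_key="stimulus",
    solution=_conversion_traj,
    solution_grad=_conversion_traj_grad,
    default_bounds={"k1": (1e-3, 1e3), "k2": (1e-3, 1e3), "k3": (1e-3, 1e3)},
)


# ---------------------------------------------------------------------------
# NGF-induced Erk1/2 phosphorylation, pathway model A
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NgfAParams:
    """Reduced (structurally identifiable) kinetic parameters of model A.

    ``kon``/``koff``: TrkA-NGF binding and unbinding; ``kbasal``: basal Erk
    phosphorylation; ``kact_T``: induced phosphorylation rate times total
    TrkA; ``kdephos``: dephosphorylation; ``sErk``: observation scale times
    total Erk (arbitrary intensity units).
    """

    kon: float
    koff: float
    kbasal: float
    kact_T: float
    kdephos: float
    sErk: float

    def __post_init__(self):
        for name in ("kon", "koff", "kbasal", "kact_T", "kdephos", "sErk"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")

    def as_dict(self) -> dict:
        return {n: getattr(self, n) for n in
                ("kon", "koff", "kbasal", "kact_T", "kdephos", "sErk")}


def ngfA_rre(state, dose, p):
    """RRE of model A in the reduced variables (a, e).

    ``a`` is the fraction of TrkA bound to NGF, ``e`` the scaled pErk
    level.  NGF is in large excess over TrkA, so the free NGF concentration
    is held at the applied ``dose``::

        da/dt = kon * dose * (1 - a) - koff * a
        de/dt = (kbasal + kact_T * a) * (sErk - e) - kdephos * e
    """
    if dose < 0:
        raise ValueError("NGF dose must be non-negative")
    q = _pdict(p)
    a, e = state[..., 0], state[..., 1]
    da = q["kon"] * dose * (1.0 - a) - q["koff"] * a
    de = (q["kbasal"] + q["kact_T"] * a) * (q["sErk"] - e) - q["kdephos"] * e
    return np.stack([da, de], axis=-1)


def ngfA_steady_state(dose, p):
    """Algebraic steady state (a, e) at constant ``dose``."""
    q = _pdict(p)
    a = q["kon"] * dose / (q["kon"] * dose + q["koff"]) if dose > 0 else 0.0
    k_up = q["kbasal"] + q["kact_T"] * a
    e = k_up * q["sErk"] / (k_up + q["kdephos"])
    return np.array([a, e])


def _ngf_initial(p, condition):
    # pre-stimulus steady state: no NGF present
    return ngfA_steady_state(0.0, p)


def ngfA_solution_batch(param_sets: Sequence[Mapping], doses: Sequence[float],
                        times, sens: bool = False):
    """Scaled pErk trajectories for many (parameter set, dose) pairs.

    The receptor occupancy ``a(t)`` is linear with constant coefficients
    and is evaluated in closed form; the pErk equation (and, with
    ``sens=True``, its six forward sensitivities) is integrated with LSODA
    in one packed call -- the pairs are independent, so the packed system
    is block diagonal.  Returns ``(n_pairs, n_times)``, or with
    ``sens=True`` a tuple ``(e, de)`` where ``de`` has shape
    ``(n_pairs, n_times, 6)`` ordered as the model's kinetic parameters
    (kon, koff, kbasal, kact_T, kdephos, sErk).
    """
    times = np.asarray(times, dtype=float)
    if isinstance(param_sets, Mapping):  # arrays of per-cell parameters
        kon = np.asarray(param_sets["kon"], dtype=float)
        koff = np.asarray(param_sets["koff"], dtype=float)
        kb = np.asarray(param_sets["kbasal"], dtype=float)
        ka = np.asarray(param_sets["kact_T"], dtype=float)
        kd = np.asarray(param_sets["kdephos"], dtype=float)
        se = np.asarray(param_sets["sErk"], dtype=float)
        n = kon.size
    else:
        n = len(param_sets)
        kon = np.array([q["kon"] for q in param_sets], dtype=float)
        koff = np.array([q["koff"] for q in param_sets], dtype=float)
        kb = np.array([q["kbasal"] for q in param_sets], dtype=float)
        ka = np.array([q["kact_T"] for q in param_sets], dtype=float)
        kd = np.array([q["kdephos"] for q in param_sets], dtype=float)
        se = np.array([q["sErk"] for q in param_sets], dtype=float)
    d = np.asarray(doses, dtype=float)
    if np.any(d < 0):
        raise ValueError("NGF dose must be non-negative")

    lam_a = kon * d + koff
    a_ss = kon * d / lam_a
    e0 = kb * se / (kb + kd)

    tgrid = times
    prepend = False
    if tgrid.size == 0 or tgrid[0] > 0.0:
        tgrid = np.concatenate([[0.0], tgrid])
        prepend = True

    if not sens:
        def rhs(e, t):
            a = a_ss * (1.0 - np.exp(-lam_a * t))
            return (kb + ka * a) * (se - e) - kd * e

        with np.errstate(all="ignore"):
            sol = odeint(rhs, e0, tgrid, rtol=RTOL, atol=ATOL, mxstep=10000)
        e = sol.T
        return e[:, 1:] if prepend else e

    dass_dkon = d * koff / lam_a**2
    dass_dkoff = -kon * d / lam_a**2
    denom0 = (kb + kd) ** 2
    s0 = np.zeros((6, n))
    s0[2] = se * kd / denom0       # d e0 / d kbasal
    s0[4] = -kb * se / denom0      # d e0 / d kdephos
    s0[5] = kb / (kb + kd)         # d e0 / d sErk
    y0 = np.concatenate([e0, s0.ravel()])

    def rhs_sens(y, t):
        e = y[:n]
        s = y[n:].reshape(6, n)
        ea = np.exp(-lam_a * t)
        a = a_ss * (1.0 - ea)
        g = kb + ka * a
        rem = se - e
        da_dkon = dass_dkon * (1.0 - ea) + a_ss * t * ea * d
        da_dkoff = dass_dkoff * (1.0 - ea) + a_ss * t * ea
        de = g * rem - kd * e
        ds = -(g + kd) * s + np.stack([
            ka * rem * da_dkon,
            ka * rem * da_dkoff,
            rem,
            a * rem,
            -e,
            g,
        ])
        return np.concatenate([de, ds.ravel()])

    with np.errstate(all="ignore"):
        sol = odeint(rhs_sens, y0, tgrid, rtol=RTOL, atol=ATOL, mxstep=10000)
    e = sol[:, :n].T
    de = sol[:, n:].reshape(tgrid.size, 6, n).transpose(2, 0, 1)
    if prepend:
        e, de = e[:, 1:], de[:, 1:, :]
    return e, de


def _ngf_traj(p, condition, times):
    q = _pdict(p)
    return ngfA_solution_batch([q], [float(condition["dose"])], times)[0]


def _ngf_traj_grad(p, condition, times):
    q = _pdict(p)
    e, de = ngfA_solution_batch([q], [float(condition["dose"])], times, sens=True)
    return e[0], de[0]


NGF_A = PathwayModel(
    name="ngf_a",
    state_names=("a", "e"),
    kinetic_param_names=("kon", "koff", "kbasal", "kact_T", "kdephos", "sErk"),
    vector_field=lambda x, u, p: ngfA_rre(np.asarray(x), u, p),
    initial_state=_ngf_initial,
    input_fn=lambda condition, t: float(condition["dose"]) if t >= 0 else 0.0,
    observe=lambda x, p: np.asarray(x)[..., 1],
    stimulus_key="dose",
    solution=_ngf_traj,
    solution_grad=_ngf_traj_grad,
    default_bounds={
        "kon": (1e-3, 1e3), "koff": (1e-3, 1e3), "kbasal": (1e-4, 1e2),
        "kact_T": (1e-3, 1e3), "kdephos": (1e-3, 1e3), "sErk": (1e-2, 1e4),
    },
)


MODEL_REGISTRY: dict[str, PathwayModel] = {
    "conversion": CONVERSION,
    "ngf_a": NGF_A,
}


def get_model(name: str) -> PathwayModel:
    try:
        return MODEL_REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown pathway model {name!r}; available: {sorted(MODEL_REGISTRY)}"
        ) from None


# ---------------------------------------------------------------------------
# Generic numerical simulation
# ---------------------------------------------------------------------------


def simulate(model: PathwayModel, params, condition: Mapping, times,
             rtol: float = RTOL, atol: float = ATOL,
             use_solution: bool = False) -> np.ndarray:
    """Observable trajectory at the requested ``times`` (non-decreasing).

    Starts from the model's steady-state initial condition at the
    pre-stimulus input and applies the condition's step stimulus at t = 0.
    With ``use_solution=True`` the model's closed-form/fast path is used
    when available; the default is the stiff-capable numerical integrator
    so that the two paths can be cross-checked.
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or np.any(np.diff(times) < 0):
        raise ValueError("times must be a non-decreasing 1-D sequence")
    if use_solution and model.solution is not None:
        return np.asarray(model.solution(_pdict(params), condition, times))

    q = _pdict(params)
    u = model.input_fn(condition, 0.0)
    x0 = np.asarray(model.initial_state(q, condition), dtype=float)
    t_span = (0.0, float(times[-1]) if times[-1] > 0 else 1.0)
    sol = solve_ivp(
        lambda t, x: np.asarray(model.vector_field(x, u, q), dtype=float),
        t_span, x0, method="LSODA", t_eval=np.clip(times, 0.0, None),
        rtol=rtol, atol=atol,
    )
    if not sol.success:
        raise SimulationError(
            f"ODE integration failed for model {model.name!r}: {sol.message}",
            params=q,
        )
    return np.asarray(model.observe(sol.y.T, q))
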