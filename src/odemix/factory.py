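"""Assembly of ODE-MM specifications and their free-parameter layout.

An ``OdemmSpec`` is the cross product of a pathway model, a variability
hypothesis (how many subpopulations, and which kinetic parameters differ
between them), a distribution assumption, and an experiment design (the
list of measured snapshots).  The free-parameter vector is laid out as

    shared kinetic | specific kinetic x n_subpop | stick-breaking weight
    fractions (n_subpop - 1) | scales (one per snapshot per component)

which gives ``|shared| + |specific| * n + (n - 1) + S * n`` parameters for
``S`` snapshots.  Scale parameters are snapshot- and component-specific:
within-subpopulation variability is free to change over time and between
conditions.  Mixture weights use a stick-breaking parameterisation so the
simplex constraint is exact with ``n - 1`` free numbers in (0, 1).

Subpopulation labels are only identifiable up to permutation; specs with
two or more subpopulations adopt the convention that subpopulation 1 has
the smaller value of the first subpopulation-specific parameter
(:meth:`OdemmSpec.canonicalize`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .mixtures import ASSUMPTIONS, DistributionAssumption
from .pathway import PathwayModel, get_model

__all__ = [
    "VariabilityHypothesis",
    "ExperimentDesign",
    "OdemmSpec",
    "build_spec",
    "count_parameters",
    "enumerate_models",
]

_WEIGHT_BOUNDS = (1e-3, 1.0 - 1e-3)
_LOGSD_BOUNDS = (1e-3, 1e1)
_NORMAL_SD_REL_BOUNDS = (1e-4, 1e1)  # relative to the data range


@dataclass(frozen=True)
class VariabilityHypothesis:
    """Which kinetic parameters take subpopulation-specific values."""

    n_subpopulations: int
    specific_params: tuple = ()
    name: str | None = None

    def __post_init__(self):
        if self.n_subpopulations < 1:
            raise ValueError("n_subpopulations must be >= 1")
        if self.n_subpopulations == 1 and self.specific_params:
            raise ValueError("a single subpopulation admits no specific parameters")
        if self.n_subpopulations > 1 and not self.specific_params:
            raise ValueError("multi-subpopulation hypotheses need specific parameters")
        object.__setattr__(self, "specific_params", tuple(self.specific_params))

    @property
    def label(self) -> str:
        if self.name:
            return self.name
        return ",".join(self.specific_params) if self.specific_params else "-"


@dataclass(frozen=True)
class ExperimentDesign:
    """Ordered snapshots (condition id, time) plus the condition records."""

    snapshots: tuple  # of (condition_id, time)
    conditions: Mapping[str, Mapping]  # condition_id -> e.g. {"stimulus": 1.0}

    def __post_init__(self):
        snaps = tuple((str(c), float(t)) for c, t in self.snapshots)
        if len(set(snaps)) != len(snaps):
            raise ValueError("snapshots must be unique (shared controls appear once)")
        missing = {c for c, _ in snaps} - set(self.conditions)
        if missing:
            raise ValueError(f"conditions missing for {sorted(missing)}")
        object.__setattr__(self, "snapshots", snaps)
        object.__setattr__(self, "conditions",
                           {k: dict(v) for k, v in self.conditions.items()})

    @property
    def n_snapshots(self) -> int:
        return len(self.snapshots)

    def by_condition(self):
        """Mapping condition_id -> sorted unique times needed there."""
        out: dict[str, list] = {}
        for c, t in self.snapshots:
            out.setdefault(c, []).append(t)
        return {c: np.unique(np.asarray(ts, dtype=float)) for c, ts in out.items()}


@dataclass(frozen=True)
class OdemmSpec:
    """Pathway x hypothesis x distribution assumption x design."""

    pathway: PathwayModel
    hypothesis: VariabilityHypothesis
    assumption: DistributionAssumption
    design: ExperimentDesign
    param_names: tuple = field(init=False)

    def __post_init__(self):
        bad = set(self.hypothesis.specific_params) - set(self.pathway.kinetic_param_names)
        if bad:
            raise ValueError(
                f"unknown specific parameter(s) {sorted(bad)}; valid names: "
                f"{list(self.pathway.kinetic_param_names)}"
            )
        object.__setattr__(self, "param_names", tuple(self._build_names()))

    # -- layout ------------------------------------------------------------
    @property
    def n_subpop(self) -> int:
        return self.hypothesis.n_subpopulations

    @property
    def shared_names(self) -> tuple:
        spec = set(self.hypothesis.specific_params)
        return tuple(p for p in self.pathway.kinetic_param_names if p not in spec)

    @property
    def specific_names(self) -> tuple:
        spec = set(self.hypothesis.specific_params)
        return tuple(p for p in self.pathway.kinetic_param_names if p in spec)

    def _build_names(self):
        names = list(self.shared_names)
        for p in self.specific_names:
            names += [f"{p}[s{j + 1}]" for j in range(self.n_subpop)]
        names += [f"v{j + 1}" for j in range(self.n_subpop - 1)]
        for cond, t in self.design.snapshots:
            names += [
                f"sigma[{cond},t={t:g}][s{j + 1}]" for j in range(self.n_subpop)
            ]
        return names

    @property
    def n_parameters(self) -> int:
        n, s = self.n_subpop, self.design.n_snapshots
        return (len(self.shared_names) + len(self.specific_names) * n
                + (n - 1) + s * n)

    @property
    def label(self) -> str:
        return (f"{self.pathway.name}|m={self.n_subpop}|{self.assumption.label}"
                f"|{self.hypothesis.label}")

    # -- pack / unpack -----------------------------------------------------
    def pack(self, kinetics: Sequence[Mapping], weights, scales) -> np.ndarray:
        """Inverse of :meth:`unpack`; ``kinetics`` is one dict per subpopulation."""
        n = self.n_subpop
        weights = np.asarray(weights, dtype=float)
        scales = np.asarray(scales, dtype=float)
        theta = [kinetics[0][p] for p in self.shared_names]
        for p in self.specific_names:
            theta += [kinetics[j][p] for j in range(n)]
        # stick-breaking fractions from weights
        rest = 1.0
        for j in range(n - 1):
            theta.append(weights[j] / rest)
            rest -= weights[j]
        theta += list(scales.reshape(-1))
        out = np.asarray(theta, dtype=float)
        assert out.size == self.n_parameters
        return out

    def unpack(self, theta):
        """Split a packed vector into (per-subpop kinetics, weights, scales)."""
        theta = np.asarray(theta, dtype=float)
        if theta.size != self.n_parameters:
            raise ValueError(
                f"expected {self.n_parameters} parameters, got {theta.size}"
            )
        n = self.n_subpop
        i = len(self.shared_names)
        shared = dict(zip(self.shared_names, theta[:i]))
        per_sub = [dict(shared) for _ in range(n)]
        for p in self.specific_names:
            for j in range(n):
                per_sub[j][p] = theta[i]
                i += 1
        v = theta[i:i + n - 1]
        i += n - 1
        weights = np.empty(n)
        rest = 1.0
        for j in range(n - 1):
            weights[j] = rest * v[j]
            rest *= 1.0 - v[j]
        weights[n - 1] = rest
        scales = theta[i:].reshape(self.design.n_snapshots, n)
        return per_sub, weights, scales

    def canonicalize(self, theta) -> np.ndarray:
        """Reorder subpopulations so the first specific parameter ascends."""
        if self.n_subpop < 2 or not self.specific_names:
            return np.asarray(theta, dtype=float).copy()
        per_sub, weights, scales = self.unpack(theta)
        key = self.specific_names[0]
        order = np.argsort([q[key] for q in per_sub], kind="stable")
        per_sub = [per_sub[j] for j in order]
        return self.pack(per_sub, weights[order], scales[:, order])

    # -- bounds ------------------------------------------------------------
    def default_bounds(self, data_range: float = 1.0):
        """(lower, upper) arrays in natural parameter space.

        Kinetic bounds come from the pathway model; stick fractions live in
        (0, 1); scale bounds depend on the family (absolute log-sd bounds
        for log-normal, bounds relative to ``data_range`` for normal sd).
        """
        lb, ub = [], []
        kin_bounds = dict(self.pathway.default_bounds)
        for name in self.param_names:
            base = name.split("[")[0]
            if base in kin_bounds:
                lo, hi = kin_bounds[base]
            elif name.startswith("v"):
                lo, hi = _WEIGHT_BOUNDS
            elif name.startswith("sigma"):
                if self.assumption.family == "normal":
                    lo = _NORMAL_SD_REL_BOUNDS[0] * data_range
                    hi = _NORMAL_SD_REL_BOUNDS[1] * data_range
                else:
                    lo, hi = _LOGSD_BOUNDS
            else:  # kinetic parameter without model-specific bounds
                lo, hi = 1e-3, 1e3
            lb.append(lo)
            ub.append(hi)
        return np.asarray(lb), np.asarray(ub)

    def transforms(self):
        """Per-coordinate optimiser transform: 'log10' or 'logit'."""
        return tuple(
            "logit" if name.startswith("v") else "log10"
            for name in self.param_names
        )


def build_spec(pathway, hypothesis, assumption, design) -> OdemmSpec:
    """Assemble an :class:`OdemmSpec`; accepts a registry name for ``pathway``."""
    if isinstance(pathway, str):
        pathway = get_model(pathway)
    return OdemmSpec(pathway=pathway, hypothesis=hypothesis,
                     assumption=assumption, design=design)


def count_parameters(spec: OdemmSpec) -> int:
    return spec.n_parameters


def enumerate_models(pathway, hypotheses, assumptions=ASSUMPTIONS,
                     design=None) -> list:
    """Cartesian product of hypotheses x assumptions, hypothesis-major."""
    if design is None:
        raise ValueError("an ExperimentDesign is required")
    if not hypotheses or not assumptions:
        raise ValueError("hypotheses and assumptions must be non-empty")
    return [
        build_spec(pathway, h, a, design)
        for h in hypotheses
        for a in assumptions
    ]
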