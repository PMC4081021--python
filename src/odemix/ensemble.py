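"""Ensemble (hierarchical) single-cell simulator for synthetic snapshot data.

Each cell draws its kinetic parameters from a subpopulation-specific
log-normal distribution (given per-parameter median and coefficient of
variation), starts from the pre-stimulus steady state, receives a step
stimulus at t = 0 and is integrated individually; the observable is read
off at the snapshot time.  Fresh cells are sampled at every snapshot, as in
destructive assays, so no cell appears at two time points.  Subpopulation
labels are kept in the ground-truth manifest for evaluation only -- they
are never part of the emitted dataset.

Shipped presets (conventions of this package, documented in the methods
note):

``conversion-scenario1`` / ``conversion-scenario2``
    Two subpopulations differing 100-fold in the stimulus-dependent
    conversion rate k1 (medians 0.02 vs 2.0, responsive fraction 0.3);
    k2 = 0.05, k3 = 0.1 shared; snapshot times {0, 0.5, 1, 2, 3, 4} at
    stimulus u = 1; 1,000 cells per snapshot.  Scenario 1 uses CV = 5%
    (homogeneous, non-overlapping subpopulations), scenario 2 CV = 40%
    (heterogeneous, strongly overlapping).

``ngf-two-subpop``
    NGF model A with two subpopulations differing 30-fold in the TrkA
    product ``kact_T`` (responsive fraction 0.3); 6 kinetic times at 1 nM
    plus 5 additional doses at 30 min (11 snapshots), 500 cells each.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .data import SnapshotDataset
from .factory import ExperimentDesign
from .pathway import conversion_solution, get_model, ngfA_solution_batch

__all__ = ["SubpopulationSpec", "EnsembleConfig", "sample_cells",
           "generate_snapshots", "get_preset", "PRESETS"]


def _lognormal_sigma(cv: float) -> float:
    """Log-sd of a log-normal with the given coefficient of variation."""
    return float(np.sqrt(np.log1p(cv**2)))


@dataclass(frozen=True)
class SubpopulationSpec:
    """Weight plus per-parameter (median, CV) of the cell-level distribution."""

    weight: float
    params: dict  # name -> (median, cv)

    def __post_init__(self):
        if not 0 < self.weight <= 1:
            raise ValueError("weight must be in (0, 1]")
        for name, (med, cv) in self.params.items():
            if med <= 0 or cv < 0:
                raise ValueError(f"bad (median, cv) for {name}")


@dataclass(frozen=True)
class EnsembleConfig:
    """Full generative description of one synthetic study."""

    pathway: str
    subpopulations: tuple
    design: ExperimentDesign
    n_cells: int = 1000
    seed: int = 0
    noise_log_sd: float = 0.0
    name: str = ""

    def __post_init__(self):
        w = sum(s.weight for s in self.subpopulations)
        if abs(w - 1.0) > 1e-9:
            raise ValueError("subpopulation weights must sum to 1")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")

    @property
    def weights(self) -> np.ndarray:
        return np.array([s.weight for s in self.subpopulations])


def sample_cells(config: EnsembleConfig, n: int, rng=None):
    """Draw n cells: subpopulation labels and per-cell parameter arrays.

    Labels are ground truth for evaluation only and are never passed to
    inference.  Returns ``(labels, params)`` with ``params`` a mapping
    name -> array of length n.
    """
    rng = np.random.default_rng(rng if rng is not None else config.seed)
    weights = config.weights
    labels = rng.choice(len(weights), size=n, p=weights)
    pnames = list(config.subpopulations[0].params)
    params = {p: np.empty(n) for p in pnames}
    for s, sub in enumerate(config.subpopulations):
        mask = labels == s
        k = int(mask.sum())
        if k == 0:
            continue
        for p in pnames:
            med, cv = sub.params[p]
            if cv == 0:
                params[p][mask] = med
            else:
                sigma = _lognormal_sigma(cv)
                params[p][mask] = med * np.exp(rng.normal(0.0, sigma, size=k))
    return labels, params


def _observe_cells(config: EnsembleConfig, params: dict, condition: dict,
                   time: float) -> np.ndarray:
    """Per-cell observable at one snapshot (vectorised over cells)."""
    if config.pathway == "conversion":
        k2, k3 = params["k2"], params["k3"]
        b0 = k2 / (k2 + k3)
        return conversion_solution(params, float(condition["stimulus"]), b0,
                                   time)
    if config.pathway == "ngf_a":
        n = len(next(iter(params.values())))
        dose = float(condition["dose"])
        e = ngfA_solution_batch(params, np.full(n, dose), np.array([time]))
        return e[:, 0]
    raise ValueError(f"no ensemble fast path for pathway {config.pathway!r}")


def generate_snapshots(config: EnsembleConfig, seed=None):
    """Simulate the study; returns ``(SnapshotDataset, manifest)``.

    The manifest records the generating truth: weights, per-subpopulation
    parameter medians and CVs, the subpopulation trajectories at the median
    parameters, per-snapshot true-label counts and the RNG seed.
    """
    root_seed = config.seed if seed is None else seed
    rng = np.random.default_rng(root_seed)
    model = get_model(config.pathway)
    snapshots = {}
    label_counts = {}
    n_resampled = 0
    for cond_id, time in config.design.snapshots:
        condition = config.design.conditions[cond_id]
        labels, params = sample_cells(config, config.n_cells, rng)
        y = np.asarray(_observe_cells(config, params, condition, time),
                       dtype=float)
        bad = ~np.isfinite(y)
        tries = 0
        while np.any(bad) and tries < 10:
            n_resampled += int(bad.sum())
            labels_r, params_r = sample_cells(config, int(bad.sum()), rng)
            y_r = _observe_cells(config, params_r, condition, time)
            y[bad], labels[bad] = y_r, labels_r
            bad = ~np.isfinite(y)
            tries += 1
        if np.any(bad):
            raise RuntimeError("ensemble simulation kept failing for some cells")
        if config.noise_log_sd > 0:
            y = y * np.exp(rng.normal(0.0, config.noise_log_sd, size=y.size))
        snapshots[(cond_id, time)] = y
        label_counts[f"{cond_id},t={time:g}"] = np.bincount(
            labels, minlength=len(config.subpopulations)).tolist()
    if n_resampled:
        warnings.warn(f"resampled {n_resampled} cells after integration failure")

    dataset = SnapshotDataset(snapshots=snapshots,
                              conditions=dict(config.design.conditions))
    median_trajectories = {}
    for s, sub in enumerate(config.subpopulations):
        med = {p: mc[0] for p, mc in sub.params.items()}
        per_cond = {}
        for cond_id, times in config.design.by_condition().items():
            condition = config.design.conditions[cond_id]
            traj = model.solution(med, condition, times)
            per_cond[cond_id] = {"times": np.asarray(times).tolist(),
                                 "observable": np.asarray(traj).tolist()}
        median_trajectories[f"subpop{s + 1}"] = per_cond
    manifest = {
        "name": config.name,
        "pathway": config.pathway,
        "seed": int(root_seed),
        "n_cells_per_snapshot": int(config.n_cells),
        "noise_log_sd": float(config.noise_log_sd),
        "weights": config.weights.tolist(),
        "subpopulations": [
            {"weight": sub.weight,
             "params": {p: {"median": mc[0], "cv": mc[1]}
                        for p, mc in sub.params.items()}}
            for sub in config.subpopulations
        ],
        "median_trajectories": median_trajectories,
        "true_label_counts": label_counts,
        "n_resampled": int(n_resampled),
    }
    return dataset, manifest


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

CONVERSION_TIMES = (0.0, 0.5, 1.0, 2.0, 3.0, 4.0)

_CONVERSION_DESIGN = ExperimentDesign(
    snapshots=tuple(("stim", t) for t in CONVERSION_TIMES),
    conditions={"stim": {"stimulus": 1.0}},
)


def _conversion_config(cv: float, name: str) -> EnsembleConfig:
    return EnsembleConfig(
        pathway="conversion",
        subpopulations=(
            SubpopulationSpec(weight=0.7, params={
                "k1": (0.02, cv), "k2": (0.05, cv), "k3": (0.1, cv)}),
            SubpopulationSpec(weight=0.3, params={
                "k1": (2.0, cv), "k2": (0.05, cv), "k3": (0.1, cv)}),
        ),
        design=_CONVERSION_DESIGN,
        n_cells=1000,
        name=name,
    )


NGF_KINETIC_TIMES = (0.0, 1.0, 5.0, 15.0, 30.0, 60.0)
NGF_EXTRA_DOSES = (0.05, 0.2, 0.8, 5.0, 25.0)

_NGF_DESIGN = ExperimentDesign(
    snapshots=tuple(("kin", t) for t in NGF_KINETIC_TIMES)
    + tuple((f"dose{d:g}", 30.0) for d in NGF_EXTRA_DOSES),
    conditions={"kin": {"dose": 1.0},
                **{f"dose{d:g}": {"dose": d} for d in NGF_EXTRA_DOSES}},
)

_NGF_SHARED = {"kon": (0.2, 0.15), "koff": (0.2, 0.15),
               "kbasal": (0.01, 0.15), "kdephos": (0.1, 0.15),
               "sErk": (10.0, 0.15)}


def _ngf_config() -> EnsembleConfig:
    return EnsembleConfig(
        pathway="ngf_a",
        subpopulations=(
            SubpopulationSpec(weight=0.7,
                              params={**_NGF_SHARED, "kact_T": (0.005, 0.15)}),
            SubpopulationSpec(weight=0.3,
                              params={**_NGF_SHARED, "kact_T": (0.15, 0.15)}),
        ),
        design=_NGF_DESIGN,
        n_cells=500,
        name="ngf-two-subpop",
    )


PRESETS = {
    "conversion-scenario1": lambda: _conversion_config(0.05, "conversion-scenario1"),
    "conversion-scenario2": lambda: _conversion_config(0.40, "conversion-scenario2"),
    "ngf-two-subpop": _ngf_config,
}


def get_preset(name: str, seed: int | None = None, **overrides) -> EnsembleConfig:
    try:
        config = PRESETS[name]()
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(PRESETS)}"
                       ) from None
    if seed is not None:
        overrides["seed"] = seed
    return replace(config, **overrides) if overrides else config
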