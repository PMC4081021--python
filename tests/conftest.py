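import numpy as np
import pytest

import odemix as ox
from odemix.pathway import PathwayModel

# ---------------------------------------------------------------------------
# Reference selection tables, frozen as inputs.
# Row layout: (m, distribution, constrained stat, specific parameter,
# n_par, loglik / 1e4, BIC / 1e4, decision).  Log-likelihoods are printed to
# four decimals on the 1e4 scale.
# ---------------------------------------------------------------------------

PRINTED_CONVERSION_TABLE = [
    (1, "normal", "mean", "-", 9, 0.9806, -1.9534, "rejected"),
    (1, "log-normal", "mean", "-", 9, 0.9785, -1.9493, "rejected"),
    (1, "log-normal", "median", "-", 9, 0.9785, -1.9492, "rejected"),
    (2, "normal", "mean", "k1", 17, 1.0998, -2.1848, "not rejected"),
    (2, "log-normal", "mean", "k1", 17, 1.1001, -2.1854, "optimal"),
    (2, "log-normal", "median", "k1", 17, 1.1001, -2.1854, "not rejected"),
    (2, "normal", "mean", "k2", 17, 0.9911, -1.9673, "rejected"),
    (2, "log-normal", "mean", "k2", 17, 1.0013, -1.9878, "rejected"),
    (2, "log-normal", "median", "k2", 17, 0.9949, -1.9750, "rejected"),
    (2, "normal", "mean", "k3", 17, 1.0087, -2.0026, "rejected"),
    (2, "log-normal", "mean", "k3", 17, 1.0077, -2.0005, "rejected"),
    (2, "log-normal", "median", "k3", 17, 1.0032, -1.9916, "rejected"),
]
N_OBS_CONVERSION = 6000  # 1,000 cells x 6 time points

PRINTED_NGF_TABLE = [
    (1, "normal", "mean", "-", 17, -5.2890, 10.5955, "rejected"),
    (1, "log-normal", "mean", "-", 17, -3.7659, 7.5495, "rejected"),
    (1, "log-normal", "median", "-", 17, -3.7556, 7.5288, "rejected"),
    (2, "normal", "mean", "Erk0", 30, -4.0348, 8.1006, "rejected"),
    (2, "log-normal", "mean", "Erk0", 30, -3.6482, 7.3274, "rejected"),
    (2, "log-normal", "median", "Erk0", 30, -3.6262, 7.2835, "rejected"),
    (2, "normal", "mean", "TrkA0", 30, -3.9846, 8.0002, "rejected"),
    (2, "log-normal", "mean", "TrkA0", 30, -3.5847, 7.2003, "not rejected"),
    (2, "log-normal", "median", "TrkA0", 30, -3.5846, 7.2001, "optimal"),
]
N_OBS_NGF = 31002  # 18,797 kinetic + 12,205 dose-response cells


@pytest.fixture(scope="session")
def scenario1():
    """Full-size homogeneous-subpopulation conversion dataset (seed 1)."""
    cfg = ox.get_preset("conversion-scenario1", seed=1)
    data, manifest = ox.generate_snapshots(cfg)
    return cfg, data, manifest


@pytest.fixture(scope="session")
def scenario1_small():
    """Down-sampled scenario-1 data for fast unit tests."""
    cfg = ox.get_preset("conversion-scenario1", seed=11, n_cells=200)
    data, manifest = ox.generate_snapshots(cfg)
    return cfg, data, manifest


@pytest.fixture(scope="session")
def h2_spec_factory():
    def make(cfg, family="normal", stat="mean"):
        return ox.build_spec(
            "conversion",
            ox.VariabilityHypothesis(2, ("k1",)),
            ox.DistributionAssumption(family, stat),
            cfg.design,
        )
    return make


def make_constant_model():
    """Pathway stub whose observable equals the single parameter mu.

    Turns the ODE-MM machinery into a plain location-model fit, for which
    closed-form results are available.
    """
    return PathwayModel(
        name="const",
        state_names=("x",),
        kinetic_param_names=("mu",),
        vector_field=lambda x, u, p: np.zeros(1),
        initial_state=lambda p, c: np.array([p["mu"]]),
        input_fn=lambda c, t: 0.0,
        observe=lambda x, p: np.asarray(x)[..., 0],
        solution=lambda p, c, t: np.full(len(t), p["mu"]),
        solution_grad=lambda p, c, t: (np.full(len(t), p["mu"]),
                                       np.ones((len(t), 1))),
        default_bounds={"mu": (1e-2, 1e2)},
    )


@pytest.fixture(scope="session")
def constant_model():
    return make_constant_model()


@pytest.fixture
def gaussian_toy(constant_model):
    """400 N(2, 0.3^2) draws wrapped as a one-snapshot dataset."""
    rng = np.random.default_rng(7)
    y = 2.0 + 0.3 * rng.standard_normal(400)
    data = ox.SnapshotDataset({("c", 0.0): y}, {"c": {"stimulus": 0.0}})
    design = ox.ExperimentDesign(snapshots=(("c", 0.0),),
                                 conditions={"c": {"stimulus": 0.0}})
    spec = ox.build_spec(constant_model, ox.VariabilityHypothesis(1),
                         ox.DistributionAssumption("normal", "mean"), design)
    return spec, data, y
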