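"""Joint likelihood: oracle equivalence, invariances, multistart MLE."""

import numpy as np
import pytest
from scipy import stats

import odemix as ox
from odemix.likelihood import (LikelihoodContext, _dtheta_dz, from_internal,
                               to_internal)

NM = ox.DistributionAssumption("normal", "mean")
LNMED = ox.DistributionAssumption("log-normal", "median")
LNMEAN = ox.DistributionAssumption("log-normal", "mean")


def _feasible_theta(spec, rng):
    theta = np.empty(spec.n_parameters)
    for i, name in enumerate(spec.param_names):
        if name.startswith("v"):
            theta[i] = rng.uniform(0.2, 0.8)
        elif name.startswith("sigma"):
            theta[i] = 10.0 ** rng.uniform(-1.5, -0.5)
        else:
            theta[i] = 10.0 ** rng.uniform(-1.5, 0.5)
    return theta


def _naive_loglik(spec, theta, data):
    """Per-cell loop with scipy distributions -- the brute-force oracle."""
    per_sub, weights, scales = spec.unpack(theta)
    total = 0.0
    for k, (cond_id, t) in enumerate(spec.design.snapshots):
        condition = spec.design.conditions[cond_id]
        locs = [ox.simulate(spec.pathway, per_sub[j], condition,
                            np.array([t]), use_solution=True)[0]
                for j in range(spec.n_subpop)]
        for y in data.values(cond_id, t):
            dens = 0.0
            for j in range(spec.n_subpop):
                m, s = locs[j], scales[k, j]
                if spec.assumption.family == "normal":
                    dens += weights[j] * stats.norm.pdf(y, m, s)
                else:
                    mu = np.log(m)
                    if spec.assumption.constrained_stat == "mean":
                        mu -= 0.5 * s**2
                    dens += weights[j] * stats.lognorm.pdf(y, s,
                                                           scale=np.exp(mu))
            total += np.log(dens)
    return total


@pytest.mark.parametrize("assumption", [NM, LNMEAN, LNMED],
                         ids=["normal-mean", "ln-mean", "ln-median"])
def test_matches_per_cell_oracle(scenario1_small, assumption):
    cfg, data, _ = scenario1_small
    spec = ox.build_spec("conversion", ox.VariabilityHypothesis(2, ("k1",)),
                         assumption, cfg.design)
    rng = np.random.default_rng(0)
    theta = _feasible_theta(spec, rng)
    fast = ox.log_likelihood(spec, theta, data)
    slow = _naive_loglik(spec, theta, data)
    assert fast == pytest.approx(slow, rel=1e-9)


def test_additive_over_duplicated_cells(scenario1_small):
    cfg, data, _ = scenario1_small
    spec = ox.build_spec("conversion", ox.VariabilityHypothesis(2, ("k1",)),
                         NM, cfg.design)
    theta = _feasible_theta(spec, np.random.default_rng(1))
    doubled = ox.SnapshotDataset(
        {k: np.concatenate([v, v]) for k, v in data.snapshots.items()},
        data.conditions)
    assert ox.log_likelihood(spec, theta, doubled) == pytest.approx(
        2 * ox.log_likelihood(spec, theta, data), rel=1e-12)


def test_invariant_under_cell_shuffling(scenario1_small):
    cfg, data, _ = scenario1_small
    spec = ox.build_spec("conversion", ox.VariabilityHypothesis(2, ("k1",)),
                         LNMED, cfg.design)
    theta = _feasible_theta(spec, np.random.default_rng(2))
    rng = np.random.default_rng(3)
    shuffled = ox.SnapshotDataset(
        {k: rng.permutation(v) for k, v in data.snapshots.items()},
        data.conditions)
    assert ox.log_likelihood(spec, theta, shuffled) == pytest.approx(
        ox.log_likelihood(spec, theta, data), rel=1e-14)


def test_invariant_under_canonicalization(scenario1_small):
    cfg, data, _ = scenario1_small
    spec = ox.build_spec("conversion", ox.VariabilityHypothesis(2, ("k1",)),
                         NM, cfg.design)
    theta = _feasible_theta(spec, np.random.default_rng(4))
    assert ox.log_likelihood(spec, spec.canonicalize(theta), data) == \
        pytest.approx(ox.log_likelihood(spec, theta, data), rel=1e-12)


def test_true_parameters_beat_perturbed_on_average():
    """Monte-Carlo oracle: the generating parameters score higher."""
    wins = 0
    for rep in range(20):
        cfg = ox.get_preset("conversion-scenario1", seed=100 + rep,
                            n_cells=150)
        data, _ = ox.generate_snapshots(cfg)
        spec = ox.build_spec("conversion",
                             ox.VariabilityHypothesis(2, ("k1",)), NM,
                             cfg.design)
        sigma = 0.03  # roughly the within-subpopulation spread of B
        true = spec.pack(
            [{"k1": 0.02, "k2": 0.05, "k3": 0.1},
             {"k1": 2.0, "k2": 0.05, "k3": 0.1}],
            [0.7, 0.3], np.full((6, 2), sigma))
        rng = np.random.default_rng(rep)
        pert = true * np.exp(rng.normal(0, 0.25, true.size))
        iv = [i for i, n in enumerate(spec.param_names) if n.startswith("v")]
        pert[iv] = np.clip(pert[iv], 0.05, 0.95)
        if ox.log_likelihood(spec, true, data) > \
                ox.log_likelihood(spec, pert, data):
            wins += 1
    assert wins >= 15


def test_gradient_matches_finite_differences(scenario1_small):
    cfg, data, _ = scenario1_small
    rng = np.random.default_rng(5)
    for assumption in (NM, LNMEAN, LNMED):
        spec = ox.build_spec("conversion",
                             ox.VariabilityHypothesis(2, ("k1",)),
                             assumption, cfg.design)
        ctx = LikelihoodContext(spec, data)
        tr = spec.transforms()
        checked = 0
        while checked < 10:
            theta = _feasible_theta(spec, rng)
            ll, g = ctx.loglik(theta, with_grad=True)
            if not np.isfinite(ll):
                continue
            z = to_internal(theta, tr)
            gz = g * _dtheta_dz(theta, tr)
            for i in rng.choice(spec.n_parameters, size=4, replace=False):
                e = np.zeros_like(z)
                e[i] = 1e-6
                fd = (ctx.loglik(from_internal(z + e, tr))
                      - ctx.loglik(from_internal(z - e, tr))) / 2e-6
                assert gz[i] == pytest.approx(fd, rel=1e-4, abs=1e-6)
            checked += 1


def test_infeasible_points_give_minus_infinity(scenario1_small):
    cfg, data, _ = scenario1_small
    spec = ox.build_spec("conversion", ox.VariabilityHypothesis(1), LNMED,
                         cfg.design)
    theta = _feasible_theta(spec, np.random.default_rng(6))
    bad = ox.SnapshotDataset(
        {k: (v if i else np.append(v, -1.0))
         for i, (k, v) in enumerate(sorted(data.snapshots.items()))},
        data.conditions)
    with pytest.raises(ValueError):
        ox.log_likelihood(spec, theta, bad)


class TestFitMultistart:
    def test_convex_toy_all_starts_converge(self, gaussian_toy):
        spec, data, y = gaussian_toy
        fit = ox.fit_multistart(spec, data, n_starts=6, seed=0)
        assert fit.theta[0] == pytest.approx(y.mean(), abs=1e-6)
        assert fit.convergence_fraction == 1.0
        # scale MLE is the (biased) sample sd
        assert fit.theta[1] == pytest.approx(y.std(), rel=1e-4)

    def test_respects_bounds(self, scenario1_small):
        cfg, data, _ = scenario1_small
        spec = ox.build_spec("conversion",
                             ox.VariabilityHypothesis(2, ("k1",)), NM,
                             cfg.design)
        fit = ox.fit_multistart(spec, data, n_starts=3, seed=2,
                                local_options={"maxiter": 40})
        lb, ub = fit.bounds
        assert np.all(fit.theta >= lb - 1e-12)
        assert np.all(fit.theta <= ub + 1e-12)

    def test_best_is_max_over_starts(self, scenario1_small):
        cfg, data, _ = scenario1_small
        spec = ox.build_spec("conversion",
                             ox.VariabilityHypothesis(2, ("k1",)), NM,
                             cfg.design)
        fit = ox.fit_multistart(spec, data, n_starts=5, seed=3)
        lls = [s.loglik for s in fit.starts if s.converged]
        assert lls, "no start converged"
        assert fit.loglik == pytest.approx(max(lls))

    def test_seed_stability_of_best_loglik(self, scenario1):
        cfg, data, _ = scenario1
        spec = ox.build_spec("conversion",
                             ox.VariabilityHypothesis(2, ("k1",)), NM,
                             cfg.design)
        fits = [ox.fit_multistart(spec, data, n_starts=50, seed=s,
                                  refine_top=6) for s in (0, 1)]
        assert fits[0].loglik == pytest.approx(fits[1].loglik, abs=1e-3)

    def test_subpopulation_means_recovered(self, scenario1):
        """Estimated subpopulation locations track the true trajectories."""
        cfg, data, manifest = scenario1
        spec = ox.build_spec("conversion",
                             ox.VariabilityHypothesis(2, ("k1",)), NM,
                             cfg.design)
        fit = ox.fit_multistart(spec, data, n_starts=10, seed=4, refine_top=4)
        ctx = LikelihoodContext(spec, data)
        per_sub, weights, _ = spec.unpack(fit.theta)
        loc = ctx.locations(per_sub)
        truth = np.column_stack([
            manifest["median_trajectories"][f"subpop{j + 1}"]["stim"]["observable"]
            for j in range(2)])
        assert np.max(np.abs(loc - truth) / truth) < 0.05
        assert weights[1] == pytest.approx(0.3, abs=0.05)


class TestEstimatorFacade:
    def test_sklearn_protocol(self, scenario1_small):
        from sklearn.base import clone

        cfg, data, _ = scenario1_small
        est = ox.OdeMixtureModel(
            pathway="conversion",
            hypothesis=ox.VariabilityHypothesis(2, ("k1",)),
            assumption=NM, n_starts=4, seed=0,
            local_options={"maxiter": 80})
        est2 = clone(est)
        assert est2.get_params()["n_starts"] == 4
        est.fit(data)
        assert hasattr(est, "theta_") and hasattr(est, "log_likelihood_")
        assert est.n_parameters_ == 17
        assert est.weights_.sum() == pytest.approx(1.0)
        score = est.score(data)
        assert score == pytest.approx(est.log_likelihood_ / data.n_cells)

    def test_fit_accepts_tidy_dataframe(self, scenario1_small):
        cfg, data, _ = scenario1_small
        df = data.to_dataframe()
        est = ox.OdeMixtureModel(pathway="conversion", n_starts=2, seed=0,
                                 local_options={"maxiter": 30}).fit(df)
        assert est.spec_.design.n_snapshots == 6

    def test_responsibilities_sum_to_one(self, scenario1_small):
        cfg, data, _ = scenario1_small
        est = ox.OdeMixtureModel(
            pathway="conversion",
            hypothesis=ox.VariabilityHypothesis(2, ("k1",)),
            assumption=NM, n_starts=3, seed=1,
            local_options={"maxiter": 60}).fit(data)
        resp = est.responsibilities(data)
        for (cond, t), R in resp.items():
            assert R.shape == (data.values(cond, t).size, 2)
            assert np.allclose(R.sum(axis=1), 1.0)
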