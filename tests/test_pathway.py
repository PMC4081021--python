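"""Pathway models: closed forms, numerical integration, steady states."""

import numpy as np
import pytest

import odemix as ox
from odemix.pathway import (CONVERSION, NGF_A, ngfA_solution_batch,
                            ngfA_steady_state)


class TestConversionRre:
    def test_steady_state_is_fixed_point(self):
        p = ox.ConversionParams(k1=2.0, k2=0.05, k3=0.1)
        b_ss = p.k2 / (p.k2 + p.k3)
        assert ox.conversion_rre(b_ss, 0.0, p) == pytest.approx(0.0, abs=1e-15)

    def test_rate_arithmetic(self):
        p = ox.ConversionParams(k1=2.0, k2=0.05, k3=0.1)
        expected = 2.05 * (2.0 / 3.0) - 0.1 / 3.0
        assert ox.conversion_rre(1.0 / 3.0, 1.0, p) == pytest.approx(expected)
        assert expected == pytest.approx(4.0 / 3.0, abs=1e-12)

    def test_pure_decay_limit(self):
        # unstimulated, no basal production: exponential decay of B
        p = {"k1": 1.0, "k2": 0.0, "k3": 0.5}
        assert ox.conversion_rre(0.4, 0.0, p) == pytest.approx(-0.5 * 0.4)

    def test_invalid_rates_rejected(self):
        with pytest.raises(ValueError):
            ox.ConversionParams(k1=-1.0, k2=0.05, k3=0.1)


class TestConversionSolution:
    def test_initial_condition(self):
        p = ox.ConversionParams(k1=2.0, k2=0.05, k3=0.1)
        assert ox.conversion_solution(p, 1.0, 0.25, 0.0) == pytest.approx(0.25)

    def test_steady_state_fixed_point(self):
        p = ox.ConversionParams(k1=2.0, k2=0.05, k3=0.1)
        lam = p.k1 + p.k2 + p.k3
        bss = (p.k1 + p.k2) / lam
        for t in (0.0, 0.3, 5.0):
            assert ox.conversion_solution(p, 1.0, bss, t) == pytest.approx(bss)

    def test_frozen_value(self):
        p = ox.ConversionParams(k1=2.0, k2=0.05, k3=0.1)
        assert ox.conversion_solution(p, 1.0, 1.0 / 3.0, 1.0) == pytest.approx(
            0.88125, abs=5e-5)

    def test_numeric_agreement_random_draws(self):
        # closed form against the stiff integrator across 100 random draws
        rng = np.random.default_rng(42)
        times = np.array([0.0, 0.3, 1.0, 2.5, 4.0])
        worst = 0.0
        for _ in range(100):
            k1, k2, k3 = 10.0 ** rng.uniform(-2, 1, size=3)
            p = ox.ConversionParams(k1=k1, k2=k2, k3=k3)
            cond = {"stimulus": float(10.0 ** rng.uniform(-1, 0.5))}
            cf = ox.simulate(CONVERSION, p, cond, times, use_solution=True)
            num = ox.simulate(CONVERSION, p, cond, times, rtol=1e-10,
                              atol=1e-12)
            worst = max(worst, float(np.abs(cf - num).max()))
        assert worst < 1e-8

    def test_mass_conservation(self):
        p = ox.ConversionParams(k1=1.3, k2=0.07, k3=0.2)
        t = np.linspace(0.0, 10.0, 200)
        b = ox.simulate(CONVERSION, p, {"stimulus": 1.0}, t, use_solution=True)
        assert np.all(b >= 0.0) and np.all(b <= p.total + 1e-12)

    def test_degenerate_rate_error(self):
        with pytest.raises(ValueError):
            ox.conversion_solution({"k1": 0.0, "k2": 0.0, "k3": 0.0}, 0.0,
                                   0.5, 1.0)


class TestNgfModel:
    p = ox.NgfAParams(kon=0.2, koff=0.2, kbasal=0.01, kact_T=0.15,
                      kdephos=0.1, sErk=10.0)

    def test_algebraic_steady_state_is_fixed_point(self):
        for dose in (0.0, 1.0, 25.0):
            ss = ngfA_steady_state(dose, self.p)
            deriv = ox.ngfA_rre(ss, dose, self.p)
            assert np.linalg.norm(deriv) < 1e-12

    def test_no_signal_without_receptor_coupling(self):
        # kact_T -> 0 decouples pErk from receptor occupancy
        q = dict(self.p.as_dict(), kact_T=0.0)
        state = np.array([0.8, 3.0])
        de = ox.ngfA_rre(state, 1.0, q)[1]
        de0 = ox.ngfA_rre(np.array([0.0, 3.0]), 1.0, q)[1]
        assert de == pytest.approx(de0)

    def test_binding_saturates_at_large_dose(self):
        assert ngfA_steady_state(1e9, self.p)[0] == pytest.approx(1.0, abs=1e-8)

    def test_negative_dose_rejected(self):
        with pytest.raises(ValueError):
            ox.ngfA_rre(np.array([0.0, 0.0]), -1.0, self.p)

    def test_trajectory_converges_to_steady_state(self):
        times = np.array([0.0, 500.0])
        traj = ox.simulate(NGF_A, self.p, {"dose": 1.0}, times,
                           use_solution=True)
        assert traj[-1] == pytest.approx(ngfA_steady_state(1.0, self.p)[1],
                                         rel=1e-6)

    def test_fast_path_matches_generic_integrator(self):
        times = np.array([0.0, 1.0, 5.0, 15.0, 30.0, 60.0])
        fast = ox.simulate(NGF_A, self.p, {"dose": 1.0}, times,
                           use_solution=True)
        num = ox.simulate(NGF_A, self.p, {"dose": 1.0}, times)
        assert np.abs(fast - num).max() < 1e-6

    def test_monotone_dose_response(self):
        doses = np.array([0.0, 0.05, 0.2, 1.0, 5.0, 25.0, 100.0])
        e_ss = [ngfA_steady_state(d, self.p)[1] for d in doses]
        assert np.all(np.diff(e_ss) >= 0)

    def test_forward_sensitivities_match_finite_differences(self):
        times = np.array([1.0, 10.0, 30.0])
        q = self.p.as_dict()
        e, de = ngfA_solution_batch([q], [1.0], times, sens=True)
        names = NGF_A.kinetic_param_names
        for i, name in enumerate(names):
            h = q[name] * 1e-6
            qp, qm = dict(q), dict(q)
            qp[name] += h
            qm[name] -= h
            ep = ngfA_solution_batch([qp], [1.0], times)[0]
            em = ngfA_solution_batch([qm], [1.0], times)[0]
            fd = (ep - em) / (2 * h)
            assert np.allclose(de[0, :, i], fd, rtol=1e-4, atol=1e-8), name


class TestSimulateContract:
    def test_steady_state_initialisation(self):
        p = ox.ConversionParams(k1=2.0, k2=0.05, k3=0.1)
        x0 = CONVERSION.initial_state(p.as_dict(), {"stimulus": 1.0})
        deriv = CONVERSION.vector_field(x0, 0.0, p.as_dict())
        assert np.linalg.norm(deriv) < 1e-10

    def test_unstimulated_trajectory_is_constant(self):
        p = ox.ConversionParams(k1=2.0, k2=0.05, k3=0.1)
        t = np.linspace(0, 5, 20)
        b = ox.simulate(CONVERSION, p, {"stimulus": 0.0}, t, use_solution=True)
        assert np.ptp(b) < 1e-12

    def test_first_point_equals_initial_observation(self):
        p = ox.ConversionParams(k1=2.0, k2=0.05, k3=0.1)
        t = np.array([0.0, 1.0])
        b = ox.simulate(CONVERSION, p, {"stimulus": 1.0}, t)
        x0 = CONVERSION.initial_state(p.as_dict(), {"stimulus": 1.0})
        assert b[0] == pytest.approx(float(CONVERSION.observe(x0, p.as_dict())))

    def test_decreasing_times_rejected(self):
        p = ox.ConversionParams(k1=2.0, k2=0.05, k3=0.1)
        with pytest.raises(ValueError):
            ox.simulate(CONVERSION, p, {"stimulus": 1.0}, [1.0, 0.5])

    def test_registry_lookup(self):
        assert ox.get_model("conversion") is CONVERSION
        assert ox.get_model("ngf_a") is NGF_A
        with pytest.raises(KeyError):
            ox.get_model("nonexistent")
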