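"""Superposition, threshold solving, and conduction velocities."""

import math

import numpy as np
import pytest

from sdspike import params as P
from sdspike.currents import make_current_model
from sdspike.cable_response import ResponseKernel
from sdspike.propagation import (PropagationProblem, membrane_potential,
                                 node_contributions, threshold_residual,
                                 solve_tsp, velocity, unmyelinated_velocity,
                                 peak_amplitude)


@pytest.fixture(scope="module")
def prob(standard):
    return PropagationProblem(params=standard)


@pytest.fixture(scope="module")
def tsp_standard(prob):
    return solve_tsp(prob).t_sp


class TestSuperposition:
    def test_contributions_sum_to_potential(self, prob, tsp_standard):
        x, t = np.array(30.0), np.array(0.05)
        terms = node_contributions(x, t, prob, tsp_standard)
        total = sum(terms.values())
        assert float(total) == pytest.approx(
            float(membrane_potential(x, t, prob, tsp_standard)), rel=1e-12)

    def test_only_past_nodes_contribute_at_threshold(self, prob, tsp_standard):
        terms = node_contributions(np.array(0.0), np.array(0.0), prob,
                                   tsp_standard)
        assert all(float(terms[n]) == 0.0 for n in range(0, prob.n_nodes + 1))
        assert sum(float(terms[n]) for n in range(-prob.n_nodes, 0)) > 0

    def test_backward_nodes_dominate_rising_phase(self, prob, tsp_standard):
        t = np.array(tsp_standard / 2)
        terms = node_contributions(np.array(0.0), t, prob, tsp_standard)
        backward = sum(float(terms[n]) for n in range(-prob.n_nodes, 0))
        forward = sum(float(terms[n]) for n in range(1, prob.n_nodes + 1))
        assert backward > forward

    def test_single_node_reduction(self, standard):
        p1 = PropagationProblem(params=standard, N=1)
        ker = p1.kernel()
        x, t = np.array(250.0), np.array(0.08)
        one_node = ker.response(np.abs(x), t)
        # with N=1 and neighbours that have not fired, only node 0 counts
        v = membrane_potential(x, t, p1, t_sp=1e6)
        assert float(v) == pytest.approx(float(one_node), rel=1e-12)

    def test_linearity_in_amplitude(self, standard, tsp_standard):
        c = standard.current
        doubled = standard.with_current(make_current_model("D", I0=2 * c.I0,
                                                           tau_m=c.tau_m,
                                                           tau_h=c.tau_h))
        p1 = PropagationProblem(params=standard)
        p2 = PropagationProblem(params=doubled)
        x, t = np.array(50.0), np.array(0.04)
        assert float(membrane_potential(x, t, p2, tsp_standard)) == pytest.approx(
            2 * float(membrane_potential(x, t, p1, tsp_standard)), rel=1e-12)


class TestThresholdResidual:
    def test_limits(self, prob):
        assert threshold_residual(50.0, prob) == pytest.approx(-prob.threshold,
                                                               abs=1e-6)

    def test_continuity(self, prob):
        ts = np.linspace(0.005, 0.05, 200)
        r = np.array([threshold_residual(t, prob) for t in ts])
        assert np.max(np.abs(np.diff(r))) < 2.0  # no jumps for scenario D

    def test_unique_rising_root(self, prob):
        ts = np.geomspace(1e-4, 5.0, 400)
        r = np.array([threshold_residual(t, prob) for t in ts])
        crossings = np.sum(np.diff(np.sign(r)) != 0)
        assert crossings == 2  # up through threshold, later back down

    def test_scenario_B_single_node_shift(self, standard):
        delta = 0.030
        pa = PropagationProblem(params=standard.with_current(
            make_current_model("A", I0=6.6)), N=1, V_thr=10.0)
        pb = PropagationProblem(params=standard.with_current(
            make_current_model("B", I0=6.6, delta=delta)), N=1, V_thr=10.0)
        ta, tb = solve_tsp(pa).t_sp, solve_tsp(pb).t_sp
        assert tb == pytest.approx(ta + delta, abs=1e-9)


class TestSolver:
    def test_residual_tolerance_and_convergence_flag(self, prob):
        res = solve_tsp(prob)
        assert res.converged
        assert abs(res.residual) <= 1e-9
        assert res.t_sp > 0

    def test_tsp_monotone_in_threshold(self, standard):
        tsps = [solve_tsp(PropagationProblem(params=standard, V_thr=v)).t_sp
                for v in (5.0, 10.0, 15.0, 20.0)]
        assert all(b > a for a, b in zip(tsps, tsps[1:]))

    def test_propagation_failure_is_explicit(self, standard):
        res = solve_tsp(PropagationProblem(params=standard, V_thr=500.0))
        assert not res.converged
        assert res.t_sp == math.inf
        assert res.v_corrected == 0.0

    def test_node_count_saturation(self, standard):
        t20 = solve_tsp(PropagationProblem(params=standard, N=20)).t_sp
        t1000 = solve_tsp(PropagationProblem(params=standard, N=1000)).t_sp
        assert abs(t20 - t1000) / t1000 < 5e-3

    def test_scenario_B_single_node_velocity_bound(self, standard):
        # with one contributing node an AP cannot outrun (L+l)/Delta
        delta = 0.030
        pb = PropagationProblem(params=standard.with_current(
            make_current_model("B", I0=6.6, delta=delta)), N=1, V_thr=10.0)
        res = velocity(pb)
        g = standard.geometry
        assert res.v_internode <= (g.L + g.l) / delta / 1e3 + 1e-12

    def test_electrotonic_scaling_invariance(self, standard):
        # rescaling all lengths (node spacing and lam) at fixed kernel
        # amplitude leaves t_sp unchanged, so v scales with the length factor
        base = PropagationProblem(params=standard)
        ker = base.kernel()
        k = 3.0
        ker_scaled = ResponseKernel(tau=ker.tau, lam=k * ker.lam,
                                    R_lambda=ker.R_lambda, beta=ker.beta,
                                    I_node=ker.I_node, model=ker.model)
        spacing = base.node_spacing

        def resp_scaled(x, t):
            return ker_scaled.response(np.asarray(x) / spacing
                                       * (k * spacing), t)

        t_base = solve_tsp(base).t_sp
        t_scaled = solve_tsp(base, response=resp_scaled).t_sp
        assert t_scaled == pytest.approx(t_base, rel=1e-9)


class TestVelocities:
    def test_corrected_velocity_below_internode_velocity(self, prob):
        res = velocity(prob)
        assert res.converged
        assert res.v_node is not None and res.v_node > 0
        assert res.v_corrected < res.v_internode

    def test_velocity_approximately_linear_in_diameter(self, standard):
        ds = np.array([2.0, 4.0, 6.0, 8.0, 10.0])
        vs = np.array([velocity(PropagationProblem(
            params=standard.with_geometry(d=float(d), L=100.0 * float(d)))
        ).v_corrected for d in ds])
        A = np.vstack([ds, np.ones_like(ds)]).T
        coef, *_ = np.linalg.lstsq(A, vs, rcond=None)
        fitted = A @ coef
        r2 = 1 - np.sum((vs - fitted) ** 2) / np.sum((vs - vs.mean()) ** 2)
        assert r2 >= 0.99

    def test_unmyelinated_square_root_scaling(self, standard):
        v1, ok1 = unmyelinated_velocity(1.0, 1.0, standard.constants, 1.0,
                                        standard.current, 15.0)
        v4, ok4 = unmyelinated_velocity(4.0, 1.0, standard.constants, 1.0,
                                        standard.current, 15.0)
        assert ok1 and ok4
        assert v4 / v1 == pytest.approx(2.0, rel=0.10)

    def test_unmyelinated_density_ordering(self, standard):
        v_full, _ = unmyelinated_velocity(1.0, 1.0, standard.constants, 1.0,
                                          standard.current, 15.0,
                                          check_convergence=False)
        v_sparse, _ = unmyelinated_velocity(1.0, 0.1, standard.constants, 1.0,
                                            standard.current, 15.0,
                                            check_convergence=False)
        assert v_sparse < v_full

    def test_unmyelinated_discretisation_converged(self, standard):
        v, ok = unmyelinated_velocity(1.0, 1.0, standard.constants, 1.0,
                                      standard.current, 15.0)
        assert ok  # halving l_disc changes v by < 2%
        with pytest.raises(ValueError):
            unmyelinated_velocity(1.0, 1.5, standard.constants, 1.0,
                                  standard.current, 15.0)

    def test_peak_amplitude_scenario_D(self, standard):
        # scenario D standard: depolarisation tens of mV, finite
        amp = peak_amplitude(PropagationProblem(params=standard))
        assert 30.0 < amp < 150.0
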