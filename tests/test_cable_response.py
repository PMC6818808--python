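"""Green's function and closed-form single-node responses.

The module's master test checks the closed-form erf solution against direct
adaptive quadrature of the convolution integral.
"""

import math

import numpy as np
import pytest
from scipy.integrate import quad

from sdspike import params as P
from sdspike import cable_response as CR
from sdspike.currents import make_current_model
from sdspike.cable_response import ResponseKernel


@pytest.fixture(scope="module")
def cab(standard):
    return standard.cable


class TestGreensFunction:
    def test_spatial_integral(self, cab):
        # integral over x of G(x,t) is exp(-t/tau)/tau (charge conservation
        # up to leak decay); oracle: adaptive quadrature
        for t in (0.01, 0.1, 1.0):
            val, _ = quad(lambda x: CR.greens_function(x, t, cab), -np.inf,
                          np.inf, limit=200)
            assert val == pytest.approx(math.exp(-t / cab.tau) / cab.tau,
                                        rel=1e-9)

    def test_symmetry_and_causality(self, cab):
        x = np.array([10.0, 300.0, 900.0])
        assert np.allclose(CR.greens_function(x, 0.2, cab),
                           CR.greens_function(-x, 0.2, cab))
        assert np.all(CR.greens_function(x, np.array(-0.1), cab) == 0.0)
        assert np.all(CR.greens_function(x, np.array(0.0), cab) == 0.0)

    def test_fast_and_slow_limits(self, cab):
        x = cab.lam
        t_fast = np.linspace(1e-4, cab.tau / 20, 50)
        g, gf = (CR.greens_function(x, t_fast, cab),
                 CR.greens_function_fast(x, t_fast, cab))
        assert np.all(np.abs(gf - g) <= 0.05 * np.abs(gf))
        t_slow = np.linspace(20 * cab.tau, 100 * cab.tau, 50)
        g, gs = (CR.greens_function(x, t_slow, cab),
                 CR.greens_function_slow(x, t_slow, cab))
        assert np.all(np.abs(gs - g) <= 0.05 * np.abs(gs))


class TestStableErfTerm:
    def test_real_argument_has_zero_imaginary_part(self):
        assert CR.stable_erf_term(0.0, 3.0) == pytest.approx(0.0, abs=1e-15)

    def test_against_arbitrary_precision(self, rng):
        mpmath = pytest.importorskip("mpmath")
        mpmath.mp.dps = 50
        # arguments with the structure of the closed-form solution:
        # theta = 2 sqrt(a/b), z = sqrt(a/t) + i sqrt(t/b)
        n_checked = 0
        while n_checked < 100:
            a = 10.0 ** rng.uniform(-4, 1)
            b = 10.0 ** rng.uniform(-3, 1)
            t = 10.0 ** rng.uniform(-4, 1)
            if t / b - a / t > 600.0:
                # the bare term itself exceeds float range there; in the
                # response it is always paired with a stronger decay
                continue
            n_checked += 1
            theta = 2.0 * math.sqrt(a / b)
            z = complex(math.sqrt(a / t), math.sqrt(t / b))
            ours = float(CR.stable_erf_term(theta, z))
            ref = mpmath.im(mpmath.exp(1j * theta)
                            * (mpmath.erf(mpmath.mpc(z.real, z.imag)) - 1))
            ref = float(ref)
            scale = max(abs(ref), 1e-300)
            assert abs(ours - ref) <= 1e-10 * max(scale, 1e-30)

    def test_decay_along_real_axis(self):
        vals = [abs(CR.stable_erf_term(1.0, x)) for x in (2.0, 5.0, 10.0)]
        assert vals[-1] < 1e-40


class TestExponentialResponse:
    def oracle(self, x, t, tau_s, cab):
        a = x * x * cab.tau / (4 * cab.lam ** 2)
        c = 1 / tau_s - 1 / cab.tau
        val, _ = quad(lambda s: math.exp(-a / s + c * s)
                      / math.sqrt(4 * math.pi * cab.tau * s), 0, t, limit=300)
        return math.exp(-t / tau_s) * val

    @pytest.mark.parametrize("tau_s", [0.013, 0.05, 0.2, 2.0])
    def test_closed_form_equals_quadrature(self, cab, tau_s):
        # the module's master test (both fast and slow currents)
        xs = [0.5 * cab.lam, cab.lam, 2 * cab.lam]
        ts = np.linspace(0.01, 5 * cab.tau, 9)
        vals, refs = [], []
        for x in xs:
            for t in ts:
                vals.append(CR._phi_unit(x, t, cab.tau, cab.lam, tau_s))
                refs.append(self.oracle(x, t, tau_s, cab))
        vals, refs = np.array(vals, dtype=float), np.array(refs)
        assert np.max(np.abs(vals - refs)) <= 1e-8 * np.max(np.abs(refs))

    def test_degenerate_time_constant_branch(self, cab):
        x, t = cab.lam, 0.5
        exact = CR._phi_unit(x, t, cab.tau, cab.lam, cab.tau)
        near = CR._phi_unit(x, t, cab.tau, cab.lam, cab.tau * (1 + 1e-9))
        assert exact == pytest.approx(near, rel=1e-5)
        assert exact == pytest.approx(self.oracle(x, t, cab.tau, cab), rel=1e-8)

    def test_short_current_approaches_impulse(self, standard):
        # tau_s -> 0 with the impulse magnitude I0 tau^(3/2) held fixed
        cab = standard.cable
        ker = ResponseKernel.from_parameter_set(
            standard.with_current(make_current_model("A", I0=6.6)))
        tau_s = 1e-5
        scale = cab.tau ** 1.5 / tau_s
        x, t = np.array(150.0), np.array([0.02, 0.05, 0.2])
        delta = CR.response_delta(x, t, ker)
        expo = scale * CR.response_exponential(x, t, ker, tau_s)
        assert np.allclose(expo, delta, rtol=2e-3)

    def test_causality_and_linearity(self, kernel_D):
        t = np.array([-0.5, -1e-9, 0.0])
        assert np.all(kernel_D.response(np.array(100.0), t) == 0.0)
        v1 = kernel_D.response(np.array(120.0), np.array(0.05))
        ker2 = ResponseKernel(tau=kernel_D.tau, lam=kernel_D.lam,
                              R_lambda=kernel_D.R_lambda, beta=kernel_D.beta,
                              I_node=2 * kernel_D.I_node, model=kernel_D.model)
        assert ker2.response(np.array(120.0), np.array(0.05)) == pytest.approx(
            2 * v1, rel=1e-12)

    def test_finite_over_extreme_ranges(self, standard):
        cab = standard.cable
        x = np.geomspace(0.1, 2000 * cab.lam, 40)
        t = np.geomspace(1e-6 * cab.tau, 400 * cab.tau, 40)
        X, T = np.meshgrid(x, t)
        for tau_s in (0.0133, 0.04, 0.468, 5.0):
            v = CR._phi_unit(X, T, cab.tau, cab.lam, tau_s)
            assert np.all(np.isfinite(v))
        ker = ResponseKernel.from_parameter_set(standard)
        assert np.all(np.isfinite(ker.response(X, T)))


class TestDelayedAndMulti:
    def test_delay_shift(self, standard):
        ker = ResponseKernel.from_parameter_set(
            standard.with_current(make_current_model("B", I0=6.6, delta=0.03)))
        t = np.array([0.01, 0.029999])
        assert np.all(CR.response_delayed(np.array(100.0), t, ker, 0.03) == 0.0)
        t2 = np.array([0.05, 0.2])
        assert np.allclose(CR.response_delayed(np.array(100.0), t2, ker, 0.03),
                           CR.response_delta(np.array(100.0), t2 - 0.03, ker))
        assert np.allclose(CR.response_delayed(np.array(100.0), t2, ker, 0.0),
                           CR.response_delta(np.array(100.0), t2, ker))

    def test_single_term_reduction(self, standard):
        m = make_current_model("C", I0=50.0, tau_c=0.1)
        ker = ResponseKernel.from_parameter_set(standard.with_current(m))
        x, t = np.array(150.0), np.array(0.1)
        assert ker.response(x, t) == pytest.approx(
            float(CR.response_exponential(x, t, ker, 0.1)), rel=1e-12)

    def test_sodium_response_nonnegative(self, kernel_D, standard):
        cab = standard.cable
        x = np.linspace(0, 3 * cab.lam, 25)
        t = np.linspace(1e-4, 5 * cab.tau, 40)
        X, T = np.meshgrid(x, t)
        assert np.all(CR.response_multi_exponential(X, T, kernel_D) >= -1e-12)
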