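"""Closed-form voltage responses of the myelinated cable to nodal currents.

The internode is a passive cable with Green's function

    G(x, t) = (4 pi lam^2 tau t)^(-1/2) exp(-x^2 tau/(4 lam^2 t) - t/tau),

and the single-node depolarisation U(x, t) is the convolution of the
cable-bound channel current with G.  For delta currents U is G itself up to a
prefactor; for exponential currents the convolution has a closed form in the
complex error function.  The error-function term is evaluated through the
Faddeeva function w(z) = exp(-z^2) erfc(-iz) so that growing and decaying
exponentials are combined analytically and no overflow can occur.

Sign conventions: tau_hat = (1/tau - 1/tau_s)^(-1) may be negative (slow
currents, tau_s > tau); internally the decay-rate difference
c = 1/tau_s - 1/tau = -1/tau_hat is used and complex arithmetic absorbs the
sign, which reconciles the two opposite tau_hat conventions found in the
scenario solutions and their derivation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.special import erfc, wofz

from .currents import CurrentModel
from .params import (CableParameters, NodeParameters, ParameterSet,
                     DENSITY_TO_NA)

#: below this |1/tau - 1/tau_s| (1/ms) the removable tau_s = tau limit is used
_DEGENERATE_RATE = 1e-12

_SQRT_PI = np.sqrt(np.pi)


def greens_function(x, t, cable: CableParameters):
    """Cable Green's function (1/(um ms)); zero for t <= 0 by causality."""
    x = np.asarray(x, dtype=float)
    t = np.asarray(t, dtype=float)
    x, t = np.broadcast_arrays(x, t)
    out = np.zeros(t.shape)
    pos = t > 0
    tp = t[pos]
    arg = -(x[pos] ** 2) * cable.tau / (4.0 * cable.lam ** 2 * tp) - tp / cable.tau
    out[pos] = np.exp(arg) / np.sqrt(4.0 * np.pi * cable.lam ** 2 * cable.tau * tp)
    return out


def greens_function_fast(x, t, cable: CableParameters):
    """Early-time (t << tau) approximation: leak term dropped."""
    x, t = np.broadcast_arrays(np.asarray(x, float), np.asarray(t, float))
    out = np.zeros(t.shape)
    pos = t > 0
    out[pos] = (np.exp(-(x[pos] ** 2) * cable.tau / (4.0 * cable.lam ** 2 * t[pos]))
                / np.sqrt(4.0 * np.pi * cable.lam ** 2 * cable.tau * t[pos]))
    return out


def greens_function_slow(x, t, cable: CableParameters):
    """Late-time (t >> tau) approximation: diffusive spread term dropped."""
    x, t = np.broadcast_arrays(np.asarray(x, float), np.asarray(t, float))
    out = np.zeros(t.shape)
    pos = t > 0
    out[pos] = (np.exp(-t[pos] / cable.tau)
                / np.sqrt(4.0 * np.pi * cable.lam ** 2 * cable.tau * t[pos]))
    return out


def stable_erf_term(theta, z):
    """Im[exp(i*theta) * (erf(z) - 1)], evaluated without overflow.

    Uses erf(z) - 1 = -exp(-z^2) w(iz), so the oscillatory/growing factor
    exp(i*theta) is combined with exp(-z^2) analytically before either is
    evaluated.
    """
    theta = np.asarray(theta, dtype=complex)
    z = np.asarray(z, dtype=complex)
    return np.imag(-np.exp(1j * theta - z * z) * wofz(1j * z))


@dataclass(frozen=True)
class ResponseKernel:
    """Everything needed to evaluate U(x, t) for one node's current.

    ``pref = R_lambda * beta * I_node`` (mV-scale); ``I_node`` is the total
    nodal current amplitude in nA (density x nodal area).  ``lam`` and
    ``R_lambda`` may describe an ephaptic eigenmode rather than the physical
    cable.
    """

    tau: float
    lam: float
    R_lambda: float
    beta: float
    I_node: float
    model: CurrentModel

    @classmethod
    def from_parameter_set(cls, params: ParameterSet,
                           lam_override: Optional[float] = None,
                           current: Optional[CurrentModel] = None) -> "ResponseKernel":
        cable, node, geom = params.cable, params.node, params.geometry
        model = current if current is not None else params.current
        lam = lam_override if lam_override is not None else cable.lam
        area = np.pi * geom.d * geom.l
        return cls(tau=cable.tau, lam=lam, R_lambda=cable.R_m / lam,
                   beta=node.beta, I_node=model.I0 * area * DENSITY_TO_NA,
                   model=model)

    @property
    def pref(self) -> float:
        return self.R_lambda * self.beta * self.I_node

    # ------------------------------------------------------------------
    def response(self, x, t):
        """Single-node depolarisation U(x, t) in mV for this kernel's scenario."""
        m = self.model
        if m.scenario == "A":
            return response_delta(x, t, self)
        if m.scenario == "B":
            return response_delayed(x, t, self, m.delta)
        if m.scenario == "C":
            return response_exponential(x, t, self, m.tau_c)
        return response_multi_exponential(x, t, self)


def response_delta(x, t, kernel: ResponseKernel):
    """Impulse (scenario A) response: the Green's function up to a prefactor.

    U(x, t) = tau R_lambda beta I0 / sqrt(4 pi t) exp(-x^2 tau/(4 lam^2 t)
    - t/tau).  Equivalently R_m beta (I0 tau^(3/2)) G(x, t): the delta
    current of amplitude I0 carries an impulse magnitude beta I0 tau^(3/2)
    (in nA ms, with t in ms), the single centralised convention that makes
    the formula dimensionally closed in the internal unit system.
    """
    x, t = np.broadcast_arrays(np.asarray(x, float), np.asarray(t, float))
    out = np.zeros(t.shape)
    pos = t > 0
    tp = t[pos]
    a = (x[pos] ** 2) * kernel.tau / (4.0 * kernel.lam ** 2)
    out[pos] = (kernel.tau * kernel.pref / np.sqrt(4.0 * np.pi * tp)
                * np.exp(-a / tp - tp / kernel.tau))
    return out


def response_delayed(x, t, kernel: ResponseKernel, delta: float):
    """Scenario B: the impulse response shifted by the hard delay Delta."""
    return response_delta(x, np.asarray(t, float) - delta, kernel)


def _phi_unit(x, t, tau: float, lam: float, tau_s: float):
    """Closed-form convolution of a unit exponential current with G.

    Returns phi(x, t; tau_s) for unit prefactor (R_lambda beta I0 = 1):
    the convolution e^(-t/tau_s) * integral_0^t (4 pi tau s)^(-1/2)
    exp(-a/s + c s) ds with a = x^2 tau/(4 lam^2), c = 1/tau_s - 1/tau.

    Evaluated as (1/(4 sqrt(tau) p)) e^(-a/t - t/tau)
    [w(i(q - p sqrt(t))) - w(i(q + p sqrt(t)))] with p = sqrt(-c),
    q = sqrt(a/t); both branches (tau_s < tau and tau_s > tau) are covered by
    the complex square root, and the tau_s = tau degeneracy by an analytic
    limit.
    """
    x, t = np.broadcast_arrays(np.asarray(x, float), np.asarray(t, float))
    out = np.zeros(t.shape)
    pos = t > 0
    if not np.any(pos):
        return out
    tp = t[pos]
    a = (x[pos] ** 2) * tau / (4.0 * lam ** 2)
    c = 1.0 / tau_s - 1.0 / tau
    q = np.sqrt(a / tp)
    damp = np.exp(-a / tp - tp / tau)
    if abs(c) < _DEGENERATE_RATE:
        # removable limit: F = 2 (sqrt(t) e^(-a/t) - sqrt(pi a) erfc(q))
        val = 2.0 * (np.sqrt(tp) * np.exp(-a / tp) - np.sqrt(np.pi * a) * erfc(q))
        out[pos] = val * np.exp(-tp / tau) / np.sqrt(4.0 * np.pi * tau)
        return out
    sq = np.sqrt(tp)
    if c < 0:
        # slow current (tau_s > tau): arguments are purely imaginary and the
        # lower one can have a large negative imaginary part, where w(z)
        # grows like exp(|z|^2).  Use w(-iy) = 2 e^(y^2) - w(iy) and combine
        # the growing exponential with the damping factor analytically:
        # damp * e^(y1^2) = exp(-2 p sqrt(a) - t/tau_s), always decaying.
        p_r = math.sqrt(-c)
        y1 = q - p_r * sq
        y2 = q + p_r * sq
        w_abs1 = np.real(wofz(1j * np.abs(y1)))
        w2 = np.real(wofz(1j * y2))
        t_term = np.exp(-2.0 * p_r * np.sqrt(a) - tp / tau_s)
        w1d = np.where(y1 >= 0, damp * w_abs1, 2.0 * t_term - damp * w_abs1)
        out[pos] = (w1d - damp * w2) / p_r / (4.0 * np.sqrt(tau))
        return out
    p = 1j * math.sqrt(c)
    diff = wofz(1j * (q - p * sq)) - wofz(1j * (q + p * sq))
    val = np.real(diff / p) * damp / (4.0 * np.sqrt(tau))
    out[pos] = val
    return out


def response_exponential(x, t, kernel: ResponseKernel, tau_s: float):
    """Response to an instantaneous-onset exponential current (scenario C)."""
    return kernel.pref * _phi_unit(x, t, kernel.tau, kernel.lam, tau_s)


def response_multi_exponential(x, t, kernel: ResponseKernel):
    """Scenario D: normalised gated sodium (and optional potassium) response.

    Sum of exponential-current responses over the binomial expansion terms,
    divided by the peak normalisation so the underlying current peaks at I0;
    the potassium profile (peak density i_K, outward) is subtracted when
    enabled.
    """
    m = kernel.model
    x = np.asarray(x, dtype=float)
    t = np.asarray(t, dtype=float)
    out = np.zeros(np.broadcast_shapes(x.shape, t.shape))
    for A_s, tau_s in m.terms:
        out = out + A_s * _phi_unit(x, t, kernel.tau, kernel.lam, tau_s)
    out = out * (kernel.pref / m.C_Na)
    if m.include_potassium:
        out_k = np.zeros_like(out)
        for A_s, tau_s in m.terms_K:
            out_k = out_k + A_s * _phi_unit(x, t, kernel.tau, kernel.lam, tau_s)
        out = out - out_k * (kernel.pref * m.i_K_over_i_Na / m.C_K)
    return out
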