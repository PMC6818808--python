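"""Inflection-point linearization of the depolarisation curve.

The implicit threshold condition has no closed-form inverse, but the rising
phase of the single-node depolarisation U(x, t) can be linearised around its
inflection point t_i (where the second time derivative vanishes), giving the
explicit estimate

    t_sp ~= t_i + (V_thr - V(t_i)) / V'(t_i).

For the impulse current the inflection time follows from a quadratic
truncation of t^4 V''(t) = 0; in the proximal limit x << lam it reduces to
t_i = zeta x^2 tau/lam^2 with zeta = (1 - sqrt(2/3))/2 ~= 0.0918.  For
exponential and gated currents analogous closed forms exist per branch.
The linearisation is single-node (N = 1); it is a diagnostic companion to
the exact Newton solve, not a production solver.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .params import CableParameters
from .currents import CurrentModel
from .cable_response import ResponseKernel, response_delta

#: proximal-limit constant of t_i = zeta x^2 tau / lam^2
ZETA = (1.0 - math.sqrt(2.0 / 3.0)) / 2.0


@dataclass(frozen=True)
class LinearizedEstimate:
    t_i: float          # inflection time (ms)
    V_i: float          # voltage at t_i (mV)
    dVdt_i: float       # slope at t_i (mV/ms)
    t_sp_lin: float     # linearised time-to-threshold (ms)
    zeta: float         # effective dimensionless constant t_i lam^2/(x^2 tau)
    valid: bool = True


def inflection_scenarioA(x: float, cable: CableParameters) -> float:
    """Rising-phase inflection time of the impulse response.

    Root of the quadratic truncation of t^4 V''/V:
    a^2 - 3 a t + ((3 - 2 u)/4) t^2 = 0, with u = x^2/lam^2 and
    a = u tau / 4; the smaller positive root is returned.  Raises if the
    truncation admits no positive root.
    """
    if x <= 0:
        raise ValueError("x must be positive")
    u = (x / cable.lam) ** 2
    a = u * cable.tau / 4.0
    c2 = (3.0 - 2.0 * u) / 4.0
    disc = 9.0 * a * a - 4.0 * c2 * a * a
    if disc < 0:
        raise ArithmeticError("no inflection point: negative discriminant")
    roots = np.roots([c2, -3.0 * a, a * a]) if c2 != 0 else np.array([a / 3.0])
    roots = np.real(roots[np.isreal(roots)])
    pos = roots[roots > 0]
    if pos.size == 0:
        raise ArithmeticError("no positive inflection time")
    return float(pos.min())


def inflection_scenarioA_proximal(x: float, cable: CableParameters) -> float:
    """Proximal (x << lam) limit t_i = zeta x^2 tau / lam^2."""
    return ZETA * x * x * cable.tau / cable.lam ** 2


def inflection_scenarioC(x: float, cable: CableParameters, tau_c: float) -> float:
    """Inflection time for the instantaneous-onset exponential current.

    Branches: for tau_c < tau the quadratic truncation gives
    t_i = (1 - sqrt(1 - (x^2 tau/(2 lam^2)) k))/(2 k), k = 1/tau - 2/tau_c
    (k is negative there, so the root is positive); for tau_c >= tau the
    slow-decay branch t_i = (tau/2)(sqrt(1 + 2 x^2/lam^2) - 1) applies.
    """
    if x <= 0:
        raise ValueError("x must be positive")
    tau, lam = cable.tau, cable.lam
    if tau_c < tau:
        k = 1.0 / tau - 2.0 / tau_c
        arg = 1.0 - (x * x * tau / (2.0 * lam ** 2)) * k
        if arg < 0:
            raise ArithmeticError("no inflection point: negative discriminant")
        return (1.0 - math.sqrt(arg)) / (2.0 * k)
    return 0.5 * tau * (math.sqrt(1.0 + 2.0 * (x / lam) ** 2) - 1.0)


def inflection_scenarioC_fast_decay(x: float, cable: CableParameters,
                                    tau_c: float) -> float:
    """tau_c << tau limit of the fast-decay branch.

    t_i = (tau_c/4)(sqrt(1 + x^2 tau/(lam^2 tau_c)) - 1), the algebraic
    limit of the quadratic-truncation root as tau_c/tau -> 0.
    """
    return 0.25 * tau_c * (math.sqrt(1.0 + x * x * cable.tau
                                     / (cable.lam ** 2 * tau_c)) - 1.0)


def inflection_chan(model: CurrentModel) -> float:
    """Inflection time of the rising gated current (x-independent part).

    t_chan = -tau_m ln(Q (1 - sqrt(1 - S))) with
    Q = (g tm^2 + 2 g tm th + 2 th^2)/(2 (g tm + th)^2) and
    S = 4 th^2 (g tm + th)^2/(g tm^2 + 2 g tm th + 2 th^2)^2.
    """
    g, tm, th = model.gamma, model.tau_m, model.tau_h
    num = g * tm * tm + 2.0 * g * tm * th + 2.0 * th * th
    Q = num / (2.0 * (g * tm + th) ** 2)
    S = 4.0 * th * th * (g * tm + th) ** 2 / num ** 2
    if S > 1.0:
        raise ArithmeticError("no channel inflection: negative inner discriminant")
    arg = Q * (1.0 - math.sqrt(1.0 - S))
    if not 0.0 < arg < 1.0:
        raise ArithmeticError("channel inflection outside the rising phase")
    return -tm * math.log(arg)


def inflection_scenarioD(x: float, cable: CableParameters,
                         model: CurrentModel) -> float:
    """Additive inflection estimate t_i = t_cab(x) + t_chan.

    t_cab is the inflection of the cable kernel (the impulse-response
    quadratic, which reduces to the distal form sqrt(2) (x/lam) tau/4 for
    x >> lam but stays accurate at internode-scale distances); t_chan is the
    inflection of the rising channel current and is independent of x.
    """
    if x <= 0:
        raise ValueError("x must be positive")
    return inflection_scenarioA(x, cable) + inflection_chan(model)


def inflection_cable_distal(x: float, cable: CableParameters) -> float:
    """Distal-limit (x >> lam) cable inflection sqrt(2) (x/lam) tau/4."""
    return math.sqrt(2.0) * (x / cable.lam) * cable.tau / 4.0


# ---------------------------------------------------------------------------


def _numeric_V_and_slope(kernel: ResponseKernel, x: float, t: float,
                         rel_h: float = 1e-5):
    h = max(rel_h * t, 1e-9)
    v = float(kernel.response(np.array(x), np.array(t)))
    vp = float(kernel.response(np.array(x), np.array(t + h)))
    vm = float(kernel.response(np.array(x), np.array(t - h)))
    return v, (vp - vm) / (2.0 * h)


def linear_tsp(x: float, kernel: ResponseKernel, V_thr: float) -> LinearizedEstimate:
    """Explicit linearised time-to-threshold for a single node at distance x.

    For the impulse scenario V(t_i) and V'(t_i) use the closed-form
    approximations (with the effective zeta = t_i lam^2/(x^2 tau), the leak
    term dropped); for the exponential and gated scenarios they are
    evaluated from the closed-form response at the closed-form t_i.
    """
    tau, lam = kernel.tau, kernel.lam
    scen = kernel.model.scenario
    fake_cable = CableParameters(tau=tau, lam=lam, R_m=kernel.R_lambda * lam,
                                 C_m=float("nan"), R_c=float("nan"),
                                 R_lambda=kernel.R_lambda)
    if scen in ("A", "B"):
        t_i = inflection_scenarioA(x, fake_cable)
        zeta_eff = t_i * lam ** 2 / (x * x * tau)
        V_i = (kernel.pref * math.sqrt(tau) * lam
               / (math.sqrt(4.0 * math.pi * zeta_eff) * x)
               * math.exp(-1.0 / (4.0 * zeta_eff)))
        dVdt_i = (1.0 - 2.0 * zeta_eff) * lam ** 2 / (4.0 * zeta_eff ** 2
                                                      * x * x * tau) * V_i
        if scen == "B":
            t_i = t_i + kernel.model.delta
    elif scen == "C":
        t_i = inflection_scenarioC(x, fake_cable, kernel.model.tau_c)
        V_i, dVdt_i = _numeric_V_and_slope(kernel, x, t_i)
        zeta_eff = t_i * lam ** 2 / (x * x * tau)
    else:
        t_i = inflection_scenarioD(x, fake_cable, kernel.model)
        V_i, dVdt_i = _numeric_V_and_slope(kernel, x, t_i)
        zeta_eff = t_i * lam ** 2 / (x * x * tau)
    valid = dVdt_i > 0
    t_sp_lin = t_i + (V_thr - V_i) / dVdt_i if valid else math.inf
    return LinearizedEstimate(t_i=t_i, V_i=V_i, dVdt_i=dVdt_i,
                              t_sp_lin=t_sp_lin, zeta=zeta_eff, valid=valid)
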