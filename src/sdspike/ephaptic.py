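"""Ephaptic coupling between axons sharing restricted extracellular space.

With a finite extracellular axial resistance R_ex, the cable equations of the
axons in a bundle couple through the extracellular potential.  For the
trans-membrane potentials P_n the coupled system is linear and can be
decoupled into independent cable modes P_tilde = P_1 + c P_2 with effective
length constants lam_tilde; for two identical axons the modes are the sum
(c = +1) and the difference (c = -1) of the two potentials.

The shared return path adds series resistance to the axial current of the
common mode, which *shortens* its electrotonic reach; we therefore fold the
coupling into the effective axial resistance,

    lam_tilde_k^2 = lam_1^2 / (1 + alpha R_ax,1^-1 (1 + c_k lam_2^2/lam_1^2)),

with alpha = 1/(R_ex^-1 + sum_m R_ax,m^-1).  For identical axons at
R_ex^-1 = 0 this gives lam_tilde_1 = lam/sqrt(2) for the sum mode and
lam_tilde_2 = lam for the difference mode; to first order in the coupling it
agrees with the linearised mode analysis of the coupled cable system, and
unlike the additive form it remains finite and well behaved in the
strong-coupling limit.  This convention is what produces the observed
phenomenology: synchronous pairs travel slower than single action
potentials, a passive neighbour is first hyperpolarised and then weakly
depolarised, and offset action potentials re-synchronise.

Each mode is solved with the single-axon response machinery (lam replaced by
lam_tilde) and the physical potentials are recovered by inverting the
transformation.  The channel-current division at a node (beta) is applied to
the physical currents before transforming, using the uncoupled cable's
longitudinal resistance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .params import ParameterSet
from .cable_response import ResponseKernel
from .propagation import (PropagationProblem, PropagationResult, solve_tsp,
                          velocity, threshold_residual, _find_bracket,
                          RESIDUAL_TOL)


@dataclass(frozen=True)
class EphapticBundle:
    """A pair (or bundle) of ephaptically coupled axons.

    ``axons`` are per-axon parameter sets; ``R_ex_inv`` is the extracellular
    axial conductance per unit length (1/(MOhm/um)).  R_ex_inv = 0 is the
    strong-coupling limit of vanishing extracellular volume.
    """

    axons: Sequence[ParameterSet]
    R_ex_inv: float = 0.0

    def __post_init__(self) -> None:
        if len(self.axons) < 2:
            raise ValueError("a bundle needs at least two axons")
        if any(p.cable.R_c <= 0 for p in self.axons):
            raise ValueError("degenerate axial conductances")

    @property
    def R_ax_inv(self) -> np.ndarray:
        """Per-axon axial conductance 1/R_c (um/MOhm)."""
        return np.array([1.0 / p.cable.R_c for p in self.axons])

    @property
    def alpha(self) -> float:
        """Coupling parameter alpha = 1/(R_ex^-1 + sum R_ax^-1) (MOhm/um)."""
        return 1.0 / (self.R_ex_inv + self.R_ax_inv.sum())


def decouple(bundle: EphapticBundle):
    """Two-axon decoupling: coefficients (c1, c2) and effective constants.

    Returns ``(c1, c2, lam_tilde1, lam_tilde2)``.  For identical axons
    c = +/-1, lam_tilde1 = lam/sqrt(1 + 2 alpha/R_ax) (the sum mode, with the
    coupling as series axial resistance), lam_tilde2 = lam (the difference
    mode, which does not drive a net extracellular return current and
    propagates exactly as an uncoupled cable).
    """
    if len(bundle.axons) != 2:
        raise ValueError("closed-form decoupling is for two axons")
    l1 = bundle.axons[0].cable.lam
    l2 = bundle.axons[1].cable.lam
    r1, r2 = bundle.R_ax_inv
    a = bundle.alpha
    if math.isclose(l1, l2, rel_tol=1e-12) and math.isclose(r1, r2, rel_tol=1e-12):
        c1, c2 = 1.0, -1.0
    else:
        # P_tilde = P1 + c P2 decouples when [1, c] is a left eigenvector of
        # the mode operator M (see coupling_matrix):
        # c^2 + B c - (r2 l2^2)/(r1 l1^2) = 0
        B = ((1.0 + a * r1) / l1 ** 2 - (1.0 + a * r2) / l2 ** 2) * l2 ** 2 / (a * r1)
        disc = math.sqrt((B / 2.0) ** 2 + (r2 * l2 ** 2) / (r1 * l1 ** 2))
        c1, c2 = -B / 2.0 + disc, -B / 2.0 - disc

    def _lam_tilde(c: float) -> float:
        mu = (1.0 + a * r1) / l1 ** 2 + c * a * r1 / l2 ** 2
        return 1.0 / math.sqrt(mu)

    return c1, c2, _lam_tilde(c1), _lam_tilde(c2)


def coupling_matrix(bundle: EphapticBundle) -> np.ndarray:
    """General n-axon mode operator M with eigenvalues 1/lam_tilde^2.

    M_nm = lam_n^-2 (delta_nm + alpha R_ax,m^-1): the inverse-squared length
    constants of the uncoupled cables, augmented by the shared-return-path
    series term.  Diagonalising M yields the decoupled modes of an arbitrary
    bundle; for two axons its eigenvalues reproduce the closed-form
    lam_tilde of :func:`decouple`.
    """
    lams = np.array([p.cable.lam for p in bundle.axons])
    r = bundle.R_ax_inv
    inv2 = 1.0 / lams ** 2
    return np.diag(inv2) + bundle.alpha * np.outer(inv2, r)


def mode_length_constants(bundle: EphapticBundle) -> np.ndarray:
    """Effective lam_tilde of all modes (descending), from eigendecomposition."""
    vals = np.linalg.eigvals(coupling_matrix(bundle))
    return np.sort(1.0 / np.sqrt(np.real(vals)))[::-1]


# ---------------------------------------------------------------------------
# identical-pair responses
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PairKernels:
    """Self- and cross-responses of an identical pair.

    For identical axons the response of axon i to a current in axon j is
        self  (i == j):  (U_mode1 + U_mode2)/2
        cross (i != j):  (U_mode1 - U_mode2)/2
    where mode k uses lam_tilde_k.  Node spacings are mode-consistent:
    x1_mode = L + l lam_tilde/lam_node.
    """

    params: ParameterSet
    bundle: EphapticBundle
    k1: ResponseKernel = field(init=False)
    k2: ResponseKernel = field(init=False)

    def __post_init__(self) -> None:
        c1, c2, lt1, lt2 = decouple(self.bundle)
        object.__setattr__(self, "k1",
                           ResponseKernel.from_parameter_set(self.params,
                                                             lam_override=lt1))
        object.__setattr__(self, "k2",
                           ResponseKernel.from_parameter_set(self.params,
                                                             lam_override=lt2))

    def spacing(self, kernel: ResponseKernel) -> float:
        g = self.params.geometry
        return g.L + g.l * kernel.lam / self.params.node.lam_node

    def self_response(self, x_frac, t):
        """Response at a node ``x_frac`` internodes away from the source.

        ``x_frac`` counts internode units so each mode can apply its own
        electrotonic spacing.
        """
        x_frac = np.asarray(x_frac, dtype=float)
        u1 = self.k1.response(np.abs(x_frac) * self.spacing(self.k1), t)
        u2 = self.k2.response(np.abs(x_frac) * self.spacing(self.k2), t)
        return 0.5 * (u1 + u2)

    def cross_response(self, x_frac, t):
        x_frac = np.asarray(x_frac, dtype=float)
        u1 = self.k1.response(np.abs(x_frac) * self.spacing(self.k1), t)
        u2 = self.k2.response(np.abs(x_frac) * self.spacing(self.k2), t)
        return 0.5 * (u1 - u2)

    def mode1_response(self, x_frac, t):
        x_frac = np.asarray(x_frac, dtype=float)
        return self.k1.response(np.abs(x_frac) * self.spacing(self.k1), t)


def make_pair(params: ParameterSet, R_ex_inv: float = 0.0) -> PairKernels:
    bundle = EphapticBundle(axons=(params, params), R_ex_inv=R_ex_inv)
    return PairKernels(params=params, bundle=bundle)


@dataclass(frozen=True)
class PairTrace:
    t: np.ndarray
    P1: np.ndarray
    P2: np.ndarray


def pair_response(pair: PairKernels, t_sp1: Optional[float],
                  t_sp2: Optional[float], node_index: float,
                  t_grid, offset2: float = 0.0, N: Optional[int] = None) -> PairTrace:
    """Trans-membrane traces of both axons at a given node position.

    Axon i fires its nodes n at n*t_sp_i (+ offset2 for axon 2); passing
    ``t_sp_i = None`` silences that axon.  ``node_index`` is the observation
    position in internode units.
    """
    t = np.asarray(t_grid, dtype=float)
    N = N if N is not None else pair.params.geometry.N
    n = np.arange(-N, N + 1)
    P1 = np.zeros_like(t)
    P2 = np.zeros_like(t)
    for t_sp, off, own in ((t_sp1, 0.0, True), (t_sp2, offset2, False)):
        if t_sp is None:
            continue
        xs = node_index - n
        ts = t[..., None] - (n * t_sp + off)
        u_self = pair.self_response(xs, ts).sum(axis=-1)
        u_cross = pair.cross_response(xs, ts).sum(axis=-1)
        if own:
            P1 += u_self
            P2 += u_cross
        else:
            P1 += u_cross
            P2 += u_self
    return PairTrace(t=t, P1=P1, P2=P2)


def paired_velocity(params: ParameterSet, R_ex_inv: float = 0.0,
                    N: Optional[int] = None):
    """Velocities of a synchronous pair and of a single uncoupled AP (m/s).

    A synchronous identical pair excites only the sum mode, so its threshold
    condition is the single-axon one evaluated on the mode-1 cable.
    Returns ``(result_pair, result_single)``.
    """
    pair = make_pair(params, R_ex_inv)
    prob = PropagationProblem(params=params, N=N)
    spacing1 = pair.spacing(pair.k1)

    def pair_resp(x, t):
        # x arrives in physical-node units of the *problem* spacing; rescale
        return pair.k1.response(np.asarray(x) / prob.node_spacing * spacing1, t)

    res_pair = velocity(prob, response=pair_resp)
    res_single = velocity(prob)
    return res_pair, res_single


def entrainment_step(params: ParameterSet, dt_in: float,
                     R_ex_inv: float = 0.0, N: Optional[int] = None,
                     sweeps: int = 3):
    """Offset of a pair of APs after one internode (ms).

    Both axons have APs arriving with inter-node period equal to the
    synchronous-pair t_sp; axon 2 lags axon 1 by ``dt_in``.  The
    threshold-crossing times of node 1 in both axons are solved
    self-consistently (the earlier axon's freshly fired node feeds into the
    later axon's depolarisation), and the new offset is returned.
    """
    pair = make_pair(params, R_ex_inv)
    prob = PropagationProblem(params=params, N=N)
    Nn = prob.n_nodes
    # reference synchronous-pair period: mode-1 solve (see paired_velocity)
    res_pair, _ = paired_velocity(params, R_ex_inv, N=N)
    t_p = res_pair.t_sp
    offs = (0.0, dt_in)
    n = np.arange(0, Nn)          # fired nodes: indices 1-n going backwards
    m = 1.0 + n                   # distance of node (1-n)...0.. in internode units

    def residual(T, i, T_other, other_fired):
        o_i, o_j = offs[i], offs[1 - i]
        fire_i = (1.0 - m) * t_p + o_i
        fire_j = (1.0 - m) * t_p + o_j
        v = pair.self_response(m, T - fire_i).sum()
        v += pair.cross_response(m, T - fire_j).sum()
        if other_fired and T_other is not None and T_other < T:
            v += pair.cross_response(0.0, T - T_other)
        return float(v) - prob.threshold

    def solve_one(i, T_other, other_fired):
        f = lambda T: residual(T, i, T_other, other_fired)
        br = _find_bracket(f, lo=1e-6, hi=10.0, points=600)
        if br is None:
            return None
        from scipy.optimize import brentq
        return brentq(f, br[0], br[1], xtol=1e-14)

    T1 = solve_one(0, None, False)
    T2 = solve_one(1, T1, True)
    if T1 is None or T2 is None:
        return None
    for _ in range(sweeps - 1):
        T1 = solve_one(0, T2, True)
        T2 = solve_one(1, T1, True)
        if T1 is None or T2 is None:
            return None
    return T2 - T1
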