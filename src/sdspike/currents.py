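"""Threshold-triggered channel-current scenarios.

Four current profiles are supported, all released when the membrane potential
crosses the firing threshold:

    A  instantaneous (delta) current,
    B  instantaneous current after a hard delay Delta,
    C  instantaneous onset with exponential decay (time constant tau_c),
    D  gated profile (1-exp(-t/tau_rise))^gamma * exp(-t/tau_fall), the
       realistic sodium (and optionally potassium) time course.

Gated profiles are reduced to signed sums of pure exponentials via the
binomial expansion, which the cable-response module can convolve in closed
form.  Amplitudes are current *densities* in pA/um^2; the total nodal current
is the density times the nodal membrane area pi*d*l.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

SCENARIOS = ("A", "B", "C", "D")

#: default potassium/sodium peak-density ratio, from the nodal conductances
#: gbar_K = 0.09 S/cm^2 and gbar_Na = 1.2 S/cm^2.
K_TO_NA_RATIO = 0.09 / 1.2


@dataclass(frozen=True)
class CurrentModel:
    """One channel-current scenario with all of its time constants.

    Time constants are in ms, amplitudes in pA/um^2.  ``terms`` holds the
    exponential expansion (A_s, tau_s) of the sodium profile (scenario D),
    excluding the normalisation constant, which is stored in ``C_Na``.
    """

    scenario: str
    I0: float = 50.0
    delta: float = 0.030          # hard delay, scenario B
    tau_c: float = 0.100          # decay constant, scenario C
    gamma: int = 1                # activation exponent, scenario D
    tau_m: float = 0.020          # Na activation
    tau_h: float = 0.040          # Na inactivation
    tau_nK: float = 0.150         # K activation
    tau_k: float = 0.300          # K decay
    include_potassium: bool = False
    i_K_over_i_Na: float = K_TO_NA_RATIO
    terms: tuple = field(default=())      # ((A_s, tau_s), ...)
    terms_K: tuple = field(default=())
    C_Na: float = 1.0
    C_K: float = 1.0

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        for name in ("tau_c", "tau_m", "tau_h", "tau_nK", "tau_k"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.gamma < 1:
            raise ValueError("gamma must be >= 1")


def make_current_model(scenario: str, **kwargs) -> CurrentModel:
    """Build a CurrentModel with the exponential expansion precomputed."""
    model = CurrentModel(scenario=scenario, **kwargs)
    terms = tuple(expand_to_exponentials(model.gamma, model.tau_m, model.tau_h))
    terms_K = tuple(expand_to_exponentials(4, model.tau_nK, model.tau_k))
    C_Na, _ = normalization_Na(model.gamma, model.tau_m, model.tau_h)
    C_K = normalization_K(model.tau_nK, model.tau_k)
    object.__setattr__(model, "terms", terms)
    object.__setattr__(model, "terms_K", terms_K)
    object.__setattr__(model, "C_Na", C_Na)
    object.__setattr__(model, "C_K", C_K)
    return model


def normalization_Na(gamma: int, tau_m: float, tau_h: float) -> tuple[float, float]:
    """Peak value C_Na of (1-e^(-t/tau_m))^gamma e^(-t/tau_h), and its time.

    The profile peaks at t_max = tau_m ln(gamma tau_h/tau_m + 1); dividing by
    C_Na normalises the peak current to I0.  Returns ``(C_Na, t_max)``.
    """
    r = gamma * tau_h / tau_m
    t_max = tau_m * math.log(r + 1.0)
    C = (r / (r + 1.0)) ** gamma * (1.0 / (r + 1.0)) ** (tau_m / tau_h)
    return C, t_max


def normalization_K(tau_nK: float, tau_k: float) -> float:
    """Peak value C_K of the potassium profile (1-e^(-t/tau_nK))^4 e^(-t/tau_k)."""
    C, _ = normalization_Na(4, tau_nK, tau_k)
    return C


def expand_to_exponentials(gamma: int, tau_rise: float, tau_fall: float):
    """Binomial expansion of the gated profile into signed exponentials.

    (1-e^(-t/tau_rise))^gamma e^(-t/tau_fall)
        = sum_{s=0}^{gamma} binom(gamma, s) (-1)^s e^(-t/tau_s),
    with tau_s = (s/tau_rise + 1/tau_fall)^(-1).  Returns [(A_s, tau_s), ...].
    """
    if gamma < 1:
        raise ValueError("gamma must be >= 1")
    out = []
    for s in range(gamma + 1):
        A_s = math.comb(gamma, s) * (-1) ** s
        tau_s = 1.0 / (s / tau_rise + 1.0 / tau_fall)
        out.append((float(A_s), tau_s))
    return out


def gated_profile(t, gamma: int, tau_rise: float, tau_fall: float):
    """The raw (unnormalised) gated profile, zero for t < 0."""
    t = np.asarray(t, dtype=float)
    out = np.where(t > 0, (1.0 - np.exp(-np.clip(t, 0, None) / tau_rise)) ** gamma
                   * np.exp(-np.clip(t, 0, None) / tau_fall), 0.0)
    return out


def current_profile(model: CurrentModel, t):
    """Channel current density (pA/um^2) at time t after threshold crossing.

    Continuous scenarios only: scenario C is an instantaneous-onset
    exponential; scenario D is the normalised sodium profile, minus the
    potassium profile (outward, hence opposite sign) when enabled.
    Scenarios A/B are delta distributions and cannot be evaluated pointwise;
    the response module treats them symbolically.
    """
    t = np.asarray(t, dtype=float)
    if model.scenario in ("A", "B"):
        raise ValueError("delta-current scenarios have no pointwise profile")
    if model.scenario == "C":
        return np.where(t >= 0, model.I0 * np.exp(-np.clip(t, 0, None) / model.tau_c), 0.0)
    i_na = model.I0 / model.C_Na * gated_profile(t, model.gamma,
                                                 model.tau_m, model.tau_h)
    if not model.include_potassium:
        return i_na
    i_k = (model.I0 * model.i_K_over_i_Na / model.C_K
           * gated_profile(t, 4, model.tau_nK, model.tau_k))
    return i_na - i_k
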