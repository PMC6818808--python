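"""Electrophysiological parameters of nodes and internodes.

All quantities are converted at load time into a single internal unit
system::

    length      micrometre (um)
    time        millisecond (ms)
    voltage     millivolt (mV)
    current     nanoampere (nA)
    resistance  megaohm (MOhm)
    capacitance nanofarad (nF)

This system closes consistently: mV = nA * MOhm and ms = MOhm * nF, so no
conversion factors appear in the cable formulas themselves.  The only places
where external units enter are the conversion constants below and the
current-density amplitudes, which are specified in pA/um^2 and multiplied by
the nodal membrane area (the side wall of a cylinder, pi*d*l) to give a total
current in nA.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

# ---------------------------------------------------------------------------
# unit conversion constants (external unit -> internal unit system)
# ---------------------------------------------------------------------------

#: 1 pF/cm  ->  nF/um   (1 pF = 1e-3 nF, 1 cm = 1e4 um)
PF_PER_CM = 1e-3 / 1e4
#: 1 MOhm*cm -> MOhm*um
MOHM_CM = 1e4
#: 1 Ohm*cm  -> MOhm*um  (1 Ohm = 1e-6 MOhm)
OHM_CM = 1e-6 * 1e4
#: 1 Ohm*cm^2 -> MOhm*um^2
OHM_CM2 = 1e-6 * 1e8
#: 1 uF/cm^2  -> nF/um^2  (1 uF = 1e3 nF)
UF_PER_CM2 = 1e3 / 1e8
#: 1 pA -> nA
PA = 1e-3
#: internal velocity unit (um/ms) -> m/s
UM_PER_MS_TO_M_PER_S = 1e-3

#: factor converting a current density in pA/um^2 times an area in um^2
#: into a total nodal current in nA.  This single constant fixes the
#: amplitude convention for all channel-current scenarios.
DENSITY_TO_NA = PA


@dataclass(frozen=True)
class PhysicalConstants:
    """First-principles constants of the myelinated fibre and its nodes.

    k1, k2 are the empirical capacitance/resistance coefficients of the
    myelin sheath (cylindrical capacitor/resistor); rho_ax is the axoplasm
    resistivity; R_n, C_n the specific membrane resistance/capacitance of a
    node of Ranvier; i_Na, i_K the peak sodium/potassium current densities.
    """

    k1: float = 3.6       # pF/cm
    k2: float = 130.0     # MOhm*cm
    rho_ax: float = 110.0  # Ohm*cm
    R_n: float = 33.0     # Ohm*cm^2
    C_n: float = 1.0      # uF/cm^2
    i_Na: float = 50.0    # pA/um^2
    i_K: float = 3.75     # pA/um^2

    def __post_init__(self) -> None:
        for name in ("k1", "k2", "rho_ax", "R_n", "C_n", "i_Na", "i_K"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass(frozen=True)
class AxonGeometry:
    """Geometry of a periodically myelinated axon.

    d : axon diameter (um); g : g-ratio (axon/fibre diameter); L : internode
    length (um); l : node length (um); N : number of contributing nodes on
    each side of the observation node.
    """

    d: float = 1.0
    g: float = 0.6
    L: float = 100.0
    l: float = 1.0
    N: int = 1000

    def __post_init__(self) -> None:
        if self.d <= 0:
            raise ValueError("axon diameter d must be positive")
        if not 0.0 < self.g < 1.0:
            raise ValueError("g-ratio must lie in (0, 1)")
        if self.L < 0:
            raise ValueError("internode length L must be non-negative")
        if self.l <= 0:
            raise ValueError("node length l must be positive")
        if self.N < 1:
            raise ValueError("N must be at least 1")

    @property
    def fibre_diameter(self) -> float:
        return self.d / self.g


@dataclass(frozen=True)
class CableParameters:
    """Passive cable parameters of the internode (internal units)."""

    tau: float        # ms
    lam: float        # um
    R_m: float        # MOhm*um (radial resistance x unit length)
    C_m: float        # nF/um  (capacitance per unit length)
    R_c: float        # MOhm/um (axial resistance per unit length)
    R_lambda: float   # MOhm, R_m / lam


@dataclass(frozen=True)
class NodeParameters:
    """Properties of a node of Ranvier (internal units)."""

    tau_node: float           # ms
    lam_node: float           # um
    R_node: float             # MOhm (total radial resistance of one node)
    beta: float               # cable-current fraction, eq. of current division
    v_node: Optional[float] = None  # m/s, filled lazily by the propagation solver


def derive_cable_parameters(geometry: AxonGeometry,
                            constants: PhysicalConstants) -> CableParameters:
    """Derive internode cable parameters from geometry and constants.

    C_m = k1/ln(1/g), R_m = k2*ln(1/g) (cylindrical capacitor/resistor),
    R_c = 4*rho_ax/(pi d^2), tau = C_m R_m = k1 k2 (independent of d and g),
    lam = sqrt(R_m/R_c).
    """
    log_inv_g = math.log(1.0 / geometry.g)
    C_m = constants.k1 * PF_PER_CM / log_inv_g            # nF/um
    R_m = constants.k2 * MOHM_CM * log_inv_g              # MOhm*um
    R_c = 4.0 * constants.rho_ax * OHM_CM / (math.pi * geometry.d ** 2)  # MOhm/um
    tau = C_m * R_m                                       # ms
    lam = math.sqrt(R_m / R_c)                            # um
    return CableParameters(tau=tau, lam=lam, R_m=R_m, C_m=C_m, R_c=R_c,
                           R_lambda=R_m / lam)


def lambda_coefficient(constants: PhysicalConstants) -> float:
    """Coefficient a in lam = a * d * sqrt(ln(1/g)) (d in um, lam in um)."""
    return math.sqrt(constants.k2 * 1e6 * math.pi / (4.0 * constants.rho_ax))


def derive_medium_constants(constants: PhysicalConstants) -> tuple[float, float]:
    """Permittivity (s/(Ohm m)) and resistivity (Ohm m) of the myelin medium.

    From the cylindrical-capacitor/resistor relations C_m = 2 pi eps/ln(1/g)
    and R_m = rho ln(1/g)/(2 pi): eps = k1/(2 pi), rho = 2 pi k2, in SI.
    """
    eps = constants.k1 * 1e-12 / 1e-2 / (2.0 * math.pi)   # F/m = s/(Ohm m)
    rho = 2.0 * math.pi * constants.k2 * 1e6 * 1e-2       # Ohm*m
    return eps, rho


#: Table coefficients for the nodal length constant, lam_node = c*sqrt(d/um) um.
LAM_NODE_COEFF_STANDARD = 38.9
LAM_NODE_COEFF_FITTED = 48.1


def nodal_length_constant(d: float, constants: PhysicalConstants,
                          *, derived: bool = False,
                          coeff: float = LAM_NODE_COEFF_STANDARD) -> float:
    """Length constant of a node of Ranvier, in um.

    By default uses the tabulated coefficient (lam_node = 38.9 sqrt(d) um for
    the standard set).  With ``derived=True`` the first-principles value
    sqrt(R_n d/(4 rho_ax)) is returned instead (about 27.4 sqrt(d) um); the
    two differ by roughly sqrt(2) and the tabulated value is used for all
    shipped experiments.
    """
    if derived:
        R_m_node = constants.R_n * OHM_CM2 / (math.pi * d)   # MOhm*um
        R_c = 4.0 * constants.rho_ax * OHM_CM / (math.pi * d ** 2)
        return math.sqrt(R_m_node / R_c)
    return coeff * math.sqrt(d)


def derive_node_parameters(geometry: AxonGeometry,
                           constants: PhysicalConstants,
                           cable: CableParameters,
                           *, lam_node_coeff: float = LAM_NODE_COEFF_STANDARD,
                           derived_lam_node: bool = False) -> NodeParameters:
    """Nodal time constant, length constant, radial resistance and beta.

    The nodal membrane area is the side wall of a cylinder, pi*d*l, so the
    total radial resistance of one node is R_n/(pi d l); this makes the total
    channel current (density x area) linear in the node length while the
    cable-bound fraction beta*I saturates.
    """
    tau_node = constants.C_n * constants.R_n * 1e-6 * 1e3  # s->ms: Ohm*cm^2 * F/cm^2 = s
    R_node = constants.R_n * OHM_CM2 / (math.pi * geometry.d * geometry.l)
    lam_node = nodal_length_constant(geometry.d, constants,
                                     derived=derived_lam_node,
                                     coeff=lam_node_coeff)
    beta = 1.0 / (1.0 + cable.R_lambda / (2.0 * R_node))
    return NodeParameters(tau_node=tau_node, lam_node=lam_node,
                          R_node=R_node, beta=beta)


# ---------------------------------------------------------------------------
# packaged parameter sets
# ---------------------------------------------------------------------------

from .currents import CurrentModel  # noqa: E402  (simple one-way dependency)


@dataclass(frozen=True)
class ParameterSet:
    """A complete, internally consistent model parameterisation."""

    label: str
    constants: PhysicalConstants
    geometry: AxonGeometry
    cable: CableParameters
    node: NodeParameters
    current: CurrentModel
    V_thr: float  # mV

    def with_geometry(self, **changes) -> "ParameterSet":
        """Rebuild the set for a modified geometry (d, g, L, l, N).

        Derived cable/node parameters are recomputed; for the fitted set the
        fitted tau and the fitted lam/lam_node coefficients are preserved
        under the rescaling lam ~ d sqrt(ln(1/g)), lam_node ~ sqrt(d).
        """
        geometry = replace(self.geometry, **changes)
        return build_parameter_set(self.label, geometry=geometry,
                                   scenario=self.current.scenario,
                                   current=self.current, V_thr=self.V_thr)

    def with_current(self, current: CurrentModel) -> "ParameterSet":
        return replace(self, current=current)


#: fitted-column values (biophysical-model calibration); entries not listed
#: here fall back to the standard first-principles derivations.
_FITTED = dict(
    tau=1.45,             # ms
    lam_coeff=12e2,       # lam = 1200 * d * sqrt(ln(1/g)) um
    lam_node_coeff=LAM_NODE_COEFF_FITTED,
    tau_node=0.020,       # ms
    d=0.73, g=0.81,
    tau_m=0.070, tau_h=0.160,   # ms
    I0=200.0,             # pA/um^2
    V_thr=4.0,            # mV
)

_STANDARD_DEFAULTS = dict(d=1.0, g=0.6, l=1.0)


def _default_current(label: str, scenario: str) -> CurrentModel:
    from . import currents
    if label == "standard":
        return currents.make_current_model(scenario, I0=50.0, tau_m=0.020,
                                           tau_h=0.040)
    return currents.make_current_model(scenario, I0=_FITTED["I0"],
                                       tau_m=_FITTED["tau_m"],
                                       tau_h=_FITTED["tau_h"])


def build_parameter_set(label: str, *,
                        geometry: Optional[AxonGeometry] = None,
                        scenario: str = "D",
                        current: Optional[CurrentModel] = None,
                        V_thr: Optional[float] = None,
                        constants: Optional[PhysicalConstants] = None) -> ParameterSet:
    """Construct a parameter set for the given label and (optional) geometry.

    ``label="standard"`` derives everything from first principles;
    ``label="fitted"`` applies the biophysical-model calibration overrides
    (tau, lam coefficient, lam_node coefficient, nodal tau, channel time
    constants, I0, V_thr, d, g); quantities without fitted values (C_m, R_c)
    keep their first-principles derivations.
    """
    if label not in ("standard", "fitted"):
        raise ValueError(f"unknown parameter-set label: {label!r}")
    constants = constants or PhysicalConstants()

    if geometry is None:
        if label == "standard":
            d, g, l = (_STANDARD_DEFAULTS[k] for k in ("d", "g", "l"))
        else:
            d, g, l = _FITTED["d"], _FITTED["g"], 1.0
        geometry = AxonGeometry(d=d, g=g, L=100.0 * d, l=l)

    cable = derive_cable_parameters(geometry, constants)
    if label == "fitted":
        lam = _FITTED["lam_coeff"] * geometry.d * math.sqrt(math.log(1.0 / geometry.g))
        cable = replace(cable, tau=_FITTED["tau"], lam=lam,
                        R_lambda=cable.R_m / lam)
        node = derive_node_parameters(geometry, constants, cable,
                                      lam_node_coeff=_FITTED["lam_node_coeff"])
        node = replace(node, tau_node=_FITTED["tau_node"])
        default_vthr = _FITTED["V_thr"]
    else:
        node = derive_node_parameters(geometry, constants, cable)
        default_vthr = 15.0

    if current is None:
        current = _default_current(label, scenario)
    return ParameterSet(label=label, constants=constants, geometry=geometry,
                        cable=cable, node=node, current=current,
                        V_thr=V_thr if V_thr is not None else default_vthr)


def load_parameter_set(label: str) -> ParameterSet:
    """Return one of the packaged parameter sets (``standard`` or ``fitted``)."""
    return build_parameter_set(label)


# ---------------------------------------------------------------------------
# flat key-value config serialization
# ---------------------------------------------------------------------------

CONFIG_KEYS = ("d_um", "g_ratio", "L_um", "l_um", "N_nodes", "V_thr_mV",
               "I0_pA_per_um2", "tau_m_us", "tau_h_us", "tau_nK_us",
               "tau_k_us", "scenario", "delta_us", "tau_c_us", "gamma",
               "include_potassium", "rho_density")


def parameter_set_to_config(params: ParameterSet,
                            rho_density: float = 1.0) -> dict:
    g, c = params.geometry, params.current
    return {
        "d_um": g.d, "g_ratio": g.g, "L_um": g.L, "l_um": g.l,
        "N_nodes": g.N, "V_thr_mV": params.V_thr,
        "I0_pA_per_um2": c.I0,
        "tau_m_us": c.tau_m * 1e3, "tau_h_us": c.tau_h * 1e3,
        "tau_nK_us": c.tau_nK * 1e3, "tau_k_us": c.tau_k * 1e3,
        "scenario": c.scenario, "delta_us": c.delta * 1e3,
        "tau_c_us": c.tau_c * 1e3, "gamma": c.gamma,
        "include_potassium": c.include_potassium,
        "rho_density": rho_density,
    }


def parameter_set_from_config(config: dict, label: str = "standard") -> ParameterSet:
    """Build a parameter set from a flat key-value mapping (keys CONFIG_KEYS)."""
    from . import currents
    unknown = sorted(set(config) - set(CONFIG_KEYS))
    if unknown:
        raise KeyError(f"unknown config keys: {', '.join(unknown)}")
    cfg = dict(config)
    geometry = AxonGeometry(d=float(cfg.get("d_um", 1.0)),
                            g=float(cfg.get("g_ratio", 0.6)),
                            L=float(cfg.get("L_um", 100.0)),
                            l=float(cfg.get("l_um", 1.0)),
                            N=int(cfg.get("N_nodes", 1000)))
    current = currents.make_current_model(
        str(cfg.get("scenario", "D")),
        I0=float(cfg.get("I0_pA_per_um2", 50.0)),
        tau_m=float(cfg.get("tau_m_us", 20.0)) * 1e-3,
        tau_h=float(cfg.get("tau_h_us", 40.0)) * 1e-3,
        tau_nK=float(cfg.get("tau_nK_us", 150.0)) * 1e-3,
        tau_k=float(cfg.get("tau_k_us", 300.0)) * 1e-3,
        delta=float(cfg.get("delta_us", 30.0)) * 1e-3,
        tau_c=float(cfg.get("tau_c_us", 100.0)) * 1e-3,
        gamma=int(cfg.get("gamma", 1)),
        include_potassium=_as_bool(cfg.get("include_potassium", False)),
    )
    V_thr = float(cfg["V_thr_mV"]) if "V_thr_mV" in cfg else None
    return build_parameter_set(label, geometry=geometry, current=current,
                               V_thr=V_thr)


def _as_bool(value) -> bool:
    if isinstance(value, bool):
        return value
    return str(value).strip().lower() in ("1", "true", "yes", "on")
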