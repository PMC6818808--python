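"""Parameter sweeps, the g-ratio power-law fit, and tabular I/O.

Velocity surfaces over geometry (diameter, g-ratio, node and internode
length), the nonlinear fit of v = kappa (ln(1/g))^alpha, and the config-file
driver used by the command-line interface.  All production paths are
deterministic; solver failures are recorded as rows with ``converged=False``
rather than dropped.
"""

from __future__ import annotations

import datetime as _dt
import itertools
import json
import math
from dataclasses import dataclass, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from . import __version__
from .params import (ParameterSet, build_parameter_set, CONFIG_KEYS,
                     parameter_set_from_config)
from .propagation import PropagationProblem, velocity, membrane_potential
from . import ephaptic as _ephaptic

SWEEP_COLUMNS = ("d_um", "g_ratio", "L_um", "l_um", "scenario", "N",
                 "t_sp_ms", "v_mps", "v_internode_mps", "converged")


def _one_velocity(base: ParameterSet, d, g, L, l, scenario, N,
                  use_node_correction: bool = True):
    p = base.with_geometry(d=d, g=g, L=L, l=l)
    if scenario != p.current.scenario:
        from .currents import make_current_model
        c = p.current
        p = p.with_current(make_current_model(
            scenario, I0=c.I0, tau_m=c.tau_m, tau_h=c.tau_h, tau_nK=c.tau_nK,
            tau_k=c.tau_k, delta=c.delta, tau_c=c.tau_c, gamma=c.gamma,
            include_potassium=c.include_potassium))
    prob = PropagationProblem(params=p, N=N,
                              use_node_correction=use_node_correction)
    return velocity(prob)


def sweep_velocity(base: ParameterSet, *, d=None, g=None, L=None, l=None,
                   scenario=None, N=None,
                   use_node_correction: bool = True) -> pd.DataFrame:
    """Velocity table over the Cartesian grid of the given axes.

    Unspecified axes default to the base parameter set's values.  ``L=None``
    tracks 100*d as d varies (the standard internode-scaling convention);
    pass explicit values to decouple L from d.
    """
    geom = base.geometry
    ds = np.atleast_1d(d if d is not None else geom.d).astype(float)
    gs = np.atleast_1d(g if g is not None else geom.g).astype(float)
    Ls = None if L is None else np.atleast_1d(L).astype(float)
    ls = np.atleast_1d(l if l is not None else geom.l).astype(float)
    scenarios = np.atleast_1d(scenario if scenario is not None
                              else base.current.scenario)
    Ns = np.atleast_1d(N if N is not None else geom.N).astype(int)

    rows = []
    for dv, gv, lv, sv, Nv in itertools.product(ds, gs, ls, scenarios, Ns):
        for Lv in (Ls if Ls is not None else [100.0 * dv]):
            res = _one_velocity(base, dv, gv, Lv, lv, sv, int(Nv),
                                use_node_correction)
            rows.append(dict(d_um=dv, g_ratio=gv, L_um=Lv, l_um=lv,
                             scenario=sv, N=int(Nv), t_sp_ms=res.t_sp,
                             v_mps=res.v_corrected,
                             v_internode_mps=res.v_internode,
                             converged=res.converged))
    return pd.DataFrame(rows, columns=SWEEP_COLUMNS)


def node_internode_grid(base: ParameterSet, *, l_range=(0.5, 3.5),
                        L_range=(27.0, 152.0), n_l: int = 7, n_L: int = 7,
                        N: Optional[int] = None) -> pd.DataFrame:
    """Velocity surface over the node-length x internode-length grid."""
    ls = np.linspace(*l_range, n_l)
    Ls = np.linspace(*L_range, n_L)
    return sweep_velocity(base, d=base.geometry.d, g=base.geometry.g,
                          L=Ls, l=ls, N=N)


@dataclass(frozen=True)
class GRatioFit:
    kappa: float
    alpha_exp: float
    fit_mode: str
    g_grid: tuple
    residual_norm: float


def fit_gratio_exponent(base: ParameterSet, g_grid: Sequence[float],
                        fit_mode: str = "fit_both",
                        use_node_correction: bool = True) -> GRatioFit:
    """Nonlinear least squares of v(g) against kappa (ln(1/g))^alpha.

    Velocities are computed at fixed axon diameter (the base set's d, with L
    held at the base set's L).  ``fit_mode="fixed_half"`` pins alpha = 0.5
    (the classical assumption); ``"fit_both"`` fits kappa and alpha.
    Initialisation is deterministic: alpha = 0.5, kappa from the smallest-g
    endpoint.
    """
    g_grid = np.asarray(sorted(g_grid), dtype=float)
    if g_grid.size < 5 or np.any((g_grid <= 0) | (g_grid >= 1)):
        raise ValueError("need >= 5 g values inside (0, 1)")
    geom = base.geometry
    tab = sweep_velocity(base, d=geom.d, g=g_grid, L=geom.L, l=geom.l,
                         use_node_correction=use_node_correction)
    if not tab.converged.all():
        raise RuntimeError("velocity solve failed on part of the g grid")
    v = tab.sort_values("g_ratio").v_mps.to_numpy()
    return fit_power_law(g_grid, v, fit_mode=fit_mode)


def fit_power_law(g_grid, velocities, fit_mode: str = "fit_both") -> GRatioFit:
    """Least-squares fit of velocities against kappa (ln(1/g))^alpha."""
    if fit_mode not in ("fit_both", "fixed_half"):
        raise ValueError(f"unknown fit_mode {fit_mode!r}")
    g_grid = np.asarray(g_grid, dtype=float)
    v = np.asarray(velocities, dtype=float)
    u = np.log(1.0 / g_grid)
    k0 = v[0] / u[0] ** 0.5
    if fit_mode == "fixed_half":
        model = lambda uu, k: k * uu ** 0.5
        popt, _ = curve_fit(model, u, v, p0=[k0])
        kappa, alpha = float(popt[0]), 0.5
    else:
        model = lambda uu, k, a: k * uu ** a
        popt, _ = curve_fit(model, u, v, p0=[k0, 0.5])
        kappa, alpha = float(popt[0]), float(popt[1])
    resid = v - model(u, *popt)
    return GRatioFit(kappa=kappa, alpha_exp=alpha, fit_mode=fit_mode,
                     g_grid=tuple(g_grid), residual_norm=float(np.linalg.norm(resid)))


def alpha_vs_length_ratio(base: ParameterSet, ratios: Sequence[float],
                          g_grid: Optional[Sequence[float]] = None) -> pd.DataFrame:
    """Fitted exponent alpha as a function of the internode/node ratio L/l."""
    g_grid = np.linspace(0.5, 0.9, 26) if g_grid is None else g_grid
    rows = []
    for r in ratios:
        p = base.with_geometry(L=r * base.geometry.l)
        fit = fit_gratio_exponent(p, g_grid)
        rows.append(dict(L_over_l=r, alpha=fit.alpha_exp, kappa=fit.kappa))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# config-driven runs
# ---------------------------------------------------------------------------

COMMANDS = ("velocity", "sweep", "ephaptic", "fit_g", "profile")
_REQUIRED = {"velocity": ("scenario", "d_um", "g_ratio"),
             "profile": ("scenario", "d_um", "g_ratio"),
             "fit_g": ("scenario", "d_um"),
             "ephaptic": ("scenario",),
             "sweep": ("scenario",)}


def read_config(path) -> dict:
    """Parse a flat ``key = value`` config file (``#`` comments allowed)."""
    cfg = {}
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"malformed config line: {line!r}")
            key, value = (s.strip() for s in line.split("=", 1))
            cfg[key] = value
    return cfg


def run_config(config_file, command: str = "velocity",
               out: Optional[str] = None, label: str = "standard") -> dict:
    """Dispatch a config file to the requested computation.

    Writes the tabular result to ``out`` (CSV, deterministic) plus a JSON
    provenance sidecar (``out + '.json'``) echoing every config key, the
    package version and a timestamp.  Returns the result summary dict.
    """
    if command not in COMMANDS:
        raise ValueError(f"unknown command {command!r}; choose from {COMMANDS}")
    cfg = read_config(config_file) if not isinstance(config_file, dict) else dict(config_file)
    unknown = sorted(set(cfg) - set(CONFIG_KEYS))
    if unknown:
        raise KeyError(f"unknown config keys: {', '.join(unknown)}")
    missing = sorted(set(_REQUIRED[command]) - set(cfg))
    if missing:
        raise KeyError(f"missing required config keys for {command}: "
                       f"{', '.join(missing)}")
    params = parameter_set_from_config(cfg, label=label)
    summary: dict = {"command": command}
    table = None

    if command == "velocity":
        res = velocity(PropagationProblem(params=params))
        summary.update(t_sp_ms=res.t_sp, v_mps=res.v_corrected,
                       v_internode_mps=res.v_internode,
                       converged=bool(res.converged))
        table = pd.DataFrame([summary])
    elif command == "sweep":
        table = node_internode_grid(params)
        summary.update(rows=len(table), v_max_mps=float(table.v_mps.max()))
    elif command == "fit_g":
        fit = fit_gratio_exponent(params, np.linspace(0.5, 0.9, 26))
        summary.update(alpha=fit.alpha_exp, kappa=fit.kappa,
                       residual_norm=fit.residual_norm)
        table = pd.DataFrame([summary])
    elif command == "profile":
        prob = PropagationProblem(params=params)
        res = velocity(prob)
        tg = np.arange(-10 * res.t_sp, 30 * res.t_sp, 5e-4)
        V = membrane_potential(np.array(0.0), tg, prob, res.t_sp)
        table = pd.DataFrame({"x_um": 0.0, "t_ms": tg, "V_mV": V})
        summary.update(t_sp_ms=res.t_sp, v_mps=res.v_corrected,
                       peak_mV=float(V.max()))
    elif command == "ephaptic":
        dt_in = 0.02
        pair = _ephaptic.make_pair(params)
        res_pair, res_single = _ephaptic.paired_velocity(params)
        tg = np.arange(-0.5, 2.0, 2e-3)
        tr = _ephaptic.pair_response(pair, res_single.t_sp, None, 0.0, tg,
                                     N=min(300, params.geometry.N))
        table = pd.DataFrame({"t_ms": tr.t, "P1_mV": tr.P1, "P2_mV": tr.P2})
        dt_out = _ephaptic.entrainment_step(params, dt_in,
                                            N=min(300, params.geometry.N))
        summary.update(v_pair_mps=res_pair.v_corrected,
                       v_single_mps=res_single.v_corrected,
                       dt_in_ms=dt_in, dt_out_ms=dt_out)

    if out is not None:
        table.to_csv(out, index=False)
        sidecar = {"config": cfg, "command": command,
                   "package_version": __version__,
                   "timestamp": _dt.datetime.now(_dt.timezone.utc).isoformat(),
                   "summary": {k: (v if not isinstance(v, float) or math.isfinite(v)
                                   else None) for k, v in summary.items()}}
        with open(str(out) + ".json", "w") as fh:
            json.dump(sidecar, fh, indent=2, default=str)
    summary["table"] = table
    return summary
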