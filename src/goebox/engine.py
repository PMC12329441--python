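"""Coupled derivative assembly and 4-Gyr stiff integration.

The full state concatenates atmosphere, two ocean boxes, crust/mantle and
four bookkeeping integrals, in the fixed ordering of ``STATE_NAMES``.  Every
flux is computed once per evaluation in :func:`compute_fluxes` and appears
in exactly one source and one sink derivative (or an explicit external
boundary: hydrogen escape, mantle outgassing), which makes the mass and
redox ledgers close to solver precision by construction:

* phosphorus:   mantle + continents + dissolved + suspended organics
* carbon:       gases + organics + crust + carbonate closure - mantle input
* fixed N:      pools + organics - cumulative (biological + abiotic) input
* redox:        d/dt [O2 - 2 CH4 - Corg] = 2*escape - mantle reductant

Integration uses an implicit stiff method (BDF) with per-species absolute
floors; the system mixes year-scale photochemistry with Gyr-scale reservoir
growth.  Output is resampled onto a uniform grid (default 1 Myr).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from . import atmosphere, forcings, geosphere, ocean
from .params import Params, T_RUN, C_TO_N, C_TO_P
from .scenario import Scenario

STATE_NAMES = [
    "O2_atm", "CH4_atm", "CO2_atm",
    "PO4_surf", "N_surf", "O2_surf", "Corg_surf",
    "PO4_deep", "N_deep", "O2_deep", "Corg_deep",
    "P_inorg", "P_org", "C_org", "N_org", "mantle_P",
    "carb_C", "esc_cum", "mantle_C_cum", "N_input_cum", "fe_donor_cum",
]
IDX = {name: i for i, name in enumerate(STATE_NAMES)}
N_STATE = len(STATE_NAMES)

#: Bookkeeping integrals may legitimately change sign (carbonate closure).
_SIGNED_STATES = {"carb_C"}

FLUX_NAMES = [
    "solar", "r_mantle", "s_fix", "s_op", "s_fungi", "climate",
    "npp", "npp_ox", "npp_anox", "npp_fe", "fix_bio", "F_abio_N", "export",
    "remin_aer_surf", "remin_anaer_surf", "settle_surf",
    "remin_aer_deep", "remin_anaer_deep", "burial_C",
    "ch4_bio", "ch4_aq_ox", "o2_airsea", "mix_P", "mix_N", "mix_O2",
    "psi", "esc", "mantle_ch4",
    "p_weather", "p_emplace", "oxw_C", "oxw_N", "oxw_P", "oxw_O2",
    "co2_relax",
]


class EngineError(RuntimeError):
    pass


def initial_state(scenario: Scenario) -> np.ndarray:
    p = scenario.params
    y0 = np.zeros(N_STATE)
    y0[IDX["CH4_atm"]] = p.init_ch4
    y0[IDX["CO2_atm"]] = p.co2_ref
    y0[IDX["PO4_surf"]] = p.init_ocean_P
    y0[IDX["N_surf"]] = p.init_ocean_N
    y0[IDX["PO4_deep"]] = p.init_ocean_P * p.vol_deep / p.vol_surf
    y0[IDX["N_deep"]] = p.init_ocean_N * p.vol_deep / p.vol_surf
    y0[IDX["Corg_surf"]] = 1.0e10
    y0[IDX["Corg_deep"]] = 1.0e10
    y0[IDX["P_inorg"]] = 1.0e15
    y0[IDX["mantle_P"]] = p.mantle_P0() * scenario.p_multiplier
    return y0


def compute_fluxes(t: float, y: np.ndarray, fs: forcings.ForcingSet,
                   p: Params) -> dict:
    """Evaluate every named instantaneous flux at one (t, state) point.

    Pure function; reservoirs are floored at zero so that a marginally
    negative solver excursion cannot generate negative outflows.
    """
    o2a = max(y[IDX["O2_atm"]], 0.0)
    ch4a = max(y[IDX["CH4_atm"]], 0.0)
    pO2 = o2a / p.M_bar
    pCH4 = ch4a / p.M_bar

    solar = float(fs.solar_rel(t))
    r_t = float(fs.r_mantle(t))
    s_fix = float(fs.s_fix(t))
    s_op = float(fs.s_op(t))
    s_fungi = float(fs.s_fungi(t))
    climate = (forcings.weathering_climate_factor(solar)
               * forcings.continental_emergence(t, p))

    surf = ocean.OceanBoxState(
        PO4=y[IDX["PO4_surf"]], fixedN=y[IDX["N_surf"]],
        O2_diss=y[IDX["O2_surf"]], Corg=y[IDX["Corg_surf"]])
    deep = ocean.OceanBoxState(
        PO4=y[IDX["PO4_deep"]], fixedN=y[IDX["N_deep"]],
        O2_diss=y[IDX["O2_deep"]], Corg=y[IDX["Corg_deep"]])

    d_fe = float(forcings.fe_donor_flux(t, p))
    bio = ocean.primary_productivity(surf, s_op=s_op, s_fix=s_fix, r_t=r_t,
                                     d_fe=d_fe, p=p)

    aer_s, anaer_s, settle_s, ch4_s, o2cons_s, nret_s, pret_s = \
        ocean.remineralize(surf, p.vol_surf, deep=False, p=p)
    aer_d, anaer_d, burial_c, ch4_d, o2cons_d, nret_d, pret_d = \
        ocean.remineralize(deep, p.vol_deep, deep=True, p=p)

    o2_airsea, ch4_bio, ch4_aq_ox = ocean.biosphere_atmosphere_exchange(
        surf.O2_diss, ch4_s + ch4_d, pO2, p)
    mix_P = ocean.mixing_flux(deep.PO4, surf.PO4, p)
    mix_N = ocean.mixing_flux(deep.fixedN, surf.fixedN, p)
    mix_O2 = ocean.mixing_flux(deep.O2_diss, surf.O2_diss, p)

    psi = atmosphere.methane_oxidation_rate(pO2, pCH4, p)
    esc = atmosphere.hydrogen_escape(pCH4, p)

    # mantle reductant not consumed by the anoxygenic biosphere vents as CH4
    mantle_ch4 = max(r_t - bio.npp_h2, 0.0) / 2.0

    p_weather = geosphere.weather_inorganic_P(
        max(y[IDX["P_inorg"]], 0.0), climate, s_fungi, p)
    p_emplace = forcings.p_emplacement_flux(max(y[IDX["mantle_P"]], 0.0), t, p)
    oxw_c, oxw_n, oxw_p, oxw_o2 = geosphere.oxidative_weathering(
        max(y[IDX["C_org"]], 0.0), max(y[IDX["N_org"]], 0.0),
        max(y[IDX["P_org"]], 0.0), pO2, climate, s_fungi, p)

    co2_relax = (y[IDX["CO2_atm"]] - p.co2_ref) / p.tau_co2

    return {
        "solar": solar, "r_mantle": r_t, "s_fix": s_fix, "s_op": s_op,
        "s_fungi": s_fungi, "climate": climate,
        "npp": bio.npp, "npp_ox": bio.npp_ox, "npp_anox": bio.npp_anox,
        "npp_fe": bio.npp_fe,
        "fix_bio": bio.fix_bio, "F_abio_N": p.F_abio_N, "export": bio.export,
        "remin_aer_surf": aer_s, "remin_anaer_surf": anaer_s,
        "settle_surf": settle_s,
        "remin_aer_deep": aer_d, "remin_anaer_deep": anaer_d,
        "burial_C": burial_c,
        "ch4_bio": ch4_bio, "ch4_aq_ox": ch4_aq_ox, "o2_airsea": o2_airsea,
        "mix_P": mix_P, "mix_N": mix_N, "mix_O2": mix_O2,
        "psi": psi, "esc": esc, "mantle_ch4": mantle_ch4,
        "p_weather": p_weather, "p_emplace": p_emplace,
        "oxw_C": oxw_c, "oxw_N": oxw_n, "oxw_P": oxw_p, "oxw_O2": oxw_o2,
        "co2_relax": co2_relax,
    }


#: states that are physically nonnegative (floored before flux evaluation)
_NONNEG = np.array([n not in _SIGNED_STATES for n in STATE_NAMES])


def derivative(t: float, y: np.ndarray, fs: forcings.ForcingSet,
               p: Params) -> np.ndarray:
    """Full state derivative: sums every flux into its source and sink.

    Marginally negative trial values from the implicit solver are floored
    at zero before flux evaluation, so outflows from an empty reservoir
    vanish and the derivative pulls the state back toward the physical
    region.
    """
    # keep every evaluation finite and bounded: wild trial states from the
    # implicit solver get a well-defined answer and are rejected by error
    # control rather than crashing the linear algebra
    y_raw = np.nan_to_num(np.asarray(y, dtype=float),
                          nan=0.0, posinf=1e30, neginf=-1e30)
    y_raw = np.clip(y_raw, -1e30, 1e30)
    y = np.where(_NONNEG, np.maximum(y_raw, 0.0), y_raw)
    f = compute_fluxes(t, y, fs, p)
    d = np.zeros(N_STATE)

    npp, fix = f["npp"], f["fix_bio"]
    remin_co2 = (f["remin_aer_surf"] + f["remin_aer_deep"]
                 + 0.5 * (f["remin_anaer_surf"] + f["remin_anaer_deep"]))

    d[IDX["O2_atm"]] = f["o2_airsea"] - 2.0 * f["psi"] - f["oxw_O2"]
    d[IDX["CH4_atm"]] = (f["ch4_bio"] + f["mantle_ch4"]
                         - f["psi"] - f["esc"])
    d[IDX["CO2_atm"]] = (f["psi"] + f["esc"] + remin_co2 + f["ch4_aq_ox"]
                         + f["oxw_C"] - npp - f["co2_relax"])

    nret_s = (f["remin_aer_surf"] + f["remin_anaer_surf"]) / C_TO_N
    pret_s = (f["remin_aer_surf"] + f["remin_anaer_surf"]) / C_TO_P
    nret_d = (f["remin_aer_deep"] + f["remin_anaer_deep"]) / C_TO_N
    pret_d = (f["remin_aer_deep"] + f["remin_anaer_deep"]) / C_TO_P

    d[IDX["PO4_surf"]] = (f["p_weather"] + f["oxw_P"] + f["mix_P"] + pret_s
                          - npp / C_TO_P)
    d[IDX["N_surf"]] = (f["F_abio_N"] + fix + f["oxw_N"] + f["mix_N"] + nret_s
                        - npp / C_TO_N)
    d[IDX["O2_surf"]] = (f["npp_ox"] - f["remin_aer_surf"]
                         - 2.0 * f["ch4_aq_ox"]
                         - f["o2_airsea"] + f["mix_O2"])
    d[IDX["Corg_surf"]] = (npp - f["export"] - f["remin_aer_surf"]
                           - f["remin_anaer_surf"] - f["settle_surf"])

    d[IDX["PO4_deep"]] = pret_d - f["mix_P"]
    d[IDX["N_deep"]] = nret_d - f["mix_N"]
    d[IDX["O2_deep"]] = -f["mix_O2"] - f["remin_aer_deep"]
    d[IDX["Corg_deep"]] = (f["export"] + f["settle_surf"]
                           - f["remin_aer_deep"] - f["remin_anaer_deep"]
                           - f["burial_C"])

    d[IDX["P_inorg"]] = f["p_emplace"] - f["p_weather"]
    d[IDX["P_org"]] = f["burial_C"] / C_TO_P - f["oxw_P"]
    d[IDX["C_org"]] = f["burial_C"] - f["oxw_C"]
    d[IDX["N_org"]] = f["burial_C"] / C_TO_N - f["oxw_N"]
    d[IDX["mantle_P"]] = -f["p_emplace"]

    d[IDX["carb_C"]] = f["co2_relax"]
    d[IDX["esc_cum"]] = f["esc"]
    d[IDX["mantle_C_cum"]] = f["mantle_ch4"]
    d[IDX["N_input_cum"]] = fix + f["F_abio_N"]
    d[IDX["fe_donor_cum"]] = f["npp_fe"]

    # relax any negative excursion back to zero (a reservoir at zero with no
    # active fluxes otherwise has a neutral derivative and can drift)
    d -= np.where(_NONNEG, np.minimum(y_raw, 0.0), 0.0) / 30.0

    if not np.all(np.isfinite(d)):
        bad = [STATE_NAMES[i] for i in np.flatnonzero(~np.isfinite(d))]
        raise EngineError(f"non-finite derivative for state(s) {bad} at t={t:.6g}")
    return d


def _atol_vector(p: Params, scale: float) -> np.ndarray:
    # roughly 1e-6 of each species' dynamic scale: micro-variations far below
    # these floors (e.g. sub-1e-13-bar O2 flicker under a thick CH4 shield)
    # are physically meaningless and must not throttle the step size
    base = {
        "O2_atm": 1e9, "CH4_atm": 1e10, "CO2_atm": 1e12,
        "PO4_surf": 1e9, "N_surf": 1e7, "O2_surf": 1e8, "Corg_surf": 1e9,
        "PO4_deep": 1e11, "N_deep": 1e9, "O2_deep": 1e8, "Corg_deep": 1e9,
        "P_inorg": 1e12, "P_org": 1e12, "C_org": 1e13, "N_org": 1e12,
        "mantle_P": 1e13, "carb_C": 1e13, "esc_cum": 1e12,
        "mantle_C_cum": 1e12, "N_input_cum": 1e10, "fe_donor_cum": 1e12,
    }
    return scale * np.array([base[n] for n in STATE_NAMES])


@dataclass
class RunResult:
    """Trajectory of one scenario: states, flux ledger, diagnostics, events."""

    scenario: Scenario
    t: np.ndarray                       # output grid, yr since 4.0 Ga
    states: pd.DataFrame                # one column per reservoir
    fluxes: pd.DataFrame                # one column per named flux
    diagnostics: pd.DataFrame = field(default_factory=pd.DataFrame)
    events: list = field(default_factory=list)

    @property
    def age_ga(self) -> np.ndarray:
        return 4.0 - self.t / 1.0e9

    def to_csv(self, path_prefix: str) -> None:
        """Serialize as delimited time-series plus a JSON metadata sidecar."""
        table = pd.concat(
            [pd.DataFrame({"t_yr": self.t, "age_ga": self.age_ga}),
             self.states.add_prefix("res_"),
             self.fluxes.add_prefix("flux_"),
             self.diagnostics.add_prefix("diag_")], axis=1)
        table.to_csv(f"{path_prefix}.csv", index=False)
        sidecar = {
            "scenario": self.scenario.to_dict(),
            "events": [e.to_dict() for e in self.events],
        }
        with open(f"{path_prefix}.json", "w") as fh:
            json.dump(sidecar, fh, indent=2, default=float)


def run(scenario: Scenario, with_diagnostics: bool = True) -> RunResult:
    """Integrate a scenario over 4 Gyr and return its resampled trajectory.

    Deterministic: repeated calls with the same scenario give bitwise
    identical output.  Raises :class:`EngineError` on solver failure or on a
    negative excursion exceeding the clipping floor.
    """
    p = scenario.params
    fs = forcings.ForcingSet.from_scenario(scenario)
    y0 = initial_state(scenario)
    sv = scenario.solver
    atol = _atol_vector(p, sv.atol_scale)

    t_grid = np.arange(0.0, T_RUN + 0.5 * sv.output_dt, sv.output_dt)
    t_grid[-1] = T_RUN

    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        sol = solve_ivp(
            derivative, (0.0, T_RUN), y0, method="BDF",
            t_eval=t_grid, args=(fs, p),
            rtol=sv.rtol, atol=atol, max_step=sv.max_step)
    if not sol.success:
        raise EngineError(f"solver failed for scenario {scenario.id!r}: {sol.message}")

    ys = sol.y.T.copy()
    # negative-value policy: clip infinitesimal excursions, fail on real ones
    for i, name in enumerate(STATE_NAMES):
        if name in _SIGNED_STATES:
            continue
        col = ys[:, i]
        floor = -max(1e4 * atol[i], 1e-5 * max(col.max(), atol[i]))
        if col.min() < floor:
            raise EngineError(
                f"state {name} fell to {col.min():.3e} (floor {floor:.3e}) "
                f"in scenario {scenario.id!r}")
        np.clip(col, 0.0, None, out=col)

    fluxes = pd.DataFrame(
        [compute_fluxes(t, y, fs, p) for t, y in zip(sol.t, ys)],
        columns=FLUX_NAMES)
    states = pd.DataFrame(ys, columns=STATE_NAMES)
    result = RunResult(scenario=scenario, t=sol.t.copy(),
                       states=states, fluxes=fluxes)
    if with_diagnostics:
        from . import diagnostics as diag
        result.diagnostics = diag.diagnostic_series(result)
        ev = diag.detect_goe(result.t, result.diagnostics["pO2"].to_numpy(),
                             scenario.t_op_model, p)
        result.events = [ev] if ev is not None else []
    return result


@dataclass
class AuditReport:
    max_rel_drift: dict
    violations: list

    @property
    def ok(self) -> bool:
        return not self.violations


def conservation_audit(result: RunResult, tol_mass: float = 1e-6,
                       tol_redox: float = 1e-4) -> AuditReport:
    """Check P/C/N closure and the redox ledger over a finished run.

    Mass closures are relative drifts of conserved totals; the redox ledger
    requires the change in total oxidizing power to equal twice the
    cumulative hydrogen escape minus the integrated mantle reductant input.
    """
    s = result.states
    p = result.scenario.params

    # conserved residual series, each paired with its gross inventory scale
    p_total = (s["mantle_P"] + s["P_inorg"] + s["P_org"]
               + s["PO4_surf"] + s["PO4_deep"]
               + (s["Corg_surf"] + s["Corg_deep"]) / C_TO_P)
    c_gross = (s["CH4_atm"] + s["CO2_atm"] + s["Corg_surf"] + s["Corg_deep"]
               + s["C_org"] + s["carb_C"].abs())
    n_gross = (s["N_surf"] + s["N_deep"] + s["N_org"]
               + (s["Corg_surf"] + s["Corg_deep"]) / C_TO_N)
    totals = {
        "P": (p_total, p_total),
        "C": (c_gross - s["carb_C"].abs() + s["carb_C"] - s["mantle_C_cum"],
              c_gross),
        "N": (n_gross - s["N_input_cum"], n_gross),
    }
    drift = {}
    violations = []
    for name, (series, gross) in totals.items():
        arr = series.to_numpy()
        scale = max(np.abs(gross.to_numpy()).max(), 1.0)
        drift[name] = float(np.abs(arr - arr[0]).max() / scale)
        if drift[name] > tol_mass:
            violations.append(f"{name} closure drift {drift[name]:.2e} > {tol_mass:.0e}")

    # redox: X(t) - X(0) + int(r) + fe_donor_cum = 2 * esc_cum
    X = (s["O2_atm"] + s["O2_surf"] + s["O2_deep"] - 2.0 * s["CH4_atm"]
         - s["Corg_surf"] - s["Corg_deep"] - s["C_org"]).to_numpy()
    t = result.t
    tc = np.minimum(t, p.tau_r)
    r_int = p.r0 * (tc - tc ** 2 / (2.0 * p.tau_r))
    resid = (X - X[0] + r_int + s["fe_donor_cum"].to_numpy()
             - 2.0 * s["esc_cum"].to_numpy())
    scale = max(np.abs(2.0 * s["esc_cum"].to_numpy()).max(), np.abs(r_int).max(), 1.0)
    drift["redox"] = float(np.abs(resid).max() / scale)
    if drift["redox"] > tol_redox:
        violations.append(f"redox ledger residual {drift['redox']:.2e} > {tol_redox:.0e}")

    return AuditReport(max_rel_drift=drift, violations=violations)
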