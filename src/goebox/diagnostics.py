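"""Derived oxygenation diagnostics and event detection.

The central quantity is the oxygen-balance ratio

    Theta = Npp / sqrt(r - dC)

with net primary productivity Npp, mantle reductant influx r and net
geologic organic-carbon accumulation dC, all in mol O2-equivalents per
year.  Atmospheric oxygenation occurs when Theta sustainably exceeds the
critical value 6e8 (in (mol O2-eq yr^-1)^(1/2)); the detector below reads
the transition directly off the pO2 trajectory as the first crossing of
1e-6 bar sustained for a debounce window.

Npp, r and dC are operational definitions in terms of this model's fluxes
(carbon fixation, mantle outgassing in O2-eq, burial minus oxidative
weathering); the parent framework defines them through its own appendix-
level flux set, which the reduced model does not reproduce term by term.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Optional

import numpy as np
import pandas as pd

from .params import Params
from . import atmosphere, geosphere


@dataclass(frozen=True)
class GOEEvent:
    """A sustained oxygenation crossing."""

    t_goe: float          # model years of the first sustained pO2 > 1e-6 bar
    age_goe: float        # same, Ga before present
    delay: float          # yr since oxygenic-photosynthesis onset
    oxic_reached: bool    # pO2 later sustained >= 1e-3 bar

    def to_dict(self) -> dict:
        return asdict(self)


def goe_ratio(npp, r, dC):
    """Theta = Npp / (r - dC)^(1/2); +inf where the net reductant supply
    r - dC is exhausted (oxidation then proceeds unimpeded)."""
    npp = np.asarray(npp, dtype=float)
    net = np.asarray(r, dtype=float) - np.asarray(dC, dtype=float)
    if np.any(npp < 0):
        raise ValueError("npp must be nonnegative")
    with np.errstate(divide="ignore", invalid="ignore"):
        theta = np.where(net > 0.0, npp / np.sqrt(np.maximum(net, 0.0)), np.inf)
    return theta if theta.ndim else float(theta)


def npp_r_dC_series(result) -> pd.DataFrame:
    """The three oxygen-balance fluxes in mol O2-eq yr^-1 (1 C = 1 O2-eq;
    mantle CH4 already counted x2 in r)."""
    f = result.fluxes
    return pd.DataFrame({
        "npp": f["npp"].to_numpy(),
        "r": f["r_mantle"].to_numpy(),
        "dC": geosphere.delta_C(f["burial_C"].to_numpy(), f["oxw_C"].to_numpy()),
    })


def sustained_crossing(t: np.ndarray, series: np.ndarray, level: float,
                       window: float) -> Optional[float]:
    """First time ``series`` exceeds ``level`` and stays above it for at
    least ``window`` years (or through the end of the record)."""
    above = series > level
    if not above.any():
        return None
    # boundaries of runs of True
    idx = np.flatnonzero(np.diff(np.concatenate(([False], above, [False]))))
    for start, stop in idx.reshape(-1, 2):
        t0 = t[start]
        t1 = t[stop - 1]
        if t1 - t0 >= window or stop == len(series):
            return float(t0)
    return None


def detect_goe(t: np.ndarray, pO2: np.ndarray, t_op_on: float,
               p: Params) -> Optional[GOEEvent]:
    """Detect the Great Oxidation: first crossing of pO2 above 1e-6 bar
    sustained for the debounce window (default 10 Myr), so that short
    transient oxidation events do not fire the detector."""
    t_goe = sustained_crossing(t, pO2, p.goe_threshold_pO2, p.goe_debounce)
    if t_goe is None:
        return None
    t_oxic = sustained_crossing(t, pO2, p.oxic_threshold_pO2, p.goe_debounce)
    return GOEEvent(
        t_goe=t_goe,
        age_goe=4.0 - t_goe / 1.0e9,
        delay=t_goe - t_op_on,
        oxic_reached=t_oxic is not None,
    )


def surface_P_fraction(states: pd.DataFrame, p: Params) -> np.ndarray:
    """Total surface phosphorus (continental inorganic + organic, dissolved,
    and suspended organic) as percent of the modern inventory; the mantle
    reservoir is excluded."""
    from .params import C_TO_P
    total = (states["P_inorg"] + states["P_org"]
             + states["PO4_surf"] + states["PO4_deep"]
             + (states["Corg_surf"] + states["Corg_deep"]) / C_TO_P)
    return 100.0 * total.to_numpy() / p.modern_P_surface


def deep_remin_fraction(result, age_start: float, age_stop: float) -> float:
    """Time-averaged percentage of the organic rain into the deep box that
    is remineralized there (rather than buried), over an age window in Ga."""
    if age_start <= age_stop:
        raise ValueError("window must run from older to younger age")
    age = result.age_ga
    mask = (age <= age_start) & (age >= age_stop)
    if not mask.any():
        raise ValueError("empty averaging window")
    f = result.fluxes
    remin = (f["remin_aer_deep"] + f["remin_anaer_deep"]).to_numpy()[mask]
    inflow = (f["export"] + f["settle_surf"]).to_numpy()[mask]
    if not (inflow > 0).any():
        raise ValueError("no export into the deep box inside the window")
    ok = inflow > 0
    return float(100.0 * np.mean(remin[ok] / inflow[ok]))


def o2_lifetime_series(result) -> np.ndarray:
    """Instantaneous atmospheric O2 lifetime: reservoir over the total O2
    sink (photochemical destruction, oxidative weathering, net uptake by
    the ocean)."""
    f = result.fluxes
    s = result.states
    sink = (2.0 * f["psi"] + f["oxw_O2"]
            + np.maximum(-f["o2_airsea"].to_numpy(), 0.0))
    out = np.empty(len(s))
    for i, (o2, sk) in enumerate(zip(s["O2_atm"].to_numpy(), sink.to_numpy()
                                     if hasattr(sink, "to_numpy") else sink)):
        out[i] = atmosphere.o2_lifetime(o2, sk)
    return out


def o2_lifetime_contrast(result) -> dict:
    """Photochemical O2 lifetime contrast across the oxidation transition.

    Evaluates the model's lifetime-versus-pO2 characteristic at the
    transition epoch (CH4 taken at the detected oxygenation crossing):
    tau(pO2) = pO2 * M_bar / (2 Psi(pO2, pCH4)), compared between the
    stable-anoxic threshold (1e-6 bar) and the stable-oxic threshold
    (1e-3 bar).  The ozone shielding factor is what separates the two
    branches, so the log10 contrast measures the shielding-driven lifetime
    extension (about three decades).
    """
    p = result.scenario.params
    if not result.events:
        raise ValueError("no oxygenation event in this run")
    i = int(np.searchsorted(result.t, result.events[0].t_goe))
    pCH4 = float(result.diagnostics["pCH4"].iloc[i])

    def tau(pO2):
        psi = atmosphere.methane_oxidation_rate(pO2, pCH4, p)
        return pO2 * p.M_bar / (2.0 * psi)

    tau_anoxic = tau(p.goe_threshold_pO2)
    tau_oxic = tau(p.oxic_threshold_pO2)
    return {"tau_anoxic": tau_anoxic, "tau_oxic": tau_oxic,
            "log10_contrast": float(np.log10(tau_oxic / tau_anoxic))}


def theta_crossing_time(result) -> Optional[float]:
    """First sustained crossing of Theta above the critical threshold."""
    p = result.scenario.params
    theta = result.diagnostics["theta"].to_numpy()
    finite = np.where(np.isfinite(theta), theta, 1e300)
    return sustained_crossing(result.t, finite, p.theta_crit, p.goe_debounce)


def diagnostic_series(result) -> pd.DataFrame:
    """Assemble the per-step diagnostic table of a finished run."""
    p = result.scenario.params
    s, f = result.states, result.fluxes
    three = npp_r_dC_series(result)
    pO2 = s["O2_atm"].to_numpy() / p.M_bar
    pCH4 = s["CH4_atm"].to_numpy() / p.M_bar
    inflow = (f["export"] + f["settle_surf"]).to_numpy()
    remin_d = (f["remin_aer_deep"] + f["remin_anaer_deep"]).to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        deep_pct = np.where(inflow > 0, 100.0 * remin_d / inflow, np.nan)
    return pd.DataFrame({
        "pO2": pO2,
        "pCH4": pCH4,
        "npp": three["npp"],
        "r": three["r"],
        "dC": three["dC"],
        "theta": goe_ratio(three["npp"], three["r"], three["dC"]),
        "fix_bio": f["fix_bio"].to_numpy(),
        "surface_P_pct": surface_P_fraction(s, p),
        "deep_remin_pct": deep_pct,
        "tau_O2": o2_lifetime_series(result),
    })
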