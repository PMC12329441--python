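"""Time-dependent boundary drivers.

Solar constant, mantle reductant outflux, logistic metabolic switches,
mantle-to-continent phosphorus emplacement and the fungal weathering boost.
All drivers are deterministic pure functions of model time (years since
4.0 Ga) and, where noted, of the current state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .params import Params, T_RUN

#: Logistic steepness such that s(t_on)=0.01 and s(t_on+ramp)=0.99.
_LOGISTIC_K = 2.0 * math.log(99.0)


def solar_rel(t, p: Params):
    """Solar constant relative to modern: linear from ``S0`` at 4.0 Ga to 1
    at present (standard faint-young-Sun scaling)."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0) or np.any(t > T_RUN):
        raise ValueError("t outside the 0..4e9 yr run horizon")
    return p.S0 + (1.0 - p.S0) * t / T_RUN


def mantle_reductant_flux(t, p: Params):
    """Mantle reductant outflux r(t) in mol O2-eq yr^-1, declining linearly
    to zero at ``tau_r``.  Delivered to the surface as CH4 (2 O2-eq each)."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0) or np.any(t > T_RUN):
        raise ValueError("t outside the 0..4e9 yr run horizon")
    return p.r0 * np.maximum(0.0, 1.0 - t / p.tau_r)


def metabolic_switch(t, t_on: Optional[float], ramp: float):
    """Smooth activation fraction of a metabolism.

    Logistic with midpoint at ``t_on + ramp/2``, pinned to 0.01 at onset and
    0.99 at onset+ramp.  ``t_on=None`` (metabolism never evolves) gives 0.
    """
    if ramp <= 0:
        raise ValueError("ramp must be positive")
    t = np.asarray(t, dtype=float)
    if t_on is None:
        return np.zeros_like(t) if t.ndim else 0.0
    k = _LOGISTIC_K / ramp
    x = np.clip(k * (t - (t_on + ramp / 2.0)), -500.0, 500.0)
    s = 1.0 / (1.0 + np.exp(-x))
    return s if t.ndim else float(s)


def p_emplacement_flux(mantle_P: float, t: float, p: Params) -> float:
    """First-order eruptive emplacement of mantle P onto the continents.

    The scenario's ``p_multiplier`` scales the *initial* mantle inventory,
    not this rate coefficient.
    """
    if mantle_P < 0:
        raise ValueError("mantle_P must be nonnegative")
    return p.k_erupt * mantle_P


def fe_donor_flux(t, p: Params):
    """Ceiling on Fe(2+)-fuelled anoxygenic photosynthesis (photoferrotrophy),
    in mol C yr^-1.  The ferrous iron supply is hydrothermal, so it declines
    with mantle activity on the same schedule as the reductant outflux."""
    t = np.asarray(t, dtype=float)
    out = p.D_fe0 * np.maximum(0.0, 1.0 - t / p.tau_r)
    return out if out.ndim else float(out)


def fungal_switch(t, t_fungi_on: float, p: Params, ramp: Optional[float] = None):
    """Continental weathering multiplier: 1 before the fungal colonization
    of land, ramping logistically to the boost factor B >= 1."""
    if ramp is None:
        ramp = p.fungal_ramp
    s = metabolic_switch(t, t_fungi_on, ramp)
    return 1.0 + (p.fungal_boost - 1.0) * s


def weathering_climate_factor(solar: float) -> float:
    """Mild climate multiplier on weathering rates, linear in the relative
    solar constant and normalized to 1 at present."""
    return solar


def continental_emergence(t, p: Params):
    """Fraction of the continental inventory exposed to subaerial
    weathering: logistic growth of emerged land area through the Archean.
    Phosphorus emplaced on still-submerged continents is counted in the
    surface inventory but only weathers as land emerges."""
    t = np.asarray(t, dtype=float)
    x = np.clip((t - p.emerg_t_mid) / p.emerg_width, -500.0, 500.0)
    a = p.emerg_A0 + (1.0 - p.emerg_A0) / (1.0 + np.exp(-x))
    return a if a.ndim else float(a)


def weathering_activity(t, p: Params):
    """Combined weathering modulation: climate factor times emerged area."""
    return weathering_climate_factor(solar_rel(t, p)) * continental_emergence(t, p)


@dataclass(frozen=True)
class ForcingSet:
    """Bound drivers for one scenario (thin convenience wrapper)."""

    t_fix_on: Optional[float]   # model years, None = never
    t_op_on: float              # model years
    t_fungi_on: float           # model years
    ramp: float                 # yr
    params: Params

    def solar_rel(self, t):
        return solar_rel(t, self.params)

    def r_mantle(self, t):
        return mantle_reductant_flux(t, self.params)

    def s_fix(self, t):
        return metabolic_switch(t, self.t_fix_on, self.ramp)

    def s_op(self, t):
        return metabolic_switch(t, self.t_op_on, self.ramp)

    def s_fungi(self, t):
        return fungal_switch(t, self.t_fungi_on, self.params)

    def f_emplace(self, mantle_P, t):
        return p_emplacement_flux(mantle_P, t, self.params)

    @classmethod
    def from_scenario(cls, scenario) -> "ForcingSet":
        return cls(
            t_fix_on=scenario.t_fix_model,
            t_op_on=scenario.t_op_model,
            t_fungi_on=scenario.t_fungi_model,
            ramp=scenario.ramp_duration,
            params=scenario.params,
        )
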