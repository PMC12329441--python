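"""Continental and mantle reservoirs.

Weathering supply of inorganic P to the ocean, oxidative weathering of
buried organic sediments (active only under an oxic atmosphere), burial of
the deep-ocean organic rain, and the net organic-carbon accumulation rate
that enters the oxygen balance as its reducing-power ledger.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .params import Params, C_TO_N, C_TO_P


@dataclass(frozen=True)
class CrustState:
    """Continental/mantle inventories (mol)."""

    P_inorg: float    # weatherable continental inorganic P
    P_org: float      # organic-bound P, inaccessible until oxidative weathering
    C_org: float      # geologic organic carbon
    N_org: float      # organic-bound N
    mantle_P: float


def weather_inorganic_P(P_inorg: float, climate: float, s_fungi: float,
                        p: Params) -> float:
    """Riverine P supply to the surface ocean: first order in the
    continental inorganic reservoir, modulated by the mild climate factor
    and the fungal boost."""
    if P_inorg < 0 or climate < 0 or s_fungi < 0:
        raise ValueError("inputs must be nonnegative")
    return p.k_w_P * P_inorg * climate * s_fungi


def oxw_activation(pO2: float, p: Params):
    """Smooth activation of oxidative weathering: a narrow logistic in
    log10(pO2) centred on the oxic threshold, times a linear O2 dependence
    above it.  Effectively zero for an anoxic atmosphere and an increasing
    function of pO2 in the oxic regime — the negative feedback that pins
    the post-GOE atmosphere just above the oxic threshold."""
    if pO2 <= 0.0:
        return 0.0
    x = (math.log10(pO2) - math.log10(p.oxw_pO2_on)) / p.oxw_width
    gate = 1.0 / (1.0 + math.exp(-min(max(x, -500.0), 500.0)))
    return gate * pO2 / p.oxw_pO2_on


def oxidative_weathering(C_org: float, N_org: float, P_org: float,
                         pO2: float, climate: float, s_fungi: float,
                         p: Params):
    """O2-consuming weathering of buried organic matter.

    Returns ``(c_flux, n_flux, p_flux, o2_consumed)`` in mol yr^-1; the O2
    consumption is 1:1 with the carbon flux (CH2O + O2 -> CO2 + H2O), and N
    and P are carried with the organic matter in proportion to their own
    crustal pools.
    """
    act = oxw_activation(pO2, p) * climate * s_fungi
    c_flux = p.k_oxw * max(C_org, 0.0) * act
    n_flux = p.k_oxw * max(N_org, 0.0) * act
    p_flux = p.k_oxw * max(P_org, 0.0) * act
    return c_flux, n_flux, p_flux, c_flux


def bury(burial_c_flux: float):
    """Crust accumulation from the unremineralized deep-ocean residual.

    Organic matter reaches the sediment at Redfield proportions: returns
    ``(dC_org, dN_org, dP_org)`` accumulation rates in mol yr^-1.
    """
    if burial_c_flux < 0:
        raise ValueError("burial flux must be nonnegative")
    return burial_c_flux, burial_c_flux / C_TO_N, burial_c_flux / C_TO_P


def delta_C(burial_c_flux, oxw_c_flux):
    """Net accumulation rate of geologic organic carbon, in mol O2-eq yr^-1
    (1 mol buried C carries 1 mol O2-eq of reducing power)."""
    return np.asarray(burial_c_flux) - np.asarray(oxw_c_flux)
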