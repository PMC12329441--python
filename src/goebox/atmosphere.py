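"""Atmospheric reservoirs and O2-CH4 photochemistry.

The load-bearing parameterization is the ozone-shielding factor ``g(pO2)``:
mutual O2-CH4 destruction is efficient in an ozone-free atmosphere
(pO2 < 1e-6 bar, g = 1) and suppressed a thousandfold once an ozone layer
has formed (pO2 >= 1e-3 bar, g = 1e-3), with a log-log linear bridge in
between.  This single smooth, nonincreasing factor stands in for a full
photochemistry code; its two plateaus are pinned to the stable anoxic and
oxic atmospheric states, and their 3-decade contrast is what lengthens the
photochemical O2 lifetime across the Great Oxidation.  Once the anoxic
steady state is pushed onto the bridge the destruction term weakens with
rising O2 and the transition runs away: this is the model's GOE mechanism.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import Params


@dataclass(frozen=True)
class AtmosphereState:
    """Molar inventories of the three tracked gases (N2 is inert background)."""

    O2: float
    CH4: float
    CO2: float

    def pO2(self, p: Params) -> float:
        return partial_pressure(self.O2, p)

    def pCH4(self, p: Params) -> float:
        return partial_pressure(self.CH4, p)


def partial_pressure(moles, p: Params):
    """Convert a molar gas inventory to bar: pX = X / M_bar."""
    moles = np.asarray(moles, dtype=float)
    if np.any(moles < 0):
        raise ValueError("gas inventory must be nonnegative")
    out = moles / p.M_bar
    return out if out.ndim else float(out)


def ozone_shield(pO2, p: Params):
    """Ozone-shielding factor g(pO2): 1 below ``g_low``, ``g_floor`` above
    ``g_high``, log-log linear in between.  Continuous and nonincreasing."""
    pO2 = np.asarray(pO2, dtype=float)
    lo, hi, floor = p.g_low, p.g_high, p.g_floor
    with np.errstate(divide="ignore"):
        x = (np.log(np.maximum(pO2, 1e-300)) - np.log(lo)) / (np.log(hi) - np.log(lo))
    x = np.clip(x, 0.0, 1.0)
    g = np.exp(x * np.log(floor))     # 10^(x * log10(floor)) with floor=1e-3
    return g if g.ndim else float(g)


def methane_oxidation_rate(pO2: float, pCH4: float, p: Params) -> float:
    """Net rate of CH4 + 2 O2 -> CO2 + 2 H2O, in mol CH4 yr^-1.

    First order in CH4 and (below the ``K_psi_O2`` saturation, effectively
    everywhere) first order in O2, modulated by ozone shielding: mass
    action in both substrates, so the rate goes smoothly to zero when
    either partial pressure vanishes.  Below the ozone window the O2
    dependence stabilizes the anoxic steady state; across the window the
    shielding factor g cancels the O2 dependence, and the runaway lands on
    the shielded branch — the two stable atmospheric states.  Because the
    per-O2 destruction rate is linear in O2 on both plateaus, the
    photochemical O2 lifetime contrast between them is the shielding
    contrast itself (three decades).
    """
    if pO2 < 0 or pCH4 < 0:
        raise ValueError("partial pressures must be nonnegative")
    if pO2 == 0.0 or pCH4 == 0.0:
        return 0.0
    avail = pO2 / (pO2 + p.K_psi_O2)
    return p.k_ox * p.M_bar * pCH4 * ozone_shield(pO2, p) * avail


def hydrogen_escape(pCH4: float, p: Params) -> float:
    """Diffusion-limited hydrogen escape, expressed as mol CH4 yr^-1 removed.

    Each escaped CH4 leaves its carbon behind as CO2: the surface is
    irreversibly oxidized by 2 mol O2-eq per mol CH4 (O2 itself unchanged).
    """
    if pCH4 < 0:
        raise ValueError("pCH4 must be nonnegative")
    return p.k_esc * p.M_bar * pCH4


def o2_lifetime(o2_moles: float, o2_sink_total: float) -> float:
    """Instantaneous atmospheric O2 lifetime: reservoir over total sink.

    The sink total (mol O2 yr^-1) should include photochemical destruction
    (2 per CH4 oxidized), oxidative weathering and net ocean uptake.
    Returns +inf when the sink vanishes, 0 for an empty reservoir.
    """
    if o2_moles <= 0.0:
        return 0.0
    if o2_sink_total <= 0.0:
        return float("inf")
    return o2_moles / o2_sink_total
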