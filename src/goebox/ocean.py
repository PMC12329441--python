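"""Two-box ocean biology.

Nutrient-limited primary productivity (Liebig law over P, fixed N and the
electron-donor ceiling), demand-following N2 fixation, export, and
aerobic/anaerobic remineralization with methanogenesis.

Productivity stoichiometry is Redfield (C:N:P = 106:16:1).  Aerobic
remineralization is gated by a Monod factor on the local dissolved-O2
concentration: a well-oxygenated surface recycles almost everything in
place, while the anoxic deep box remineralizes methanogenically and leaks a
fixed fraction of its organic rain into the crust.  Surface organic matter
that neither aerobic nor anaerobic processing consumes settles into the deep
box, so a uniformly anoxic ocean exports a much larger share of production
than a redox-stratified one — the feedback that separates weak, N-starved
biospheres from vigorous oxygenic ones.
"""

from __future__ import annotations

from dataclasses import dataclass

from .params import Params, C_TO_N, C_TO_P


@dataclass(frozen=True)
class OceanBoxState:
    """Dissolved and suspended inventories of one ocean box (mol)."""

    PO4: float
    fixedN: float
    O2_diss: float
    Corg: float


@dataclass(frozen=True)
class BioRates:
    """Instantaneous biosphere fluxes (mol yr^-1)."""

    npp: float                # total C fixation
    npp_ox: float             # oxygenic share (produces free O2)
    npp_anox: float           # anoxygenic share (external electron donors)
    npp_h2: float             # anoxygenic share drawing on the mantle reductant
    npp_fe: float             # anoxygenic share drawing on ferrous iron
    fix_bio: float            # biological N2 fixation (mol N yr^-1)
    export: float             # direct export of new production into the deep box


def donor_ceiling(s_op: float, r_t: float, d_fe: float, p: Params) -> float:
    """Electron-donor ceiling on C fixation: mantle reductant (H2/CH4) plus
    the photoferrotrophy ceiling for the anoxygenic biosphere, effectively
    unbounded once oxygenesis is active."""
    return p.beta_anox * r_t + d_fe + s_op * p.D_ox


def primary_productivity(surface: OceanBoxState, s_op: float, s_fix: float,
                         r_t: float, d_fe: float, p: Params) -> BioRates:
    """Liebig-law productivity and demand-following N2 fixation.

    The N-free potential ``min(P-limit, donor ceiling)`` sets the fixation
    demand; fixers cover the gap between that demand and what the dissolved
    fixed-N pool supplies kinetically, up to the ``fix_max`` cap.  Realized
    production is then re-limited by the actual N supply (pool + fixation).

    The anoxygenic share draws first on the mantle reductant (capping its
    delivery to the atmosphere as CH4), then on the ferrous-iron donor; the
    iron-fuelled share imports reducing power from outside the tracked
    ledger and is reported separately so the redox audit can account it.
    """
    P_lim = p.k_upt_P * max(surface.PO4, 0.0) * C_TO_P
    D = donor_ceiling(s_op, r_t, d_fe, p)
    npp_potential = min(P_lim, D)

    n_from_pool = p.k_upt_N * max(surface.fixedN, 0.0)   # mol N yr^-1
    demand_gap = npp_potential / C_TO_N - n_from_pool
    fix_bio = s_fix * min(p.fix_max, max(0.0, demand_gap))

    npp = min(npp_potential, C_TO_N * (n_from_pool + fix_bio))

    npp_anox = (1.0 - s_op) * min(npp, p.beta_anox * r_t + d_fe)
    npp_h2 = min(npp_anox, p.beta_anox * r_t)
    return BioRates(npp=npp, npp_ox=npp - npp_anox, npp_anox=npp_anox,
                    npp_h2=npp_h2, npp_fe=npp_anox - npp_h2,
                    fix_bio=fix_bio, export=export_production(npp, p))


def nitrogen_fixation(surface: OceanBoxState, npp_demand: float, s_fix: float,
                      p: Params) -> float:
    """Biological N2 fixation for a given C-fixation demand (mol N yr^-1).

    Demand-following: covers the unmet Redfield N demand after kinetic
    resupply from the dissolved pool, capped at ``fix_max``.  The abiotic
    fixed-N source (``F_abio_N``) is independent of this term.
    """
    gap = npp_demand / C_TO_N - p.k_upt_N * max(surface.fixedN, 0.0)
    return s_fix * min(p.fix_max, max(0.0, gap))


def export_production(npp: float, p: Params) -> float:
    """Direct export of new production out of the photic zone: f_exp * npp."""
    if npp < 0:
        raise ValueError("npp must be nonnegative")
    return p.f_exp * npp


def aerobic_fraction(o2_conc: float, p: Params) -> float:
    """Monod gate on aerobic remineralization, on dissolved [O2] (mol m^-3)."""
    c = max(o2_conc, 0.0)
    return c / (c + p.K_O2_aer)


def remineralize(box: OceanBoxState, volume: float, deep: bool, p: Params):
    """First-order processing of a box's suspended organic carbon.

    Aerobic respiration (1 O2 per C) competes with anaerobic methanogenic
    remineralization (2 CH2O -> CH4 + CO2, no O2) and with loss from the
    box: settling into the deep box for the surface, burial into the crust
    for the deep box.  Nutrients return to the dissolved pools at Redfield
    proportion to the total C remineralized.

    Returns ``(remin_aerobic, remin_anaerobic, loss, ch4_produced,
    o2_consumed, n_returned, p_returned)`` in mol yr^-1.
    """
    corg = max(box.Corg, 0.0)
    phi = aerobic_fraction(box.O2_diss / volume, p)
    k_anaer = p.k_rem_anaer_deep if deep else p.k_rem_anaer_surf
    k_loss = p.k_bury_deep if deep else p.k_settle_surf

    remin_aer = p.k_rem_aer * phi * corg
    remin_anaer = k_anaer * (1.0 - phi) * corg
    loss = k_loss * corg

    total_remin = remin_aer + remin_anaer
    return (remin_aer, remin_anaer, loss,
            0.5 * remin_anaer,               # CH4 produced
            remin_aer,                       # O2 consumed
            total_remin / C_TO_N,            # N returned
            total_remin / C_TO_P)            # P returned


def methanotroph_fraction(pO2: float, p: Params) -> float:
    """Fraction of biogenic CH4 oxidized in the water column before it can
    outgas.  The methanotrophic filter needs an oxygenated mixed layer, so
    it is gated on atmospheric pO2 (Monod, half-saturation ``K_aq_ch4``):
    negligible under an anoxic atmosphere, near-complete once the
    atmosphere is oxic — which is what collapses the Proterozoic CH4
    greenhouse after the Great Oxidation."""
    x = max(pO2, 0.0)
    return x / (x + p.K_aq_ch4)


def biosphere_atmosphere_exchange(o2_surf: float, ch4_produced: float,
                                  pO2: float, p: Params):
    """Net gas exchange of the marine biosphere with the atmosphere.

    Returns ``(o2_flux, ch4_flux, ch4_aq_oxidized)`` in mol yr^-1: the
    piston-velocity O2 flux (positive seaward-to-air), the CH4 actually
    reaching the atmosphere, and the methanotrophically consumed CH4
    (which draws 2 mol O2 per mol CH4 from the surface box and returns the
    carbon as CO2).
    """
    f_aq = methanotroph_fraction(pO2, p)
    ch4_ox = f_aq * max(ch4_produced, 0.0)
    return (air_sea_o2_flux(o2_surf, pO2, p),
            max(ch4_produced, 0.0) - ch4_ox,
            ch4_ox)


def air_sea_o2_flux(o2_surf: float, pO2: float, p: Params) -> float:
    """Piston-velocity O2 exchange, positive from ocean to atmosphere:
    k_gas * ([O2]_surface - Henry-law saturation)."""
    conc = max(o2_surf, 0.0) / p.vol_surf
    return p.k_gas * (conc - p.H_O2 * pO2)


def mixing_flux(pool_deep: float, pool_surf: float, p: Params) -> float:
    """Overturning exchange of a dissolved species, positive into the
    surface box: Q * ([X]_deep - [X]_surface)."""
    return p.Q_mix * (max(pool_deep, 0.0) / p.vol_deep
                      - max(pool_surf, 0.0) / p.vol_surf)
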