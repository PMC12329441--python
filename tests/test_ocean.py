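"""Marine biosphere: Liebig productivity, fixation, export, remineralization."""

import numpy as np
import pytest

from goebox.params import Params, C_TO_N, C_TO_P
from goebox import ocean


@pytest.fixture(scope="module")
def p():
    return Params()


def box(PO4=0.0, N=0.0, O2=0.0, Corg=0.0):
    return ocean.OceanBoxState(PO4=PO4, fixedN=N, O2_diss=O2, Corg=Corg)


def test_liebig_no_phosphorus_no_production(p):
    bio = ocean.primary_productivity(box(PO4=0.0, N=1e20), s_op=1.0,
                                     s_fix=1.0, r_t=1e14, d_fe=1e14, p=p)
    assert bio.npp == 0.0


def test_donor_ceiling_selected_without_oxygenesis(p):
    # abundant nutrients, no oxygenic pathway: the reductant-limited ceiling
    bio = ocean.primary_productivity(box(PO4=1e25, N=1e22), s_op=0.0,
                                     s_fix=1.0, r_t=1e14, d_fe=0.0, p=p)
    assert bio.npp == pytest.approx(p.beta_anox * 1e14)
    assert bio.npp_anox == pytest.approx(bio.npp)
    assert bio.npp_ox == pytest.approx(0.0)
    # with a ferrous-iron donor available the ceiling includes it
    bio2 = ocean.primary_productivity(box(PO4=1e25, N=1e22), s_op=0.0,
                                      s_fix=1.0, r_t=1e14, d_fe=5e14, p=p)
    assert bio2.npp == pytest.approx(p.beta_anox * 1e14 + 5e14)
    assert bio2.npp_h2 == pytest.approx(p.beta_anox * 1e14)
    assert bio2.npp_fe == pytest.approx(5e14)


def test_oxygenic_share_when_active(p):
    bio = ocean.primary_productivity(box(PO4=1e25, N=1e22), s_op=1.0,
                                     s_fix=1.0, r_t=1e14, d_fe=1e14, p=p)
    full_ceiling = p.D_ox + p.beta_anox * 1e14 + 1e14
    assert bio.npp == pytest.approx(min(full_ceiling, p.k_upt_P * 1e25 * 106,
                                        (p.k_upt_N * 1e22 + p.fix_max) * 106 / 16))
    assert bio.npp_anox == 0.0


def test_fixation_demand_following(p):
    # demand fully met by the dissolved pool -> no biological fixation
    rich = box(PO4=1e15, N=1e20)
    assert ocean.nitrogen_fixation(rich, npp_demand=1e13, s_fix=1.0, p=p) == 0.0
    # no fixers -> zero regardless of demand
    poor = box(PO4=1e15, N=0.0)
    assert ocean.nitrogen_fixation(poor, npp_demand=1e15, s_fix=0.0, p=p) == 0.0
    # gap-covering, capped
    gap = ocean.nitrogen_fixation(poor, npp_demand=1e15, s_fix=1.0, p=p)
    assert gap == pytest.approx(min(p.fix_max, 1e15 / C_TO_N))


def test_export_fraction_exact(p):
    assert ocean.export_production(0.0, p) == 0.0
    npp = 3.3e15
    assert ocean.export_production(npp, p) / npp == pytest.approx(p.f_exp)
    with pytest.raises(ValueError):
        ocean.export_production(-1.0, p)


def test_remineralize_carbon_balance(p):
    """Processing of a box's Corg splits exactly into aerobic + anaerobic +
    loss; CH4 is half the anaerobic carbon; nutrients return at Redfield."""
    b = box(O2=0.0, Corg=1e15)
    aer, anaer, loss, ch4, o2c, nret, pret = ocean.remineralize(
        b, p.vol_deep, deep=True, p=p)
    assert aer == 0.0                      # no O2: no aerobic pathway
    assert ch4 == pytest.approx(0.5 * anaer)
    assert o2c == aer
    assert nret == pytest.approx((aer + anaer) / C_TO_N)
    assert pret == pytest.approx((aer + anaer) / C_TO_P)
    # anoxic deep-box split: remineralized fraction is k_anaer/(k_anaer+k_bury)
    frac = (aer + anaer) / (aer + anaer + loss)
    assert frac == pytest.approx(
        p.k_rem_anaer_deep / (p.k_rem_anaer_deep + p.k_bury_deep))


def test_remineralize_abundant_oxygen_all_aerobic(p):
    b = box(O2=1.0 * p.vol_deep, Corg=1e15)   # 1 mol/m3 >> K_O2
    aer, anaer, loss, ch4, o2c, nret, pret = ocean.remineralize(
        b, p.vol_deep, deep=True, p=p)
    assert anaer < 1e-3 * aer
    assert ch4 < 1e-3 * aer


def test_methanotroph_fraction_gating(p):
    assert ocean.methanotroph_fraction(0.0, p) == 0.0
    assert ocean.methanotroph_fraction(1e-8, p) < 1e-3       # anoxic: filter off
    assert ocean.methanotroph_fraction(1e-2, p) > 0.98       # oxic: near-complete


def test_biosphere_atmosphere_exchange_bookkeeping(p):
    # no remineralization and no methanogenesis: all produced O2 outgasses,
    # no CH4 flux
    o2_pool = 1e15
    o2_flux, ch4_flux, ch4_ox = ocean.biosphere_atmosphere_exchange(
        o2_pool, ch4_produced=0.0, pO2=0.0, p=p)
    assert ch4_flux == 0.0 and ch4_ox == 0.0
    assert o2_flux == pytest.approx(p.k_gas * o2_pool / p.vol_surf)
    # pure methanogenic source under an anoxic sky passes through unoxidized
    _, ch4_flux, ch4_ox = ocean.biosphere_atmosphere_exchange(
        0.0, ch4_produced=1e13, pO2=1e-9, p=p)
    assert ch4_flux == pytest.approx(1e13, rel=1e-4)


def test_mixing_flux_sign_and_equilibrium(p):
    # equal concentrations: no net exchange
    assert ocean.mixing_flux(p.vol_deep * 0.1, p.vol_surf * 0.1, p) == pytest.approx(0.0)
    assert ocean.mixing_flux(p.vol_deep * 0.2, p.vol_surf * 0.1, p) > 0
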