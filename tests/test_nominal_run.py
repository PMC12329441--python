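"""Emergent behaviour of the nominal 4-Gyr run.

These are the physics checks on the reference chronology: the long anoxic
Archean, the early quasi-steady escape balance, redox stratification, and
the numerical robustness of the detected oxygenation age.
"""

import numpy as np
import pytest

from goebox import nominal_scenario, run
from goebox.scenario import SolverSettings
from goebox import diagnostics as diag

from conftest import window_mask


def test_archean_anoxic_then_goe(nominal_result):
    """pO2 stays below 1e-6 bar from the oxygenesis onset at 3.5 Ga down to
    2.5 Ga, and the sustained crossing comes shortly after."""
    d = nominal_result.diagnostics
    arch = window_mask(nominal_result, 3.5, 2.5)
    assert (d["pO2"].to_numpy()[arch] < 1e-6).all()
    assert len(nominal_result.events) == 1
    ev = nominal_result.events[0]
    assert ev.oxic_reached


def test_pre_biotic_escape_balances_mantle_flux(nominal_result):
    """Before the biosphere matters (3.9-3.85 Ga) the atmosphere is in
    quasi-steady state: hydrogen escape (in O2-equivalents, 2 per CH4)
    balances the mantle reductant flux to within 10%."""
    win = window_mask(nominal_result, 3.9, 3.85)
    f = nominal_result.fluxes
    esc_o2eq = 2.0 * f["esc"].to_numpy()[win]
    r = f["r_mantle"].to_numpy()[win]
    assert abs((esc_o2eq - r).mean() / r.mean()) < 0.1


def test_redox_stratification(nominal_result):
    """Surface dissolved O2 never falls below deep dissolved O2 before the
    GOE: the ocean stays redox-stratified."""
    s = nominal_result.states
    pre = nominal_result.t < nominal_result.events[0].t_goe
    surf = s["O2_surf"].to_numpy()[pre] / nominal_result.scenario.params.vol_surf
    deep = s["O2_deep"].to_numpy()[pre] / nominal_result.scenario.params.vol_deep
    assert (surf >= deep - 1e-12).all()


def test_theta_crossing_precedes_goe(nominal_result):
    tc = diag.theta_crossing_time(nominal_result)
    assert tc is not None
    assert tc <= nominal_result.events[0].t_goe + \
        nominal_result.scenario.params.goe_debounce


def test_goe_age_converged_in_tolerance():
    """Tightening the solver tolerance moves the detected oxygenation age
    by less than the output resolution."""
    base = run(nominal_scenario())
    tight = run(nominal_scenario().replace(
        solver=SolverSettings(rtol=5e-9)))
    assert abs(base.events[0].t_goe - tight.events[0].t_goe) <= 2e6


def test_goe_age_invariant_under_grid_refinement(nominal_result):
    fine = run(nominal_scenario().replace(
        solver=SolverSettings(output_dt=5e5)))
    assert abs(fine.events[0].t_goe - nominal_result.events[0].t_goe) <= \
        nominal_result.scenario.params.goe_debounce


def test_two_stable_atmospheric_states(nominal_result):
    """With fluxes frozen at a mid-Archean snapshot, the O2 balance admits a
    stable anoxic root below 1e-6 bar; with the post-GOE methane load it
    admits a stable oxic root at or above 1e-3 bar."""
    from goebox.params import Params
    from goebox import atmosphere
    p = nominal_result.scenario.params
    f = nominal_result.fluxes
    i_pre = np.argmin(np.abs(nominal_result.age_ga - 3.0))
    i_post = np.argmin(np.abs(nominal_result.age_ga - 2.0))

    def o2_balance(pO2, source, ch4_moles):
        psi = atmosphere.methane_oxidation_rate(pO2, ch4_moles / p.M_bar, p)
        return source - 2.0 * psi

    # anoxic branch: the pre-GOE source finds its zero below 1e-6 bar
    src_pre = 2.0 * f["psi"].iloc[i_pre]       # sink balancing the source then
    ch4_pre = nominal_result.states["CH4_atm"].iloc[i_pre]
    lo = np.logspace(-12, -6.05, 200)
    bal = np.array([o2_balance(x, src_pre, ch4_pre) for x in lo])
    assert bal[0] > 0 and bal[-1] < 0          # crossing inside the anoxic range

    # oxic branch: post-GOE CH4 load admits a root at/above 1e-3 bar
    src_post = 2.0 * f["psi"].iloc[i_post]
    ch4_post = nominal_result.states["CH4_atm"].iloc[i_post]
    hi = np.logspace(-3.0, 0, 200)
    bal_hi = np.array([o2_balance(x, src_post, ch4_post) for x in hi])
    assert bal_hi[0] > 0 and bal_hi[-1] < 0


def test_fixation_plateau_below_cap(nominal_result):
    d = nominal_result.diagnostics
    win = window_mask(nominal_result, 3.0, 2.5)
    fx = d["fix_bio"].to_numpy()[win]
    assert (fx < nominal_result.scenario.params.fix_max).all()
    assert fx.min() > 0
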