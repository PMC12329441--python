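# Model description and methods

`goebox` is a reduced-order box model of the coupled carbon, nitrogen,
oxygen and phosphorus cycles over the last four billion years, built to
study what controls the timing of the Great Oxidation Event (GOE): the
onset ages of oxygenic photosynthesis and biological N2 fixation, and the
growth of the weatherable continental phosphorus reservoir.

## Reservoir structure

Sixteen molar reservoirs plus five bookkeeping integrals:

| sphere | reservoirs |
|---|---|
| atmosphere | O2, CH4, CO2 (N2 inert background; `pX = X / M_bar`, `M_bar = 1.8e20` mol/bar) |
| surface ocean (100 m photic layer, 3.6e16 m³) | PO4, fixed N, dissolved O2, suspended organic C |
| deep ocean (1.3e18 m³) | PO4, fixed N, dissolved O2, sinking organic C |
| continents | weatherable inorganic P, organic-bound P, organic C, organic N |
| mantle | P available for eruptive emplacement |
| integrals | carbonate closure, cumulative H escape, mantle C input, fixed-N input, Fe-donor input |

All fluxes are mol yr⁻¹ of the transported species; redox bookkeeping uses
O2-equivalents (1 CH4 = 2 O2-eq, 1 organic C = 1 O2-eq). The derivative is
assembled so that four ledgers close identically: total P; total C against
the cumulative mantle CH4 input and the carbonate closure term; total fixed
N against its cumulative biological + abiotic input; and total oxidizing
power, whose change equals twice the cumulative hydrogen escape minus the
integrated external reductant input (mantle outgassing plus the
ferrous-iron photosynthetic donor). `conservation_audit` verifies all four
on every trajectory (P/C/N to 1e-6 relative, redox to 1e-4).

## Forcings

* Solar constant: linear from 0.75 at 4.0 Ga to 1 today; weathering rates
  carry a mild linear climate multiplier in it.
* Mantle reductant outflux `r(t) = r0 (1 − t/τ_r)`, delivered as CH4;
  `r0 = 1.47e14` mol O2-eq yr⁻¹ and `τ_r = 3.4` Gyr are calibrated so the
  nominal chronology oxygenates at 2.4 Ga and scenarios without N2
  fixation stay anoxic until after the 750 Ma fungal-weathering forcing.
* Metabolic switches: logistic activation with `s(t_on) = 0.01` and
  `s(t_on + ramp) = 0.99`, ramp 100 Myr.
* Continental emergence: logistic growth of the subaerially weatherable
  land fraction (midpoint 3.4 Ga, width 150 Myr, 3% at 4.0 Ga).
  Phosphorus emplaced on still-submerged continents counts toward the
  surface inventory but weathers only as land emerges. This is what keeps
  the pre-oxygenesis ocean P stock low in the nominal chronology; without
  it, everything emplaced before 3.5 Ga ends up dissolved and fuels an
  onset burst that oxygenates the atmosphere a billion years too early.
* Fungal land colonization at 0.75 Ga: logistic ×6 boost on continental
  weathering.
* Photoferrotrophy ceiling `D_fe(t) = 6.5e14 (1 − t/τ_r)` mol C yr⁻¹:
  the Fe²⁺ supply is hydrothermal, so it declines with mantle activity.

## Marine biosphere

Liebig's law with Redfield stoichiometry (C:N:P = 106:16:1):
`npp = min(k_P·PO4_surf·106, N supply·106/16, donor ceiling)`. The donor
ceiling is `β·r(t) + D_fe(t)` for the anoxygenic biosphere (β = 0.7 mol C
per mol O2-eq; the H2/CH4 share is deducted from the CH4 delivered to the
atmosphere, the Fe share imports reducing power that the redox ledger
accounts as an external donor) and effectively unbounded
(`D_ox = 3e16` mol C yr⁻¹) once oxygenesis is active.

The P uptake coefficient is deliberately slow (`k_P = 5e-5 yr⁻¹` on the
surface pool): productivity is then proportional to the standing dissolved
stock. At the quasi-steady plateau this is transparent (the plateau is set
by the weathering input, `npp* = 106·w/b` with `b` the burial fraction of
production), but at an oxygenesis onset it makes the initial productivity
scale with the P stockpile the pre-oxygenic ocean accumulated — the
mechanism by which the dissolved phosphorus reservoir dictates whether the
GOE is immediate or delayed. Nitrogen fixation is demand-following: fixers
cover the gap between the potential (P- or donor-limited) Redfield N
demand and the kinetic supply from the dissolved pool, capped at
`2e13` mol N yr⁻¹; an abiotic source of 1e11 mol N yr⁻¹ operates
throughout.

Production splits into direct export (`f_exp = 0.065`) and a suspended
pool processed by first-order aerobic respiration (Monod-gated on local
dissolved O2, half-saturation 1e-4 mol m⁻³), anaerobic methanogenic
remineralization (2 CH2O → CH4 + CO2), and settling. Under an oxygenated
surface nearly everything recycles in place; under an anoxic surface about
half the residue settles out, so a weak anoxic biosphere exports several
times more of its production — the distinction between redox-stratified
and uniformly anoxic oceans. In the deep box anaerobic remineralization
competes with burial at fixed first-order rates (0.094 vs 0.006 yr⁻¹), so
the anoxic deep ocean remineralizes 94% of its organic rain regardless of
the flux — the invariance across onset scenarios follows structurally.
Biogenic CH4 passes a methanotrophic water-column filter gated on
atmospheric pO2 (half-saturation 1e-4 bar): transparent under an anoxic
sky, near-complete once the atmosphere is oxic, which is what collapses
the methane greenhouse after the GOE.

## Atmosphere

CH4 photo-oxidation is mass action in both substrates with an
ozone-shielding factor: `Ψ = k_ox·M_bar·pCH4·g(pO2)·pO2/(pO2+K)` with
`K = 0.3` bar (so effectively first order in O2 throughout), `g = 1` below
1e-6 bar, `1e-3` above 1e-3 bar, log-log linear between. The anoxic state
is stabilized by the O2 dependence; across the shielding window `g ∝
1/pO2` cancels it, and the atmosphere slides to the shielded branch — the
GOE. Because the per-O2 destruction coefficient is linear in O2 on both
plateaus, the photochemical lifetime contrast between the two thresholds
equals the shielding contrast itself (three decades); the trajectory's
end-to-end lifetime ratio is somewhat larger (~3.7 decades) because CH4
itself declines while the transition is in progress. Hydrogen escape is
diffusion-limited (`1e-4 yr⁻¹` on the CH4 inventory); each escaped CH4
leaves its carbon as CO2, irreversibly oxidizing the surface by 2 O2-eq.
Atmospheric CO2 relaxes toward 5e19 mol on a 3-kyr carbonate-closure
timescale (a fast buffer; its dynamics carry no claims).

## Geosphere

Inorganic P weathering is first order in the continental reservoir times
climate, emergence and the fungal boost. The deep-box burial residual
accretes to the continents at Redfield proportions; organic-bound P is
inaccessible until oxidative weathering activates (narrow logistic in
log pO2 at 1e-3 bar) with a linear O2 dependence above the threshold —
the post-GOE thermostat that pins the Proterozoic atmosphere between
~1e-3 and ~5e-3 bar. Oxidative weathering consumes 1 O2 per C and returns
C, N and P from the crustal organic pools. ΔC, the net accumulation rate
of geologic organic carbon, is burial minus oxidative weathering.

## Emergent chronology (nominal run)

With the frozen constants the nominal scenario (fixation 3.8 Ga,
oxygenesis 3.5 Ga) produces: a CH4-rich anoxic Archean; productivity
rising to a weathering-limited plateau ~1.4e16 mol C yr⁻¹; an N2-fixation
plateau of ~1.1e13 mol N yr⁻¹; 94% deep remineralization; a biogenic
CH4:O2 release ratio of 0.47; surface P crossing 20% of modern at 3.27 Ga;
Θ = Npp/(r−ΔC)^½ crossing 6e8 at ~3.3 Ga; and a sustained oxygenation
crossing at 2.437 Ga followed by a Proterozoic state near 1e-3–5e-3 bar.
The oxygen-balance ratio Θ uses operational flux definitions (carbon
fixation, mantle outgassing in O2-eq, burial minus oxidative weathering);
the parent framework defines these through its own appendix-level flux
set, which this reduced model does not reproduce term by term.

## Numerics

Stiff implicit BDF integration (scipy), rtol 1e-8, per-species absolute
floors at roughly 1e-6 of each reservoir's dynamic scale — tight enough to
resolve partial pressures five decades below the detection threshold,
loose enough not to resolve sub-1e-13-bar flicker. Output is resampled to
a uniform 1 Myr grid; the GOE detector requires a crossing of 1e-6 bar
sustained for 10 Myr so that transient oxidation events (which genuinely
occur in marginal scenarios) do not fire it. Negative solver excursions
are relaxed back to zero inside the derivative and clipped in the output
below a floor of max(1e4·atol, 1e-5 of the species maximum); larger
negativity is a hard error. A full 4-Gyr run takes seconds; the 36-run
experiment grids complete in a few minutes on one core.

## Calibration

Eight constants (`r0`, `τ_r`, `k_ox`, `k_erupt`, `k_w_P`,
`k_rem_anaer_deep`, `β_anox`, `fix_max`) are not printed anywhere and were
fitted once against the anchor set (GOE age 2.4 Ga, fixation plateau 1e13,
94% deep remineralization, 20%-of-modern P at 3.25 Ga, CH4:O2 ratio 0.5,
two-decade productivity/reductant contrast), by manual iteration plus the
derivative-free simplex in `experiments.calibrate`; the result is frozen
as the `Params` defaults. `calibrate()` at the defaults verifies the fixed
point; the perturb-and-recalibrate test demonstrates parameter recovery.

## Design choices and limitations

* The rapid/delayed discriminator is the dissolved-P stockpile at onset
  interacting with the fixation cap and the declining reductant flux; the
  resulting tipping fraction (~20% of modern surface P) emerges from the
  same calibration that sets the nominal chronology, but its exact value
  is grid-quantized by the six onset ages.
* A "negligible" oxygenation delay is one shorter than the 100-Myr
  metabolic ramp: the logistic reaches half activation only 50 Myr after
  onset, so even the limiting instant case registers a ~60-70 Myr delay;
  a cutoff inside the ramp would misclassify it.
* The deep ocean stays anoxic throughout (overturning delivers far less O2
  than remineralization demands), so the Phanerozoic deep-ocean
  oxygenation is outside the model's reach, as is any post-GOE rise of N2
  fixation to modern levels (crustal organic-N weathering floods the
  fixed-N pool instead).
* No-fixation worlds oxygenate when the mantle reductant flux runs out
  (~0.6 Ga), shortly after the fungal forcing rather than because of it.
* No sulfur or iron chemistry (the ferrous donor is a prescribed ceiling,
  not an Fe reservoir), no isotopes, no seafloor weathering or
  hydrothermal P, no spatially resolved circulation, no climate module.
* Scenario configs and grids are generated programmatically; the grid
  generators are pure functions, and the only randomized inputs
  (`sample_scenarios`) drive property tests — the forward model itself is
  deterministic.
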