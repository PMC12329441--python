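"""Model constants: rate coefficients, capacities, stoichiometry, thresholds.

All fluxes are in mol yr^-1 of the transported species, reservoirs in mol,
times in years since 4.0 Ga (the start of the run), partial pressures in bar.
Redox bookkeeping uses mol O2-equivalents: 1 CH4 = 2 O2-eq, 1 organic C =
1 O2-eq.

The values below are the frozen nominal calibration: the handful of free
constants (``r0``, ``tau_r``, ``k_ox``, ``k_erupt``, ``k_w``, ``k_anaer_deep``,
``beta_anox``, ``fix_max``) were fitted once against the printed anchors of
the oxygenation chronology (see ``experiments.calibrate`` and
docs/methods.md) and are not meant to be edited casually.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from typing import Mapping

import yaml

#: Length of the simulated interval: 4.0 Ga before present to today, in years.
T_RUN = 4.0e9

#: Redfield stoichiometry (mol C : mol N : mol P).
REDFIELD_C = 106.0
REDFIELD_N = 16.0
REDFIELD_P = 1.0

#: mol C per mol N / per mol P in organic matter.
C_TO_N = REDFIELD_C / REDFIELD_N
C_TO_P = REDFIELD_C / REDFIELD_P


@dataclass(frozen=True)
class Params:
    """Every constant of the reduced Earth-oxygenation model.

    Grouped by subsystem; units in the field comments.  All entries must be
    strictly positive (checked by :meth:`validate`).
    """

    # --- atmosphere -------------------------------------------------------
    M_bar: float = 1.8e20           # mol of gas per bar of atmosphere
    k_ox: float = 8.0e3             # yr^-1, CH4+2O2 photochemical oxidation coefficient
    K_psi_O2: float = 0.3           # bar, O2 half-saturation of CH4 oxidation (mass-action below)
    k_esc: float = 1.0e-4           # yr^-1, diffusion-limited hydrogen escape (on CH4)
    g_low: float = 1.0e-6           # bar, pO2 below which no ozone shielding (g=1)
    g_high: float = 1.0e-3          # bar, pO2 above which full shielding (g=g_floor)
    g_floor: float = 1.0e-3         # shielding factor at/above g_high (3-decade lifetime gain)
    co2_ref: float = 5.0e19         # mol, reference atmospheric CO2 (carbonate closure)
    tau_co2: float = 3.0e3          # yr, relaxation time of CO2 toward co2_ref

    # --- forcings ---------------------------------------------------------
    S0: float = 0.75                # solar constant at 4.0 Ga relative to modern
    emerg_A0: float = 0.03          # emerged continental area at 4.0 Ga, fraction of final
    emerg_t_mid: float = 6.0e8      # yr, midpoint of continental emergence
    emerg_width: float = 1.5e8      # yr, logistic width of emergence
    r0: float = 1.47e14             # mol O2-eq yr^-1, mantle reductant outflux at 4.0 Ga
    tau_r: float = 3.4e9            # yr, e-folding-to-zero time of the linear reductant decline
    fungal_boost: float = 6.0       # weathering multiplier after fungal land colonization
    fungal_ramp: float = 1.0e8      # yr, logistic ramp of the fungal boost

    # --- marine biosphere -------------------------------------------------
    vol_surf: float = 3.6e16        # m^3, surface-ocean box volume (~100 m photic layer)
    vol_deep: float = 1.3e18        # m^3, deep-ocean box volume
    k_upt_P: float = 5.0e-5          # yr^-1, P uptake rate coefficient on the surface pool
    k_upt_N: float = 0.5            # yr^-1, N uptake rate coefficient on the surface pool
    beta_anox: float = 0.7          # mol C per mol O2-eq, anoxygenic donor-use efficiency
    D_fe0: float = 6.5e14          # mol C yr^-1, photoferrotrophy ceiling at 4.0 Ga (Fe2+ donor)
    D_ox: float = 3.0e16            # mol C yr^-1, effective ceiling of the oxygenic biosphere
    fix_max: float = 2.0e13         # mol N yr^-1, cap on biological N2 fixation
    F_abio_N: float = 1.0e11        # mol N yr^-1, abiotic fixed-N source (volcanic+metamorphic+mantle)
    f_exp: float = 0.065            # direct export fraction of new production
    K_O2_aer: float = 1.0e-4        # mol m^-3, half-saturation of aerobic remineralization
    k_rem_aer: float = 1.0          # yr^-1, aerobic remineralization of suspended/sinking Corg
    k_rem_anaer_surf: float = 0.02  # yr^-1, anaerobic (methanogenic) remineralization, surface box
    k_settle_surf: float = 0.02     # yr^-1, settling of surface Corg residue into the deep box
    k_rem_anaer_deep: float = 0.094  # yr^-1, anaerobic remineralization, deep box
    k_bury_deep: float = 0.006      # yr^-1, burial of deep-box Corg into the crust
    Q_mix: float = 5.0e14           # m^3 yr^-1, surface-deep overturning exchange
    k_gas: float = 4.0e17           # m^3 yr^-1, piston-velocity air-sea O2 exchange (v_p * area)
    H_O2: float = 1.2               # mol m^-3 bar^-1, O2 solubility (Henry coefficient)
    K_aq_ch4: float = 1.0e-4        # bar pO2, half-saturation of the water-column methanotrophic filter

    # --- geosphere --------------------------------------------------------
    k_erupt: float = 6.0e-11        # yr^-1, mantle->continent P emplacement
    k_w_P: float = 2.8e-9           # yr^-1, weathering of continental inorganic P
    k_oxw: float = 2.0e-10          # yr^-1, oxidative weathering of buried organics
    oxw_pO2_on: float = 1.0e-3      # bar, activation threshold of oxidative weathering
    oxw_width: float = 0.15         # decades of pO2, width of the logistic activation
    modern_P_surface: float = 2.4e21  # mol, modern weatherable surface P (percent normalization)

    # --- diagnostics ------------------------------------------------------
    goe_threshold_pO2: float = 1.0e-6   # bar, oxygenation crossing level
    oxic_threshold_pO2: float = 1.0e-3  # bar, stable-oxic level
    goe_debounce: float = 1.0e7         # yr, sustained-crossing window for event detection
    theta_crit: float = 6.0e8           # (mol O2-eq yr^-1)^(1/2), GOE ratio threshold

    # --- initial conditions ----------------------------------------------
    init_ch4: float = 1.0e15        # mol, initial atmospheric CH4 (spin-up value)
    init_ocean_P: float = 1.0e12    # mol, initial dissolved PO4 per box
    init_ocean_N: float = 1.0e12    # mol, initial dissolved fixed N per box

    def mantle_P0(self) -> float:
        """Initial mantle P such that the nominal run reaches 100% modern
        surface P at present (p_multiplier scales this value)."""
        import math
        return self.modern_P_surface / (1.0 - math.exp(-self.k_erupt * T_RUN))

    def validate(self) -> None:
        for name, value in asdict(self).items():
            if not (value > 0):
                raise ValueError(f"Params.{name} must be strictly positive, got {value!r}")
        if self.g_low >= self.g_high:
            raise ValueError("Params.g_low must be below g_high")

    def replace(self, **kwargs) -> "Params":
        p = replace(self, **kwargs)
        p.validate()
        return p

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "Params":
        unknown = set(d) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown Params keys: {sorted(unknown)}")
        p = cls(**d)
        p.validate()
        return p

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# goebox model constants (units documented in goebox.params)\n")
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def load(cls, path) -> "Params":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))
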