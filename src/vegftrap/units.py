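"""Unit conversions used throughout the package.

Internal unit system
--------------------
length  : cm
time    : s
volume  : cm^3 (compartment volumes), L for fluid-phase bookkeeping
conc.   : pM = pmol / L of the *fluid phase* the species lives in
          (plasma for blood species; available interstitial fluid for
          tissue species; surface and matrix species are expressed as
          pmol per liter of the adjacent fluid so that all mass-action
          products are dimensionally uniform)
rates   : kon in M^-1 s^-1 at the config boundary, converted to
          pM^-1 s^-1 internally; first-order rates in s^-1
"""

from __future__ import annotations

import math

AVOGADRO = 6.02214076e23

SECONDS_PER_MINUTE = 60.0
SECONDS_PER_HOUR = 3600.0
SECONDS_PER_DAY = 86400.0

#: 1 M = 1e12 pM
PM_PER_M = 1e12
#: kon given per molar -> per picomolar
KON_M_TO_PM = 1e-12
#: pmol/L -> pmol/cm^3
PM_TO_PMOL_PER_CM3 = 1e-3

UM_PER_CM = 1e4
UM2_PER_CM2 = 1e8
UM3_PER_CM3 = 1e12


def um_to_cm(x: float) -> float:
    return x / UM_PER_CM


def um2_to_cm2(x: float) -> float:
    return x / UM2_PER_CM2


def um3_to_cm3(x: float) -> float:
    return x / UM3_PER_CM3


def days_to_seconds(x: float) -> float:
    return x * SECONDS_PER_DAY


def seconds_to_days(x: float) -> float:
    return x / SECONDS_PER_DAY


def half_life_to_rate(half_life_s: float) -> float:
    """First-order removal rate ln(2)/t_1/2 (s^-1) from a half-life in seconds.

    The 72 h serum half-life of VEGF Trap converts to 1.6e-4 min^-1 this way.
    """
    if half_life_s <= 0:
        raise ValueError("half-life must be positive")
    return math.log(2.0) / half_life_s


def dose_to_moles(dose_mg_per_kg: float, body_weight_g: float, mw_da: float) -> float:
    """Moles of drug delivered by an IV dose expressed in mg per kg body weight."""
    if mw_da <= 0:
        raise ValueError("molecular weight must be positive")
    if dose_mg_per_kg < 0 or body_weight_g <= 0:
        raise ValueError("dose must be >= 0 and body weight > 0")
    mass_g = dose_mg_per_kg * (body_weight_g * 1e-3) * 1e-3  # mg/kg * kg -> mg -> g
    return mass_g / mw_da


def infusion_rate_pM_per_s(
    dose_mg_per_kg: float,
    body_weight_g: float,
    mw_da: float,
    plasma_volume_cm3: float,
    duration_s: float,
) -> float:
    """Constant molar inflow to plasma, as pM/s, for a finite infusion.

    In the limit duration -> 0 the delivered increment equals
    dose * BW / (MW * V_plasma), i.e. a bolus.
    """
    if duration_s <= 0:
        raise ValueError("infusion duration must be positive")
    if plasma_volume_cm3 <= 0:
        raise ValueError("plasma volume must be positive")
    moles = dose_to_moles(dose_mg_per_kg, body_weight_g, mw_da)
    v_liters = plasma_volume_cm3 * 1e-3
    return moles * 1e12 / v_liters / duration_s  # pmol/L/s


def molecules_per_cell_s_to_pM_per_s(
    q: float, cells_per_cm3: float, tissue_volume_cm3: float, fluid_volume_l: float
) -> float:
    """Secretion source: molecules/cell/s into a fluid phase, as pM/s."""
    pmol_per_s = q * cells_per_cm3 * tissue_volume_cm3 / AVOGADRO * 1e12
    return pmol_per_s / fluid_volume_l


def receptors_per_cell_to_pM(
    sites_per_cell: float, cells_per_cm3: float, tissue_volume_cm3: float, fluid_volume_l: float
) -> float:
    """Surface site density expressed as pmol per liter of adjacent fluid."""
    pmol = sites_per_cell * cells_per_cm3 * tissue_volume_cm3 / AVOGADRO * 1e12
    return pmol / fluid_volume_l


def stokes_einstein_radius_nm(mw_da: float) -> float:
    """Empirical Stokes-Einstein radius a_E = 0.483 * MW^0.386 (MW in Da, a_E in nm).

    Used to scale transendothelial permeability of macromolecules such as
    sVEGFR1 from their molecular weight.
    """
    if mw_da <= 0:
        raise ValueError("molecular weight must be positive")
    return 0.483 * mw_da**0.386
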