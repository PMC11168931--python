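"""Physical constants, gas solubility functions and unit conversions.

All solubility functions are for fresh water (zero salinity) at a total
pressure of 1 atm. Gas-phase mixing ratios (ppmv) follow the convention of
a headspace in equilibrium with the liquid: the mixing ratio of the dry gas
in water-saturated air/He at 1 atm total pressure, i.e. the partial pressure
is referenced to ``P_total - p_w(T)``. This is the convention of Weiss &
Price (1980), whose N2O fit is used here.
"""

from __future__ import annotations

import numpy as np

# universal gas constant, J mol-1 K-1
R_GAS = 8.314462618
ATM_PA = 101325.0
T0_K = 273.15

#: moles of electrons accepted per mole of gas respired
ELECTRONS_PER_MOL = {"O2": 4.0, "N2O": 2.0}

#: molar mass of N in N2O-N accounting (two N atoms per N2O), g mol-1
G_N_PER_MOL_N2O = 28.014

SUPPORTED_SOLUBILITY_GASES = ("N2O", "O2")


def water_vapour_pressure_atm(temperature_c: float) -> float:
    """Saturation vapour pressure of fresh water, atm.

    Weiss & Price (1980), eq. (10), at zero salinity; valid 0-40 degC.
    """
    t_k = temperature_c + T0_K
    return float(np.exp(24.4543 - 67.4509 * (100.0 / t_k) - 4.8489 * np.log(t_k / 100.0)))


def _k0_n2o(temperature_c: float) -> float:
    # Weiss & Price (1980), Table 2: K0 in mol l-1 atm-1, S = 0.
    t_k = temperature_c + T0_K
    return float(
        np.exp(-62.7062 + 97.3066 * (100.0 / t_k) + 24.1406 * np.log(t_k / 100.0))
    )


def _k0_o2(temperature_c: float) -> float:
    # Benson & Krause (1984) freshwater O2 saturation (mg l-1, water-saturated
    # air at 1 atm), as standardized by USGS/APHA, converted to a Henry
    # coefficient in mol l-1 atm-1 by dividing out the dry O2 mole fraction.
    t_k = temperature_c + T0_K
    ln_c_star = (
        -139.34411
        + 1.575701e5 / t_k
        - 6.642308e7 / t_k**2
        + 1.2438e10 / t_k**3
        - 8.621949e11 / t_k**4
    )
    c_star_mol_l = np.exp(ln_c_star) / 31.998e3  # mg/l -> mol/l
    x_o2_dry = 0.20946
    p_dry = 1.0 - water_vapour_pressure_atm(temperature_c)
    return float(c_star_mol_l / (x_o2_dry * p_dry))


def henry_coefficient(gas: str, temperature_c: float) -> float:
    """Solubility K0 (mol l-1 atm-1) of ``gas`` in fresh water.

    Supported gases: N2O (Weiss & Price 1980) and O2 (Benson & Krause 1984).
    """
    if not 0.0 <= temperature_c <= 40.0:
        raise ValueError(f"temperature {temperature_c} degC outside supported 0-40 degC")
    if gas == "N2O":
        return _k0_n2o(temperature_c)
    if gas == "O2":
        return _k0_o2(temperature_c)
    raise ValueError(
        f"no solubility function for gas {gas!r}; supported: {SUPPORTED_SOLUBILITY_GASES}"
    )


def _dry_mol_total(headspace_volume_ml: float, temperature_c: float,
                   pressure_pa: float) -> float:
    # the headspace over a liquid culture is water-saturated; mixing ratios
    # refer to the dry gas, so the reference amount excludes water vapour
    t_k = temperature_c + T0_K
    p_dry = pressure_pa - water_vapour_pressure_atm(temperature_c) * ATM_PA
    return p_dry * headspace_volume_ml * 1e-6 / (R_GAS * t_k)


def mol_per_vial_from_ppmv(ppmv, headspace_volume_ml: float, temperature_c: float,
                           pressure_pa: float = ATM_PA):
    """Convert a headspace mixing ratio (ppmv, dry basis) to moles per vial."""
    n_dry = _dry_mol_total(headspace_volume_ml, temperature_c, pressure_pa)
    return np.asarray(ppmv, dtype=float) * 1e-6 * n_dry


def ppmv_from_mol_per_vial(mol, headspace_volume_ml: float, temperature_c: float,
                           pressure_pa: float = ATM_PA):
    """Convert moles per vial to a headspace mixing ratio (ppmv, dry basis)."""
    n_dry = _dry_mol_total(headspace_volume_ml, temperature_c, pressure_pa)
    return np.asarray(mol, dtype=float) / n_dry * 1e6
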