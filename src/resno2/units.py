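"""Gas-phase unit conversions for NO2.

Trace-gas guideline values are quoted interchangeably as mass concentrations
(µg/m³) and mixing ratios (ppbv); stove emission rates as volumetric (mL/h)
and mass (mg/h) rates. All conversions here go through the ideal-gas molar
volume at an explicit temperature and pressure. The default reference state
is 20 °C and 1 atm, which reproduces the conventional pairings
10 µg/m³ ≈ 5.2 ppbv and 25 mL/h ≈ 48 mg/h.
"""

from __future__ import annotations

from dataclasses import dataclass

# CODATA gas constant, J/(mol K)
GAS_CONSTANT = 8.314462618

#: Molar mass of NO2, g/mol. Fixed; not a tunable.
MOLAR_MASS_NO2 = 46.0055


@dataclass(frozen=True)
class GasConditions:
    """Temperature/pressure reference state for gas conversions.

    Parameters
    ----------
    temperature : float
        Absolute temperature in kelvin. Must be positive.
    pressure : float
        Absolute pressure in pascal. Must be positive.
    """

    temperature: float = 293.15
    pressure: float = 101325.0

    def __post_init__(self) -> None:
        if not self.temperature > 0:
            raise ValueError(f"temperature must be > 0 K, got {self.temperature}")
        if not self.pressure > 0:
            raise ValueError(f"pressure must be > 0 Pa, got {self.pressure}")

    @property
    def molar_volume_l(self) -> float:
        """Ideal-gas molar volume in L/mol at these conditions."""
        return GAS_CONSTANT * self.temperature / self.pressure * 1000.0


#: Default reference conditions: 20 °C, 101,325 Pa.
STANDARD_CONDITIONS = GasConditions()


def ugm3_to_ppbv(conc: float, cond: GasConditions = STANDARD_CONDITIONS) -> float:
    """Convert a mass concentration (µg/m³) to a mixing ratio (ppbv).

    ppbv = conc × V_m / M, with V_m the ideal-gas molar volume (L/mol)
    at ``cond`` and M the molar mass of NO2.
    """
    if conc < 0:
        raise ValueError(f"concentration must be >= 0, got {conc}")
    return conc * cond.molar_volume_l / MOLAR_MASS_NO2


def ppbv_to_ugm3(mixing_ratio: float, cond: GasConditions = STANDARD_CONDITIONS) -> float:
    """Convert a mixing ratio (ppbv) to a mass concentration (µg/m³)."""
    if mixing_ratio < 0:
        raise ValueError(f"mixing ratio must be >= 0, got {mixing_ratio}")
    return mixing_ratio * MOLAR_MASS_NO2 / cond.molar_volume_l


def mlh_to_mgh(vol_rate: float, cond: GasConditions = STANDARD_CONDITIONS) -> float:
    """Convert a volumetric emission rate (mL NO2/h) to a mass rate (mg/h).

    mg/h = vol_rate / V_m[mL/mol] × M[mg/mol].
    """
    if vol_rate < 0:
        raise ValueError(f"volumetric rate must be >= 0, got {vol_rate}")
    molar_volume_ml = cond.molar_volume_l * 1000.0
    return vol_rate / molar_volume_ml * (MOLAR_MASS_NO2 * 1000.0)


def mgh_to_mlh(mass_rate: float, cond: GasConditions = STANDARD_CONDITIONS) -> float:
    """Convert a mass emission rate (mg NO2/h) to a volumetric rate (mL/h)."""
    if mass_rate < 0:
        raise ValueError(f"mass rate must be >= 0, got {mass_rate}")
    molar_volume_ml = cond.molar_volume_l * 1000.0
    return mass_rate / (MOLAR_MASS_NO2 * 1000.0) * molar_volume_ml


def mgm3_to_ppbv(conc_mg: float, cond: GasConditions = STANDARD_CONDITIONS) -> float:
    """Convert mg/m³ (the simulator's internal mass unit) to ppbv."""
    return ugm3_to_ppbv(conc_mg * 1000.0, cond)


def per_second_to_per_hour(rate: float) -> float:
    """Convert a first-order rate constant from s⁻¹ to h⁻¹."""
    return rate * 3600.0


def per_hour_to_per_second(rate: float) -> float:
    """Convert a first-order rate constant from h⁻¹ to s⁻¹."""
    return rate / 3600.0
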