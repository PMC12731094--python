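"""Unit conversions used throughout the package.

Internal convention is SI: metres, seconds, mol·m⁻³, Pa.  Dissolved-gas
partial pressures are handled in atm internally and exposed in mmHg where
the literature quotes them; concentrations are reported in µM
(1 mol·m⁻³ = 1000 µM).
"""

from __future__ import annotations

MMHG_PER_ATM = 760.0
UM_PER_MOL_M3 = 1000.0  # 1 mol/m³ = 1 mmol/L = 1000 µmol/L


def mmhg_to_atm(p_mmhg: float) -> float:
    return p_mmhg / MMHG_PER_ATM


def atm_to_mmhg(p_atm: float) -> float:
    return p_atm * MMHG_PER_ATM


def ml_per_min_to_m3_per_s(q: float) -> float:
    """Pump flow rate, mL·min⁻¹ → m³·s⁻¹."""
    return q * 1e-6 / 60.0


def m3_per_s_to_ml_per_min(q: float) -> float:
    return q * 60.0 / 1e-6


def nmol_per_min_to_mol_per_s(rate: float) -> float:
    """Consumption rate, nmol·min⁻¹ → mol·s⁻¹."""
    return rate * 1e-9 / 60.0


def mol_per_s_to_nmol_per_min(rate: float) -> float:
    return rate * 60.0 / 1e-9


def mol_m3_to_um(c):
    """Concentration, mol·m⁻³ → µM (works on arrays)."""
    return c * UM_PER_MOL_M3


def um_to_mol_m3(c):
    return c / UM_PER_MOL_M3
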