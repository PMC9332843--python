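"""Physical constants and unit conversions.

Internal conventions used throughout the package:

* lengths in angstrom (Å),
* electric potential in thermal units k_B T / e,
* energies in k_B T,
* concentrations in mol/L (M) at the API surface, number densities in
  ions/Å³ internally,
* times in picoseconds inside quadratures, rates in s⁻¹ at the surface.
"""

from __future__ import annotations

import math

from scipy import constants as _sc

# CODATA values via scipy
ELEMENTARY_CHARGE = _sc.elementary_charge  # C
BOLTZMANN = _sc.Boltzmann  # J/K
VACUUM_PERMITTIVITY = _sc.epsilon_0  # F/m
AVOGADRO = _sc.Avogadro  # 1/mol

#: 1 mol/L expressed as ions per Å³ (N_A × 10⁻²⁷).
MOLAR_TO_PER_A3 = AVOGADRO * 1e-27
PER_A3_TO_MOLAR = 1.0 / MOLAR_TO_PER_A3

#: Conversion 1 kcal/mol → k_B T at temperature T.
def kcal_per_mol_to_kt(energy: float, temperature: float = 300.0) -> float:
    joule_per_mol = energy * _sc.calorie * 1000.0
    return joule_per_mol / (AVOGADRO * BOLTZMANN * temperature)


def kt_to_kcal_per_mol(energy: float, temperature: float = 300.0) -> float:
    return energy * AVOGADRO * BOLTZMANN * temperature / (_sc.calorie * 1000.0)


def thermal_voltage_mv(temperature: float = 300.0) -> float:
    """k_B T / e in millivolts (≈25.85 mV at 300 K)."""
    return BOLTZMANN * temperature / ELEMENTARY_CHARGE * 1e3


def coulomb_length(temperature: float = 300.0) -> float:
    """e² / (4π ε₀ k_B T) in Å — the vacuum Coulomb (Bjerrum·εr) length.

    ≈ 557 Å at 300 K; dividing by a relative permittivity gives the
    distance at which two unit charges interact with 1 k_B T.
    """
    return (
        ELEMENTARY_CHARGE**2
        / (4.0 * math.pi * VACUUM_PERMITTIVITY * BOLTZMANN * temperature)
        * 1e10
    )


#: Å²/ps → m²/s (1 Å² = 1e-20 m², 1 ps = 1e-12 s).
A2_PER_PS_TO_M2_PER_S = 1e-8
M2_PER_S_TO_A2_PER_PS = 1e8

PS_TO_S = 1e-12
INV_PS_TO_INV_S = 1e12
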