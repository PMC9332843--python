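"""Steric (Bikerman) ion distributions with Born solvation.

The classical Poisson–Boltzmann distribution lets the local counter-ion
concentration grow without bound in deep potential wells.  The Bikerman
(lattice-gas) correction caps it at the reciprocal ion volume 1/a³ — for
K⁺ with a = 2.76 Å that is ≈79 M, which is exactly the saturation level
reached at the carbonyl ridges of the KcsA selectivity filter.  On top of
the electrostatic energy each ion pays a Born solvation penalty for
sitting in a low-dielectric region, evaluated from the local relative
permittivity field.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .constants import (
    BOLTZMANN,
    ELEMENTARY_CHARGE,
    MOLAR_TO_PER_A3,
    VACUUM_PERMITTIVITY,
)

__all__ = [
    "IonSpecies",
    "BikermanParams",
    "potassium",
    "chloride",
    "default_params",
    "born_solvation_delta",
    "bikerman_concentrations",
    "steric_term",
    "debye_length",
    "screening_length",
]

# Exponent clip: e^±600 is finite in float64; the Bikerman ratios saturate
# long before this matters, so clipping only guards transient iterates.
_EXP_CLIP = 600.0


@dataclass(frozen=True)
class IonSpecies:
    """A mobile ion species.

    Parameters
    ----------
    name : str
    valence : int
        Signed charge number (+1 for K⁺, −1 for Cl⁻).
    diameter : float
        Effective (lattice) diameter a in Å; a³ is the excluded volume.
    born_radius : float
        Radius used in the Born solvation term, Å.  Defaults to a/2.
    bulk_concentration : float
        Bulk concentration in mol/L.
    diffusion_coefficient : float
        Bulk diffusion coefficient in m²/s.
    """

    name: str
    valence: int
    diameter: float
    bulk_concentration: float
    diffusion_coefficient: float
    born_radius: float | None = None

    def __post_init__(self) -> None:
        if self.diameter < 0:
            raise ValueError("ion diameter must be >= 0")
        if self.bulk_concentration < 0:
            raise ValueError("bulk concentration must be >= 0")
        if self.born_radius is None:
            object.__setattr__(self, "born_radius", self.diameter / 2.0)
        if self.born_radius <= 0:
            raise ValueError("Born radius must be > 0")

    @property
    def volume(self) -> float:
        """Excluded volume a³ in Å³."""
        return self.diameter**3

    @property
    def bulk_density(self) -> float:
        """Bulk number density in ions/Å³."""
        return self.bulk_concentration * MOLAR_TO_PER_A3


def potassium(concentration: float = 0.1) -> IonSpecies:
    """K⁺ with the model defaults (a = 2.76 Å, D = 1.957e-9 m²/s)."""
    return IonSpecies("K+", +1, 2.76, concentration, 1.957e-9)


def chloride(concentration: float = 0.1) -> IonSpecies:
    """Cl⁻ with the model defaults (a = 3.62 Å, D = 2.032e-9 m²/s)."""
    return IonSpecies("Cl-", -1, 3.62, concentration, 2.032e-9)


@dataclass(frozen=True)
class BikermanParams:
    """Electrolyte + dielectric parameters for the equilibrium model."""

    cation: IonSpecies = field(default_factory=potassium)
    anion: IonSpecies = field(default_factory=chloride)
    temperature: float = 300.0
    eps_bulk: float = 80.0
    eps_protein: float = 2.0
    eps_sf: float = 1.5

    def __post_init__(self) -> None:
        if not (1.0 <= self.eps_sf <= self.eps_bulk):
            raise ValueError("require 1 <= eps_sf <= eps_bulk")
        if self.bulk_void_occupancy >= 1.0:
            raise ValueError(
                "bulk packing fraction p_b*a_p^3 + n_b*a_n^3 must be < 1"
            )

    @property
    def bulk_void_occupancy(self) -> float:
        """Bulk packing fraction p_b a_p³ + n_b a_n³ (dimensionless)."""
        return (
            self.cation.bulk_density * self.cation.volume
            + self.anion.bulk_density * self.anion.volume
        )

    def with_concentration(self, c: float) -> "BikermanParams":
        """Same parameters at a different symmetric bulk concentration."""
        return replace(
            self,
            cation=replace(self.cation, bulk_concentration=c),
            anion=replace(self.anion, bulk_concentration=c),
        )


def default_params(concentration: float = 0.1) -> BikermanParams:
    """The documented defaults: 100 mM KCl, T = 300 K, εr 80/2/1.5."""
    return BikermanParams(
        cation=potassium(concentration), anion=chloride(concentration)
    )


def born_solvation_delta(
    species: IonSpecies,
    eps_local,
    eps_bulk: float = 80.0,
    temperature: float = 300.0,
):
    """Born transfer energy ΔW = z²e²/(8πε₀r)·(1/εr_local − 1/εr_bulk), in k_BT.

    Positive when the local permittivity is below bulk: the cost of
    dragging a charged sphere of radius ``species.born_radius`` into the
    low-dielectric filter.  ``eps_local`` may be a scalar or an array.
    """
    eps_local = np.asarray(eps_local, dtype=float)
    if np.any(eps_local < 1.0) or eps_bulk < 1.0:
        raise ValueError("relative permittivities must be >= 1")
    r = species.born_radius * 1e-10  # m
    prefactor = (
        (species.valence * ELEMENTARY_CHARGE) ** 2
        / (8.0 * math.pi * VACUUM_PERMITTIVITY * r)
        / (BOLTZMANN * temperature)
    )
    out = prefactor * (1.0 / eps_local - 1.0 / eps_bulk)
    return out if out.ndim else float(out)


def bikerman_concentrations(
    phi,
    dw_cation,
    dw_anion,
    params: BikermanParams,
):
    """Equilibrium Bikerman concentrations p, n in mol/L.

    ``phi`` is the electric potential in k_BT/e, ``dw_*`` the Born
    penalties in k_BT (scalars or arrays broadcastable against ``phi``).

    The distribution follows from equating the steric chemical potential
    to its bulk value::

        p a³/(1-v) = p_b a³/(1-v_b) · exp(-z_p φ - ΔW_p)   (and same for n)

    which solves to ``p = p_b E_p / (1 + p_b a_p³ (E_p - 1) + n_b a_n³ (E_n - 1))``
    with the full Boltzmann–Born factor ``E_i = exp(-z_i φ - ΔW_i)``.  As
    a³ → 0 this reduces to the classical Boltzmann–Born distribution; as
    φ → −∞ the cation concentration saturates at 1/a_p³ regardless of the
    solvation penalty, which is what produces the ≈80 M plateaus at the
    carbonyl ridges.
    """
    phi = np.asarray(phi, dtype=float)
    cat, an = params.cation, params.anion
    ep = np.exp(np.clip(-cat.valence * phi - dw_cation, -_EXP_CLIP, _EXP_CLIP))
    en = np.exp(np.clip(-an.valence * phi - dw_anion, -_EXP_CLIP, _EXP_CLIP))
    denom = (
        1.0
        + cat.bulk_density * cat.volume * (ep - 1.0)
        + an.bulk_density * an.volume * (en - 1.0)
    )
    p = cat.bulk_concentration * ep / denom
    n = an.bulk_concentration * en / denom
    if phi.ndim:
        return p, n
    return float(p), float(n)


def steric_term(p, n, params: BikermanParams):
    """Steric part of the chemical potential, log(1 − p a_p³ − n a_n³), in k_BT.

    ``p`` and ``n`` in mol/L.  Approaches −11.5 k_BT at a void fraction of
    10⁻⁵ (the level reached at the saturated carbonyl ridges).
    """
    p = np.asarray(p, dtype=float)
    n = np.asarray(n, dtype=float)
    void = (
        1.0
        - p * MOLAR_TO_PER_A3 * params.cation.volume
        - n * MOLAR_TO_PER_A3 * params.anion.volume
    )
    if np.any(void <= 0.0):
        raise ValueError("void fraction must be positive")
    out = np.log(void)
    return out if out.ndim else float(out)


def debye_length(
    eps_r: float = 1.5, concentration: float = 0.1, temperature: float = 300.0
) -> float:
    """Single-species screening length sqrt(ε₀ εr k_B T / (c₀ e²)) in Å.

    This is the form used to characterise the filter interior (1.89 Å for
    εr = 1.5, c₀ = 100 mM, 300 K).  Note it omits the factor 2 that the
    conventional 1:1-electrolyte Debye length carries; see
    :func:`screening_length` for that form.
    """
    c_number = concentration * 1e3 * 6.02214076e23  # 1/m³
    lam_sq = (
        VACUUM_PERMITTIVITY
        * eps_r
        * BOLTZMANN
        * temperature
        / (c_number * ELEMENTARY_CHARGE**2)
    )
    return math.sqrt(lam_sq) * 1e10


def screening_length(
    eps_r: float = 80.0, concentration: float = 0.1, temperature: float = 300.0
) -> float:
    """Conventional Debye length of a 1:1 salt (factor 2 included), in Å."""
    return debye_length(eps_r, concentration, temperature) / math.sqrt(2.0)
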