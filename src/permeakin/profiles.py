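"""1D free-energy profiles along a permeation coordinate.

Profiles stand in for the potential-of-mean-force curves that biased
sampling (ABF-style) would produce for binding/unbinding and single-file
interconversion steps: smooth sums of signed Gaussian wells and barriers
of a few kcal/mol, tabulated on a fine uniform grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .constants import kcal_per_mol_to_kt

__all__ = [
    "GaussianFeature",
    "SyntheticProfileSpec",
    "EnergyProfile",
    "make_profile",
]

#: Default diffusion coefficients in Å²/ps: bulk bath and filter interior.
D_BATH = 0.235
D_SF = 0.040


@dataclass(frozen=True)
class GaussianFeature:
    """One signed Gaussian: a well (negative) or barrier (positive)."""

    center: float  # Å
    width: float  # Å (standard deviation)
    height: float  # kcal/mol, signed

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("feature width must be > 0")


@dataclass(frozen=True)
class SyntheticProfileSpec:
    """Recipe for a synthetic 1D free-energy profile.

    ``noise_kcal`` adds smooth, seeded roughness (a low-pass filtered
    Gaussian field) so property tests can exercise irregular profiles.
    """

    x_min: float = 0.0
    x_max: float = 15.0
    features: tuple[GaussianFeature, ...] = ()
    diffusion_coefficient: float = D_SF  # Å²/ps
    spacing: float = 0.05  # Å, matching the sampling bin of the biased runs
    noise_kcal: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.x_max <= self.x_min:
            raise ValueError("x_max must exceed x_min")
        if not (0 < self.spacing <= 0.05 + 1e-12):
            raise ValueError("spacing must be in (0, 0.05] Å")
        if self.diffusion_coefficient <= 0:
            raise ValueError("diffusion coefficient must be > 0")


@dataclass(frozen=True)
class EnergyProfile:
    """Tabulated free energy U(x) in k_BT on a uniform, increasing grid.

    ``landmarks`` optionally labels positions along the coordinate, e.g.
    ``{"i": 1.0, "b": 5.0, "f": 9.0}`` for initial well / barrier top /
    final well as used by the first-passage rate formulas.
    """

    x: np.ndarray  # Å
    u: np.ndarray  # k_BT
    diffusion_coefficient: float = D_SF  # Å²/ps
    temperature: float = 300.0
    landmarks: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        u = np.asarray(self.u, dtype=float)
        if x.ndim != 1 or x.size < 2 or np.any(np.diff(x) <= 0):
            raise ValueError("x must be a strictly increasing 1D grid")
        if u.shape != x.shape:
            raise ValueError("u must match x in shape")
        if not np.all(np.isfinite(u)):
            raise ValueError("U must be finite")
        if self.diffusion_coefficient <= 0:
            raise ValueError("diffusion coefficient must be > 0")
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "u", u)

    @property
    def spacing(self) -> float:
        return float(self.x[1] - self.x[0])

    def with_landmarks(self, **marks: float) -> "EnergyProfile":
        lm = dict(self.landmarks)
        lm.update(marks)
        for name, pos in lm.items():
            if not (self.x[0] <= pos <= self.x[-1]):
                raise ValueError(f"landmark {name!r} at {pos} outside grid")
        return replace(self, landmarks=lm)

    def index_of(self, position: float) -> int:
        """Grid index closest to ``position``."""
        if not (self.x[0] - 1e-9 <= position <= self.x[-1] + 1e-9):
            raise ValueError(f"position {position} outside grid")
        return int(np.argmin(np.abs(self.x - position)))


def make_profile(spec: SyntheticProfileSpec, temperature: float = 300.0) -> EnergyProfile:
    """Tabulate the profile described by ``spec``.

    Deterministic for a fixed seed; with no features and no noise the
    profile is identically zero.
    """
    n = int(round((spec.x_max - spec.x_min) / spec.spacing)) + 1
    x = spec.x_min + spec.spacing * np.arange(n)
    u_kcal = np.zeros(n)
    for feat in spec.features:
        u_kcal += feat.height * np.exp(-0.5 * ((x - feat.center) / feat.width) ** 2)
    if spec.noise_kcal > 0.0:
        rng = np.random.default_rng(spec.seed)
        raw = rng.standard_normal(n)
        # smooth over ~1 Å so the roughness stays physical
        sigma_pts = max(1, int(round(1.0 / spec.spacing)))
        kernel = np.exp(-0.5 * (np.arange(-3 * sigma_pts, 3 * sigma_pts + 1) / sigma_pts) ** 2)
        kernel /= kernel.sum()
        smooth = np.convolve(raw, kernel, mode="same")
        u_kcal += spec.noise_kcal * smooth / max(np.std(smooth), 1e-12)
    scale = kcal_per_mol_to_kt(1.0, temperature)
    return EnergyProfile(
        x=x,
        u=u_kcal * scale,
        diffusion_coefficient=spec.diffusion_coefficient,
        temperature=temperature,
    )


def profile_from_arrays(
    x: Sequence[float],
    u_kcal: Sequence[float],
    diffusion_coefficient: float = D_SF,
    temperature: float = 300.0,
) -> EnergyProfile:
    """Build a profile from tabulated (x [Å], U [kcal/mol]) data."""
    scale = kcal_per_mol_to_kt(1.0, temperature)
    return EnergyProfile(
        x=np.asarray(x, dtype=float),
        u=np.asarray(u_kcal, dtype=float) * scale,
        diffusion_coefficient=diffusion_coefficient,
        temperature=temperature,
    )
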