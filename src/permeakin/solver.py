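"""Equilibrium Bikerman–Poisson–Boltzmann solver on the 3D grid.

Solves the variable-coefficient Poisson equation

    ∇·(εr ∇φ) + 4π l_c (z_p p(φ) + z_n n(φ) + q) = 0

in thermal units (φ in k_BT/e, densities in e₀/Å³, l_c the vacuum
Coulomb length ≈557 Å at 300 K) with the steric Bikerman closure for
p and n, Born penalties from the local dielectric, Dirichlet φ = 0 on
the two z faces and zero normal derivative on the lateral faces.
Interface continuity of the dielectric flux is enforced by harmonic
face averaging of εr.

The default algorithm is a damped Newton iteration whose linearised
steps are solved by Jacobi-preconditioned conjugate gradients; an
explicit RK4 pseudo-time relaxation of the same residual is available
as ``method="pseudo_time"`` (the textbook method-of-lines route, only
practical on small grids).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks
from scipy.sparse.linalg import LinearOperator, cg

from .bikerman import BikermanParams, born_solvation_delta
from .constants import MOLAR_TO_PER_A3, PER_A3_TO_MOLAR, coulomb_length
from .geometry import (
    LABEL_PROTEIN,
    ChannelGeometry,
    ChannelGeometrySpec,
    GridSpec,
    make_geometry,
)

__all__ = [
    "FieldState",
    "LineDensity",
    "SolverOptions",
    "ConvergenceError",
    "solve_equilibrium",
    "line_density",
    "epsilon_scan",
]


class ConvergenceError(RuntimeError):
    """Raised when the nonlinear solve fails; carries the residual history."""

    def __init__(self, message: str, history: list[float]):
        super().__init__(message)
        self.residual_history = history


@dataclass(frozen=True)
class SolverOptions:
    """Tolerances and iteration limits for :func:`solve_equilibrium`.

    ``tol`` bounds the scaled residual max-norm ‖h²·F‖∞/(1+‖φ‖∞) (reduced
    units); ``occupancy_tol`` additionally requires the relative change of
    the per-site occupancies between Newton iterates to fall below it.
    """

    tol: float = 1e-6
    occupancy_tol: float = 1e-5
    max_iter: int = 200
    cg_rtol: float = 1e-3
    cg_max_iter: int = 2000
    newton_clamp: float = 25.0  # largest |δφ| per Newton step, k_BT/e
    method: str = "newton"
    pseudo_dt_safety: float = 0.9
    verbose: bool = False


@dataclass(frozen=True)
class FieldState:
    """Converged potential and concentration fields.

    ``phi`` in k_BT/e on the whole grid; ``p``/``n`` in mol/L on solution
    cells (zero inside the protein).
    """

    phi: np.ndarray
    p: np.ndarray
    n: np.ndarray
    residual: float
    iterations: int
    residual_history: tuple[float, ...] = field(default_factory=tuple)


@dataclass(frozen=True)
class LineDensity:
    """Cross-sectionally integrated K⁺ density along the pore axis."""

    z: np.ndarray  # Å
    lam: np.ndarray  # ions/Å
    occupancy: dict[str, float]  # expected ion count per site window


class _System:
    """Precomputed discrete operator pieces for one geometry/parameter set."""

    def __init__(self, geometry: ChannelGeometry, params: BikermanParams):
        self.geometry = geometry
        self.params = params
        self.h = geometry.grid.h
        eps = geometry.eps
        self.shape = eps.shape
        inv_h2 = 1.0 / self.h**2

        def harmonic(a, b):
            return 2.0 * a * b / (a + b)

        # face conductances (interior faces), in units of 1/Å²
        self.cx = harmonic(eps[:-1, :, :], eps[1:, :, :]) * inv_h2
        self.cy = harmonic(eps[:, :-1, :], eps[:, 1:, :]) * inv_h2
        self.cz = harmonic(eps[:, :, :-1], eps[:, :, 1:]) * inv_h2
        # Dirichlet faces at z_min/z_max: half-cell distance
        self.cz_lo = 2.0 * eps[:, :, 0] * inv_h2
        self.cz_hi = 2.0 * eps[:, :, -1] * inv_h2

        self.diag_a = np.zeros(self.shape)
        self.diag_a[:-1, :, :] += self.cx
        self.diag_a[1:, :, :] += self.cx
        self.diag_a[:, :-1, :] += self.cy
        self.diag_a[:, 1:, :] += self.cy
        self.diag_a[:, :, :-1] += self.cz
        self.diag_a[:, :, 1:] += self.cz
        self.diag_a[:, :, 0] += self.cz_lo
        self.diag_a[:, :, -1] += self.cz_hi

        self.solution = geometry.labels != LABEL_PROTEIN
        self.alpha = 4.0 * math.pi * coulomb_length(params.temperature)
        self.q = geometry.q

        # Born penalties from the local dielectric (solution cells)
        self.dw_p = np.where(
            self.solution,
            born_solvation_delta(
                params.cation, np.maximum(eps, 1.0), params.eps_bulk, params.temperature
            ),
            0.0,
        )
        self.dw_n = np.where(
            self.solution,
            born_solvation_delta(
                params.anion, np.maximum(eps, 1.0), params.eps_bulk, params.temperature
            ),
            0.0,
        )
        cat, an = params.cation, params.anion
        self.zp, self.zn = cat.valence, an.valence
        self.pb = cat.bulk_density  # Å⁻³
        self.nb = an.bulk_density
        self.vp = cat.volume
        self.vn = an.volume

    # -- discrete operator ------------------------------------------------
    def apply_a(self, phi: np.ndarray) -> np.ndarray:
        """A φ where A = −∇·(ε∇·) with the stated boundary conditions."""
        out = self.diag_a * phi
        out[:-1, :, :] -= self.cx * phi[1:, :, :]
        out[1:, :, :] -= self.cx * phi[:-1, :, :]
        out[:, :-1, :] -= self.cy * phi[:, 1:, :]
        out[:, 1:, :] -= self.cy * phi[:, :-1, :]
        out[:, :, :-1] -= self.cz * phi[:, :, 1:]
        out[:, :, 1:] -= self.cz * phi[:, :, :-1]
        return out

    # -- Bikerman closure -------------------------------------------------
    def densities(self, phi: np.ndarray, with_derivative: bool = False):
        """Number densities p, n (Å⁻³) and optionally dρ/dφ (ρ = z_p p + z_n n)."""
        ep = np.exp(np.clip(-self.zp * phi - self.dw_p, -600.0, 600.0))
        en = np.exp(np.clip(-self.zn * phi - self.dw_n, -600.0, 600.0))
        denom = 1.0 + self.pb * self.vp * (ep - 1.0) + self.nb * self.vn * (en - 1.0)
        p = np.where(self.solution, self.pb * ep / denom, 0.0)
        n = np.where(self.solution, self.nb * en / denom, 0.0)
        if not with_derivative:
            return p, n
        # bounded form: with occupied fractions f_p = p_b v_p E_p / denom,
        # f_n = n_b v_n E_n / denom (both < 1),
        #   dp/dφ = -p (z_p - z_p f_p - z_n f_n),  and analogously for n
        fp = self.pb * self.vp * ep / denom
        fn = self.nb * self.vn * en / denom
        common = self.zp * fp + self.zn * fn
        dp = -p * (self.zp - common)
        dn = -n * (self.zn - common)
        drho = np.where(self.solution, self.zp * dp + self.zn * dn, 0.0)
        return p, n, drho

    def residual(self, phi: np.ndarray) -> np.ndarray:
        """F(φ) = −Aφ + α(z_p p + z_n n + q)."""
        p, n = self.densities(phi)
        rho = self.zp * p + self.zn * n + self.q
        return -self.apply_a(phi) + self.alpha * rho

    def scaled_residual_norm(self, f: np.ndarray, phi: np.ndarray) -> float:
        return float(np.max(np.abs(f))) * self.h**2 / (1.0 + float(np.max(np.abs(phi))))


def _site_occupancies(
    system: _System, phi: np.ndarray, radius: float = 6.0, half_width: float = 1.5
) -> np.ndarray:
    geom = system.geometry
    sites = geom.spec.site_z
    if not sites:
        return np.zeros(0)
    p, _ = system.densities(phi)
    lam = _integrate_lambda(geom, p * PER_A3_TO_MOLAR, radius)
    z = geom.grid.axis("z")
    out = []
    for z0 in sites.values():
        window = (z >= z0 - half_width) & (z <= z0 + half_width)
        out.append(float(np.sum(lam[window])) * geom.grid.h)
    return np.asarray(out)


def solve_equilibrium(
    geometry: ChannelGeometry,
    params: BikermanParams,
    options: SolverOptions | None = None,
) -> FieldState:
    """Solve for the equilibrium potential and ion distributions.

    Returns a :class:`FieldState`; raises :class:`ConvergenceError` (with
    the residual history attached) if the iteration does not reach the
    requested tolerance.
    """
    opts = options or SolverOptions()
    system = _System(geometry, params)
    if opts.method == "newton":
        return _solve_newton(system, opts)
    if opts.method == "pseudo_time":
        return _solve_pseudo_time(system, opts)
    raise ValueError(f"unknown method {opts.method!r}")


def _solve_newton(system: _System, opts: SolverOptions) -> FieldState:
    phi = np.zeros(system.shape)
    history: list[float] = []
    occ_prev = _site_occupancies(system, phi)
    n_cells = phi.size
    f = system.residual(phi)
    for iteration in range(1, opts.max_iter + 1):
        res = system.scaled_residual_norm(f, phi)
        history.append(res)
        occ = _site_occupancies(system, phi)
        occ_change = (
            float(np.max(np.abs(occ - occ_prev) / (np.abs(occ_prev) + 1e-30)))
            if occ.size and iteration > 1
            else math.inf
        )
        occ_prev = occ
        if opts.verbose:
            print(f"  newton iter {iteration:3d}: residual {res:.3e}")
        if res < opts.tol and (not occ.size or occ_change < opts.occupancy_tol):
            p, n = system.densities(phi)
            return FieldState(
                phi=phi,
                p=p * PER_A3_TO_MOLAR,
                n=n * PER_A3_TO_MOLAR,
                residual=res,
                iterations=iteration - 1,
                residual_history=tuple(history),
            )
        _, _, drho = system.densities(phi, with_derivative=True)
        jac_diag = system.diag_a - system.alpha * drho  # SPD diagonal part
        inv_diag = 1.0 / jac_diag

        def matvec(v: np.ndarray) -> np.ndarray:
            v3 = v.reshape(system.shape)
            out = system.apply_a(v3) - system.alpha * drho * v3
            return out.ravel()

        op = LinearOperator((n_cells, n_cells), matvec=matvec)
        pre = LinearOperator(
            (n_cells, n_cells), matvec=lambda v: (v.reshape(system.shape) * inv_diag).ravel()
        )
        delta, info = cg(
            op,
            f.ravel(),
            rtol=opts.cg_rtol,
            maxiter=opts.cg_max_iter,
            M=pre,
        )
        delta = delta.reshape(system.shape)
        if info > 0:
            # CG hit the iteration cap: use the partial step (still a
            # descent direction for this monotone problem)
            pass
        step_max = float(np.max(np.abs(delta)))
        scale = min(1.0, opts.newton_clamp / step_max) if step_max > 0 else 1.0
        best = None
        for _ in range(8):
            trial = phi + scale * delta
            f_trial = system.residual(trial)
            norm_trial = system.scaled_residual_norm(f_trial, trial)
            if best is None or norm_trial < best[0]:
                best = (norm_trial, trial, f_trial)
            if norm_trial < history[-1]:
                break
            scale *= 0.5
        _, phi, f = best
    raise ConvergenceError(
        f"Newton iteration did not converge in {opts.max_iter} steps "
        f"(last residual {history[-1]:.3e})",
        history,
    )


def _solve_pseudo_time(system: _System, opts: SolverOptions) -> FieldState:
    """Explicit RK4 integration of ∂φ/∂t = ∇·(ε∇φ) + αρ(φ) to steady state."""
    phi = np.zeros(system.shape)
    h2 = system.h**2
    eps_max = float(system.geometry.eps.max())
    history: list[float] = []
    # stability bound of the diffusive operator plus a margin for the
    # (saturating) source-term stiffness
    dt = opts.pseudo_dt_safety * 2.78 * h2 / (12.0 * eps_max)
    max_steps = opts.max_iter
    occ_prev = _site_occupancies(system, phi)
    for step in range(1, max_steps + 1):
        k1 = system.residual(phi)
        k2 = system.residual(phi + 0.5 * dt * k1)
        k3 = system.residual(phi + 0.5 * dt * k2)
        k4 = system.residual(phi + dt * k3)
        phi = phi + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
        if step % 50 == 0 or step == max_steps:
            f = system.residual(phi)
            res = system.scaled_residual_norm(f, phi)
            history.append(res)
            occ = _site_occupancies(system, phi)
            occ_change = (
                float(np.max(np.abs(occ - occ_prev) / (np.abs(occ_prev) + 1e-30)))
                if occ.size
                else 0.0
            )
            occ_prev = occ
            if opts.verbose:
                print(f"  pseudo-time step {step}: residual {res:.3e}")
            if res < opts.tol and occ_change < opts.occupancy_tol:
                p, n = system.densities(phi)
                return FieldState(
                    phi=phi,
                    p=p * PER_A3_TO_MOLAR,
                    n=n * PER_A3_TO_MOLAR,
                    residual=res,
                    iterations=step,
                    residual_history=tuple(history),
                )
    raise ConvergenceError(
        f"pseudo-time marching did not converge in {max_steps} steps "
        f"(last residual {history[-1]:.3e})",
        history,
    )


def _integrate_lambda(
    geometry: ChannelGeometry, p_molar: np.ndarray, radius: float
) -> np.ndarray:
    """λ(z) in ions/Å: xy-integral of [K⁺] over solution cells within ``radius``."""
    grid = geometry.grid
    x = grid.axis("x")
    y = grid.axis("y")
    rr = np.sqrt(x[:, None] ** 2 + y[None, :] ** 2)
    in_cyl = (rr <= radius)[:, :, None] & geometry.solution_mask
    dens = np.where(in_cyl, p_molar, 0.0) * MOLAR_TO_PER_A3  # ions/Å³
    return dens.sum(axis=(0, 1)) * grid.h**2


def line_density(
    state: FieldState,
    geometry: ChannelGeometry,
    radius: float = 6.0,
    half_width: float = 1.5,
) -> LineDensity:
    """Integrate the cation field over the pore cross-section.

    ``radius`` bounds the integration cylinder (large enough to include
    the vestibule sites, small enough to exclude bulk); site occupancies
    integrate λ over ±``half_width`` Å windows around each site.
    """
    lam = _integrate_lambda(geometry, state.p, radius)
    z = geometry.grid.axis("z")
    occupancy = {}
    for name, z0 in geometry.spec.site_z.items():
        window = (z >= z0 - half_width) & (z <= z0 + half_width)
        occupancy[name] = float(np.sum(lam[window])) * geometry.grid.h
    return LineDensity(z=z, lam=lam, occupancy=occupancy)


def count_peaks(
    density: LineDensity,
    z_lo: float,
    z_hi: float,
    prominence_fraction: float = 0.1,
) -> list[float]:
    """Peak z-positions of λ within [z_lo, z_hi].

    A peak must have a prominence above ``prominence_fraction`` of the
    maximum λ inside the window.
    """
    window = (density.z >= z_lo) & (density.z <= z_hi)
    lam = density.lam[window]
    z = density.z[window]
    if lam.size < 3:
        return []
    peaks, _ = find_peaks(lam, prominence=prominence_fraction * float(lam.max()))
    return [float(z[i]) for i in peaks]


def epsilon_scan(
    spec: ChannelGeometrySpec,
    grid: GridSpec,
    params: BikermanParams,
    eps_values=(10.0, 8.0, 6.0, 4.0, 2.0, 1.5),
    options: SolverOptions | None = None,
    radius: float = 6.0,
) -> dict[float, dict[str, float]]:
    """Re-solve the equilibrium per filter dielectric value.

    Returns {ε_SF: site-occupancy table}.  Solver failures are re-raised
    labelled with the offending ε value.  As ε_SF decreases, the Born
    penalty grows and the S1/S4 occupancies fall — the dielectric scan
    that singles out ε_SF = 1.5 as the value emptying S1 and S4.
    """
    results: dict[float, dict[str, float]] = {}
    for eps_sf in eps_values:
        geometry = make_geometry(
            spec,
            grid,
            eps_bulk=params.eps_bulk,
            eps_protein=params.eps_protein,
            eps_sf=eps_sf,
        )
        try:
            state = solve_equilibrium(geometry, params, options)
        except ConvergenceError as exc:
            raise ConvergenceError(
                f"solve failed at eps_SF = {eps_sf}: {exc}", exc.residual_history
            ) from exc
        density = line_density(state, geometry, radius=radius)
        results[float(eps_sf)] = dict(density.occupancy)
    return results
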