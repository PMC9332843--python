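"""Rate theory: first-passage rates, Kramers, Smoluchowski, voltage tilts."""

import math

import numpy as np
import pytest
import scipy.sparse as sp
import scipy.sparse.linalg as spl
from scipy.integrate import trapezoid

from permeakin.constants import kcal_per_mol_to_kt, thermal_voltage_mv
from permeakin.profiles import (
    EnergyProfile,
    GaussianFeature,
    SyntheticProfileSpec,
    make_profile,
)
from permeakin.rates import (
    VoltageTilt,
    kramers_rate,
    mean_first_passage_time,
    mfpt_rate,
    rates_vs_voltage,
    smoluchowski_cylindrical,
    smoluchowski_hemispherical,
    tilt_profile,
)

D_BATH = 0.235
D_K_BULK = 1.957e-9  # m²/s


def double_parabola_profile(barrier_kcal: float, half_distance: float) -> EnergyProfile:
    """Matched double-parabola barrier: wells at ±d, barrier at 0.

    Well and barrier curvatures are both 4ΔU/d² (ΔU in k_BT); the domain
    extends one well-width beyond each minimum so the basins are complete.
    """
    delta = kcal_per_mol_to_kt(barrier_kcal)
    d = half_distance

    def u(x):
        x = np.asarray(x)
        a = np.abs(x)
        return np.where(a <= d / 2, delta * (1 - 2 * (x / d) ** 2),
                        2 * delta * ((a - d) / d) ** 2)

    x = np.linspace(-2 * d, 2 * d, 4001)
    return EnergyProfile(x=x, u=u(x), diffusion_coefficient=D_BATH).with_landmarks(
        i=-d, b=0.0, f=d
    )


def chain_rate(profile: EnergyProfile) -> float:
    """Independent oracle: the same two-well rate on a discretised random walk.

    Nearest-neighbour hops with detailed-balance rates (D/h²)e^{−ΔU/2};
    passage times from a linear solve of the chain equations, basin
    weights from sums of e^{−U}.  Returns s⁻¹.
    """
    x, u, d = profile.x, profile.u, profile.diffusion_coefficient
    h = x[1] - x[0]
    ib = profile.index_of(profile.landmarks["b"])
    if profile.landmarks["f"] < profile.landmarks["i"]:
        x, u = -x[::-1], u[::-1]
        ib = len(x) - 1 - ib

    def chain_mfpt(xs, us, absorb_index):
        n = len(xs)
        up = d / h**2 * np.exp(-(us[1:] - us[:-1]) / 2)
        dn = d / h**2 * np.exp(-(us[:-1] - us[1:]) / 2)
        keep = [k for k in range(n) if k != absorb_index]
        idx = {k: j for j, k in enumerate(keep)}
        a = sp.lil_matrix((n - 1, n - 1))
        for k in keep:
            j, tot = idx[k], 0.0
            if k + 1 < n:
                tot += up[k]
                if k + 1 != absorb_index:
                    a[j, idx[k + 1]] += up[k]
            if k - 1 >= 0:
                tot += dn[k - 1]
                if k - 1 != absorb_index:
                    a[j, idx[k - 1]] += dn[k - 1]
            a[j, j] -= tot
        tau = spl.spsolve(a.tocsr(), -np.ones(n - 1))
        return tau

    tau_left = chain_mfpt(x[: ib + 1], u[: ib + 1], ib)[0]
    tau_right = chain_mfpt(x[ib:], u[ib:], 0)
    tau_right = tau_right[-1]
    z_f = trapezoid(np.exp(-(u[: ib + 1] - u.min())), x[: ib + 1])
    z_b = trapezoid(np.exp(-(u[ib:] - u.min())), x[ib:])
    return 1e12 / (tau_left + tau_right * z_f / z_b)


class TestMeanFirstPassage:
    def test_flat_profile_free_diffusion(self):
        prof = EnergyProfile(
            x=np.linspace(0, 10, 2001), u=np.zeros(2001), diffusion_coefficient=D_BATH
        )
        tau = mean_first_passage_time(prof, 0.0, 10.0)
        assert tau == pytest.approx(10.0**2 / (2 * D_BATH), rel=1e-6)  # 212.8 ps
        assert 1e12 / tau == pytest.approx(4.7e9, rel=0.01)

    def test_quadratic_barrier_rate_order_of_magnitude(self):
        # 5 kcal/mol barrier, 2 Å well-to-peak, bath diffusion coefficient:
        # the analytic estimate for this landscape is ~1e8 s⁻¹
        prof = double_parabola_profile(5.0, 2.0)
        k = mfpt_rate(prof)
        assert 10**7.5 <= k <= 10**8.5

    def test_missing_landmarks_rejected(self):
        prof = EnergyProfile(x=np.linspace(0, 5, 101), u=np.zeros(101))
        with pytest.raises(ValueError, match="landmarks"):
            mfpt_rate(prof)

    def test_coarse_basin_rejected(self):
        prof = EnergyProfile(x=np.linspace(0, 5, 31), u=np.zeros(31)).with_landmarks(
            i=0.0, b=0.5, f=5.0
        )
        with pytest.raises(ValueError, match="coarse"):
            mfpt_rate(prof)

    @pytest.mark.parametrize("seed", range(6))
    def test_agrees_with_random_walk_oracle(self, seed):
        rng = np.random.default_rng(seed)
        depth_i = float(rng.uniform(1.5, 5.0))
        depth_f = float(rng.uniform(1.5, 5.0))
        barrier = float(rng.uniform(1.0, 4.0))
        spec = SyntheticProfileSpec(
            0.0, 12.0,
            (
                GaussianFeature(3.0, float(rng.uniform(0.5, 0.9)), -depth_i),
                GaussianFeature(6.0, float(rng.uniform(0.6, 1.0)), barrier),
                GaussianFeature(9.0, float(rng.uniform(0.5, 0.9)), -depth_f),
            ),
            diffusion_coefficient=0.04,
            noise_kcal=0.15,
            seed=seed,
        )
        prof = make_profile(spec).with_landmarks(i=3.0, b=6.0, f=9.0)
        assert mfpt_rate(prof) == pytest.approx(chain_rate(prof), rel=0.02)

    def test_mirrored_landmarks_give_reverse_rate(self):
        spec = SyntheticProfileSpec(
            0.0, 12.0,
            (
                GaussianFeature(3.0, 0.6, -4.0),
                GaussianFeature(6.0, 0.8, 2.0),
                GaussianFeature(9.0, 0.6, -2.0),
            ),
        )
        prof = make_profile(spec).with_landmarks(i=3.0, b=6.0, f=9.0)
        back = prof.with_landmarks(i=9.0, b=6.0, f=3.0)
        # deeper initial well => slower escape
        assert mfpt_rate(prof) < mfpt_rate(back)


class TestKramers:
    def test_zero_barrier_prefactor(self):
        k = kramers_rate(0.0, 2.0, 2.0, D_BATH)
        assert k == pytest.approx(D_BATH / (2 * math.pi) * 2.0 * 1e12, rel=1e-12)

    def test_arrhenius_factor(self):
        k1 = kramers_rate(6.0, 1.0, 1.0, D_BATH)
        k2 = kramers_rate(7.0, 1.0, 1.0, D_BATH)
        assert k2 / k1 == pytest.approx(math.exp(-1.0), rel=1e-12)

    @pytest.mark.parametrize("barrier_kcal", [3.0, 5.0, 7.0])
    def test_matches_mfpt_within_factor_two(self, barrier_kcal):
        d = 2.0
        delta = kcal_per_mol_to_kt(barrier_kcal)
        curvature = 4 * delta / d**2
        k_kramers = kramers_rate(delta, curvature, curvature, D_BATH)
        k_mfpt = mfpt_rate(double_parabola_profile(barrier_kcal, d))
        assert 0.5 <= k_mfpt / k_kramers <= 2.0

    def test_invalid_curvature(self):
        with pytest.raises(ValueError):
            kramers_rate(1.0, -1.0, 1.0, D_BATH)


class TestSmoluchowski:
    def test_hemispherical_free_diffusion_closed_form(self):
        r = np.linspace(1.5, 300.0, 30001)
        k = smoluchowski_hemispherical(np.zeros_like(r), r, D_K_BULK)
        closed = 2 * math.pi * D_K_BULK * 1.5e-10 * 6.02214076e23 * 1e3
        assert closed == pytest.approx(1.11e9, rel=0.01)
        assert k == pytest.approx(closed, rel=1e-4)  # trapezoid accuracy

    def test_constant_offset_scales_boltzmann(self):
        r = np.linspace(1.5, 300.0, 30001)
        k0 = smoluchowski_hemispherical(np.zeros_like(r), r, D_K_BULK)
        k1 = smoluchowski_hemispherical(np.full_like(r, 2.0), r, D_K_BULK)
        assert k1 / k0 == pytest.approx(math.exp(-2.0), rel=1e-9)

    def test_infinite_barrier_blocks_association(self):
        r = np.linspace(1.5, 50.0, 2001)
        u = np.zeros_like(r)
        u[500] = np.inf
        assert smoluchowski_hemispherical(u, r, D_K_BULK) == 0.0

    def test_cylindrical_free_diffusion_closed_form(self):
        k = smoluchowski_cylindrical(lambda r: np.zeros_like(r), 1.5, 8.5, 20.0, D_K_BULK)
        d_a2ps = D_K_BULK * 1e8
        closed = math.pi * d_a2ps * 8.5**2 / (20.0 - 1.5) * 1e12 * 1e-27 * 6.02214076e23
        assert k == pytest.approx(closed, rel=1e-9)

    def test_vestibule_radius_scaling(self):
        # widening the intracellular vestibule from 8.5 to 13.5 Å scales
        # the association constant by (13.5/8.5)² ≈ 2.52
        u = lambda r: 1.5 * np.exp(-((r - 5.0) ** 2))
        k_wide = smoluchowski_cylindrical(u, 1.5, 13.5, 20.0, D_K_BULK)
        k_narrow = smoluchowski_cylindrical(u, 1.5, 8.5, 20.0, D_K_BULK)
        assert k_wide / k_narrow == pytest.approx((13.5 / 8.5) ** 2, rel=1e-9)
        assert k_wide / k_narrow == pytest.approx(2.52, abs=0.01)

    def test_monotone_in_geometry(self):
        u = lambda r: np.zeros_like(np.asarray(r))
        ks = [smoluchowski_cylindrical(u, 1.5, rv, 20.0, D_K_BULK) for rv in (5, 8, 12)]
        assert ks[0] < ks[1] < ks[2]
        kl = [smoluchowski_cylindrical(u, 1.5, 8.5, lv, D_K_BULK) for lv in (10, 20, 30)]
        assert kl[0] > kl[1] > kl[2]


class TestVoltageTilt:
    def make_profile(self):
        spec = SyntheticProfileSpec(
            0.0, 12.0,
            (
                GaussianFeature(3.0, 0.5, -6.0),
                GaussianFeature(6.0, 0.8, 3.0),
                GaussianFeature(9.0, 0.5, -6.0),
            ),
        )
        return make_profile(spec).with_landmarks(i=3.0, b=6.0, f=9.0)

    def test_zero_voltage_is_identity(self):
        prof = self.make_profile()
        assert tilt_profile(prof, VoltageTilt(0.0)) is prof

    def test_endpoint_energy_difference(self):
        prof = self.make_profile()
        tilted = tilt_profile(prof, VoltageTilt(100.0, z_eff=1.0))
        drop = (tilted.u[-1] - prof.u[-1]) - (tilted.u[0] - prof.u[0])
        assert drop == pytest.approx(-100.0 / thermal_voltage_mv(300.0), rel=1e-12)
        assert abs(drop) == pytest.approx(3.868, abs=0.002)

    def test_detailed_balance_ratio_identity(self):
        prof = self.make_profile()
        tab = rates_vs_voltage(prof, [0.0, 100.0], z_eff=1.0)
        ratio0 = tab["k_f"][0] / tab["k_b"][0]
        ratio1 = tab["k_f"][1] / tab["k_b"][1]
        expected = math.exp(100.0 / thermal_voltage_mv(300.0))
        assert ratio1 / ratio0 == pytest.approx(expected, rel=0.02)

    def test_symmetric_profile_equal_rates_at_zero(self):
        tab = rates_vs_voltage(self.make_profile(), [0.0])
        assert tab["k_f"][0] == pytest.approx(tab["k_b"][0], rel=1e-6)

    def test_monotone_over_physiological_range(self):
        tab = rates_vs_voltage(self.make_profile(), np.arange(-200, 201, 50))
        assert np.all(np.diff(tab["k_f"]) > 0)
        assert np.all(np.diff(tab["k_b"]) < 0)

    def test_zero_effective_valence_removes_voltage_dependence(self):
        tab = rates_vs_voltage(self.make_profile(), [-150.0, 0.0, 150.0], z_eff=0.0)
        assert np.ptp(tab["k_f"]) == pytest.approx(0.0, abs=1e-6 * tab["k_f"][0])

    def test_span_outside_grid_rejected(self):
        prof = self.make_profile()
        with pytest.raises(ValueError):
            tilt_profile(prof, VoltageTilt(50.0, span=(-5.0, 20.0)))


def test_unit_round_trips_are_exact():
    from permeakin.constants import (
        A2_PER_PS_TO_M2_PER_S,
        M2_PER_S_TO_A2_PER_PS,
        MOLAR_TO_PER_A3,
        PER_A3_TO_MOLAR,
    )

    assert A2_PER_PS_TO_M2_PER_S * M2_PER_S_TO_A2_PER_PS == pytest.approx(1.0, rel=1e-12)
    assert MOLAR_TO_PER_A3 * PER_A3_TO_MOLAR == pytest.approx(1.0, rel=1e-12)
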