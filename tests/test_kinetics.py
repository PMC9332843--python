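"""The 4-state association/dissociation kinetic scheme."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.linalg import expm

from permeakin.constants import thermal_voltage_mv
from permeakin.kinetics import (
    TABLE_ADJUSTED,
    TABLE_RAW_MD,
    DriveConditions,
    RateSet,
    StateOccupancy,
    conductance_concentration,
    current,
    cycle_balance,
    enforce_reversibility,
    iv_curve,
    rate_matrix,
    reversal_potential,
    steady_state,
)

rate_values = st.floats(1e6, 1e12)
random_rates = st.builds(
    RateSet,
    ka1=rate_values, kd1=rate_values, ka2=rate_values, kd2=rate_values,
    ka3=rate_values, kd3=rate_values, ka4=rate_values, kd4=rate_values,
    kf0=rate_values, kb0=rate_values,
)


class TestSteadyState:
    def test_symmetric_rates_give_symmetric_occupancy(self):
        rates = RateSet(*([1e8] * 8), kf0=2e8, kb0=2e8)
        occ = steady_state(rates, DriveConditions(0.0, 0.1, 0.1))
        assert occ.n1 == pytest.approx(occ.n3, rel=1e-12)
        assert occ.n.sum() == pytest.approx(1.0, abs=1e-12)

    def test_adjusted_table_detailed_balance_at_equilibrium(self):
        drive = DriveConditions(0.0, 0.1, 0.1)
        occ = steady_state(TABLE_ADJUSTED, drive)
        q = rate_matrix(TABLE_ADJUSTED, drive)
        # every edge flux equals its reverse flux
        for i in range(4):
            for j in range(4):
                if i != j and q[i, j] > 0:
                    fwd = q[i, j] * occ.n[i]
                    rev = q[j, i] * occ.n[j]
                    assert fwd == pytest.approx(rev, rel=1e-10)

    @settings(max_examples=80, derandomize=True, deadline=None)
    @given(rates=random_rates, v=st.floats(-150, 150), c=st.floats(0.01, 1.0))
    def test_matches_master_equation_propagation(self, rates, v, c):
        drive = DriveConditions(v, c, c)
        occ = steady_state(rates, drive)
        q = rate_matrix(rates, drive)
        # brute-force oracle: propagate the master equation to long time
        t_relax = 50.0 / np.abs(q.diagonal()).min()
        p_inf = np.ones(4) / 4 @ expm(q * t_relax)
        np.testing.assert_allclose(occ.n, p_inf, atol=1e-8)
        assert np.all(occ.n >= 0) and np.all(occ.n <= 1)

    def test_occupancies_on_simplex(self):
        occ = steady_state(TABLE_RAW_MD, DriveConditions(80.0, 0.2, 0.1))
        assert occ.n.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all((occ.n >= 0) & (occ.n <= 1))


class TestCurrent:
    def test_equilibrium_current_vanishes(self):
        # balanced rates + symmetric baths + V = 0 force I = 0
        i0 = current(TABLE_ADJUSTED, DriveConditions(0.0, 0.1, 0.1))
        assert abs(i0) < 1e-6

    @settings(max_examples=80, derandomize=True, deadline=None)
    @given(rates=random_rates, v=st.floats(-200, 200), c=st.floats(0.01, 1.6))
    def test_intracellular_equals_extracellular_flux(self, rates, v, c):
        drive = DriveConditions(v, c, c)
        occ = steady_state(rates, drive)
        # current() itself asserts Eq-in = Eq-ex; just exercise it
        i = current(rates, drive, occ)
        assert math.isfinite(i)

    def test_throughput_to_current_scale(self):
        # 1e8 cycles/s × 1.6e-19 C = 16 pA, inside the expected 10-20 pA
        i_pa = 1e8 * 1.6e-19 * 1e12
        assert 10.0 <= i_pa <= 20.0

    def test_non_steady_occupancy_rejected(self):
        bad = StateOccupancy(n=np.array([0.7, 0.1, 0.1, 0.1]))
        with pytest.raises(ArithmeticError, match="steady state"):
            current(TABLE_ADJUSTED, DriveConditions(50.0, 0.1, 0.1), bad)


class TestCycleBalance:
    def test_adjusted_table_is_exactly_balanced(self):
        ratios = cycle_balance(TABLE_ADJUSTED)
        assert ratios == pytest.approx((1.0, 1.0, 1.0), abs=1e-12)

    def test_raw_table_is_not_balanced(self):
        ratios = cycle_balance(TABLE_RAW_MD)
        assert max(abs(r - 1.0) for r in ratios) > 0.1

    def test_uniform_scaling_leaves_ratios_unchanged(self):
        scaled = RateSet.from_array(TABLE_RAW_MD.as_array() * 3.7)
        np.testing.assert_allclose(
            cycle_balance(scaled), cycle_balance(TABLE_RAW_MD), rtol=1e-12
        )


class TestEnforceReversibility:
    def test_balanced_set_is_fixed_point(self):
        fixed = enforce_reversibility(TABLE_ADJUSTED)
        np.testing.assert_allclose(
            fixed.as_array(), TABLE_ADJUSTED.as_array(), rtol=1e-12
        )

    def test_raw_table_becomes_balanced(self):
        balanced = enforce_reversibility(TABLE_RAW_MD)
        ratios = cycle_balance(balanced)
        assert ratios == pytest.approx((1.0, 1.0, 1.0), abs=1e-10)
        rel = np.abs(balanced.as_array() / TABLE_RAW_MD.as_array() - 1.0)
        assert rel.max() < 0.35  # log-space projection stays close

    def test_idempotent(self):
        once = enforce_reversibility(TABLE_RAW_MD)
        twice = enforce_reversibility(once)
        np.testing.assert_allclose(once.as_array(), twice.as_array(), rtol=1e-12)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(rates=random_rates)
    def test_projection_balances_any_rate_set(self, rates):
        balanced = enforce_reversibility(rates)
        assert cycle_balance(balanced) == pytest.approx((1.0, 1.0, 1.0), abs=1e-9)


class TestIVCurve:
    def test_equilibrium_point_and_sublinearity(self):
        drive = DriveConditions(0.0, 0.1, 0.1)
        volts = np.arange(-200.0, 201.0, 20.0)
        table = iv_curve(TABLE_ADJUSTED, drive, volts)
        i = table["I_pA"]
        assert i[volts == 0.0][0] == pytest.approx(0.0, abs=1e-6)
        assert np.all(np.diff(i) > 0)  # monotone
        # sublinear: the slope decreases toward both extremes
        slope = np.diff(i) / np.diff(volts)
        assert slope[-1] < slope[len(slope) // 2]
        assert slope[0] < slope[len(slope) // 2]

    def test_outward_rectification(self):
        table = iv_curve(
            TABLE_ADJUSTED, DriveConditions(0.0, 0.1, 0.1), [-200.0, 200.0]
        )
        assert table["I_pA"][1] > abs(table["I_pA"][0])

    def test_large_voltage_ceiling_matches_reduced_model(self):
        # As V -> +inf the interconversion becomes one-way (kb -> inf,
        # kf -> 0): state 3 drains instantly to 1.  Eliminating state 3
        # leaves a 3-state cycle whose stationary flux bounds the current.
        r = TABLE_ADJUSTED
        c = 0.1
        q = np.zeros((3, 3))  # states 1, 2, 4; transitions into 3 => into 1
        q[0, 1] = r.ka1 * c          # 1 -> 2
        q[1, 0] = r.kd1 + r.kd2      # 2 -> 1 directly or via instant 3 -> 1
        q[0, 2] = r.kd3              # 1 -> 4
        q[2, 0] = r.ka3 * c + r.ka4 * c  # 4 -> 1 directly or via 3
        np.fill_diagonal(q, -q.sum(axis=1))
        a = q.T.copy()
        a[2, :] = 1.0
        n = np.linalg.solve(a, np.array([0.0, 0.0, 1.0]))
        flux = r.ka1 * c * n[0] + r.ka4 * c * n[2] - r.kd1 * n[1]
        ceiling = flux * 1.602176634e-19 * 1e12
        i_big = iv_curve(TABLE_ADJUSTED, DriveConditions(0.0, c, c), [1500.0])
        assert i_big["I_pA"][0] == pytest.approx(ceiling, rel=1e-3)

    def test_mirror_symmetry(self):
        r = TABLE_ADJUSTED
        mirrored = RateSet(
            ka1=r.ka2, kd1=r.kd2, ka2=r.ka1, kd2=r.kd1,
            ka3=r.ka4, kd3=r.kd4, ka4=r.ka3, kd4=r.kd3,
            kf0=r.kb0, kb0=r.kf0,
        )
        volts = [-120.0, -40.0, 60.0, 180.0]
        fwd = iv_curve(r, DriveConditions(0.0, 0.05, 0.4), volts)
        rev = iv_curve(mirrored, DriveConditions(0.0, 0.4, 0.05), [-v for v in volts])
        np.testing.assert_allclose(fwd["I_pA"], -rev["I_pA"], rtol=1e-10)


class TestConductance:
    def test_vanishes_at_zero_concentration_limit(self):
        table = conductance_concentration(TABLE_ADJUSTED, 100.0, [1e-5, 1e-4])
        assert table["G_pS"][0] < table["G_pS"][1]
        assert table["G_pS"][0] == pytest.approx(0.0, abs=1e-2)

    def test_monotone_and_saturating(self):
        # over the experimentally characterised range 10 mM - 1.6 M the
        # chord conductance rises and flattens (Michaelis-Menten-like);
        # the doubling ratio G(2c)/G(c) falls toward 1
        conc = np.array([0.01, 0.02, 0.05, 0.1, 0.2, 0.4, 0.8, 1.6])
        table = conductance_concentration(TABLE_ADJUSTED, 100.0, conc)
        g = table["G_pS"]
        assert np.all(np.diff(g) >= 0)
        doubling = g[[1, 3, 5, 7]] / g[[0, 2, 4, 6]]
        assert np.all(np.diff(doubling) < 0)
        # proportional growth would give 2.0; saturation onset pulls the
        # top-of-range ratio well below that
        assert doubling[-1] < 1.7

    def test_zero_voltage_rejected(self):
        with pytest.raises(ValueError):
            conductance_concentration(TABLE_ADJUSTED, 0.0, [0.1])


class TestReversalPotential:
    def test_symmetric_baths_reverse_at_zero(self):
        assert reversal_potential(TABLE_ADJUSTED, 0.1, 0.1) == pytest.approx(0.0, abs=1e-4)

    def test_tenfold_gradient_is_nernstian(self):
        v_rev = reversal_potential(TABLE_ADJUSTED, 0.1, 1.0)
        assert v_rev == pytest.approx(thermal_voltage_mv(300.0) * math.log(10.0), abs=0.01)
        assert v_rev == pytest.approx(59.5, abs=0.1)

    def test_scale_invariance_in_concentration(self):
        a = reversal_potential(TABLE_ADJUSTED, 0.05, 0.4)
        b = reversal_potential(TABLE_ADJUSTED, 0.10, 0.8)
        assert a == pytest.approx(b, abs=1e-3)

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(rates=random_rates, ratio=st.floats(0.1, 10.0))
    def test_nernstian_for_any_balanced_set(self, rates, ratio):
        balanced = enforce_reversibility(rates)
        k_in = 0.1
        k_ex = k_in * ratio
        v_rev = reversal_potential(balanced, k_in, k_ex)
        nernst = thermal_voltage_mv(300.0) * math.log(k_ex / k_in)
        assert v_rev == pytest.approx(nernst, abs=0.1)

    def test_missing_bracket_rejected(self):
        with pytest.raises(ValueError, match="bracket"):
            reversal_potential(TABLE_ADJUSTED, 0.1, 1.0, bracket_mv=10.0)


def test_rate_set_validation():
    with pytest.raises(ValueError):
        RateSet(*([0.0] * 8), kf0=1.0, kb0=1.0)


def test_voltage_closure_detailed_balance_ratio():
    r = TABLE_ADJUSTED
    v = 87.0
    vt = thermal_voltage_mv(300.0)
    assert r.kf(v) * r.kb(v) == pytest.approx(r.kf0 * r.kb0, rel=1e-12)
    assert r.kb(v) / r.kf(v) == pytest.approx(r.kb0 / r.kf0 * math.exp(v / vt), rel=1e-12)
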