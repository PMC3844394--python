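"""Discrete-time model, z-plane poles and Monte-Carlo robustness analysis."""

import cmath
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from p53loop import (
    DNA_DAMAGE_DISTRIBUTION,
    ContinuousParams,
    DiscreteParams,
    char_poles,
    dt_closed_loop_coeffs,
    dt_steady_state_error,
    euler_discretize,
    monte_carlo_poles,
    pole_to_damping,
    scale_condition,
    simulate_discrete,
    steady_state_error,
)


class TestSimulateDiscrete:
    def test_zero_weights_kill_dynamics(self):
        params = DiscreteParams(w_xy=0, w_zy=0, w_yz=0, w_y=0, w_z=0)
        _, y, z = simulate_discrete(params, initial=(2.0, 3.0, 4.0), n_steps=5)
        assert np.all(y[1:] == 0) and np.all(z[1:] == 0)

    def test_identity_dynamics_hold_state(self):
        with pytest.warns(UserWarning):  # w = 1 sits outside the nominal range
            params = DiscreteParams(w_xy=0, w_zy=0, w_yz=0, w_y=1.0, w_z=1.0)
        x, y, z = simulate_discrete(params, initial=(1.0, 2.0, 3.0), n_steps=10)
        assert np.all(x == 1.0) and np.all(y == 2.0) and np.all(z == 3.0)

    def test_single_hand_iteration(self):
        params = DiscreteParams(w_xy=0, w_zy=0.2662, w_yz=0, w_y=0, w_z=0)
        _, y, _ = simulate_discrete(params, initial=(0.0, 0.0, 1.0), n_steps=1)
        assert y[1] == pytest.approx(0.2662)

    def test_step_count_validated(self, dna_damage_params):
        with pytest.raises(ValueError):
            simulate_discrete(dna_damage_params, n_steps=0)


class TestSteadyStateError:
    def test_value_at_identified_means(self, dna_damage_params):
        assert dt_steady_state_error(dna_damage_params) == pytest.approx(0.26989, abs=1e-4)

    def test_no_activation_no_error(self, dna_damage_params):
        assert dt_steady_state_error(dna_damage_params.replace(w_zy=0.0)) == 0.0

    def test_zero_denominator_raises(self):
        with pytest.warns(UserWarning):
            params = DiscreteParams(w_xy=0, w_zy=0.0, w_yz=0.5, w_y=1.0, w_z=0.5)
        with pytest.raises(ZeroDivisionError):
            dt_steady_state_error(params.replace(w_yz=0.0))

    @settings(derandomize=True, max_examples=30)
    @given(
        p=st.tuples(*[st.floats(0.05, 3.0) for _ in range(4)]),
        T=st.sampled_from([0.01, 0.11, 0.5]),
    )
    def test_euler_substitution_matches_continuous_exactly(self, p, T):
        p_zy, p_yz, p_y, p_z = p
        if max(p_y, p_z) * T >= 1.0:  # forward Euler valid only below 1/T
            return
        continuous = ContinuousParams(p_xy=1.0, p_zy=p_zy, p_yz=p_yz, p_y=p_y, p_z=p_z)
        discrete = euler_discretize(p_zy, p_yz, p_y, p_z, T)
        assert dt_steady_state_error(discrete) == pytest.approx(
            steady_state_error(continuous), rel=1e-12
        )

    def test_time_domain_response_matches_final_value_theorem(self, dna_damage_params):
        # sustained unit disturbance on the p53 update, no ATM input
        _, _, z = simulate_discrete(
            dna_damage_params, initial=(0.0, 0.0, 0.0), n_steps=400, disturbance=1.0
        )
        error_offset = dna_damage_params.w_zy * z[-1]
        assert error_offset == pytest.approx(dt_steady_state_error(dna_damage_params), abs=1e-6)


class TestClosedLoopPoles:
    def test_coeffs_at_identified_means(self, dna_damage_params):
        gain, b, c = dt_closed_loop_coeffs(dna_damage_params)
        assert gain == pytest.approx(0.1656)
        assert b == pytest.approx(1.2364)
        assert c == pytest.approx(0.3609737, abs=1e-6)

    def test_real_pole_pair_at_identified_means(self, dna_damage_params):
        rec0, rec1 = char_poles(dna_damage_params)
        assert sorted([rec0.pole.real, rec1.pole.real]) == pytest.approx(
            [0.47261, 0.76379], abs=1e-4
        )
        assert rec0.pole.imag == rec1.pole.imag == 0.0
        assert rec0.zeta == rec1.zeta == 1.0

    def test_complex_pair_when_feedback_strengthened(self, dna_damage_params):
        rec0, rec1 = char_poles(dna_damage_params.replace(w_yz=0.6708))
        assert rec0.pole == rec1.pole.conjugate()
        assert rec0.magnitude == pytest.approx(0.70389, abs=1e-4)
        assert rec0.zeta == pytest.approx(0.5758, abs=1e-3)

    def test_double_pole_without_coupling(self):
        params = DiscreteParams(w_xy=0, w_zy=0, w_yz=0, w_y=0.6, w_z=0.6)
        rec0, rec1 = char_poles(params)
        assert rec0.pole == rec1.pole == pytest.approx(0.6)

    def test_poles_are_roots_of_characteristic_polynomial(self, dna_damage_params):
        _, b, c = dt_closed_loop_coeffs(dna_damage_params)
        for rec in char_poles(dna_damage_params):
            assert abs(rec.pole**2 - b * rec.pole + c) < 1e-12


class TestPoleToDamping:
    def test_positive_real_pole_is_critically_damped(self):
        zeta, _ = pole_to_damping(0.7637 + 0j)
        assert zeta == 1.0

    def test_unit_circle_pole_is_undamped(self):
        zeta, omega = pole_to_damping(cmath.exp(1j * 0.5))
        assert zeta == pytest.approx(0.0, abs=1e-12)
        assert omega == pytest.approx(0.5 / 0.11)

    def test_negative_real_pole_uses_theta_pi(self):
        r = 0.5
        zeta, _ = pole_to_damping(-r + 0j)
        assert zeta == pytest.approx(-math.log(r) / math.hypot(math.log(r), math.pi))

    def test_origin_and_unity_poles_rejected(self):
        with pytest.raises(ValueError):
            pole_to_damping(0j)
        with pytest.raises(ValueError):
            pole_to_damping(1.0 + 0j)

    @settings(derandomize=True, max_examples=50)
    @given(r=st.floats(0.01, 0.999), theta=st.floats(-math.pi + 1e-6, math.pi))
    def test_zeta_in_unit_interval_inside_disk(self, r, theta):
        zeta, _ = pole_to_damping(cmath.rect(r, theta))
        assert 0.0 <= zeta <= 1.0
        # away from the real axis the mapped damping is strictly below 1
        if abs(theta) > 1e-9:
            assert zeta < 1.0

    def test_zeta_independent_of_sampling_period(self):
        pole = cmath.rect(0.8, 0.4)
        z1, _ = pole_to_damping(pole, T=0.11)
        z2, _ = pole_to_damping(pole, T=0.5)
        assert z1 == z2


class TestMonteCarlo:
    def test_degenerate_distribution_reproduces_mean_poles(self, dna_damage_params):
        dist = DNA_DAMAGE_DISTRIBUTION.replace(w_y_sd=0, w_z_sd=0, w_zy_sd=0, w_yz_sd=0)
        result = monte_carlo_poles(dist, n_samples=10, seed=0)
        expected = sorted(rec.pole.real for rec in char_poles(dna_damage_params))
        for pair in result.poles:
            assert sorted(p.real for p in pair) == pytest.approx(expected, abs=1e-12)

    def test_reproducible_under_fixed_seed(self, identified_distribution):
        a = monte_carlo_poles(identified_distribution, n_samples=50, seed=42)
        b = monte_carlo_poles(identified_distribution, n_samples=50, seed=42)
        assert np.array_equal(a.poles, b.poles)
        assert a.summary == b.summary

    def test_dna_damage_condition_is_heavily_damped(self, identified_distribution):
        result = monte_carlo_poles(identified_distribution, n_samples=100, seed=1)
        assert result.median_zeta >= 0.8

    def test_strengthened_feedback_lowers_damping(self, identified_distribution):
        dist = identified_distribution.replace(w_yz_mean=0.6708)
        result = monte_carlo_poles(dist, n_samples=100, seed=1)
        assert result.median_zeta <= 0.8

    def test_median_stable_under_doubling(self, identified_distribution):
        m1 = monte_carlo_poles(identified_distribution, n_samples=400, seed=11).median_zeta
        m2 = monte_carlo_poles(identified_distribution, n_samples=800, seed=12).median_zeta
        assert abs(m1 - m2) < 0.05

    def test_post_translational_beats_transcriptional(self, identified_distribution):
        trans = scale_condition(identified_distribution, 3.67, "transcriptional")
        post = scale_condition(identified_distribution, 3.67, "post_translational")
        z_trans = monte_carlo_poles(trans, n_samples=200, seed=5).median_zeta
        z_post = monte_carlo_poles(post, n_samples=200, seed=5).median_zeta
        assert z_post > z_trans


class TestScaleCondition:
    def test_identity_fold(self, identified_distribution):
        assert scale_condition(identified_distribution, 1.0, "transcriptional") == identified_distribution

    def test_transcriptional_scales_only_wyz(self, identified_distribution):
        scaled = scale_condition(identified_distribution, 3.67, "transcriptional")
        assert scaled.w_yz_mean == pytest.approx(0.1656 * 3.67)  # = 0.6078
        assert scaled.w_z_mean == identified_distribution.w_z_mean
        assert scaled.w_yz_sd == identified_distribution.w_yz_sd

    def test_post_translational_also_divides_wz(self, identified_distribution):
        scaled = scale_condition(identified_distribution, 3.67, "post_translational")
        assert scaled.w_yz_mean == pytest.approx(0.1656 * 3.67)
        assert scaled.w_z_mean == pytest.approx(0.3627 / 3.67)  # = 0.09883
        assert scaled.w_z_sd == identified_distribution.w_z_sd

    def test_published_means_accepted_as_overrides(self, identified_distribution):
        scaled = scale_condition(
            identified_distribution, 3.67, "post_translational",
            w_yz_mean_override=0.6708, w_z_mean_override=0.0998,
        )
        assert scaled.w_yz_mean == 0.6708
        assert scaled.w_z_mean == 0.0998

    def test_invalid_arguments_rejected(self, identified_distribution):
        with pytest.raises(ValueError):
            scale_condition(identified_distribution, -1.0)
        with pytest.raises(ValueError):
            scale_condition(identified_distribution, 2.0, "epigenetic")
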