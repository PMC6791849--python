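"""Closed-form kinetics: frozen examples, invariants, and the RK4 oracle."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pefreseal import (
    DomainError,
    FieldResponseParams,
    MembraneFluorescenceParams,
    PulseSpec,
    UptakeConstants,
    ValidationError,
    WallPoreParams,
    absorption_rate,
    baseline_uptake,
    fluorescence_intensity,
    integrate_uptake_ode,
    pef_amplitude,
    pore_excess,
    rate_integral_from_fraction,
    uptake_closed_form,
    uptake_with_delay,
)


class TestPefAmplitude:
    def test_zero_at_and_below_threshold(self):
        fr = FieldResponseParams(b=0.01, E_th_p=2.0, t_ch=1.0)
        assert pef_amplitude(fr, PulseSpec(E_p=2.0, t_p=150.0)) == 0.0
        assert pef_amplitude(fr, PulseSpec(E_p=0.5, t_p=150.0)) == 0.0

    def test_long_pulse_saturates_to_quadratic_field_law(self):
        fr = FieldResponseParams(b=0.01, E_th_p=2.0, t_ch=1.0)
        long_pulse = pef_amplitude(fr, PulseSpec(E_p=4.0, t_p=5000.0))
        assert long_pulse == pytest.approx(0.01 * 4.0 * 1.5**2, rel=1e-9)

    def test_hand_evaluated_example(self):
        # b (E-E_th)^2 f^2 (1-e^-1)^2 = 0.01*4*2.25*(1-1/e)^2
        fr = FieldResponseParams(b=0.01, E_th_p=2.0, t_ch=1.0, f=1.5)
        expected = 0.01 * 4.0 * 2.25 * (1.0 - math.exp(-1.0)) ** 2
        assert pef_amplitude(fr, PulseSpec(E_p=4.0, t_p=1.0)) == pytest.approx(
            expected, rel=1e-12
        )
        assert expected == pytest.approx(0.0359619, rel=1e-5)

    def test_monotone_in_field_and_duration(self):
        fr = FieldResponseParams(b=0.01, E_th_p=2.0, t_ch=10.0)
        fields = [pef_amplitude(fr, PulseSpec(E_p=e, t_p=150.0)) for e in (1.0, 2.93, 4.38, 5.85)]
        assert fields == sorted(fields)
        durations = [pef_amplitude(fr, PulseSpec(E_p=4.0, t_p=tp)) for tp in (5.0, 50.0, 500.0)]
        assert durations == sorted(durations)

    def test_negative_parameters_rejected(self):
        with pytest.raises(ValidationError):
            FieldResponseParams(b=-0.01, E_th_p=2.0, t_ch=1.0)
        with pytest.raises(ValidationError):
            PulseSpec(E_p=-1.0, t_p=150.0)


class TestPoreExcess:
    def test_initial_value_and_one_time_constant(self):
        assert pore_excess(0.05, 24.0, 0.0) == pytest.approx(0.05)
        assert pore_excess(0.05, 24.0, 24.0) == pytest.approx(0.05 / math.e)

    def test_two_time_constants_frozen_value(self):
        assert pore_excess(0.049262, 24.0, 48.0) == pytest.approx(0.0066668, rel=1e-4)

    def test_negative_time_rejected(self):
        with pytest.raises(ValidationError):
            pore_excess(0.05, 24.0, -1.0)

    def test_absorption_rate_decays_to_baseline(self):
        wall = WallPoreParams(k_a0=7.329e-4, A=0.049262, tau_d=24.0)
        assert absorption_rate(wall, 24.0) == pytest.approx(0.018855, rel=1e-4)
        assert absorption_rate(wall, 1e6) == pytest.approx(wall.k_a0, rel=1e-9)
        flat = WallPoreParams(k_a0=7.329e-4, A=0.0, tau_d=24.0)
        t = np.array([0.0, 10.0, 100.0])
        assert np.allclose(absorption_rate(flat, t), flat.k_a0)


class TestUptakeClosedForm:
    def test_zero_at_t0_and_saturates_at_Nm(self, constants, wall_reference):
        assert uptake_closed_form(constants, wall_reference, 0.0) == 0.0
        assert uptake_closed_form(constants, wall_reference, 1e7) == pytest.approx(
            constants.N_m, rel=1e-6
        )

    def test_baseline_anchor_fraction(self, constants):
        # inverse oracle (test_estimation) pins k_a0; forward must return 0.12
        wall = WallPoreParams(k_a0=7.3287e-4, A=0.0, tau_d=24.0)
        n = uptake_closed_form(constants, wall, 180.0)
        assert n / constants.N_m == pytest.approx(0.1200, abs=1e-4)

    def test_delayed_uptake_hand_chain(self, constants):
        # S_dt = exp(-0.5*(k_a0*180 + A*24*e^-2*(1-e^-7.5))) -> ratio 0.2391
        wall = WallPoreParams(k_a0=7.3287e-4, A=0.049262, tau_d=24.0)
        ratio = uptake_with_delay(constants, wall, 180.0, 48.0)
        assert ratio == pytest.approx(0.2391, abs=5e-4)

    def test_delay_zero_reduces_to_closed_form(self, constants, wall_reference):
        direct = uptake_closed_form(constants, wall_reference, 180.0) / constants.N_m
        assert uptake_with_delay(constants, wall_reference, 180.0, 0.0) == pytest.approx(
            direct, rel=1e-12
        )

    def test_large_delay_and_zero_amplitude_recover_baseline(
        self, constants, wall_reference
    ):
        base = baseline_uptake(constants, wall_reference.k_a0, 180.0)
        far = uptake_with_delay(constants, wall_reference, 180.0, 5000.0)
        assert far == pytest.approx(base, abs=1e-12)
        untreated = WallPoreParams(
            k_a0=wall_reference.k_a0, A=0.0, tau_d=wall_reference.tau_d
        )
        for dt in (0.0, 30.0, 120.0):
            assert uptake_with_delay(constants, untreated, 180.0, dt) == pytest.approx(
                base, rel=1e-12
            )

    def test_short_pore_lifetime_recovers_baseline_for_positive_delay(
        self, constants, calibration
    ):
        wall = WallPoreParams(k_a0=calibration.k_a0, A=calibration.A_reference, tau_d=1e-6)
        base = baseline_uptake(constants, calibration.k_a0, 180.0)
        assert uptake_with_delay(constants, wall, 180.0, 1.0) == pytest.approx(
            base, rel=1e-9
        )

    def test_baseline_trivial_limits(self, constants):
        assert baseline_uptake(constants, 0.0, 180.0) == 0.0
        assert baseline_uptake(constants, 7.329e-4, 1e8) == pytest.approx(1.0, rel=1e-6)

    def test_monotone_in_time_and_delay(self, constants, wall_reference):
        t = np.linspace(0.0, 300.0, 40)
        n = np.asarray(uptake_closed_form(constants, wall_reference, t))
        assert np.all(np.diff(n) > 0)
        dt = np.linspace(0.0, 600.0, 40)
        r = np.asarray(uptake_with_delay(constants, wall_reference, 180.0, dt))
        assert np.all(np.diff(r) <= 0)

    def test_domain_error_when_capacity_exceeds_pool(self, wall_reference):
        bad = UptakeConstants(N_m=1.5, N_s=1.0)
        with pytest.raises(DomainError):
            uptake_closed_form(bad, wall_reference, 10.0)

    def test_equal_roots_limit_is_continuous(self, wall_reference):
        nearly = UptakeConstants(N_m=1.0 - 1e-12, N_s=1.0)
        exactly = UptakeConstants(N_m=1.0, N_s=1.0)
        a = uptake_closed_form(nearly, wall_reference, 120.0)
        b = uptake_closed_form(exactly, wall_reference, 120.0)
        assert a == pytest.approx(b, rel=1e-6)

    def test_rate_integral_round_trip(self, constants):
        for frac in (0.0, 0.12, 0.65, 0.97):
            K = rate_integral_from_fraction(constants, frac)
            wall = WallPoreParams(k_a0=1.0, A=0.0, tau_d=1.0)
            assert uptake_closed_form(constants, wall, K) / constants.N_m == pytest.approx(
                frac, abs=1e-12
            )


@settings(max_examples=60, derandomize=True, deadline=None)
@given(
    k_a0=st.floats(0.0, 0.05),
    A=st.floats(0.0, 0.1),
    tau_d=st.floats(5.0, 100.0),
    N_m=st.floats(0.1, 0.9),
    delta_t=st.floats(0.0, 300.0),
    t=st.floats(0.1, 400.0),
)
def test_fraction_bounded_and_delay_monotone(k_a0, A, tau_d, N_m, delta_t, t):
    """Absorbed fraction lies in [0, 1) and never increases with the delay."""
    constants = UptakeConstants(N_m=N_m, N_s=1.0)
    wall = WallPoreParams(k_a0=k_a0, A=A, tau_d=tau_d)
    r = uptake_with_delay(constants, wall, t, delta_t)
    assert 0.0 <= r < 1.0
    r_later = uptake_with_delay(constants, wall, t, delta_t + 50.0)
    assert r_later <= r + 1e-12


class TestFluorescence:
    def test_endpoints(self):
        p = MembraneFluorescenceParams(I0=100.0, I_r=20.0, tau_l=20.0)
        assert fluorescence_intensity(p, 0.0) == pytest.approx(120.0)
        assert fluorescence_intensity(p, 1e7) == pytest.approx(20.0)

    def test_one_time_constant_frozen_value(self):
        p = MembraneFluorescenceParams(I0=100.0, I_r=20.0, tau_l=20.0)
        assert fluorescence_intensity(p, 20.0) == pytest.approx(56.788, abs=1e-3)

    def test_half_life_is_tau_log_two(self):
        p = MembraneFluorescenceParams(I0=80.0, I_r=5.0, tau_l=33.0)
        half = fluorescence_intensity(p, 33.0 * math.log(2.0)) - p.I_r
        assert half == pytest.approx(p.I0 / 2.0, rel=1e-12)

    def test_strictly_decreasing(self):
        p = MembraneFluorescenceParams(I0=100.0, I_r=20.0, tau_l=20.0)
        dt = np.linspace(0.0, 600.0, 50)
        y = np.asarray(fluorescence_intensity(p, dt))
        assert np.all(np.diff(y) < 0)

    def test_negative_delay_rejected(self):
        p = MembraneFluorescenceParams(I0=100.0, I_r=20.0, tau_l=20.0)
        with pytest.raises(ValidationError):
            fluorescence_intensity(p, -5.0)


class TestOdeOracle:
    def test_flat_when_no_absorption(self, constants):
        wall = WallPoreParams(k_a0=0.0, A=0.0, tau_d=24.0)
        grid = np.array([0.0, 30.0, 90.0, 180.0])
        assert np.all(integrate_uptake_ode(constants, wall, 0.0, grid) == 0.0)

    def test_final_value_below_capacity(self, constants, wall_reference):
        grid = np.array([0.0, 60.0, 180.0])
        n = integrate_uptake_ode(constants, wall_reference, 0.0, grid)
        assert n[-1] < constants.N_m

    def test_calibrated_terminal_fraction(self, constants, wall_reference):
        grid = np.array([0.0, 180.0])
        n = integrate_uptake_ode(constants, wall_reference, 0.0, grid)
        assert n[-1] / constants.N_m == pytest.approx(0.650, abs=1e-6)

    def test_non_monotone_grid_rejected(self, constants, wall_reference):
        with pytest.raises(ValidationError):
            integrate_uptake_ode(
                constants, wall_reference, 0.0, np.array([0.0, 10.0, 5.0])
            )
        with pytest.raises(ValidationError):
            integrate_uptake_ode(
                constants, wall_reference, 0.0, np.array([5.0, 10.0])
            )

    def test_closed_form_matches_rk4_on_random_parameters(self):
        """Closed form vs fixed-step RK4: <= 1e-6 relative over 100 draws."""
        rng = np.random.default_rng(20191014)
        grid = np.linspace(0.0, 180.0, 10)
        grid[0] = 0.0
        worst = 0.0
        for _ in range(100):
            constants = UptakeConstants(N_m=rng.uniform(0.2, 0.8), N_s=1.0)
            wall = WallPoreParams(
                k_a0=rng.uniform(0.0, 0.1),
                A=rng.uniform(0.0, 0.1),
                tau_d=rng.uniform(5.0, 100.0),
            )
            delta_t = rng.uniform(0.0, 120.0)
            ode = integrate_uptake_ode(constants, wall, delta_t, grid)
            closed = constants.N_m * np.asarray(
                uptake_with_delay(constants, wall, grid, delta_t)
            )
            worst = max(worst, float(np.max(np.abs(ode - closed)) / constants.N_m))
        assert worst <= 1e-6
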