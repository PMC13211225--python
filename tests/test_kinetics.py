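"""Forward-model checks: Arrhenius rates, rate law, integration, lag times."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from accelstab.kinetics import (
    KineticModelSpec,
    KineticParameters,
    KineticsError,
    TemperatureProfile,
    conversion_to_signal,
    integrate_conversion,
    isothermal_alpha,
    lag_time,
    rate_constant,
    reaction_rate,
    total_conversion,
)


def one_step_params(A=1e12, ea=80e3, y0=0.0, dy=1.0, alpha0=1e-6):
    return KineticParameters(A=(A,), Ea=(ea,), y0=y0, dY=(dy,), alpha0=(alpha0,))


class TestRateConstant:
    def test_zero_activation_energy_returns_prefactor(self):
        assert rate_constant(2.0, 0.0, 298.15) == pytest.approx(2.0)

    def test_high_temperature_limit_approaches_prefactor(self):
        assert rate_constant(1.0, 1e5, 1e12) == pytest.approx(1.0, rel=1e-6)

    def test_known_value(self):
        # frozen from a 30-digit arbitrary-precision evaluation of the closed form
        assert rate_constant(1e10, 1e5, 318.15) == pytest.approx(
            3.8120979538877099e-07, rel=1e-13
        )

    @pytest.mark.parametrize("A,ea,T", [(0.0, 1.0, 300.0), (-1.0, 1.0, 300.0), (1.0, -1.0, 300.0), (1.0, 1.0, 0.0)])
    def test_invalid_inputs_raise(self, A, ea, T):
        with pytest.raises(KineticsError):
            rate_constant(A, ea, T)


class TestReactionRate:
    @pytest.mark.parametrize(
        "alpha,k,n,m,expected",
        [
            (0.0, 5.0, 1.0, 1.0, 0.0),  # autocatalytic seed absent
            (0.3, 2.0, 0.0, 0.0, 2.0),  # zero order: constant rate
            (0.5, 4.0, 1.0, 1.0, 1.0),
            (1.0, 3.0, 1.0, 0.0, 0.0),  # exhausted reactant
            (0.0, 3.0, 1.0, 0.0, 3.0),  # first order starts at k
        ],
    )
    def test_rate_law_values(self, alpha, k, n, m, expected):
        assert reaction_rate(alpha, k, n, m) == pytest.approx(expected)

    def test_outside_unit_interval_raises(self):
        with pytest.raises(KineticsError):
            reaction_rate(1.2, 1.0, 1.0, 0.0)


def _analytic_alpha(n, m, a0, tau):
    """Independent closed forms used as the integration oracle."""
    tau = np.asarray(tau, float)
    if (n, m) == (1.0, 0.0):
        return 1.0 - (1.0 - a0) * np.exp(-tau)
    if (n, m) == (0.0, 0.0):
        return np.minimum(a0 + tau, 1.0)
    if (n, m) == (1.0, 1.0):
        e = np.exp(tau)
        return a0 * e / (1.0 - a0 + a0 * e)
    raise NotImplementedError


class TestIntegration:
    @pytest.mark.parametrize(
        "n,m,a0", [(1.0, 0.0, 0.0), (0.0, 0.0, 0.0), (1.0, 1.0, 1e-4)]
    )
    @pytest.mark.parametrize("method", ["auto", "numeric"])
    def test_matches_analytic_solutions(self, n, m, a0, method):
        """First-order, zero-order and Prout–Tompkins trajectories agree
        with their analytic solutions to <= 1e-6 relative over α∈[0, 0.99]."""
        if m > 0:
            # scaled horizon that sweeps the logistic up to alpha ~ 0.99
            tau = np.linspace(0.0, math.log(0.99 / 0.01 * (1 - a0) / a0), 60)
        else:
            tau = np.linspace(0.0, -math.log(1 - 0.99) if n > 0 else 0.99, 60)
        got = isothermal_alpha(n, m, a0 if m > 0 else 0.0, tau, method=method)
        want = _analytic_alpha(n, m, a0 if m > 0 else 0.0, tau)
        assert np.allclose(got, want, rtol=1e-6, atol=1e-9)

    def test_profile_integration_first_order(self):
        spec = KineticModelSpec(((1.0, 0.0),))
        params = one_step_params()
        profile = TemperatureProfile.isothermal(40.0, duration_months=6.0)
        t = np.linspace(0, 6, 13)
        k = params.k(0, 273.15 + 40.0)
        traj = integrate_conversion(spec, params, profile, t)
        assert np.allclose(traj.alpha[0], 1 - np.exp(-k * t), rtol=1e-9)

    def test_times_beyond_profile_raise(self):
        spec = KineticModelSpec(((1.0, 0.0),))
        profile = TemperatureProfile.isothermal(25.0, duration_months=1.0)
        with pytest.raises(KineticsError):
            integrate_conversion(spec, one_step_params(), profile, [0.0, 2.0])

    def test_m0_trajectory_ignores_seed_conversion(self):
        spec = KineticModelSpec(((1.0, 0.0),))
        profile = TemperatureProfile.isothermal(40.0, duration_months=3.0)
        t = np.linspace(0, 3, 7)
        a_small = integrate_conversion(spec, one_step_params(alpha0=1e-9), profile, t)
        a_big = integrate_conversion(spec, one_step_params(alpha0=5e-3), profile, t)
        assert np.array_equal(a_small.alpha, a_big.alpha)

    @given(
        n=st.sampled_from([0.0, 0.5, 1.0, 2.0]),
        m=st.sampled_from([0.0, 0.5, 1.0]),
        k_scale=st.floats(0.05, 5.0),
    )
    def test_conversion_monotone_in_time(self, n, m, k_scale):
        spec = KineticModelSpec(((n, m),))
        params = one_step_params(A=1e12 * k_scale)
        profile = TemperatureProfile(((2.0, 298.15), (2.0, 318.15)))
        traj = integrate_conversion(spec, params, profile, np.linspace(0, 4, 41))
        assert np.all(np.diff(traj.alpha[0]) >= -1e-12)
        assert np.all((traj.alpha >= 0) & (traj.alpha <= 1))

    @given(split=st.floats(0.2, 2.8))
    def test_segment_splitting_is_neutral(self, split):
        """Splitting an isothermal segment in two leaves the trajectory unchanged."""
        spec = KineticModelSpec(((1.0, 1.0),))
        params = one_step_params(alpha0=1e-4)
        t = np.linspace(0, 3, 31)
        whole = integrate_conversion(spec, params, TemperatureProfile(((3.0, 313.15),)), t)
        parts = integrate_conversion(
            spec, params, TemperatureProfile(((split, 313.15), (3.0 - split, 313.15))), t
        )
        assert np.allclose(whole.alpha, parts.alpha, rtol=1e-9, atol=1e-12)

    @given(t_lo=st.floats(250.0, 320.0), bump=st.floats(0.1, 40.0))
    def test_conversion_monotone_in_temperature(self, t_lo, bump):
        spec = KineticModelSpec(((1.0, 0.0),))
        params = one_step_params()
        t = [3.0]
        a_lo = integrate_conversion(
            spec, params, TemperatureProfile(((3.0, t_lo),)), t
        ).alpha[0, 0]
        a_hi = integrate_conversion(
            spec, params, TemperatureProfile(((3.0, t_lo + bump),)), t
        ).alpha[0, 0]
        assert a_hi >= a_lo - 1e-12


class TestSignalMapping:
    def test_no_conversion_returns_baseline(self):
        from accelstab.kinetics import ConversionTrajectory

        traj = ConversionTrajectory(np.arange(4.0), np.zeros((1, 4)))
        y = conversion_to_signal(traj, one_step_params(y0=100.0, dy=-40.0))
        assert np.allclose(y, 100.0)

    def test_complete_reaction_shifts_by_amplitude(self):
        from accelstab.kinetics import ConversionTrajectory

        traj = ConversionTrajectory(np.arange(3.0), np.ones((1, 3)))
        y = conversion_to_signal(traj, one_step_params(y0=100.0, dy=-40.0))
        assert np.allclose(y, 60.0)

    def test_two_step_linear_combination(self):
        from accelstab.kinetics import ConversionTrajectory

        params = KineticParameters(
            A=(1.0, 1.0), Ea=(0.0, 0.0), y0=100.0, dY=(-10.0, -30.0)
        )
        traj = ConversionTrajectory(
            np.array([0.0]), np.array([[1.0], [0.5]])
        )
        assert conversion_to_signal(traj, params)[0] == pytest.approx(75.0)


class TestLagTime:
    def test_first_order_characteristic_time(self):
        spec = KineticModelSpec(((1.0, 0.0),))
        params = one_step_params()
        T = 313.15
        k = params.k(0, T)
        got = lag_time(spec, params, T, threshold=1 - math.exp(-1))
        assert got == pytest.approx(1.0 / k, rel=1e-6)

    def test_zero_threshold_is_zero(self):
        spec = KineticModelSpec(((1.0, 0.0),))
        assert lag_time(spec, one_step_params(), 298.15, 0.0) == 0.0

    def test_larger_autocatalytic_order_delays_onset(self):
        """The autocatalytic order m lengthens the pre-aggregation lag."""
        lags = []
        for m in (0.5, 1.0, 1.5):
            spec = KineticModelSpec(((1.0, m),))
            lags.append(lag_time(spec, one_step_params(A=5e12), 313.15, 0.5))
        assert lags[0] < lags[1] < lags[2]

    def test_beyond_horizon_sentinel(self):
        spec = KineticModelSpec(((1.0, 0.0),))
        slow = one_step_params(A=1e-3)
        assert lag_time(spec, slow, 278.15, 0.9, horizon_months=12.0) == math.inf


class TestTemperatureProfile:
    def test_cycling_profile_alternates(self):
        p = TemperatureProfile.cycling(8.0, 25.0, 1.0, 2)
        assert len(p.segments) == 4
        assert p.segments[0][1] == pytest.approx(281.15)
        assert p.segments[1][1] == pytest.approx(298.15)

    def test_config_shorthand(self):
        p = TemperatureProfile.from_config([{"temp_C": 5}], default_duration=36.0)
        assert p.total_duration == 36.0

    def test_cycling_with_equal_temperatures_matches_isothermal(self):
        spec = KineticModelSpec(((1.0, 0.0),))
        params = one_step_params()
        t = np.linspace(0, 4, 17)
        cyc = total_conversion(
            spec, params, TemperatureProfile.cycling(25.0, 25.0, 1.0, 2), t
        )
        iso = total_conversion(
            spec, params, TemperatureProfile.isothermal(25.0, duration_months=4.0), t
        )
        assert np.allclose(cyc, iso, rtol=1e-10)
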