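"""Forward model: input function, ODE system, solver and signal."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nernstfit.biophysics import equilibrium_constant
from nernstfit.model import (
    FrameSchedule,
    InputFunctionParams,
    KineticParameters,
    SolverError,
    gamma_variate,
    model_signal,
    ode_rhs,
    predict_signal,
    sample_frames,
    solve_model,
)
from nernstfit.simulate import simulation_study_truth

STUDY_INPUT = InputFunctionParams(a0=1.0, alpha=12.0, beta=4.0, t0=1.0)

rates = st.floats(1e-4, 1.0)
volts = st.floats(-160.0, -5.0)


class TestGammaVariate:
    def test_zero_before_arrival(self):
        t = np.array([0.0, 0.5, 0.999, 1.0])
        assert np.all(gamma_variate(t, STUDY_INPUT) == 0.0)

    def test_peak_location_and_value(self):
        # maximum at t0 + alpha/beta = 4 s, value 3^12 e^-12
        t = np.linspace(1.0, 10.0, 9001)
        u = gamma_variate(t, STUDY_INPUT)
        assert t[np.argmax(u)] == pytest.approx(4.0, abs=1e-3)
        assert gamma_variate(4.0, STUDY_INPUT) == pytest.approx(
            3.0**12 * math.exp(-12.0), rel=1e-12
        )

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            InputFunctionParams(alpha=-1.0)


class TestOdeRhs:
    def test_rest_state_is_stationary(self):
        p = simulation_study_truth(kf=0.5)
        assert np.all(ode_rhs((0.0, 0.0, 0.0), 0.0, p) == 0.0)

    @given(
        cp=st.floats(0, 5), cc=st.floats(0, 5), cm=st.floats(0, 5),
        k1=rates, k2=rates, em=volts, dpsi=volts,
    )
    @settings(max_examples=50, deadline=None)
    def test_exchange_conserves_mass(self, cp, cc, cm, k1, k2, em, dpsi):
        """Without flow and decay the membrane fluxes cancel exactly."""
        p = KineticParameters(
            kf=0.0, k1=k1, em_mv=em, k2=k2, dpsi_mv=dpsi, k_prime=0.0
        )
        d = ode_rhs((cp, cc, cm), 100.0, p)
        assert d.sum() == pytest.approx(0.0, abs=1e-14 * max(1.0, cp + cc + cm))

    def test_mitochondrial_efflux_rate(self):
        p = KineticParameters(
            kf=0.0, k1=0.0, em_mv=-50.0, k2=0.01, dpsi_mv=-100.0, k_prime=0.0
        )
        d = ode_rhs((0.0, 0.0, 1.0), 10.0, p)
        assert d[2] == pytest.approx(-2.365e-4, rel=1e-3)


class TestSolveModel:
    def test_no_rates_means_no_signal(self):
        p = KineticParameters(kf=0.0, k1=0.0, k2=0.0, k_prime=0.0)
        traj = solve_model(p, np.linspace(0, 100, 11))
        assert np.all(traj.total() == 0.0)

    def test_analytic_matches_stiff_solver(self):
        p = simulation_study_truth(kf=2.0)
        t = np.linspace(0.0, 1800.0, 400)
        a = solve_model(p, t, method="analytic")
        n = solve_model(p, t, method="lsoda", rtol=1e-8, atol=1e-12)
        for name in ("cp", "cc", "cm"):
            assert getattr(a, name) == pytest.approx(
                getattr(n, name), abs=1e-7, rel=1e-5
            )

    @pytest.mark.parametrize("method", ["analytic", "lsoda"])
    def test_conservation_without_flow_and_decay(self, method):
        atol = 1e-9
        p = KineticParameters(
            kf=0.0, k1=0.1, em_mv=-50.0, k2=0.01, dpsi_mv=-100.0, k_prime=0.0
        )
        t = np.linspace(0.0, 2000.0, 200)
        traj = solve_model(p, t, method=method, atol=atol, y0=[1.0, 0.2, 0.1])
        assert np.all(np.abs(traj.total() - 1.3) < 10 * max(atol, 1e-9))

    def test_decay_scales_conserved_total(self):
        """With kf = 0 the total activity decays exactly as exp(-k' t)."""
        kp = 3.2059e-5
        p = KineticParameters(
            kf=0.0, k1=0.1, em_mv=-50.0, k2=0.01, dpsi_mv=-100.0, k_prime=kp
        )
        t = np.linspace(0.0, 3600.0, 50)
        traj = solve_model(p, t, y0=[1.0, 0.0, 0.0])
        assert traj.total() == pytest.approx(np.exp(-kp * t), rel=1e-6)

    def test_positivity_for_random_parameters(self):
        rng = np.random.default_rng(0)
        t = np.linspace(0.0, 600.0, 200)
        for _ in range(10):
            p = KineticParameters(
                kf=rng.uniform(0.05, 2.0),
                k1=rng.uniform(0.01, 0.5),
                em_mv=-rng.uniform(10, 150),
                k2=rng.uniform(0.001, 0.05),
                dpsi_mv=-rng.uniform(10, 150),
            )
            traj = solve_model(p, t)
            for name in ("cp", "cc", "cm"):
                assert np.all(getattr(traj, name) >= -1e-9)

    def test_long_time_ratios_reach_nernst_equilibrium(self):
        """With plasma concentration clamped, cc/cp -> K1 and cm/cc -> K2."""
        from scipy.integrate import solve_ivp

        p = KineticParameters(
            kf=0.0, k1=0.1, em_mv=-50.0, k2=0.01, dpsi_mv=-100.0, k_prime=0.0
        )

        def clamped(t, y):
            d = ode_rhs(y, t, p)
            d[0] = 0.0  # hold cp constant
            return d

        res = solve_ivp(
            clamped, (0.0, 50000.0), [1.0, 0.0, 0.0],
            method="LSODA", rtol=1e-10, atol=1e-12,
        )
        cp, cc, cm = res.y[:, -1]
        k1 = equilibrium_constant(p.em_mv)
        k2 = equilibrium_constant(p.dpsi_mv)
        assert cc / cp == pytest.approx(k1, rel=1e-3)
        assert cm / cc == pytest.approx(k2, rel=1e-3)

    def test_depolarization_washes_out_retained_activity(self):
        """Retained signal at 30 min falls monotonically as dPsi_m collapses."""
        t = np.array([0.0, 1800.0])
        retained = []
        for dpsi in (-150.0, -100.0, -50.0, -25.0, 0.0):
            p = dataclasses.replace(simulation_study_truth(kf=0.5), dpsi_mv=dpsi)
            retained.append(model_signal(p, times=t)[-1])
        assert np.all(np.diff(retained) < 0)

    def test_solver_error_carries_parameters(self):
        p = simulation_study_truth(kf=5.0)  # beta + lambda_min < 0
        with pytest.raises(SolverError) as exc:
            solve_model(p, np.linspace(0, 10, 5), method="analytic")
        assert exc.value.params is p

    def test_rejects_unsorted_times(self):
        with pytest.raises(ValueError):
            solve_model(simulation_study_truth(kf=1.0), [0.0, 2.0, 1.0])


class TestPredictSignal:
    def test_baseline_only(self):
        traj = solve_model(
            KineticParameters(kf=0.0, k1=0.0, k2=0.0, k_prime=0.0),
            np.linspace(0, 10, 5),
        )
        assert predict_signal(traj, 0.3, 0.3, b=0.07) == pytest.approx(0.07)

    def test_weighted_sum(self):
        traj = solve_model(
            KineticParameters(kf=0.0, k1=0.0, k2=0.0, k_prime=0.0),
            np.linspace(0, 10, 3),
            y0=[1.0, 2.0, 4.0],
        )
        s = predict_signal(traj, 0.3, 0.3, b=0.05)
        assert s == pytest.approx(0.3 + 0.6 + 1.6 + 0.05)

    def test_plasma_only(self):
        p = simulation_study_truth(kf=1.0)
        t = np.linspace(0, 100, 50)
        traj = solve_model(p, t)
        assert predict_signal(traj, 1.0, 0.0, 0.02) == pytest.approx(traj.cp + 0.02)

    def test_invalid_volume_fractions(self):
        traj = solve_model(simulation_study_truth(kf=1.0), np.linspace(0, 10, 3))
        with pytest.raises(ValueError):
            predict_signal(traj, 0.7, 0.5)


class TestFrames:
    def test_constant_signal(self):
        frames = FrameSchedule(np.arange(0.0, 50.0, 10.0), np.full(5, 10.0))
        assert sample_frames(lambda t: np.full_like(t, 3.3), frames) == pytest.approx(
            np.full(5, 3.3)
        )

    def test_midpoint_equals_mean_for_linear_signal(self):
        frames = FrameSchedule(np.array([0.0]), np.array([10.0]))
        assert sample_frames(lambda t: np.asarray(t, float), frames)[0] == 5.0

    def test_midpoint_vs_trapezoid_for_quadratic(self):
        """Midpoint gives 25 on [0,10] for t^2; the true mean is 100/3."""
        frames = FrameSchedule(np.array([0.0]), np.array([10.0]))
        fn = lambda t: np.asarray(t, float) ** 2
        mid = sample_frames(fn, frames, mode="midpoint")[0]
        trap = sample_frames(fn, frames, mode="trapezoid", n_sub=1000)[0]
        assert mid == 25.0
        assert trap == pytest.approx(100.0 / 3.0, rel=1e-4)

    def test_invalid_schedules_rejected(self):
        with pytest.raises(ValueError):
            FrameSchedule(np.array([0.0, 5.0]), np.array([6.0, 5.0]))  # overlap
        with pytest.raises(ValueError):
            FrameSchedule(np.array([5.0, 0.0]), np.array([1.0, 1.0]))  # unsorted
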