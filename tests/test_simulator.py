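"""Integration, burn-in equilibria and trajectory summaries."""

import numpy as np
import pytest

from oncoeco import (
    CellState,
    DisturbanceSchedule,
    SolverOptions,
    Trajectory,
    cancer_free_equilibrium,
    canonical_scenarios,
    default_initial_state,
    equilibrate,
    integrate,
    summarize,
)
from oncoeco.reference import rk4_trajectory

EMPTY5 = DisturbanceSchedule((), 5.0)


def _rel(a, b):
    a, b = np.asarray(a, float), np.asarray(b, float)
    return np.max(np.abs(a - b) / np.maximum(np.abs(b), 1e-12))


class TestIntegrate:
    def test_cancer_free_dynamics_stay_cancer_free(self, params):
        """Without conversion, C = 0 is exactly invariant and H settles to
        the single-species resource-logistic equilibrium."""
        p = params.replace(epsilon=0.0)
        traj = integrate(p, EMPTY5, default_initial_state(p))
        assert np.all(traj.C == 0.0)
        cf = cancer_free_equilibrium(p)
        assert traj.H[-1] == pytest.approx(cf.H, rel=1e-6)
        assert traj.R[-1] == pytest.approx(cf.R, rel=1e-6)

    def test_overwhelming_immunity_suppresses_cancer(self, params):
        # per-capita growth bound a_c*R - rho_c - theta << 0
        p = params.replace(theta=1e6)
        traj = integrate(p, EMPTY5, default_initial_state(p))
        assert traj.fractions.max() < 1e-3

    def test_sampling_grid(self, params, baseline_equilibrium):
        traj = integrate(params, DisturbanceSchedule((), 2.0), baseline_equilibrium)
        assert traj.times[0] == 0.0
        assert traj.times[-1] == 2.0
        assert np.all(np.diff(traj.times) > 0)
        # at least daily output resolution
        assert np.max(np.diff(traj.times)) <= 1.0 / 365.0 + 1e-12

    def test_agrees_with_fixed_step_reference(self, params, baseline_equilibrium):
        from oncoeco import Disturbance

        sch = DisturbanceSchedule(
            (
                Disturbance("immune", 0.1, 2.0 / 12.0, "replace", 0.0),
                Disturbance("resource", 0.15, 10.0 / 365.0, "scale", 10.0),
            ),
            0.3,
        )
        traj = integrate(params, sch, baseline_equilibrium, 0.3)
        # step must sit inside RK4's stability region: during the resource
        # surge the fastest rate constants reach ~1e5/yr
        t, y = rk4_trajectory(params, sch, baseline_equilibrium, 0.3, step=1e-5, t_eval=traj.times)
        assert np.array_equal(t, traj.times)
        assert _rel(np.column_stack([traj.H, traj.C, traj.R]), y) < 1e-4

    def test_capacity_never_exceeded_beyond_band(self, params, baseline_equilibrium):
        sch = canonical_scenarios(params, magnitudes=(0.0, 100.0))[4]
        traj = integrate(params, sch, baseline_equilibrium)
        assert np.max(traj.H + traj.C) <= params.K * 1.15

    def test_pulse_edges_are_sample_points(self, params, baseline_equilibrium):
        sch = canonical_scenarios(params, magnitudes=(0.0, 10.0))[4]
        traj = integrate(params, sch, baseline_equilibrium)
        for edge in sch.breakpoints:
            assert np.any(traj.times == edge)

    def test_invalid_horizon_rejected(self, params, baseline_equilibrium):
        with pytest.raises(ValueError):
            integrate(params, EMPTY5, baseline_equilibrium, horizon=-1.0)


class TestEquilibrate:
    def test_matches_algebraic_cancer_free_solution(self, params):
        """Independent oracle: closed-form root of the C = 0 subsystem."""
        p = params.replace(epsilon=0.0)
        state, converged, _ = equilibrate(p)
        assert converged
        cf = cancer_free_equilibrium(p)
        assert state.H == pytest.approx(cf.H, rel=1e-6)
        assert state.R == pytest.approx(cf.R, rel=1e-6)
        assert state.C == 0.0

    def test_resource_balance_identity(self, params, baseline_equilibrium):
        s = baseline_equilibrium
        residual = abs(params.sigma - s.R * (params.c * s.H + params.a * s.C))
        assert residual / params.sigma < 1e-6

    def test_basin_of_attraction(self, params, baseline_equilibrium):
        for H0 in (params.K / 2.0, params.K / 10.0):
            state, converged, _ = equilibrate(params, CellState(H0, 0.0, 2.0))
            assert converged
            assert _rel(state.as_array(), baseline_equilibrium.as_array()) < 1e-5

    def test_baseline_run_is_stationary(self, params, baseline_equilibrium):
        traj = integrate(params, DisturbanceSchedule((), 10.0), baseline_equilibrium)
        states = np.column_stack([traj.H, traj.C, traj.R])
        assert _rel(states, baseline_equilibrium.as_array()) < 1e-6

    def test_capacity_respected_at_equilibrium(self, params, baseline_equilibrium):
        assert baseline_equilibrium.H + baseline_equilibrium.C <= params.K * (1 + 1e-6)

    def test_disturbances_are_transient(self, params, baseline_equilibrium):
        """Pulses shift the system only temporarily: the trajectory returns
        to the pre-disturbance equilibrium after they end."""
        sch = canonical_scenarios(params, magnitudes=(0.0, 100.0), horizon=6.0)[4]
        traj = integrate(params, sch, baseline_equilibrium)
        assert _rel(traj.final_state.as_array(), baseline_equilibrium.as_array()) < 1e-3

    def test_tolerance_refinement_stability(self, params, baseline_equilibrium):
        sch = canonical_scenarios(params, magnitudes=(0.0, 10.0))[4]
        peak = summarize(integrate(params, sch, baseline_equilibrium)).peak_fraction
        tight = SolverOptions(rtol=1e-9, atol=1e-10)
        peak_tight = summarize(
            integrate(params, sch, baseline_equilibrium, options=tight)
        ).peak_fraction
        assert abs(peak - peak_tight) < 1e-4


def _fraction_trajectory(times, fractions):
    times = np.asarray(times, float)
    fractions = np.asarray(fractions, float)
    C = fractions * 100.0
    H = (1.0 - fractions) * 100.0
    return Trajectory(
        times=times,
        H=H,
        C=C,
        R=np.ones_like(times),
        fractions=fractions,
        theta_eff=np.zeros_like(times),
        sigma_eff=np.zeros_like(times),
    )


class TestSummarize:
    def test_constant_fraction_below_threshold(self):
        traj = _fraction_trajectory([0.0, 1.0, 2.0], [0.3, 0.3, 0.3])
        s = summarize(traj, thresholds=(0.5, 0.25))
        assert s.peak_fraction == 0.3
        assert s.time_above[0.5] == 0.0
        assert s.time_above[0.25] == pytest.approx(2.0)

    def test_triangular_profile_occupancy(self):
        # rises 0 -> 0.6 over half a year, back to 0: above 0.5 for 1/6 y
        traj = _fraction_trajectory([0.0, 0.5, 1.0], [0.0, 0.6, 0.0])
        s = summarize(traj, thresholds=(0.5,))
        assert s.time_above[0.5] == pytest.approx(1.0 / 6.0, rel=1e-12)
        assert s.peak_fraction == 0.6
        assert s.peak_time == 0.5

    def test_burden_integral_is_trapezoid(self):
        traj = _fraction_trajectory([0.0, 1.0], [0.0, 1.0])
        # C goes 0 -> 100 linearly: integral 50 cell-years
        s = summarize(traj)
        assert s.burden_integral == pytest.approx(50.0)

    def test_empty_trajectory_rejected(self):
        traj = _fraction_trajectory([], [])
        with pytest.raises(ValueError):
            summarize(traj)
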