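"""Pulse schedules and effective-parameter resolution."""

import pytest

from oncoeco import (
    IMMUNE_PULSE_DURATION,
    RESOURCE_PULSE_DURATION,
    Disturbance,
    DisturbanceSchedule,
    canonical_scenarios,
    effective_parameters,
)


def immune_pulse(start=1.0, magnitude=0.0, mode="replace"):
    return Disturbance("immune", start, IMMUNE_PULSE_DURATION, mode, magnitude)


def resource_pulse(start=1.0, magnitude=10.0, mode="scale"):
    return Disturbance("resource", start, RESOURCE_PULSE_DURATION, mode, magnitude)


class TestEffectiveParameters:
    def test_identity_outside_pulses(self, params):
        sch = DisturbanceSchedule((immune_pulse(1.0),), 5.0)
        assert effective_parameters(0.5, sch, params) == (params.theta, params.sigma)

    def test_immunosuppression_replaces_theta(self, params):
        sch = DisturbanceSchedule((immune_pulse(1.0, 0.0),), 5.0)
        theta, sigma = effective_parameters(1.05, sch, params)
        assert theta == 0.0
        assert sigma == params.sigma

    def test_resource_surge_scales_sigma(self, params):
        sch = DisturbanceSchedule((resource_pulse(1.0, 10.0),), 5.0)
        theta, sigma = effective_parameters(1.01, sch, params)
        assert sigma == pytest.approx(4e5)
        assert theta == params.theta

    def test_add_mode_increments(self, params):
        sch = DisturbanceSchedule((resource_pulse(1.0, 5.0, mode="add"),), 5.0)
        _, sigma = effective_parameters(1.01, sch, params)
        assert sigma == params.sigma + 5.0

    def test_half_open_window(self, params):
        p = immune_pulse(1.0)
        sch = DisturbanceSchedule((p,), 5.0)
        assert effective_parameters(p.start, sch, params)[0] == 0.0
        assert effective_parameters(p.end, sch, params)[0] == params.theta

    def test_piecewise_constant_at_edges(self, params):
        p = immune_pulse(1.0)
        sch = DisturbanceSchedule((p,), 5.0)
        eps = 1e-9
        assert effective_parameters(p.start - eps, sch, params)[0] == params.theta
        assert effective_parameters(p.start + eps, sch, params)[0] == 0.0
        assert effective_parameters(p.end - eps, sch, params)[0] == 0.0
        assert effective_parameters(p.end + eps, sch, params)[0] == params.theta

    def test_overlapping_pulses_compose_in_declaration_order(self, params):
        scale = Disturbance("resource", 1.0, 0.5, "scale", 10.0)
        replace = Disturbance("resource", 1.2, 0.5, "replace", 7.0)
        sch = DisturbanceSchedule((scale, replace), 5.0)
        # replace declared after scale overwrites it in the overlap
        assert effective_parameters(1.3, sch, params)[1] == 7.0
        sch_rev = DisturbanceSchedule((replace, scale), 5.0)
        assert effective_parameters(1.3, sch_rev, params)[1] == 70.0

    def test_disjoint_pulses_commute(self, params):
        a, b = immune_pulse(1.0), resource_pulse(3.0)
        s1 = DisturbanceSchedule((a, b), 5.0)
        s2 = DisturbanceSchedule((b, a), 5.0)
        for t in (0.5, 1.05, 3.01, 4.9):
            assert effective_parameters(t, s1, params) == effective_parameters(t, s2, params)

    def test_time_outside_horizon_rejected(self, params):
        sch = DisturbanceSchedule((), 5.0)
        for t in (-0.1, 5.1):
            with pytest.raises(ValueError):
                effective_parameters(t, sch, params)


class TestScheduleInvariants:
    def test_pulse_beyond_horizon_rejected(self):
        with pytest.raises(ValueError, match="horizon"):
            DisturbanceSchedule((immune_pulse(4.95),), 5.0)

    def test_bad_target_and_mode_rejected(self):
        with pytest.raises(ValueError):
            Disturbance("diet", 0.0, 1.0)
        with pytest.raises(ValueError):
            Disturbance("immune", 0.0, 1.0, "divide", 2.0)

    def test_nonpositive_duration_rejected(self):
        with pytest.raises(ValueError):
            Disturbance("immune", 0.0, 0.0)

    def test_breakpoints_are_pulse_edges(self):
        p = immune_pulse(1.0)
        sch = DisturbanceSchedule((p,), 5.0)
        assert sch.breakpoints == (p.start, p.end)


@pytest.fixture(scope="module")
def scenarios(params):
    return canonical_scenarios(params, gap=10.0 / 365.0, magnitudes=(0.0, 10.0))


class TestCanonicalScenarios:
    def test_five_scenarios(self, scenarios):
        assert len(scenarios) == 5

    def test_immune_only_pulse_lasts_two_months(self, scenarios):
        (pulse,) = scenarios[0].pulses
        assert pulse.target == "immune"
        assert pulse.duration == 2.0 / 12.0

    def test_resource_only_pulse_lasts_ten_days(self, scenarios):
        (pulse,) = scenarios[1].pulses
        assert pulse.target == "resource"
        assert pulse.duration == 10.0 / 365.0

    def test_resource_before_immune(self, scenarios):
        res = next(p for p in scenarios[2].pulses if p.target == "resource")
        imm = next(p for p in scenarios[2].pulses if p.target == "immune")
        assert res.end == pytest.approx(imm.start - 10.0 / 365.0)

    def test_resource_after_immune(self, scenarios):
        res = next(p for p in scenarios[3].pulses if p.target == "resource")
        imm = next(p for p in scenarios[3].pulses if p.target == "immune")
        assert res.start == pytest.approx(imm.end + 10.0 / 365.0)

    def test_resource_window_inside_immune_window(self, scenarios):
        res = next(p for p in scenarios[4].pulses if p.target == "resource")
        imm = next(p for p in scenarios[4].pulses if p.target == "immune")
        assert imm.start < res.start and res.end < imm.end

    def test_matched_magnitudes_across_scenarios(self, scenarios):
        for sch in scenarios:
            for p in sch.pulses:
                assert p.magnitude == (0.0 if p.target == "immune" else 10.0)

    def test_insufficient_lead_time_rejected(self, params):
        with pytest.raises(ValueError):
            canonical_scenarios(params, start=0.01)
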