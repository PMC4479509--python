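"""Randomized inputs for stress-testing: sporadic pulse schedules and
jittered parameter sets.

Pulse arrivals follow a homogeneous Poisson process per target (exponential
gaps — the minimal model of "sporadic"), with the canonical durations
(2-month immune windows, 10-day resource surges).  Parameter jitter is
mean-preserving log-normal, so jittered sets always satisfy the positivity
invariants.  Everything is reproducible from explicit integer seeds; no
global random state is touched.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .disturbance import (
    IMMUNE_PULSE_DURATION,
    RESOURCE_PULSE_DURATION,
    Disturbance,
    DisturbanceSchedule,
)
from .params import ModelParameters

__all__ = [
    "ScheduleGeneratorSpec",
    "random_schedule",
    "jitter_parameters",
    "scenario_ordering_robustness",
]


@dataclass(frozen=True)
class ScheduleGeneratorSpec:
    """Specification of a random sporadic-disturbance schedule.

    ``immune_rate`` / ``resource_rate`` are expected pulses per year;
    ``magnitude_ranges`` maps target to a (low, high) magnitude interval
    (immune pulses use mode ``replace`` — the drawn value becomes the
    effective theta; resource pulses use mode ``scale``).
    """

    horizon: float = 20.0
    immune_rate: float = 0.5
    resource_rate: float = 2.0
    immune_duration: float = IMMUNE_PULSE_DURATION
    resource_duration: float = RESOURCE_PULSE_DURATION
    magnitude_ranges: dict = field(
        default_factory=lambda: {"immune": (0.0, 0.0), "resource": (5.0, 100.0)}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.horizon <= 0:
            raise ValueError("horizon must be > 0")
        if self.immune_rate < 0 or self.resource_rate < 0:
            raise ValueError("pulse rates must be >= 0")
        if self.immune_duration <= 0 or self.resource_duration <= 0:
            raise ValueError("pulse durations must be > 0")


def random_schedule(spec: ScheduleGeneratorSpec) -> DisturbanceSchedule:
    """Draw a sporadic schedule: Poisson pulse arrivals per target.

    Pulse start times accumulate exponential gaps until the horizon; pulses
    are truncated at the horizon if they would overrun it.  Identical specs
    (including seed) produce identical schedules.
    """
    rng = np.random.default_rng(spec.seed)
    expected_cover = (
        spec.immune_rate * spec.immune_duration + spec.resource_rate * spec.resource_duration
    )
    if expected_cover > 1.0:
        warnings.warn(
            f"expected pulse coverage {expected_cover:.2f} exceeds the horizon; "
            "pulses will overlap heavily",
            stacklevel=2,
        )
    pulses: list[Disturbance] = []
    specs = (
        ("immune", spec.immune_rate, spec.immune_duration, "replace"),
        ("resource", spec.resource_rate, spec.resource_duration, "scale"),
    )
    for target, rate, duration, mode in specs:
        lo, hi = spec.magnitude_ranges.get(target, (0.0, 0.0))
        t = 0.0
        while rate > 0:
            t += rng.exponential(1.0 / rate)
            if t >= spec.horizon:
                break
            dur = min(duration, spec.horizon - t)
            pulses.append(Disturbance(target, t, dur, mode, float(rng.uniform(lo, hi))))
    pulses.sort(key=lambda p: (p.start, p.target))
    return DisturbanceSchedule(tuple(pulses), spec.horizon)


def jitter_parameters(
    base: ModelParameters, coefficient_of_variation: float, seed: int
) -> ModelParameters:
    """Multiplicatively jitter every rate/shape constant.

    Each field is multiplied by an independent log-normal factor with mean 1
    and the requested coefficient of variation; the carrying capacity K is
    rounded back to an integer (at least 1).  cv = 0 returns the base set
    unchanged.
    """
    cv = coefficient_of_variation
    if not (0.0 <= cv < 1.0):
        raise ValueError(f"coefficient of variation must be in [0, 1), got {cv}")
    if cv == 0.0:
        return base
    rng = np.random.default_rng(seed)
    s2 = math.log(1.0 + cv * cv)
    mu = -0.5 * s2
    changes: dict[str, float] = {}
    for name in ModelParameters.field_names():
        factor = float(rng.lognormal(mean=mu, sigma=math.sqrt(s2)))
        value = getattr(base, name) * factor
        if name == "K":
            value = max(1.0, round(value))
        changes[name] = value
    return base.replace(**changes)


def scenario_ordering_robustness(
    base: ModelParameters,
    n_sets: int = 50,
    coefficient_of_variation: float = 0.1,
    seed: int = 0,
    factor: float = 10.0,
    horizon: float = 3.0,
) -> dict:
    """How often the disturbance-timing conclusions survive parameter jitter.

    For ``n_sets`` jittered parameter sets, burns each in to equilibrium,
    runs the five canonical scenarios and checks (i) the resource-only pulse
    outpeaks the immune-only pulse and (ii) a resource pulse during or after
    the immune window is the worst timing.  Returns the fraction of sets
    satisfying each claim and both — a robustness report, not an assertion.
    Jittered sets whose burn-in does not converge are skipped (counted).
    """
    from .disturbance import canonical_scenarios
    from .simulate import equilibrate, integrate, summarize

    rng = np.random.default_rng(seed)
    n_used = n_skipped = n_resource = n_timing = n_both = 0
    for _ in range(n_sets):
        p = jitter_parameters(base, coefficient_of_variation, int(rng.integers(2**31 - 1)))
        state, ok, _ = equilibrate(p)
        if not ok:
            n_skipped += 1
            continue
        peaks = []
        for sch in canonical_scenarios(p, magnitudes=(0.0, factor), horizon=horizon):
            peaks.append(summarize(integrate(p, sch, state)).peak_fraction)
        n_used += 1
        resource_beats_immune = peaks[1] > peaks[0]
        worst_is_during_or_after = max(peaks[3], peaks[4]) >= max(peaks) - 1e-12
        n_resource += resource_beats_immune
        n_timing += worst_is_during_or_after
        n_both += resource_beats_immune and worst_is_during_or_after
    return {
        "n_sets": n_sets,
        "n_used": n_used,
        "n_skipped": n_skipped,
        "resource_beats_immune": n_resource / n_used if n_used else float("nan"),
        "worst_is_during_or_after": n_timing / n_used if n_used else float("nan"),
        "both": n_both / n_used if n_used else float("nan"),
    }
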