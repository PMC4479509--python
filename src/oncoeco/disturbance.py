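"""Timed pulse disturbances on immune efficiency and resource supply.

A disturbance is a rectangular pulse over a half-open window
``[start, start + duration)`` that modifies the immune elimination rate
``theta`` or the resource input rate ``sigma``.  The canonical pulses are a
2-month immunosuppression window (winter-time immune depression; ``theta``
replaced by 0) and a 10-day resource surge (festive over-eating; ``sigma``
scaled up).  Months are exactly 1/12 year and days exactly 1/365 year.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .params import ModelParameters

__all__ = [
    "IMMUNE_PULSE_DURATION",
    "RESOURCE_PULSE_DURATION",
    "Disturbance",
    "DisturbanceSchedule",
    "effective_parameters",
    "canonical_scenarios",
    "SCENARIO_LABELS",
]

IMMUNE_PULSE_DURATION = 2.0 / 12.0  # 2 months, years
RESOURCE_PULSE_DURATION = 10.0 / 365.0  # 10 days, years

_TARGETS = ("immune", "resource")
_MODES = ("replace", "scale", "add")


@dataclass(frozen=True)
class Disturbance:
    """One rectangular pulse on ``theta`` (immune) or ``sigma`` (resource).

    ``mode`` fixes how ``magnitude`` applies while the pulse is active:
    ``replace`` overwrites the rate, ``scale`` multiplies it, ``add``
    increments it.
    """

    target: str
    start: float
    duration: float
    mode: str = "replace"
    magnitude: float = 0.0

    def __post_init__(self) -> None:
        if self.target not in _TARGETS:
            raise ValueError(f"target must be one of {_TARGETS}, got {self.target!r}")
        if self.mode not in _MODES:
            raise ValueError(f"mode must be one of {_MODES}, got {self.mode!r}")
        if not (math.isfinite(self.start) and self.start >= 0):
            raise ValueError(f"start must be finite and >= 0, got {self.start}")
        if not (math.isfinite(self.duration) and self.duration > 0):
            raise ValueError(f"duration must be finite and > 0, got {self.duration}")
        if not (math.isfinite(self.magnitude) and self.magnitude >= 0):
            raise ValueError(f"magnitude must be finite and >= 0, got {self.magnitude}")

    @property
    def end(self) -> float:
        return self.start + self.duration

    def active(self, t: float) -> bool:
        """Whether the half-open window [start, end) contains ``t``."""
        return self.start <= t < self.end

    def apply(self, value: float) -> float:
        if self.mode == "replace":
            return self.magnitude
        if self.mode == "scale":
            return value * self.magnitude
        return value + self.magnitude


@dataclass(frozen=True)
class DisturbanceSchedule:
    """An ordered list of pulses over a finite horizon (years).

    Declaration order is meaningful: overlapping pulses on the same target
    compose in list order (replace overwrites whatever came before it).
    """

    pulses: tuple[Disturbance, ...] = ()
    horizon: float = 10.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "pulses", tuple(self.pulses))
        if not (math.isfinite(self.horizon) and self.horizon > 0):
            raise ValueError(f"horizon must be finite and > 0, got {self.horizon}")
        for p in self.pulses:
            if p.end > self.horizon * (1 + 1e-12):
                raise ValueError(
                    f"pulse on {p.target!r} ends at {p.end:g} y, beyond the "
                    f"horizon {self.horizon:g} y"
                )

    @property
    def breakpoints(self) -> tuple[float, ...]:
        """Sorted unique pulse edges in (0, horizon): integration restart points."""
        edges = set()
        for p in self.pulses:
            for e in (p.start, p.end):
                if 0.0 < e < self.horizon:
                    edges.add(e)
        return tuple(sorted(edges))


def effective_parameters(
    t: float, schedule: DisturbanceSchedule, params: ModelParameters
) -> tuple[float, float]:
    """Effective (theta, sigma) at time ``t`` under the schedule.

    Starts from the baseline rates and applies every pulse whose window
    contains ``t``, in declaration order.  Piecewise constant in ``t`` with
    breakpoints exactly at pulse edges.
    """
    if not (0.0 <= t <= schedule.horizon):
        raise ValueError(f"time {t} outside schedule horizon [0, {schedule.horizon}]")
    theta, sigma = params.theta, params.sigma
    for p in schedule.pulses:
        if p.active(t):
            if p.target == "immune":
                theta = p.apply(theta)
            else:
                sigma = p.apply(sigma)
    return theta, sigma


SCENARIO_LABELS = (
    "immune-only",
    "resource-only",
    "resource-before-immune",
    "resource-after-immune",
    "resource-during-immune",
)


def canonical_scenarios(
    params: ModelParameters,
    gap: float = 10.0 / 365.0,
    magnitudes: tuple[float, float] = (0.0, 10.0),
    start: float = 0.5,
    horizon: float = 6.0,
) -> list[DisturbanceSchedule]:
    """The five canonical disturbance-timing scenarios.

    1. immune pulse only (2 months, theta replaced by ``magnitudes[0]``);
    2. resource pulse only (10 days, sigma scaled by ``magnitudes[1]``);
    3. resource pulse ending ``gap`` years before the immune pulse starts;
    4. resource pulse starting ``gap`` years after the immune pulse ends;
    5. resource pulse centered inside the immune pulse window.

    All immune pulses start at ``start`` years (a post-burn-in offset); all
    five schedules share the same magnitudes and horizon.
    """
    if gap <= 0:
        raise ValueError(f"gap must be > 0, got {gap}")
    immune_mag, resource_factor = magnitudes
    t0 = start
    if t0 - gap - RESOURCE_PULSE_DURATION < 0:
        raise ValueError(
            f"start={t0:g} y leaves no room for a resource pulse {gap:g} y "
            "before the immune window"
        )

    def immune(at: float) -> Disturbance:
        return Disturbance("immune", at, IMMUNE_PULSE_DURATION, "replace", immune_mag)

    def resource(at: float) -> Disturbance:
        return Disturbance("resource", at, RESOURCE_PULSE_DURATION, "scale", resource_factor)

    imm = immune(t0)
    centered = t0 + (IMMUNE_PULSE_DURATION - RESOURCE_PULSE_DURATION) / 2.0
    scenarios = [
        (imm,),
        (resource(t0),),
        (resource(t0 - gap - RESOURCE_PULSE_DURATION), imm),
        (imm, resource(imm.end + gap)),
        (imm, resource(centered)),
    ]
    return [DisturbanceSchedule(pulses, horizon) for pulses in scenarios]
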