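"""Model constants and instantaneous state.

The model tracks three compartments: healthy cells ``H``, cancerous cells
``C`` and a shared resource stock ``R``.  Twelve rate/shape constants govern
the dynamics; the shipped defaults are the published parameterization of the
system (time unit: years).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass

__all__ = ["ModelParameters", "CellState", "DEFAULT_PARAMETERS"]


@dataclass(frozen=True)
class ModelParameters:
    """Rate and shape constants of the tumor-immune-resource system.

    Attributes
    ----------
    epsilon:
        Conversion (mutation) rate of healthy into cancerous cells, per year.
    K:
        Carrying capacity of the tissue: maximum total cell number supported
        by crowding/contact inhibition.
    rho_s:
        Healthy-cell death rate, per year.
    rho_c:
        Cancerous-cell death rate, per year.
    a:
        Resource-consumption rate of cancerous cells, per cell per
        resource-unit per year.
    c:
        Resource-consumption rate of healthy cells, per cell per
        resource-unit per year.
    d:
        Healthy-cell birth conversion rate: new cells per unit of consumed
        resource.
    a_c:
        Asymptote of the Gompertz-gated cancerous division rate, per
        resource-unit per year.
    b_c:
        Gompertz displacement (dimensionless); sets how strongly division is
        suppressed at very small cancer populations.
    d_c:
        Gompertz steepness, per cell; sets how quickly the gate opens as the
        cancer population grows.
    theta:
        Baseline immune elimination rate of cancerous cells, per year.
    sigma:
        Baseline resource input rate, resource-units per year.
    """

    epsilon: float = 365.0 / 1000.0
    K: float = 1.0e3
    rho_s: float = 365.0 / 40.0
    rho_c: float = 365.0 / 15.0
    a: float = 365.0
    c: float = 365.0 / 10.0
    d: float = 365.0 / 30.0
    a_c: float = 365.0 / 8.0
    b_c: float = 1.0e5
    d_c: float = 15.0
    theta: float = 365.0 / 25.0
    sigma: float = 4.0e4
    gate_consumption: bool = False
    """If True the Gompertz gate also throttles cancerous resource
    consumption (``a``), not only division.  Off by default: the gate is
    stated for the division rate."""

    _POSITIVE = ("K", "rho_s", "rho_c", "a", "c", "d", "a_c", "b_c", "d_c", "sigma")
    _NONNEGATIVE = ("epsilon", "theta")

    def __post_init__(self) -> None:
        for name in self._POSITIVE:
            v = getattr(self, name)
            if not math.isfinite(v) or v <= 0:
                raise ValueError(f"parameter {name!r} must be finite and > 0, got {v}")
        for name in self._NONNEGATIVE:
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"parameter {name!r} must be finite and >= 0, got {v}")
        if self.K < 1:
            raise ValueError(f"carrying capacity K must be >= 1, got {self.K}")

    def replace(self, **changes: float) -> "ModelParameters":
        """Return a copy with the given fields overridden (validated)."""
        return dataclasses.replace(self, **changes)

    @classmethod
    def field_names(cls) -> tuple[str, ...]:
        return tuple(f.name for f in dataclasses.fields(cls) if f.name != "gate_consumption")

    def to_dict(self) -> dict[str, float]:
        d = dataclasses.asdict(self)
        return d


#: The published default parameterization (Fig-caption values, time in years).
DEFAULT_PARAMETERS = ModelParameters()


# Transient overshoot band on H+C: cancerous growth escapes total-crowding
# control, so resource surges can push the total a few percent past K before
# healthy-cell crowding pulls it back.  Equilibria respect K strictly.
CAPACITY_TOLERANCE = 0.15


@dataclass(frozen=True)
class CellState:
    """Instantaneous system state: healthy cells, cancerous cells, resource.

    Counts are continuous densities; fractional cells are meaningful (the
    Gompertz gate is precisely what suppresses sub-threshold populations).
    """

    H: float
    C: float
    R: float

    def __post_init__(self) -> None:
        for name in ("H", "C", "R"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"state component {name} must be finite, got {v}")
            if v < 0:
                raise ValueError(f"state component {name} must be >= 0, got {v}")

    def validate_capacity(self, params: ModelParameters, tol: float = CAPACITY_TOLERANCE) -> None:
        """Raise if H+C exceeds the carrying capacity beyond ``tol``."""
        if self.H + self.C > params.K * (1.0 + tol):
            raise ValueError(
                f"total cell count {self.H + self.C:g} exceeds capacity "
                f"K={params.K:g} by more than {tol:.0%}"
            )

    def as_array(self):
        import numpy as np

        return np.array([self.H, self.C, self.R], dtype=float)

    @classmethod
    def from_array(cls, y, clip_tol: float = 1e-9) -> "CellState":
        """Build a state from a solver vector, clamping tiny negatives.

        Negative components beyond ``clip_tol`` (relative to scale 1) are an
        integration failure and raise.
        """
        vals = []
        for name, v in zip(("H", "C", "R"), y):
            v = float(v)
            if v < 0:
                if v < -clip_tol:
                    raise ValueError(f"state component {name} went negative: {v}")
                v = 0.0
            vals.append(v)
        return cls(*vals)
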