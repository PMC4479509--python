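"""Core dynamics: the Gompertz proliferation gate and the system right-hand side.

The model couples two cell populations competing for one resource::

    dH/dt = d * c * R * H * (1 - (H + C)/K) - rho_s * H - epsilon * H
    dC/dt = a_c * g(C) * R * C * (1 - C/K) + epsilon * H - rho_c * C - theta * C
    dR/dt = sigma - c * R * H - a * R * C

with the Gompertz gate ``g(C) = exp(-b_c * exp(-d_c * C))``.

Healthy cells convert consumed resource (``c*R`` per cell) into offspring
with efficiency ``d`` and are contact-inhibited by the *total* population.
Cancerous cells are modelled with two hallmark asymmetries: they consume
resource at the high rate ``a`` but their division rate ``a_c * g(C) * R``
is set by the gated proliferative machinery rather than by consumption
efficiency (metabolic wastefulness), and they escape contact inhibition by
healthy tissue, responding only to their own crowding ``(1 - C/K)``.  The
gate keeps divisions off until the population reaches a threshold of about
one cell — a lone cancerous cell cannot recruit the cooperative factors
(e.g. angiogenesis) needed for efficient proliferation.

Immune surveillance removes cancerous cells at rate ``theta``; resources
flow in at the constant rate ``sigma``.  Disturbances act purely by
substituting effective values for ``theta`` and ``sigma``.
"""

from __future__ import annotations

import math

from .params import CellState, ModelParameters

__all__ = ["gompertz_gate", "cancer_birth_rate", "derivatives", "cancer_fraction"]

# exp() overflows above ~709; clamp the inner exponent well inside that.
_EXP_CLAMP = 700.0


def gompertz_gate(C: float, params: ModelParameters) -> float:
    """Gompertz sigmoid gate g(C) = exp(-b_c * exp(-d_c * C)), in [0, 1].

    Monotone nondecreasing in ``C``; ~0 at C=0 for large ``b_c`` and -> 1 as
    C grows.  Computed in log space, ``exp(-exp(log(b_c) - d_c*C))``, so it
    is safe for displacements up to at least 1e9.

    Parameters
    ----------
    C:
        Cancerous-cell count, must be >= 0.
    params:
        Supplies the displacement ``b_c`` and steepness ``d_c``.
    """
    if not math.isfinite(C) or C < 0:
        raise ValueError(f"cancerous-cell count must be finite and >= 0, got {C}")
    inner = math.log(params.b_c) - params.d_c * C
    if inner > _EXP_CLAMP:
        return 0.0  # gate fully closed; exp(-huge) underflows
    return math.exp(-math.exp(inner))


def cancer_birth_rate(C: float, params: ModelParameters) -> float:
    """Gated cancerous division-rate coefficient b(C) = a_c * g(C).

    Ranges from ~0 (gate closed) up to the asymptote ``a_c``.
    """
    return params.a_c * gompertz_gate(C, params)


def _rhs(
    H: float,
    C: float,
    R: float,
    theta_eff: float,
    sigma_eff: float,
    p: ModelParameters,
) -> tuple[float, float, float]:
    """Unchecked right-hand side shared by the integrators.

    Tolerates the tiny negative excursions an adaptive solver may probe
    (clamped to 0 before the gate).
    """
    Cg = C if C > 0.0 else 0.0
    inner = math.log(p.b_c) - p.d_c * Cg
    gate = 0.0 if inner > _EXP_CLAMP else math.exp(-math.exp(inner))
    crowd_total = 1.0 - (H + C) / p.K
    crowd_cancer = 1.0 - C / p.K
    a_eff = p.a * gate if p.gate_consumption else p.a

    dH = p.d * p.c * R * H * crowd_total - p.rho_s * H - p.epsilon * H
    dC = p.a_c * gate * R * C * crowd_cancer + p.epsilon * H - p.rho_c * C - theta_eff * C
    dR = sigma_eff - p.c * R * H - a_eff * R * C
    return dH, dC, dR


def derivatives(
    state: CellState,
    theta_eff: float,
    sigma_eff: float,
    params: ModelParameters,
) -> tuple[float, float, float]:
    """Instantaneous time derivatives (dH/dt, dC/dt, dR/dt).

    Pure function of its arguments: all time dependence enters through the
    effective immune rate ``theta_eff`` and resource input ``sigma_eff``.

    Boundary behaviour guarantees nonnegativity in the continuous limit:
    H=0 gives dH/dt=0; C=0 gives dC/dt = epsilon*H >= 0; R=0 gives
    dR/dt = sigma_eff >= 0.
    """
    for name, v in (("theta_eff", theta_eff), ("sigma_eff", sigma_eff)):
        if not math.isfinite(v) or v < 0:
            raise ValueError(f"{name} must be finite and >= 0, got {v}")
    return _rhs(state.H, state.C, state.R, theta_eff, sigma_eff, params)


def cancer_fraction(state: CellState) -> float:
    """Proportion of cancerous cells, C / (H + C).

    The empty state (H = C = 0) maps to 0 by convention, so summaries of
    extinct trajectories remain well defined.
    """
    total = state.H + state.C
    if total <= 0.0:
        return 0.0
    return state.C / total
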