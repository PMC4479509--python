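"""Fixed-step classical Runge-Kutta reference integrator.

A deliberately simple 4th-order fixed-step scheme used as an independent
cross-check of the adaptive production integrator.  It shares only the
model right-hand side; stepping and pulse handling are implemented from
scratch here.  Pulse edges are honoured by splitting the time axis into
constant-forcing segments; within a segment the solver lands exactly on
every requested sample time by shortening the final sub-steps (so the step
size is always <= the nominal one and the order is preserved).
"""

from __future__ import annotations

import math

import numpy as np

from .disturbance import DisturbanceSchedule, effective_parameters
from .model import _rhs
from .params import CellState, ModelParameters

__all__ = ["rk4_trajectory"]


def rk4_trajectory(
    params: ModelParameters,
    schedule: DisturbanceSchedule,
    init: CellState,
    horizon: float,
    step: float = 1e-5,
    t_eval=None,
):
    """Integrate with classical RK4 at a fixed nominal step (years).

    Returns ``(times, states)``: the requested sample times (default: pulse
    edges and the endpoints) and one (H, C, R) row per sample.
    """
    if step <= 0:
        raise ValueError(f"step must be > 0, got {step}")
    edges = [0.0] + [e for e in schedule.breakpoints if e < horizon] + [horizon]
    if t_eval is None:
        t_eval = np.array(edges)
    t_eval = np.unique(np.concatenate((np.asarray(t_eval, dtype=float), edges)))
    if t_eval[0] < 0 or t_eval[-1] > horizon * (1 + 1e-12):
        raise ValueError("t_eval must lie within [0, horizon]")

    out_t: list[float] = []
    out_y: list[np.ndarray] = []
    y = np.asarray(init.as_array(), dtype=float)
    if t_eval[0] == 0.0:
        out_t.append(0.0)
        out_y.append(y.copy())

    for left, right in zip(edges[:-1], edges[1:]):
        theta, sigma = effective_parameters(0.5 * (left + right), schedule, params)
        targets = t_eval[(t_eval > left) & (t_eval <= right)]
        t = left
        for target in targets:
            span = target - t
            n_sub = max(1, math.ceil(span / step - 1e-12))
            h = span / n_sub
            for _ in range(n_sub):
                y = _rk4_step(y, h, theta, sigma, params)
            t = target
            out_t.append(t)
            out_y.append(y.copy())
    return np.array(out_t), np.vstack(out_y)


def _rk4_step(y, h, theta, sigma, params):
    def f(yv):
        return np.array(_rhs(yv[0], yv[1], yv[2], theta, sigma, params))

    k1 = f(y)
    k2 = f(y + 0.5 * h * k1)
    k3 = f(y + 0.5 * h * k2)
    k4 = f(y + h * k3)
    return y + (h / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
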