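"""Forward integration, burn-in to equilibrium, and trajectory summaries.

The forcing is piecewise constant (rectangular pulses), so the integrator is
restarted at every pulse edge: each segment between edges is solved with an
adaptive, stiffness-switching method (LSODA) under constant effective rates.
The Gompertz gate makes the cancer equation stiff near C ~ 0, which LSODA
handles by switching to BDF.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .disturbance import DisturbanceSchedule, effective_parameters
from .model import _rhs, cancer_fraction
from .params import CAPACITY_TOLERANCE, CellState, ModelParameters

__all__ = [
    "SolverOptions",
    "Trajectory",
    "TrajectorySummary",
    "integrate",
    "equilibrate",
    "summarize",
    "default_initial_state",
    "cancer_free_equilibrium",
]


@dataclass(frozen=True)
class SolverOptions:
    """Tolerances and stepping controls for the production integrator.

    rtol/atol are deliberately tight (1e-8 / 1e-9 cells or resource-units):
    the gate transition region spans fractions of a cell.
    """

    rtol: float = 1e-8
    atol: float = 1e-9
    method: str = "LSODA"
    max_step: float = math.inf
    samples_per_year: int = 365


@dataclass(frozen=True)
class Trajectory:
    """Time-ordered system states under a disturbance schedule.

    Arrays are aligned: ``times`` (years, strictly increasing, from 0 to the
    horizon), the three state components, the cancer fraction, and the
    effective rates that were in force at each sample.
    """

    times: np.ndarray
    H: np.ndarray
    C: np.ndarray
    R: np.ndarray
    fractions: np.ndarray
    theta_eff: np.ndarray
    sigma_eff: np.ndarray

    def __len__(self) -> int:
        return len(self.times)

    def state(self, i: int) -> CellState:
        return CellState(float(self.H[i]), float(self.C[i]), float(self.R[i]))

    @property
    def final_state(self) -> CellState:
        return self.state(len(self) - 1)

    def to_frame(self):
        """Trajectory as a pandas DataFrame (one row per sample)."""
        import pandas as pd

        return pd.DataFrame(
            {
                "t": self.times,
                "H": self.H,
                "C": self.C,
                "R": self.R,
                "fraction": self.fractions,
                "theta_eff": self.theta_eff,
                "sigma_eff": self.sigma_eff,
            }
        )


@dataclass(frozen=True)
class TrajectorySummary:
    """Headline statistics of one trajectory."""

    peak_fraction: float
    peak_time: float
    time_above: dict[float, float]
    final_fraction: float
    burden_integral: float  # cell-years of cancerous burden


def default_initial_state(params: ModelParameters) -> CellState:
    """Burn-in starting point: half-capacity healthy tissue, no cancer.

    H = K/2, C = 0 (the conversion rate epsilon seeds C immediately),
    R = sigma / (c * H) — the resource level that balances consumption by
    the initial healthy population.
    """
    H0 = params.K / 2.0
    return CellState(H0, 0.0, params.sigma / (params.c * H0))


def _segment_edges(schedule: DisturbanceSchedule, horizon: float) -> list[float]:
    edges = [0.0]
    edges += [e for e in schedule.breakpoints if e < horizon]
    edges.append(horizon)
    return edges


def integrate(
    params: ModelParameters,
    schedule: DisturbanceSchedule,
    init: CellState,
    horizon: float | None = None,
    options: SolverOptions = SolverOptions(),
) -> Trajectory:
    """Integrate the system from ``init`` over the schedule's horizon.

    The integration is restarted at every pulse edge so the
    piecewise-constant forcing is never smoothed across a discontinuity.
    Output is sampled on a uniform grid (``options.samples_per_year``, at
    least daily resolution is the default) plus every segment edge.

    Raises
    ------
    RuntimeError
        If the solver fails to converge, naming the time point.
    ValueError
        If a state invariant is violated beyond tolerance.
    """
    horizon = schedule.horizon if horizon is None else float(horizon)
    if horizon <= 0:
        raise ValueError(f"horizon must be > 0, got {horizon}")
    for p in schedule.pulses:
        if p.end > horizon * (1 + 1e-12):
            raise ValueError(f"pulse ending at {p.end:g} y exceeds horizon {horizon:g} y")

    n_samples = max(2, int(round(horizon * options.samples_per_year)) + 1)
    grid = np.linspace(0.0, horizon, n_samples)
    edges = _segment_edges(schedule, horizon)

    times: list[np.ndarray] = []
    states: list[np.ndarray] = []
    thetas: list[np.ndarray] = []
    sigmas: list[np.ndarray] = []

    # With epsilon = 0 the set {C = 0} is an exact invariant manifold
    # (dC/dt vanishes identically on it); project out the roundoff-scale
    # drift the solver's linear algebra introduces, which could otherwise
    # seed spurious exponential growth in invasible regimes.
    cancer_locked = params.epsilon == 0.0 and init.C == 0.0

    y = init.as_array()
    for left, right in zip(edges[:-1], edges[1:]):
        mid = 0.5 * (left + right)
        theta_eff, sigma_eff = effective_parameters(mid, schedule, params)

        def rhs(t, yv, th=theta_eff, sg=sigma_eff):
            return _rhs(yv[0], yv[1], yv[2], th, sg, params)

        t_eval = grid[(grid > left) & (grid < right)]
        t_eval = np.unique(np.concatenate(([left], t_eval, [right])))
        sol = solve_ivp(
            rhs,
            (left, right),
            y,
            method=options.method,
            t_eval=t_eval,
            rtol=options.rtol,
            atol=options.atol,
            max_step=options.max_step,
        )
        if not sol.success:
            raise RuntimeError(
                f"integration failed near t = {sol.t[-1] if len(sol.t) else left:.6g} y: "
                f"{sol.message}"
            )
        if cancer_locked:
            sol.y[1, :] = 0.0
        times.append(sol.t)
        states.append(sol.y.T)
        thetas.append(np.full(len(sol.t), theta_eff))
        sigmas.append(np.full(len(sol.t), sigma_eff))
        y = sol.y[:, -1].copy()

    # segment seams are duplicated (right edge of one = left edge of next);
    # keep the later copy so samples at a pulse edge carry the post-edge rates
    t_all = np.concatenate(times)
    y_all = np.vstack(states)
    th_all = np.concatenate(thetas)
    sg_all = np.concatenate(sigmas)
    keep = np.ones(len(t_all), dtype=bool)
    keep[:-1] = t_all[1:] > t_all[:-1]
    t_all, y_all, th_all, sg_all = t_all[keep], y_all[keep], th_all[keep], sg_all[keep]

    y_all = _clamp_nonnegative(y_all, t_all)
    total = y_all[:, 0] + y_all[:, 1]
    worst = np.argmax(total)
    if total[worst] > params.K * (1.0 + CAPACITY_TOLERANCE):
        raise ValueError(
            f"carrying-capacity invariant violated at t = {t_all[worst]:.6g} y: "
            f"H + C = {total[worst]:g} > K(1 + {CAPACITY_TOLERANCE})"
        )

    with np.errstate(invalid="ignore"):
        frac = np.where(total > 0, y_all[:, 1] / np.where(total > 0, total, 1.0), 0.0)
    return Trajectory(
        times=t_all,
        H=y_all[:, 0],
        C=y_all[:, 1],
        R=y_all[:, 2],
        fractions=frac,
        theta_eff=th_all,
        sigma_eff=sg_all,
    )


def _clamp_nonnegative(y: np.ndarray, t: np.ndarray, tol: float = 1e-6) -> np.ndarray:
    worst = y.min()
    if worst < -tol:
        i, j = np.unravel_index(np.argmin(y), y.shape)
        name = "HCR"[j]
        raise ValueError(
            f"nonnegativity violated: {name} = {worst:g} at t = {t[i]:.6g} y"
        )
    return np.maximum(y, 0.0)


def equilibrate(
    params: ModelParameters,
    init_guess: CellState | None = None,
    *,
    rel_tol: float = 1e-8,
    max_years: float = 500.0,
    chunk_years: float = 5.0,
    options: SolverOptions = SolverOptions(),
) -> tuple[CellState, bool, float]:
    """Run the undisturbed system to steady state by long integration.

    Integrates in chunks until the maximum relative change of (H, C, R)
    over a trailing 1-year window drops below ``rel_tol``, or ``max_years``
    simulated years elapse (then ``converged=False``; limit cycles are
    reported the same way, not as errors).

    Returns
    -------
    (state, converged, elapsed_years)
    """
    if init_guess is None:
        init_guess = default_initial_state(params)
    y = init_guess.as_array()
    cancer_locked = params.epsilon == 0.0 and init_guess.C == 0.0  # exact invariant
    elapsed = 0.0
    converged = False

    def rhs(t, yv):
        return _rhs(yv[0], yv[1], yv[2], params.theta, params.sigma, params)

    while elapsed < max_years:
        step = min(chunk_years, max_years - elapsed)
        sol = solve_ivp(
            rhs,
            (0.0, step),
            y,
            method=options.method,
            t_eval=[max(0.0, step - 1.0), step],
            rtol=options.rtol,
            atol=options.atol,
        )
        if not sol.success:
            raise RuntimeError(f"burn-in integration failed near t = {elapsed:.6g} y: {sol.message}")
        if cancer_locked:
            sol.y[1, :] = 0.0
        y_prev, y_new = sol.y[:, 0], sol.y[:, -1]
        elapsed += step
        y = y_new.copy()
        if step >= 1.0:
            denom = np.maximum(np.maximum(np.abs(y_new), np.abs(y_prev)), 1e-12)
            if np.max(np.abs(y_new - y_prev) / denom) < rel_tol:
                converged = True
                break
    return CellState.from_array(y, clip_tol=1e-6), converged, elapsed


def cancer_free_equilibrium(params: ModelParameters) -> CellState:
    """Closed-form equilibrium of the cancer-free (C = 0) subsystem.

    From dH/dt = 0 and dR/dt = 0 with C = 0:
        R* (1 - H*/K) = (rho_s + epsilon) / (d c)      and   sigma = c H* R*,
    which rearrange to R* = (rho_s + epsilon)/(d c) + sigma/(c K) and
    H* = sigma / (c R*).  Used as an independent algebraic cross-check of
    the burn-in integrator.
    """
    p = params
    R = (p.rho_s + p.epsilon) / (p.d * p.c) + p.sigma / (p.c * p.K)
    H = p.sigma / (p.c * R)
    return CellState(H, 0.0, R)


def summarize(traj: Trajectory, thresholds: tuple[float, ...] = (0.5,)) -> TrajectorySummary:
    """Summary statistics: peak fraction/time, occupancy above thresholds,
    final fraction and the time-integrated cancerous burden.

    ``time_above`` treats the sampled fraction as piecewise linear between
    samples; the burden integral uses the trapezoid rule.
    """
    if len(traj) == 0:
        raise ValueError("cannot summarize an empty trajectory")
    f = traj.fractions
    t = traj.times
    i_peak = int(np.argmax(f))
    time_above = {thr: _time_above(t, f, thr) for thr in thresholds}
    return TrajectorySummary(
        peak_fraction=float(f[i_peak]),
        peak_time=float(t[i_peak]),
        time_above=time_above,
        final_fraction=float(f[-1]),
        burden_integral=float(np.trapezoid(traj.C, t)),
    )


def _time_above(t: np.ndarray, f: np.ndarray, thr: float) -> float:
    """Lebesgue measure of {t : f(t) >= thr} for piecewise-linear f."""
    if len(t) < 2:
        return 0.0
    t0, t1 = t[:-1], t[1:]
    f0, f1 = f[:-1], f[1:]
    dt = t1 - t0
    lo = np.minimum(f0, f1)
    hi = np.maximum(f0, f1)
    full = lo >= thr
    none = hi < thr
    partial = ~(full | none)
    frac = np.zeros_like(dt)
    frac[full] = 1.0
    with np.errstate(divide="ignore", invalid="ignore"):
        span = hi[partial] - lo[partial]
        frac[partial] = np.where(span > 0, (hi[partial] - thr) / span, 1.0)
    return float(np.sum(dt * frac))
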