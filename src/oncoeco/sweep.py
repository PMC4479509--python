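"""Equilibrium invasibility surface over an (immune efficiency, resource
supply) grid.

Each grid cell burns the undisturbed system in to steady state with the
cell's (theta, sigma) and records the equilibrium cancer fraction — the
invasibility surface: how permanent immune depression and permanent resource
enrichment jointly open the door to the cancerous phenotype.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import cancer_fraction
from .params import CellState, ModelParameters
from .simulate import SolverOptions, equilibrate

__all__ = ["SweepGrid", "default_grid_axes", "sweep", "monotonicity_report"]


@dataclass(frozen=True)
class SweepGrid:
    """Equilibrium cancer fraction over a (theta, sigma) grid.

    ``theta_values`` are descending (moving down the rows weakens immune
    surveillance, matching the surface's conventional orientation);
    ``sigma_values`` ascend.  ``fraction[i, j]`` is the equilibrium cancer
    fraction at (theta_values[i], sigma_values[j]); ``converged[i, j]``
    flags whether the burn-in met its convergence criterion.
    """

    theta_values: np.ndarray
    sigma_values: np.ndarray
    fraction: np.ndarray
    converged: np.ndarray

    def __post_init__(self) -> None:
        shape = (len(self.theta_values), len(self.sigma_values))
        if self.fraction.shape != shape or self.converged.shape != shape:
            raise ValueError(f"matrix shape must be {shape}")
        if np.any((self.fraction < 0) | (self.fraction > 1)):
            raise ValueError("fractions must lie in [0, 1]")

    def to_frame(self):
        """Grid as a pandas DataFrame (theta rows, sigma columns)."""
        import pandas as pd

        return pd.DataFrame(self.fraction, index=self.theta_values, columns=self.sigma_values)


def default_grid_axes(n_theta: int = 20, n_sigma: int = 20) -> tuple[np.ndarray, np.ndarray]:
    """Default sweep axes: theta log-spaced over [365/200, 365/2]
    (descending) and sigma log-spaced over [1e3, 1e6] (ascending), each
    adjusted so the disturbance-baseline point (365/25, 4e4) is an interior
    grid point (the nearest log-spaced point is replaced by the anchor).
    """
    theta = np.geomspace(365.0 / 2.0, 365.0 / 200.0, n_theta)
    sigma = np.geomspace(1.0e3, 1.0e6, n_sigma)
    theta[np.argmin(np.abs(np.log(theta) - np.log(365.0 / 25.0)))] = 365.0 / 25.0
    sigma[np.argmin(np.abs(np.log(sigma) - np.log(4.0e4)))] = 4.0e4
    return theta, sigma


def sweep(
    params: ModelParameters,
    theta_values,
    sigma_values,
    *,
    options: SolverOptions = SolverOptions(),
    max_years: float = 500.0,
) -> SweepGrid:
    """Equilibrium cancer fraction for every (theta, sigma) combination.

    Cells are independent (each starts from the same default burn-in
    protocol), so the result does not depend on evaluation order.  A cell
    whose burn-in does not converge is flagged, never fatal.
    """
    theta_values = np.asarray(theta_values, dtype=float)
    sigma_values = np.asarray(sigma_values, dtype=float)
    if np.any(theta_values < 0) or np.any(sigma_values <= 0):
        raise ValueError("theta values must be >= 0 and sigma values > 0")
    frac = np.zeros((len(theta_values), len(sigma_values)))
    conv = np.zeros_like(frac, dtype=bool)
    for i, th in enumerate(theta_values):
        for j, sg in enumerate(sigma_values):
            p = params.replace(theta=float(th), sigma=float(sg))
            state, ok, _ = equilibrate(p, options=options, max_years=max_years)
            frac[i, j] = cancer_fraction(state)
            conv[i, j] = ok
    return SweepGrid(theta_values, sigma_values, frac, conv)


def monotonicity_report(grid: SweepGrid, tolerance: float = 1e-3) -> list[dict]:
    """Adjacent-cell violations of the expected monotone response.

    The equilibrium cancer fraction should be nonincreasing in theta at
    fixed sigma and nondecreasing in sigma at fixed theta.  Returns one
    record per adjacent pair violating this beyond ``tolerance``; pairs
    involving non-converged cells are excluded.
    """
    out: list[dict] = []
    f, conv = grid.fraction, grid.converged
    th, sg = grid.theta_values, grid.sigma_values
    n_t, n_s = f.shape
    for j in range(n_s):
        for i in range(n_t - 1):
            if not (conv[i, j] and conv[i + 1, j]):
                continue
            hi_th, lo_th = (i, i + 1) if th[i] > th[i + 1] else (i + 1, i)
            excess = f[hi_th, j] - f[lo_th, j]
            if excess > tolerance:
                out.append(
                    {"axis": "theta", "theta": (th[hi_th], th[lo_th]), "sigma": sg[j], "excess": excess}
                )
    for i in range(n_t):
        for j in range(n_s - 1):
            if not (conv[i, j] and conv[i, j + 1]):
                continue
            lo_sg, hi_sg = (j, j + 1) if sg[j] < sg[j + 1] else (j + 1, j)
            deficit = f[i, lo_sg] - f[i, hi_sg]
            if deficit > tolerance:
                out.append(
                    {"axis": "sigma", "theta": th[i], "sigma": (sg[lo_sg], sg[hi_sg]), "excess": deficit}
                )
    return out
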