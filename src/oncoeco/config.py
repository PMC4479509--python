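"""YAML run configuration, trajectory/grid writers and provenance sidecars.

A run configuration has four optional blocks — ``parameters``, ``schedule``
(explicit pulses or a random-generator spec), ``run`` (horizon, solver
tolerances, sampling, output paths) and ``sweep`` (grid axes) — plus a
``seed``.  Omitted fields fall back to documented defaults; the parameter
defaults are the published figure-caption values.  Unknown keys are
rejected so a typo can never silently fall back to a default.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .disturbance import Disturbance, DisturbanceSchedule
from .params import ModelParameters
from .simulate import SolverOptions, Trajectory
from .sweep import SweepGrid
from .synth import ScheduleGeneratorSpec

__all__ = [
    "RunConfig",
    "load_config",
    "parse_config",
    "serialize_config",
    "save_config",
    "write_trajectory",
    "read_trajectory",
    "write_grid",
]


@dataclass(frozen=True)
class RunConfig:
    """Validated, fully-defaulted description of one run."""

    parameters: ModelParameters = ModelParameters()
    schedule: DisturbanceSchedule | None = None
    generator: ScheduleGeneratorSpec | None = None
    horizon: float = 6.0
    solver: SolverOptions = SolverOptions()
    seed: int = 0
    sweep_theta: tuple[float, ...] | None = None
    sweep_sigma: tuple[float, ...] | None = None

    def resolved_schedule(self) -> DisturbanceSchedule:
        """The explicit schedule, generating one from the spec if needed."""
        if self.schedule is not None:
            return self.schedule
        if self.generator is not None:
            from .synth import random_schedule

            return random_schedule(self.generator)
        return DisturbanceSchedule((), self.horizon)


def _check_keys(block: dict, allowed: set[str], where: str) -> None:
    for key in block:
        if key not in allowed:
            raise ValueError(f"unknown key {key!r} in {where} block")


def parse_config(text: str) -> RunConfig:
    """Parse and validate a YAML config string into a ``RunConfig``."""
    raw = yaml.safe_load(text)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValueError("config root must be a mapping")
    _check_keys(raw, {"parameters", "schedule", "run", "sweep", "seed"}, "top-level")

    param_block = raw.get("parameters") or {}
    allowed = set(ModelParameters.field_names()) | {"gate_consumption"}
    _check_keys(param_block, allowed, "parameters")
    params = ModelParameters(**{k: v for k, v in param_block.items()})

    run_block = raw.get("run") or {}
    _check_keys(
        run_block,
        {"horizon", "rtol", "atol", "method", "max_step", "samples_per_year"},
        "run",
    )
    horizon = float(run_block.get("horizon", 6.0))
    solver = SolverOptions(
        rtol=float(run_block.get("rtol", 1e-8)),
        atol=float(run_block.get("atol", 1e-9)),
        method=str(run_block.get("method", "LSODA")),
        max_step=float(run_block.get("max_step", math.inf)),
        samples_per_year=int(run_block.get("samples_per_year", 365)),
    )

    seed = int(raw.get("seed", 0))

    schedule = None
    generator = None
    sched_block = raw.get("schedule")
    if sched_block is not None:
        _check_keys(sched_block, {"pulses", "generator"}, "schedule")
        if "pulses" in sched_block and "generator" in sched_block:
            raise ValueError("schedule block must give either 'pulses' or 'generator', not both")
        if "pulses" in sched_block:
            pulses = []
            for k, p in enumerate(sched_block["pulses"] or []):
                _check_keys(p, {"target", "start", "duration", "mode", "magnitude"}, f"pulse {k}")
                pulses.append(
                    Disturbance(
                        target=p["target"],
                        start=float(p["start"]),
                        duration=float(p["duration"]),
                        mode=p.get("mode", "replace"),
                        magnitude=float(p.get("magnitude", 0.0)),
                    )
                )
            schedule = DisturbanceSchedule(tuple(pulses), horizon)
        else:
            g = sched_block["generator"] or {}
            _check_keys(
                g,
                {
                    "horizon",
                    "immune_rate",
                    "resource_rate",
                    "immune_duration",
                    "resource_duration",
                    "magnitude_ranges",
                    "seed",
                },
                "generator",
            )
            g = dict(g)
            g.setdefault("horizon", horizon)
            g.setdefault("seed", seed)
            if "magnitude_ranges" in g:
                g["magnitude_ranges"] = {
                    k: tuple(float(x) for x in v) for k, v in g["magnitude_ranges"].items()
                }
            generator = ScheduleGeneratorSpec(**g)

    sweep_block = raw.get("sweep") or {}
    _check_keys(sweep_block, {"theta", "sigma", "n_theta", "n_sigma"}, "sweep")
    sweep_theta = sweep_sigma = None
    if sweep_block:
        if "theta" in sweep_block:
            sweep_theta = tuple(float(x) for x in sweep_block["theta"])
            sweep_sigma = tuple(float(x) for x in sweep_block["sigma"])
        else:
            from .sweep import default_grid_axes

            th, sg = default_grid_axes(
                int(sweep_block.get("n_theta", 20)), int(sweep_block.get("n_sigma", 20))
            )
            sweep_theta, sweep_sigma = tuple(th), tuple(sg)

    return RunConfig(
        parameters=params,
        schedule=schedule,
        generator=generator,
        horizon=horizon,
        solver=solver,
        seed=seed,
        sweep_theta=sweep_theta,
        sweep_sigma=sweep_sigma,
    )


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML config file."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    try:
        return parse_config(path.read_text())
    except yaml.YAMLError as exc:
        raise ValueError(f"malformed YAML in {path}: {exc}") from exc


def serialize_config(config: RunConfig) -> str:
    """Render a config back to canonical YAML (lossless round-trip)."""
    doc: dict = {
        "parameters": {k: getattr(config.parameters, k) for k in ModelParameters.field_names()},
        "run": {
            "horizon": config.horizon,
            "rtol": config.solver.rtol,
            "atol": config.solver.atol,
            "method": config.solver.method,
            "samples_per_year": config.solver.samples_per_year,
        },
        "seed": config.seed,
    }
    if config.parameters.gate_consumption:
        doc["parameters"]["gate_consumption"] = True
    if math.isfinite(config.solver.max_step):
        doc["run"]["max_step"] = config.solver.max_step
    if config.schedule is not None:
        doc["schedule"] = {
            "pulses": [
                {
                    "target": p.target,
                    "start": p.start,
                    "duration": p.duration,
                    "mode": p.mode,
                    "magnitude": p.magnitude,
                }
                for p in config.schedule.pulses
            ]
        }
    elif config.generator is not None:
        g = dataclasses.asdict(config.generator)
        g["magnitude_ranges"] = {k: list(v) for k, v in g["magnitude_ranges"].items()}
        doc["schedule"] = {"generator": g}
    if config.sweep_theta is not None:
        doc["sweep"] = {"theta": list(config.sweep_theta), "sigma": list(config.sweep_sigma)}
    return yaml.safe_dump(doc, sort_keys=True)


def save_config(config: RunConfig, path: str | Path) -> None:
    Path(path).write_text(serialize_config(config))


def config_hash(config: RunConfig) -> str:
    return hashlib.sha256(serialize_config(config).encode()).hexdigest()


_TRAJ_COLUMNS = ("t", "H", "C", "R", "fraction", "theta_eff", "sigma_eff")


def write_trajectory(
    traj: Trajectory, path: str | Path, config: RunConfig | None = None
) -> Path:
    """Write a trajectory as a CSV table at full floating precision.

    A JSON sidecar (``<path>.meta.json``) records the software version and,
    when a config is given, its hash and seed, so any table can be traced
    back to the exact run that produced it.
    """
    path = Path(path)
    df = traj.to_frame()
    df.to_csv(path, index=False, float_format="%.17g")
    meta = {"version": __version__, "rows": len(df), "columns": list(_TRAJ_COLUMNS)}
    if config is not None:
        meta["config_sha256"] = config_hash(config)
        meta["seed"] = config.seed
    Path(str(path) + ".meta.json").write_text(json.dumps(meta, indent=2) + "\n")
    return path


def read_trajectory(path: str | Path) -> Trajectory:
    """Read a trajectory table written by :func:`write_trajectory`."""
    import pandas as pd

    df = pd.read_csv(path)
    missing = set(_TRAJ_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trajectory table {path} is missing columns {sorted(missing)}")
    return Trajectory(
        times=df["t"].to_numpy(),
        H=df["H"].to_numpy(),
        C=df["C"].to_numpy(),
        R=df["R"].to_numpy(),
        fractions=df["fraction"].to_numpy(),
        theta_eff=df["theta_eff"].to_numpy(),
        sigma_eff=df["sigma_eff"].to_numpy(),
    )


def write_grid(grid: SweepGrid, path: str | Path) -> Path:
    """Write a sweep grid as CSV with theta row labels and sigma columns."""
    path = Path(path)
    df = grid.to_frame()
    df.index.name = "theta\\sigma"
    df.to_csv(path, float_format="%.17g")
    conv = Path(str(path) + ".converged.csv")
    import pandas as pd

    pd.DataFrame(
        grid.converged.astype(int), index=grid.theta_values, columns=grid.sigma_values
    ).to_csv(conv)
    return path
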