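"""Parameter sweeps over the feedback model (delay/coupling/phase grids).

A sweep runs one scalar DDE solve per grid point, evaluates an observable,
and resamples it onto a shared time axis, producing the matrices behind
time-versus-delay and time-versus-coupling population maps.  Rows are
independent: a failed cell is recorded and the sweep continues.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .dde import solve_scalar
from .model import FeedbackCoupling
from .observables import population

__all__ = ["SweepAxis", "SweepGrid", "SweepResult", "sweep", "default_dt"]

_SWEEPABLE = ("tau", "gamma0", "phi", "delta0")


def default_dt(tau: float) -> float:
    """Solver step policy for sweep cells: τ/200 capped at 0.5 fs, with a
    τ/10 floor for sub-femtosecond delays so near-Markovian cells stay
    affordable (the delayed term is then a small perturbation and τ/10
    resolves it fully)."""
    if tau <= 0:
        return 0.5
    if tau < 1.0:
        return tau / 10.0
    return min(tau / 200.0, 0.5)


@dataclass(frozen=True)
class SweepAxis:
    name: str
    start: float
    stop: float
    count: int
    spacing: str = "linear"

    def __post_init__(self):
        if self.name not in _SWEEPABLE:
            raise ValueError(f"sweep axis must be one of {_SWEEPABLE}, got {self.name!r}")
        if self.count < 2:
            raise ValueError("axis count must be >= 2")
        if not self.start < self.stop:
            raise ValueError("axis needs start < stop")
        if self.spacing not in ("linear", "log"):
            raise ValueError("spacing must be 'linear' or 'log'")
        if self.spacing == "log" and self.start <= 0:
            raise ValueError("log spacing needs start > 0")

    def values(self) -> np.ndarray:
        if self.spacing == "log":
            return np.geomspace(self.start, self.stop, self.count)
        return np.linspace(self.start, self.stop, self.count)


@dataclass
class SweepGrid:
    """Axis definitions plus fixed parameters and solver settings."""

    axes: list
    base: FeedbackCoupling
    t_max: float = 2000.0
    dt: Optional[float] = None  # None → per-cell default_dt(tau)
    observable: str = "population"
    n_times: int = 400
    max_points: int = 10**6

    def __post_init__(self):
        if not self.axes:
            raise ValueError("at least one sweep axis is required")
        names = [ax.name for ax in self.axes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate sweep axes")
        total = math.prod(ax.count for ax in self.axes)
        if total > self.max_points:
            raise ValueError(
                f"grid has {total} points, exceeding the cap {self.max_points}"
            )
        if self.observable != "population":
            raise ValueError("sweeps currently evaluate the scalar population only")


@dataclass
class SweepResult:
    grid: SweepGrid
    points: pd.DataFrame  # one row per grid cell, the swept parameter values
    times: np.ndarray  # shared time axis
    values: np.ndarray  # (n_points, n_times), NaN rows for failed cells
    failures: dict = field(default_factory=dict)

    def to_long_frame(self) -> pd.DataFrame:
        """Long-format table: one row per (grid cell, time point)."""
        reps = len(self.times)
        out = self.points.loc[self.points.index.repeat(reps)].reset_index(drop=True)
        out["t"] = np.tile(self.times, len(self.points))
        out["value"] = self.values.ravel()
        return out

    def to_csv(self, path, sidecar: bool = True) -> None:
        self.to_long_frame().to_csv(path, index=False)
        if sidecar:
            import json

            meta = {
                "axes": [
                    {
                        "name": ax.name,
                        "start": ax.start,
                        "stop": ax.stop,
                        "count": ax.count,
                        "spacing": ax.spacing,
                    }
                    for ax in self.grid.axes
                ],
                "base": self.grid.base.as_dict(),
                "t_max": self.grid.t_max,
                "observable": self.grid.observable,
                "failures": {str(k): v for k, v in self.failures.items()},
            }
            with open(str(path) + ".meta.json", "w") as fh:
                json.dump(meta, fh, indent=2)


def sweep(grid: SweepGrid) -> SweepResult:
    """Run the sweep: one scalar solve per grid cell, shared time axis."""
    axis_values = [ax.values() for ax in grid.axes]
    names = [ax.name for ax in grid.axes]
    cells = list(itertools.product(*axis_values))
    times = np.linspace(0.0, grid.t_max, grid.n_times)
    values = np.full((len(cells), grid.n_times), np.nan)
    failures = {}
    for i, cell in enumerate(cells):
        params = dict(zip(names, cell))
        try:
            coupling = grid.base.replace(**params)
            dt = grid.dt if grid.dt is not None else default_dt(coupling.tau)
            traj = solve_scalar(coupling, t_max=grid.t_max, dt=dt)
            pop = population(traj)
            values[i] = np.interp(times, pop.times, np.real(pop.values))
        except Exception as exc:
            failures[i] = f"{params}: {exc}"
    points = pd.DataFrame(cells, columns=names)
    return SweepResult(grid=grid, points=points, times=times, values=values, failures=failures)
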