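"""Numerical integration of the oxidation kinetics and noiseless observation.

The system can be stiff when substrate oxidation is much faster than
catalyst activation (k2 >> k1), so integration uses LSODA, which switches
between Adams and BDF automatically.  Default tolerances are tight
(rtol 1e-8, atol 1e-12 on mol/L-scale states) because the downstream
conservation checks and steady-state identities are asserted at 1e-6
relative or better.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.integrate import odeint

from .errors import IntegrationFailure, InvalidInputError
from .model_core import (
    EXTENDED,
    SPECIES,
    ExperimentDescriptor,
    RateConstants,
    initial_conditions,
)

#: default dense-output resolution for bands and plots
DENSE_GRID_POINTS = 601

DEFAULT_RTOL = 1e-8
DEFAULT_ATOL = 1e-12

#: undershoot beyond this many absolute tolerances is treated as failure
UNDERSHOOT_FACTOR = 1e3


@dataclass(frozen=True)
class Trajectory:
    """Solution of the ODE system on a time grid.

    ``states`` has shape (n_times, 7) in :data:`porphkin.model_core.SPECIES`
    order, clipped to be non-negative.
    """

    times: np.ndarray
    states: np.ndarray
    descriptor: ExperimentDescriptor
    params: RateConstants

    def species(self, name: str) -> np.ndarray:
        try:
            idx = SPECIES.index(name)
        except ValueError:
            raise InvalidInputError(f"unknown species {name!r}") from None
        return self.states[:, idx]

    def to_frame(self) -> pd.DataFrame:
        """Tidy long-format table (time_s, species, value)."""
        n = len(self.times)
        return pd.DataFrame({
            "time_s": np.repeat(self.times, len(SPECIES)),
            "species": np.tile(SPECIES, n),
            "value": self.states.reshape(-1),
        })


def default_grid(descriptor: ExperimentDescriptor, n: int = DENSE_GRID_POINTS) -> np.ndarray:
    return np.linspace(0.0, descriptor.t_max, n)


def integrate(
    params: RateConstants,
    descriptor: ExperimentDescriptor,
    grid: Optional[np.ndarray] = None,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
) -> Trajectory:
    """Solve the kinetic ODEs on ``grid`` (seconds; defaults to a dense
    601-point grid over [0, t_max]).

    Raises :class:`IntegrationFailure` if the solver reports failure or
    the solution undershoots zero by more than ``1e3 * atol``.
    """
    if rtol <= 0 or atol <= 0:
        raise InvalidInputError("tolerances must be positive")
    if grid is None:
        grid = default_grid(descriptor)
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or len(grid) == 0:
        raise InvalidInputError("grid must be a non-empty 1-d array")
    if grid[0] < 0 or grid[-1] > descriptor.t_max * (1 + 1e-12):
        raise InvalidInputError("grid must lie within [0, t_max]")
    if np.any(np.diff(grid) <= 0):
        raise InvalidInputError("grid must be strictly increasing")

    schedule = descriptor.schedule()
    y0 = initial_conditions(descriptor.s0, schedule).as_array()
    k4 = float(params.k4) if params.variant == EXTENDED else 0.0
    delta = schedule.delta

    k1, k2, k3 = params.k1, params.k2, params.k3

    def f(y, t):
        cat, cs, ox, sub = y[0], y[1], y[2], y[3]
        act = k1 * cat * ox
        turn = k2 * sub * cs
        dead = k3 * cat * ox
        direct = k4 * sub * ox
        return (-act - dead + turn, act - turn,
                -act - dead - direct + delta, -turn - direct,
                turn, direct, dead)

    # prepend t=0 if the grid starts later so y0 seeds the solver exactly
    t_eval = grid if grid[0] == 0.0 else np.concatenate([[0.0], grid])
    with np.errstate(all="ignore"):
        states, info = odeint(f, y0, t_eval, rtol=rtol, atol=atol,
                              full_output=True, printmessg=False)
    if info["message"] != "Integration successful." or not np.all(np.isfinite(states)):
        raise IntegrationFailure(
            f"solver failed: {info['message']}", {"params": params}
        )
    if grid[0] != 0.0:
        states = states[1:]
    undershoot = float(states.min())
    if undershoot < -UNDERSHOOT_FACTOR * atol:
        raise IntegrationFailure(
            f"negative concentration {undershoot:.3e} exceeds undershoot budget",
            {"params": params},
        )
    return Trajectory(times=grid, states=np.clip(states, 0.0, None),
                      descriptor=descriptor, params=params)


def observe(
    traj: Trajectory,
    descriptor: Optional[ExperimentDescriptor] = None,
    channel: str = "substrate",
    scale: Optional[float] = None,
) -> np.ndarray:
    """Predicted detector response at the design's sample times.

    Linear response: ``scale`` x concentration, where ``scale`` defaults
    to the descriptor's ``response_scale``.  ``channel`` names a state
    variable ("substrate", "metabolite_cat", ...).
    """
    if descriptor is None:
        descriptor = traj.descriptor
    t_obs = descriptor.sample_times_s
    if t_obs[0] < traj.times[0] - 1e-9 or t_obs[-1] > traj.times[-1] + 1e-9:
        raise InvalidInputError("sample times fall outside the trajectory span")
    if scale is None:
        scale = descriptor.response_scale
    conc = np.interp(t_obs, traj.times, traj.species(channel))
    return scale * conc


def write_trajectory(traj: Trajectory, path) -> None:
    traj.to_frame().to_csv(path, index=False)
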