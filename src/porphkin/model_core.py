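"""Reaction system definitions for FeTPPS-catalysed biomimetic oxidation.

The chemistry is a three-step catalytic cycle: the resting iron porphyrin
(FeTPPS) is activated by the oxidant tBuOOH to a high-valent oxo species
(FeTPPS*), which oxidises the substrate and regenerates the resting
catalyst; in parallel the resting catalyst is irreversibly destroyed by
the oxidant (FeTPPS0).  An optional fourth channel lets the substrate
react directly with the oxidant without catalyst involvement (the
"extended" model variant, needed for substrates with biphasic decay).

All three product pools (catalytic metabolite, non-catalytic metabolite,
dead catalyst) are carried as explicit state variables purely so that the
catalyst and substrate mass balances are machine-checkable; they do not
feed back into the rate laws.

Units: concentrations in mol/L, time in seconds, bimolecular rate
constants in L mol^-1 s^-1 (equivalently "per response-unit per second"
when the data are raw peak areas — a uniform rescaling of the observed
signal is absorbed into the constants and does not change the fit).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np

from .errors import ConfigurationError, InvalidInputError

#: State-vector layout used throughout the package.
SPECIES: Tuple[str, ...] = (
    "fetpps",
    "fetpps_star",
    "tbuooh",
    "substrate",
    "metabolite_cat",
    "metabolite_noncat",
    "fetpps_dead",
)

ONE_SHOT = "one_shot"
CONTINUOUS = "continuous"
STANDARD = "standard"
EXTENDED = "extended"


def _require_finite_nonneg(name: str, value: float) -> None:
    if not math.isfinite(value) or value < 0:
        raise InvalidInputError(f"{name} must be finite and >= 0, got {value!r}")


@dataclass(frozen=True)
class RateConstants:
    """Bimolecular rate constants of the catalytic cycle.

    Parameters
    ----------
    k1 : catalyst activation, FeTPPS + tBuOOH -> FeTPPS*.
    k2 : substrate oxidation, S + FeTPPS* -> metabolite + FeTPPS.
    k3 : apparent catalyst degradation, FeTPPS + tBuOOH -> FeTPPS0
         (a lumped descriptor of several deactivation pathways).
    k4 : direct (non-catalytic) substrate oxidation by tBuOOH; only
         present in the ``extended`` variant.
    """

    k1: float
    k2: float
    k3: float
    k4: Optional[float] = None
    variant: str = STANDARD

    def __post_init__(self) -> None:
        if self.variant not in (STANDARD, EXTENDED):
            raise InvalidInputError(f"unknown variant {self.variant!r}")
        _require_finite_nonneg("k1", self.k1)
        _require_finite_nonneg("k2", self.k2)
        _require_finite_nonneg("k3", self.k3)
        if self.variant == EXTENDED:
            if self.k4 is None:
                raise ConfigurationError("extended variant requires k4")
            _require_finite_nonneg("k4", self.k4)
        elif self.k4 is not None:
            raise ConfigurationError("k4 given but variant is 'standard'")

    @property
    def names(self) -> Tuple[str, ...]:
        return ("k1", "k2", "k3", "k4") if self.variant == EXTENDED else ("k1", "k2", "k3")

    def as_array(self) -> np.ndarray:
        vals = [self.k1, self.k2, self.k3]
        if self.variant == EXTENDED:
            vals.append(float(self.k4))  # type: ignore[arg-type]
        return np.asarray(vals, dtype=float)

    @classmethod
    def from_array(cls, values: Sequence[float], variant: str = STANDARD) -> "RateConstants":
        values = list(map(float, values))
        if variant == EXTENDED:
            if len(values) != 4:
                raise InvalidInputError("extended variant expects 4 constants")
            return cls(values[0], values[1], values[2], values[3], variant=EXTENDED)
        if len(values) != 3:
            raise InvalidInputError("standard variant expects 3 constants")
        return cls(values[0], values[1], values[2])


def feed_rate(s0: float, eqv: float, t_max: float) -> float:
    """Linear oxidant feed rate delta = eqv * s0 / t_max (mol L^-1 s^-1).

    The continuous-dosing experiments deliver ``eqv`` molar equivalents
    of oxidant at a constant rate over the reaction window, so the feed
    term is fully determined by the design.
    """
    for name, v in (("s0", s0), ("eqv", eqv), ("t_max", t_max)):
        if not math.isfinite(v) or v <= 0:
            raise InvalidInputError(f"{name} must be finite and > 0, got {v!r}")
    return eqv * s0 / t_max


@dataclass(frozen=True)
class DosingSchedule:
    """How the oxidant is delivered: single bolus at t=0 or linear feed."""

    mode: str
    eqv: float
    t_max: float
    delta: float = 0.0

    def __post_init__(self) -> None:
        if self.mode not in (ONE_SHOT, CONTINUOUS):
            raise InvalidInputError(f"unknown dosing mode {self.mode!r}")
        if not (math.isfinite(self.eqv) and self.eqv > 0):
            raise InvalidInputError("eqv must be > 0")
        if not (math.isfinite(self.t_max) and self.t_max > 0):
            raise InvalidInputError("t_max must be > 0")
        if self.mode == ONE_SHOT and self.delta != 0.0:
            raise InvalidInputError("one_shot dosing requires delta = 0")
        if self.mode == CONTINUOUS and self.delta <= 0.0:
            raise InvalidInputError("continuous dosing requires delta > 0")

    @classmethod
    def one_shot(cls, eqv: float, t_max: float) -> "DosingSchedule":
        return cls(ONE_SHOT, eqv, t_max, 0.0)

    @classmethod
    def continuous(cls, s0: float, eqv: float, t_max: float) -> "DosingSchedule":
        return cls(CONTINUOUS, eqv, t_max, feed_rate(s0, eqv, t_max))


@dataclass(frozen=True)
class SystemState:
    """Concentrations of every tracked pool at one instant (mol/L)."""

    fetpps: float
    fetpps_star: float
    tbuooh: float
    substrate: float
    metabolite_cat: float = 0.0
    metabolite_noncat: float = 0.0
    fetpps_dead: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.asarray([getattr(self, s) for s in SPECIES], dtype=float)

    @classmethod
    def from_array(cls, y: Sequence[float]) -> "SystemState":
        y = list(map(float, y))
        if len(y) != len(SPECIES):
            raise InvalidInputError(f"state vector must have {len(SPECIES)} entries")
        return cls(*y)

    @property
    def total_catalyst(self) -> float:
        return self.fetpps + self.fetpps_star + self.fetpps_dead

    @property
    def total_substrate(self) -> float:
        return self.substrate + self.metabolite_cat + self.metabolite_noncat


@dataclass(frozen=True)
class ExperimentDescriptor:
    """Design of one kinetic run: concentrations, dosing, sampling.

    ``response_scale`` converts model concentration to detector response
    (peak area per mol/L); it defaults to 1 so areas equal concentrations
    numerically.  ``sample_times`` are in minutes, matching how the data
    files are written; everything internal runs in seconds.
    """

    s0: float = 5e-4
    eqv: float = 10.0
    mode: str = CONTINUOUS
    t_max: float = 3600.0
    sample_times: Tuple[float, ...] = (2, 4, 6, 8, 10, 15, 20, 25, 30, 40, 50, 60)
    n_replicates: int = 3
    response_scale: float = 1.0

    def __post_init__(self) -> None:
        if not (math.isfinite(self.s0) and self.s0 > 0):
            raise InvalidInputError("s0 must be > 0")
        if self.response_scale <= 0:
            raise InvalidInputError("response_scale must be > 0")
        if self.n_replicates < 1:
            raise InvalidInputError("n_replicates must be >= 1")
        times = tuple(float(t) for t in self.sample_times)
        if len(times) == 0:
            raise InvalidInputError("sample_times must be non-empty")
        if any(b <= a for a, b in zip(times, times[1:])):
            raise InvalidInputError("sample_times must be strictly increasing")
        if times[-1] * 60.0 > self.t_max * (1 + 1e-12):
            raise InvalidInputError("sample_times must lie within t_max")
        object.__setattr__(self, "sample_times", times)
        # triggers DosingSchedule validation of mode/eqv/t_max
        self.schedule()

    def schedule(self) -> DosingSchedule:
        if self.mode == ONE_SHOT:
            return DosingSchedule.one_shot(self.eqv, self.t_max)
        return DosingSchedule.continuous(self.s0, self.eqv, self.t_max)

    @property
    def sample_times_s(self) -> np.ndarray:
        return np.asarray(self.sample_times, dtype=float) * 60.0

    def replace(self, **kwargs) -> "ExperimentDescriptor":
        from dataclasses import replace as _replace

        return _replace(self, **kwargs)


def initial_conditions(s0: float, schedule: DosingSchedule) -> SystemState:
    """Initial state implied by the dosing design.

    The catalyst loading is tied to the design as [FeTPPS]_0 = s0/eqv;
    the activated form starts at zero.  One-shot dosing places the full
    oxidant charge eqv*s0 in solution at t=0, continuous dosing starts
    with no oxidant (it arrives through the feed term).
    """
    if not (math.isfinite(s0) and s0 > 0):
        raise InvalidInputError("s0 must be > 0")
    tbuooh0 = schedule.eqv * s0 if schedule.mode == ONE_SHOT else 0.0
    return SystemState(
        fetpps=s0 / schedule.eqv,
        fetpps_star=0.0,
        tbuooh=tbuooh0,
        substrate=s0,
    )


def rhs_array(y: np.ndarray, k1: float, k2: float, k3: float,
              k4: float, delta: float) -> np.ndarray:
    """Time derivative of the state vector (``SPECIES`` order).

    ``k4 = 0`` gives the standard (purely catalytic) model; the feed
    term ``delta`` adds oxidant at a constant rate and is zero for
    one-shot dosing.  Written so catalyst and substrate conservation
    hold exactly: every loss term reappears in a bookkeeping pool.
    """
    cat, cat_star, oxi, sub = y[0], y[1], y[2], y[3]
    act = k1 * cat * oxi           # activation flux
    turn = k2 * sub * cat_star     # catalytic oxidation flux
    dead = k3 * cat * oxi          # catalyst degradation flux
    direct = k4 * sub * oxi        # non-catalytic oxidation flux
    return np.array([
        -act - dead + turn,        # fetpps
        act - turn,                # fetpps_star
        -act - dead - direct + delta,  # tbuooh
        -turn - direct,            # substrate
        turn,                      # metabolite_cat
        direct,                    # metabolite_noncat
        dead,                      # fetpps_dead
    ])


def rhs(state: SystemState, params: RateConstants, delta: float = 0.0) -> np.ndarray:
    """Rate laws evaluated at ``state``; returns d/dt in ``SPECIES`` order."""
    if params.variant == EXTENDED:
        k4 = float(params.k4)  # type: ignore[arg-type]
    else:
        k4 = 0.0
    return rhs_array(state.as_array(), params.k1, params.k2, params.k3, k4, delta)
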