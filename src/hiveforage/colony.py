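"""Colony state and forward dynamics.

A colony of ``N`` bees contains ``round(N * r)`` sedentary individuals
(brood, household workers) and ``N_f = N - round(N * r)`` foragers.  Every
bee, sedentary or not, consumes ``q`` reward units per step, so the colony
burns ``N * q`` per step and its nectar stores ``B`` must never go negative.
Each forager carries an experience counter: the number of whole time steps it
has spent on complex flowers.  Experience is never forgotten; a bee that
returns to simple flowers keeps its skill.  Mortality is a constant per-step
hazard ``mu = 1 - survival**(1/T)`` chosen so that a bee alive at step 0 is
still alive at the horizon with probability ``survival``; every death is
replaced immediately by a naive (experience-0) bee.

Two state representations are used:

* a full experience histogram (``ColonyState`` + ``Allocation`` +
  :func:`advance`) for arbitrary per-step, per-experience-class decisions —
  this is what the brute-force optimizer enumerates over; and
* a cohort roll-out (:func:`simulate`) for "switch once, permanently"
  schedules (:class:`SwitchSchedule`), where the cohort switched at step
  ``tau`` has experience ``t - tau`` at step ``t`` and decays at the per-step
  hazard, its replacements re-entering the unswitched (simple-flower) pool.

Within a step the order of events is: allocate, earn intake (each bee paid at
the experience it holds at the start of the step, so a naive bee's first
complex step pays ``c(0)``), consume ``N * q``, apply mortality/replacement,
increment the experience of complex-assigned survivors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

from .learning import LearningCurveParams, complex_reward

__all__ = [
    "ConfigurationError",
    "ColonyParams",
    "ColonyState",
    "Allocation",
    "SwitchSchedule",
    "Trajectory",
    "check_feasible",
    "step_intake",
    "advance",
    "simulate",
]

#: numerical slack for histogram-mass and bookkeeping checks
TOL = 1e-9
#: numerical slack for the "stores >= 0" feasibility constraint (solutions
#: that ride the constraint can undershoot zero by accumulated rounding)
FEAS_TOL = 1e-6

Mode = Literal["expected", "stochastic"]


class ConfigurationError(ValueError):
    """A parameter set under which no policy can keep the stores solvent."""


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass(frozen=True)
class ColonyParams:
    """Colony-level parameters.

    Parameters
    ----------
    N : int
        Total colony size (bees), sedentary individuals included.
    r : float
        Proportion of the colony that stays in the hive, in ``[0, 1)``.
    q : float
        Per-bee, per-step nectar consumption (reward units).
    T : int
        Time horizon: the step at which colony activity ends.
    survival : float
        Probability a bee alive at step 0 is still alive at the horizon.
    initial_stores : float
        Nectar stores at step 0 (reward units).
    """

    N: int = 100
    r: float = 0.0
    q: float = 30.0
    T: int = 100
    survival: float = 1.0
    initial_stores: float = 0.0

    def __post_init__(self) -> None:
        if self.N < 1:
            raise ValueError(f"N must be >= 1, got {self.N}")
        if not 0.0 <= self.r < 1.0:
            raise ValueError(f"r must be in [0, 1), got {self.r}")
        if self.q <= 0:
            raise ValueError(f"q must be > 0, got {self.q}")
        if self.T < 1:
            raise ValueError(f"T must be >= 1, got {self.T}")
        if not 0.0 < self.survival <= 1.0:
            raise ValueError(f"survival must be in (0, 1], got {self.survival}")
        if self.initial_stores < 0:
            raise ValueError(f"initial_stores must be >= 0, got {self.initial_stores}")
        if self.n_foragers < 1:
            raise ValueError(
                f"forager count N - round(N*r) = {self.n_foragers} must be >= 1"
            )

    @property
    def n_sedentary(self) -> int:
        """Sedentary bees, ``round(N*r)`` with .5 rounded away from zero."""
        return _round_half_away(self.N * self.r)

    @property
    def n_foragers(self) -> int:
        return self.N - self.n_sedentary

    @property
    def step_mortality(self) -> float:
        """Per-step hazard ``mu`` with ``(1 - mu)**T = survival``."""
        return 1.0 - self.survival ** (1.0 / self.T)


def check_feasible(cp: ColonyParams, lc: LearningCurveParams) -> None:
    """Raise :class:`ConfigurationError` if even an all-simple colony starves.

    With zero initial stores the all-simple allocation is the highest-intake
    policy at step 0, so ``N_f * s >= N * q`` is necessary for any feasible
    trajectory from an empty store.
    """
    if cp.n_foragers * lc.s < cp.N * cp.q - TOL:
        raise ConfigurationError(
            f"infeasible configuration: max step intake N_f*s = "
            f"{cp.n_foragers * lc.s:g} < per-step consumption N*q = {cp.N * cp.q:g}"
        )


# ---------------------------------------------------------------------------
# histogram representation


@dataclass
class ColonyState:
    """Forager experience histogram plus colony stores at step ``t``.

    ``h[e]`` counts foragers with experience ``e`` (fractional in
    expected-value mode); ``B`` is the nectar store.
    """

    t: int
    h: np.ndarray
    B: float

    @classmethod
    def initial(cls, cp: ColonyParams) -> "ColonyState":
        h = np.zeros(cp.T + 1)
        h[0] = cp.n_foragers
        return cls(t=0, h=h, B=cp.initial_stores)


@dataclass
class Allocation:
    """Foragers of each experience level assigned to complex flowers."""

    a: np.ndarray

    def validate(self, h: np.ndarray) -> None:
        a = np.asarray(self.a, dtype=float)
        if a.shape != h.shape:
            raise ValueError(f"allocation shape {a.shape} != histogram {h.shape}")
        if np.any(a < -TOL) or np.any(a > h + TOL):
            raise ValueError("allocation must satisfy 0 <= a_e <= h_e for every e")


def step_intake(
    state: ColonyState, alloc: Allocation, lc: LearningCurveParams
) -> float:
    """Gross colony intake of one step under the given allocation."""
    alloc.validate(state.h)
    a = np.asarray(alloc.a, dtype=float)
    n_simple = state.h.sum() - a.sum()
    levels = np.arange(len(a), dtype=float)
    return float(n_simple * lc.s + np.sum(a * complex_reward(levels, lc)))


def advance(
    state: ColonyState,
    alloc: Allocation,
    cp: ColonyParams,
    lc: LearningCurveParams,
    mode: Mode = "expected",
    rng: np.random.Generator | None = None,
) -> tuple[ColonyState, float, bool]:
    """Advance the colony one step; returns ``(new_state, intake, feasible)``.

    ``feasible`` is False when the updated stores would be negative; the
    caller decides whether to raise or prune.  In stochastic mode per-bin
    deaths are Binomial draws from ``rng``.
    """
    if state.t >= cp.T:
        raise ValueError(f"cannot advance past the horizon T={cp.T}")
    intake = step_intake(state, alloc, lc)
    B = state.B + intake - cp.N * cp.q
    feasible = B >= -FEAS_TOL

    a = np.asarray(alloc.a, dtype=float)
    h = state.h - a
    h[1:] += a[:-1]  # complex-assigned survivors gain one step of experience
    if np.any(a[-1:] > 0):
        h[-1] += a[-1]  # experience saturates at the top bin

    mu = cp.step_mortality
    if mu > 0:
        if mode == "expected":
            lost = h.sum() * mu
            h = h * (1.0 - mu)
            h[0] += lost
        elif mode == "stochastic":
            if rng is None:
                raise ValueError("stochastic mode requires an rng")
            counts = np.round(h).astype(np.int64)
            deaths = rng.binomial(counts, mu)
            h = (counts - deaths).astype(float)
            h[0] += deaths.sum()
        else:
            raise ValueError(f"unknown mode {mode!r}")
    return ColonyState(t=state.t + 1, h=h, B=B), intake, feasible


# ---------------------------------------------------------------------------
# permanent-switch schedules


@dataclass(frozen=True)
class SwitchSchedule:
    """Per-step counts of foragers newly and permanently switched to complex.

    ``m[t]`` foragers leave the simple pool at step ``t`` and forage on
    complex flowers for the rest of their lives.  Entries are integers for
    colonies with two or more foragers and fractions of foraging time in the
    solitary (``N_f == 1``) limit.
    """

    m: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.m, dtype=float)
        if m.ndim != 1:
            raise ValueError("schedule must be one-dimensional")
        if np.any(m < -TOL):
            raise ValueError("switch counts must be >= 0")
        object.__setattr__(self, "m", m)

    def __len__(self) -> int:
        return len(self.m)

    @classmethod
    def all_simple(cls, T: int) -> "SwitchSchedule":
        return cls(np.zeros(T))

    @property
    def total_switched(self) -> float:
        return float(self.m.sum())


@dataclass
class Trajectory:
    """Tidy per-step record of a simulated schedule.

    ``steps`` has one row per time step with columns ``t``, ``n_simple``,
    ``n_complex``, ``new_switchers``, ``cum_switched``, ``intake``,
    ``stores`` (after consumption), and ``mean_experience`` of the bees on
    complex flowers.  ``feasible`` is True iff stores stayed non-negative at
    every step.
    """

    steps: pd.DataFrame
    feasible: bool
    consumption_per_step: float
    initial_stores: float = 0.0

    @property
    def objective(self) -> float:
        """Total net intake over the horizon (gross intake minus T*N*q)."""
        return float(self.steps["intake"].sum()
                     - len(self.steps) * self.consumption_per_step)

    @property
    def final_stores(self) -> float:
        return float(self.steps["stores"].iloc[-1])

    @property
    def min_stores(self) -> float:
        return float(self.steps["stores"].min())

    def to_csv(self, path) -> None:
        self.steps.to_csv(path, index=False)


def simulate(
    schedule: SwitchSchedule,
    cp: ColonyParams,
    lc: LearningCurveParams,
    mode: Mode = "expected",
    seed: int | None = None,
) -> Trajectory:
    """Roll a permanent-switch schedule forward over the whole horizon.

    Deterministic in expected mode.  Stores falling below zero are reported
    through ``Trajectory.feasible``, never raised.  A schedule that switches
    more bees than remain in the simple pool is invalid and raises.
    """
    if len(schedule) != cp.T:
        raise ValueError(f"schedule length {len(schedule)} != horizon T={cp.T}")
    rng = np.random.default_rng(seed) if mode == "stochastic" else None
    mu = cp.step_mortality
    nf = cp.n_foragers
    c_arr = complex_reward(np.arange(cp.T, dtype=float), lc)

    cohorts = np.zeros(cp.T)  # mass of the cohort switched at step tau
    unswitched = float(nf)
    B = cp.initial_stores
    cum_switched = 0.0
    feasible = True
    rows = []
    for t in range(cp.T):
        m_t = float(schedule.m[t])
        if mode == "stochastic":
            m_t = float(round(m_t))
        if m_t > unswitched + TOL:
            raise ValueError(
                f"schedule switches {m_t:g} bees at step {t} but only "
                f"{unswitched:g} remain unswitched"
            )
        m_t = min(m_t, unswitched)
        unswitched -= m_t
        cohorts[t] = m_t
        cum_switched += m_t

        ages = t - np.arange(t + 1)
        live = cohorts[: t + 1]
        n_complex = float(live.sum())
        intake = unswitched * lc.s + float(live @ c_arr[ages])
        B = B + intake - cp.N * cp.q
        if B < -FEAS_TOL:
            feasible = False
        mean_exp = float(live @ ages / n_complex) if n_complex > TOL else 0.0
        rows.append(
            (t, unswitched, n_complex, m_t, cum_switched, intake, B, mean_exp)
        )

        if mu > 0:
            if mode == "expected":
                cohorts[: t + 1] *= 1.0 - mu
                unswitched = unswitched * (1.0 - mu) + nf * mu
            else:
                live_int = np.round(cohorts[: t + 1]).astype(np.int64)
                deaths = rng.binomial(live_int, mu)
                cohorts[: t + 1] = live_int - deaths
                u_int = int(round(unswitched))
                deaths_u = int(rng.binomial(u_int, mu))
                unswitched = u_int - deaths_u + int(deaths.sum()) + deaths_u

    steps = pd.DataFrame(
        rows,
        columns=[
            "t",
            "n_simple",
            "n_complex",
            "new_switchers",
            "cum_switched",
            "intake",
            "stores",
            "mean_experience",
        ],
    )
    return Trajectory(
        steps=steps,
        feasible=feasible,
        consumption_per_step=cp.N * cp.q,
        initial_stores=cp.initial_stores,
    )
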