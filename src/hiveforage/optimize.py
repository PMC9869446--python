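"""Optimal allocation of foragers between simple and complex flowers.

The colony's objective is total net intake over the horizon,
``sum_t intake_t - T * N * q``, subject to stores staying non-negative at
every step.  Because the learning curve is monotone and experience is never
forgotten, production solvers restrict attention to "switch once,
permanently" policies: the decision object is a :class:`SwitchSchedule`
giving the number of foragers newly and permanently reassigned to complex
flowers at each step.  Within that class:

* ``greedy`` switches, at each step, the largest number of bees whose
  whole-horizon forward simulation (assuming no further switches) keeps the
  stores solvent, provided the survival-discounted marginal value of
  switching now is positive;
* ``lp`` solves the same class exactly as a HiGHS mixed-integer program
  (a plain linear program in the solitary fractional-time mode);
* ``bruteforce`` enumerates ALL per-step, per-experience-class allocations
  on tiny instances and is the ground truth the permanent-switch restriction
  is validated against.

The marginal value of switching one bee at step ``t`` is
``sum_{j=0}^{T-t-1} sigma_j * (c(j) - s)`` with ``sigma_j = (1-mu)**j`` the
probability the bee is still alive ``j`` steps later; with ``survival = 1``
this reduces to ``sum c(j) > s * (T - t)``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import scipy.optimize as sopt

from .colony import (
    TOL,
    ColonyParams,
    ConfigurationError,
    SwitchSchedule,
    Trajectory,
    check_feasible,
    simulate,
)
from .learning import LearningCurveParams, complex_reward

__all__ = [
    "PolicySolution",
    "schedule_value",
    "optimize",
    "greedy_schedule",
    "milp_schedule",
    "bruteforce_oracle",
    "BruteForceSolution",
    "all_complex_step",
]

INFEASIBLE = float("-inf")


@dataclass
class PolicySolution:
    """A solved allocation policy: schedule, roll-out and diagnostics."""

    schedule: SwitchSchedule
    trajectory: Trajectory
    objective: float
    all_complex_step: int | None
    method: str
    colony: ColonyParams
    learning: LearningCurveParams


def schedule_value(
    schedule: SwitchSchedule, cp: ColonyParams, lc: LearningCurveParams
) -> float:
    """Objective of a schedule in expected mode; ``-inf`` if infeasible."""
    traj = simulate(schedule, cp, lc, mode="expected")
    return traj.objective if traj.feasible else INFEASIBLE


def all_complex_step(traj: Trajectory, tol: float = 1e-9) -> int | None:
    """First step with zero foragers on simple flowers, or None if never."""
    hit = traj.steps.index[traj.steps["n_simple"] <= tol]
    return int(traj.steps.loc[hit[0], "t"]) if len(hit) else None


# ---------------------------------------------------------------------------
# shared precomputations


def _curves(cp: ColonyParams, lc: LearningCurveParams):
    """c(j), sigma_j and the prefix sums P_k = sum_{j<=k} sigma_j (c_j - s)."""
    j = np.arange(cp.T, dtype=float)
    c = complex_reward(j, lc)
    sigma = (1.0 - cp.step_mortality) ** j
    prefix = np.cumsum(sigma * (c - lc.s))
    return c, sigma, prefix


# ---------------------------------------------------------------------------
# greedy


def greedy_schedule(
    cp: ColonyParams, lc: LearningCurveParams, fractional: bool | None = None
) -> SwitchSchedule:
    """Earliest-feasible permanent switching with whole-horizon lookahead.

    At each step the solver switches the largest batch of unswitched bees
    such that the remaining trajectory (no further switches assumed) keeps
    stores non-negative, and only while the survival-discounted value of a
    switch is positive.  Batch sizes are integers by default; in fractional
    mode (forced when the colony has a single forager) they are continuous
    proportions of foraging time, under which the solution scales exactly
    linearly with colony size.
    """
    check_feasible(cp, lc)
    T, nf, mu = cp.T, cp.n_foragers, cp.step_mortality
    if fractional is None:
        fractional = nf == 1
    c, sigma, prefix = _curves(cp, lc)

    m_sched = np.zeros(T)
    cohorts = np.zeros(T)  # mass per switch step
    ages = np.arange(T)  # age of cohort tau at the current step is t - tau
    unswitched = float(nf)
    B = cp.initial_stores
    for t in range(T):
        R = T - t
        gain = prefix[R - 1]
        m_t = 0.0
        if gain > 1e-12 and unswitched > TOL:
            m_t = _max_feasible_switch(
                t, cohorts, unswitched, B, cp, lc, c, sigma, prefix
            )
            if not fractional:
                m_t = float(np.floor(m_t + 1e-9))
        m_sched[t] = m_t
        unswitched -= m_t
        cohorts[t] = m_t

        live = cohorts[: t + 1]
        intake = unswitched * lc.s + float(live @ c[t - ages[: t + 1]])
        B += intake - cp.N * cp.q
        if mu > 0:
            cohorts[: t + 1] *= 1.0 - mu
            unswitched = unswitched * (1.0 - mu) + nf * mu
    return SwitchSchedule(m_sched)


def _max_feasible_switch(
    t: int,
    cohorts: np.ndarray,
    unswitched: float,
    B: float,
    cp: ColonyParams,
    lc: LearningCurveParams,
    c: np.ndarray,
    sigma: np.ndarray,
    prefix: np.ndarray,
) -> float:
    """Largest extra switch at step ``t`` keeping all future stores >= 0.

    The future stores path is affine in the batch size ``m``:
    ``B_k(m) = base_k + m * prefix_k`` where ``base_k`` assumes no further
    switches, so the bound is a min over the steps where ``prefix_k < 0``.
    """
    R = cp.T - t
    u = np.arange(R)
    # cohort earnings decay with sigma while their experience keeps growing
    idx = np.nonzero(cohorts[:t])[0]
    if len(idx):
        age_mat = (t - idx)[:, None] + u[None, :]
        cohort_contrib = sigma[u] * (cohorts[idx] @ c[age_mat])
    else:
        cohort_contrib = np.zeros(R)
    # unswitched pool relaxes toward nf as replacements of dead cohort bees
    # join it: u_{k+1} = u_k (1-mu) + nf * mu
    pool = cp.n_foragers + (unswitched - cp.n_foragers) * sigma[u]
    intake = pool * lc.s + cohort_contrib
    base = B + np.cumsum(intake - cp.N * cp.q)

    P = prefix[:R]
    binding = P < -TOL
    if not np.any(binding):
        return unswitched
    bound = np.min(base[binding] / -P[binding])
    return float(min(max(bound, 0.0), unswitched))


# ---------------------------------------------------------------------------
# exact policy-class solve (mixed-integer / linear program)


def milp_schedule(
    cp: ColonyParams,
    lc: LearningCurveParams,
    relaxation: bool = False,
    fractional: bool | None = None,
) -> SwitchSchedule:
    """Solve the permanent-switch class exactly with HiGHS.

    Decision variables are the batch sizes ``m_t``; the objective and every
    stores constraint are linear in them.  Integrality is imposed except in
    the solitary fractional-time mode or when ``relaxation=True`` (the pure
    LP relaxation, useful as a diagnostic upper bound).
    """
    check_feasible(cp, lc)
    T, nf = cp.T, cp.n_foragers
    if fractional is None:
        fractional = nf == 1
    _, _, prefix = _curves(cp, lc)

    gains = prefix[::-1].copy()  # gains[tau] = prefix[T-1-tau]
    # stores after step t' - 1:  B0 + t' (nf s - N q) + sum_tau m_tau P[t'-1-tau]
    A = np.zeros((T, T))
    for tprime in range(1, T + 1):
        taus = np.arange(tprime)
        A[tprime - 1, taus] = -prefix[tprime - 1 - taus]
    rhs = cp.initial_stores + np.arange(1, T + 1) * (nf * lc.s - cp.N * cp.q)

    constraints = [
        sopt.LinearConstraint(A, ub=rhs + TOL),
        sopt.LinearConstraint(np.ones((1, T)), ub=[float(nf)]),
    ]
    integrality = np.zeros(T) if (fractional or relaxation) else np.ones(T)
    res = sopt.milp(
        c=-gains,
        constraints=constraints,
        bounds=sopt.Bounds(0.0, float(nf)),
        integrality=integrality,
    )
    if not res.success:
        raise ConfigurationError(f"MILP solve failed: {res.message}")
    m = res.x
    if not fractional and not relaxation:
        m = np.round(m)
    else:
        m = np.clip(m, 0.0, None)
    # zero out negligible numerical dust so schedules compare cleanly
    m[np.abs(m) < 1e-9] = 0.0
    return SwitchSchedule(m)


# ---------------------------------------------------------------------------
# exhaustive oracle


@dataclass
class BruteForceSolution:
    """Global optimum over unrestricted per-experience-class allocations."""

    objective: float
    allocations: list[tuple[tuple[int, int], ...]]  # per step: ((e, a_e), ...)


def bruteforce_oracle(
    cp: ColonyParams, lc: LearningCurveParams
) -> BruteForceSolution:
    """Enumerate every feasible allocation path on a tiny instance.

    Restricted to ``N_f <= 3``, ``T <= 6`` and ``survival = 1`` so the
    search space is small and deterministic.  Unlike the production solvers
    this explores non-permanent policies (bees may switch back and forth),
    which is exactly what makes it a valid check of the permanent-switch
    restriction.
    """
    if cp.n_foragers > 3 or cp.T > 6:
        raise ValueError("oracle instances are limited to N_f <= 3 and T <= 6")
    if cp.survival != 1.0:
        raise ValueError("oracle requires survival = 1 (deterministic dynamics)")
    check_feasible(cp, lc)

    T = cp.T
    c = complex_reward(np.arange(T + 1, dtype=float), lc)
    consumption = cp.N * cp.q

    best_obj = INFEASIBLE
    best_path: list | None = None

    def recurse(t: int, hist: tuple, B: float, acc: float, path: list) -> None:
        nonlocal best_obj, best_path
        if t == T:
            if acc > best_obj:
                best_obj, best_path = acc, list(path)
            return
        levels = [e for e, n in enumerate(hist) if n > 0]
        counts = [hist[e] for e in levels]
        for alloc in itertools.product(*(range(n + 1) for n in counts)):
            intake = sum(
                (n - a) * lc.s + a * c[e]
                for e, n, a in zip(levels, counts, alloc)
            )
            B2 = B + intake - consumption
            if B2 < -TOL:
                continue
            h2 = list(hist)
            for e, a in zip(levels, alloc):
                h2[e] -= a
                h2[e + 1] += a
            path.append(tuple((e, a) for e, a in zip(levels, alloc) if a))
            recurse(t + 1, tuple(h2), B2, acc + intake - consumption, path)
            path.pop()

    hist0 = tuple([cp.n_foragers] + [0] * T)
    recurse(0, hist0, cp.initial_stores, 0.0, [])
    if best_path is None:
        raise ConfigurationError("no feasible allocation path exists")
    return BruteForceSolution(objective=best_obj, allocations=best_path)


# ---------------------------------------------------------------------------
# front door


def optimize(
    cp: ColonyParams,
    lc: LearningCurveParams,
    method: str = "greedy",
    fractional: bool | None = None,
) -> PolicySolution:
    """Compute the optimal policy; ``method`` is ``greedy`` or ``lp``.

    ``fractional=True`` switches continuous proportions of foraging time
    rather than whole bees (automatic for a single forager).
    (``bruteforce`` solutions live outside the permanent-switch class and are
    returned by :func:`bruteforce_oracle` instead.)
    """
    if method == "greedy":
        sched = greedy_schedule(cp, lc, fractional=fractional)
    elif method == "lp":
        sched = milp_schedule(cp, lc, fractional=fractional)
    elif method == "bruteforce":
        raise ValueError("use bruteforce_oracle() for exhaustive solutions")
    else:
        raise ValueError(f"unknown method {method!r}")
    traj = simulate(sched, cp, lc, mode="expected")
    if not traj.feasible:
        raise ConfigurationError(
            f"{method} produced an infeasible schedule (min stores "
            f"{traj.min_stores:g}); configuration is likely unsolvable"
        )
    return PolicySolution(
        schedule=sched,
        trajectory=traj,
        objective=traj.objective,
        all_complex_step=all_complex_step(traj),
        method=method,
        colony=cp,
        learning=lc,
    )
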