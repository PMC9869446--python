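"""Model/Results front end for the colony foraging optimization.

`ColonyForagingModel` bundles the colony and learning-curve parameters;
``fit()`` solves for the optimal permanent-switch schedule and returns a
:class:`ForagingResults` carrying the schedule, its trajectory, the objective
and a human-readable ``summary()``.  Simulation of arbitrary schedules and
plotting hang off these two objects.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .colony import ColonyParams, SwitchSchedule, Trajectory, simulate
from .config import echo_config, load_config, params_from_dict
from .learning import LearningCurveParams, breakeven_experience
from .optimize import PolicySolution, optimize

__all__ = ["ColonyForagingModel", "ForagingResults"]


class ColonyForagingModel:
    """Discrete-time model of forager allocation between flower types.

    Parameters
    ----------
    colony : ColonyParams, optional
        Colony composition, consumption, horizon, survival and initial
        stores.  Defaults to the standard parameter set.
    learning : LearningCurveParams, optional
        Logistic learning curve on complex flowers and the simple-flower
        reward.

    Examples
    --------
    >>> res = ColonyForagingModel().fit()
    >>> res.schedule.m[0], res.all_complex_step
    (50.0, 22)
    """

    def __init__(
        self,
        colony: ColonyParams | None = None,
        learning: LearningCurveParams | None = None,
    ) -> None:
        self.colony = colony if colony is not None else ColonyParams()
        self.learning = learning if learning is not None else LearningCurveParams()

    @classmethod
    def from_config(cls, source) -> "ColonyForagingModel":
        """Build a model from a YAML/JSON config file path or a flat dict."""
        if isinstance(source, dict):
            cp, lc = params_from_dict(source)
        else:
            cp, lc = load_config(source)
        return cls(colony=cp, learning=lc)

    def fit(
        self, method: str = "greedy", fractional: bool | None = None
    ) -> "ForagingResults":
        """Solve for the optimal switch schedule.

        ``method`` is ``"greedy"`` (default) or ``"lp"`` (exact HiGHS solve
        of the same policy class); ``fractional=True`` allocates continuous
        proportions of foraging time instead of whole bees.
        """
        sol = optimize(self.colony, self.learning, method=method,
                       fractional=fractional)
        return ForagingResults(model=self, **sol.__dict__)

    def simulate(
        self,
        schedule: SwitchSchedule | np.ndarray,
        mode: str = "expected",
        seed: int | None = None,
    ) -> Trajectory:
        """Roll out an arbitrary switch schedule (no optimization)."""
        if not isinstance(schedule, SwitchSchedule):
            schedule = SwitchSchedule(np.asarray(schedule, dtype=float))
        return simulate(schedule, self.colony, self.learning, mode=mode, seed=seed)


@dataclass
class ForagingResults(PolicySolution):
    """Fitted allocation policy with reporting conveniences."""

    model: ColonyForagingModel = None

    @property
    def first_switch_step(self) -> int | None:
        nz = np.nonzero(self.schedule.m > 1e-12)[0]
        return int(nz[0]) if len(nz) else None

    @property
    def total_complex_bee_steps(self) -> float:
        """Sum over steps of the number of foragers on complex flowers."""
        return float(self.trajectory.steps["n_complex"].sum())

    def summary(self) -> str:
        cp, lc = self.colony, self.learning
        acs = self.all_complex_step
        lines = [
            "Colony foraging optimization",
            "=" * 40,
            f"method:                  {self.method}",
            f"colony size N:           {cp.N}  (foragers {cp.n_foragers}, "
            f"sedentary {cp.n_sedentary})",
            f"horizon T:               {cp.T}",
            f"survival to horizon:     {cp.survival:g}",
            f"simple reward s:         {lc.s:g}   consumption q: {cp.q:g}",
            f"learning curve:          K={lc.K:g} m={lc.m:g} "
            f"alpha={lc.alpha:g} beta={lc.beta:g}",
            f"breakeven experience:    {breakeven_experience(lc)} steps",
            "-" * 40,
            f"objective (net intake):  {self.objective:.3f}",
            f"switched at step 0:      {self.schedule.m[0]:g} "
            f"of {cp.n_foragers} foragers",
            f"first switch step:       {self.first_switch_step}",
            f"all-complex step:        {'never' if acs is None else acs}",
            f"total complex bee-steps: {self.total_complex_bee_steps:.1f}",
            f"final stores:            {self.trajectory.final_stores:.3f}",
            f"feasible:                {self.trajectory.feasible}",
        ]
        return "\n".join(lines)

    def save(self, outdir) -> Path:
        """Write trajectory CSV, JSON summary and config echo to ``outdir``."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.trajectory.to_csv(out / "trajectory.csv")
        payload = {
            "method": self.method,
            "objective": self.objective,
            "all_complex_step": self.all_complex_step,
            "first_switch_step": self.first_switch_step,
            "total_complex_bee_steps": self.total_complex_bee_steps,
            "m_t": [float(v) for v in self.schedule.m],
        }
        (out / "solution.json").write_text(json.dumps(payload, indent=2) + "\n")
        echo_config(self.colony, self.learning, out)
        return out

    def plot_allocation(self, ax=None):
        """Plot foragers on complex flowers (and stores) against time."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        st = self.trajectory.steps
        ax.plot(st["t"], st["n_complex"], lw=2, label="foragers on complex")
        ax.plot(st["t"], st["cum_switched"], lw=1, ls="--",
                label="cumulative switchers")
        ax.set_xlabel("time step")
        ax.set_ylabel("foragers")
        ax2 = ax.twinx()
        ax2.plot(st["t"], st["stores"], color="tab:green", alpha=0.5,
                 label="stores")
        ax2.set_ylabel("nectar stores")
        ax.legend(loc="upper left")
        return ax
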