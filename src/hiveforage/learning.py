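"""Logistic learning curve for handling morphologically complex flowers.

Foragers on simple (open, radially symmetric) flowers collect a fixed reward
``s`` per time step with no skill required.  Complex flowers (bilateral
symmetry, deep corolla tubes, concealed nectaries) pay off only after a
learning period: a bee with ``e`` time steps of accumulated experience on
complex flowers earns

    c(e) = m + K / (1 + exp(-(alpha * e - beta)))

per step, i.e. a logistic curve rising from roughly ``m`` (the minimal reward
a naive bee scrapes together) to ``K + m`` (the reward of a fully proficient
handler).  ``alpha`` sets the steepness and ``beta`` the position of the
curve; ``beta / alpha`` is the inflection point, so larger ``beta`` means a
slower learner.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "LearningCurveParams",
    "complex_reward",
    "simple_reward",
    "breakeven_experience",
]


@dataclass(frozen=True)
class LearningCurveParams:
    """Parameters of the reward functions on the two flower types.

    Parameters
    ----------
    K : float
        Maximum learning progress (reward units); the asymptotic reward on
        complex flowers is ``K + m``.
    m : float
        Minimal per-step reward on complex flowers without any learning.
    alpha : float
        Shape (steepness) of the logistic learning curve, per time step.
    beta : float
        Position of the logistic curve.  Higher ``beta`` shifts the curve
        right, i.e. a slower learner.
    s : float
        Per-bee, per-step reward on simple flowers (no learning needed).
    """

    K: float = 100.0
    m: float = 10.0
    alpha: float = 0.45
    beta: float = 10.0
    s: float = 50.0

    def __post_init__(self) -> None:
        for name in ("K", "m", "alpha", "beta", "s"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v!r}")
        if self.K <= 0:
            raise ValueError(f"K must be > 0, got {self.K}")
        if self.m < 0:
            raise ValueError(f"m must be >= 0, got {self.m}")
        if self.alpha <= 0:
            raise ValueError(f"alpha must be > 0, got {self.alpha}")
        if self.s <= 0:
            raise ValueError(f"s must be > 0, got {self.s}")
        if not (self.m < self.s < self.K + self.m):
            # Outside this band one flower type dominates the other at every
            # experience level and the simple/complex trade-off degenerates.
            # Still constructible (dominated cases are legitimate corner
            # cases for the optimizer), but never silently.
            warnings.warn(
                "degenerate simple/complex trade-off: require "
                f"m < s < K + m, got m={self.m}, s={self.s}, K+m={self.K + self.m}",
                UserWarning,
                stacklevel=2,
            )

    @property
    def inflection(self) -> float:
        """Experience at the inflection point of the learning curve."""
        return self.beta / self.alpha

    @property
    def max_complex_reward(self) -> float:
        return self.K + self.m


def complex_reward(e, p: LearningCurveParams):
    """Per-step reward on complex flowers at experience ``e`` (time steps).

    Accepts a scalar or array of non-negative experience values; experience is
    integer-valued in the colony dynamics but the curve itself is defined for
    any non-negative real.  Strictly increasing, bounded in ``(m, K + m)``.
    """
    e_arr = np.asarray(e, dtype=float)
    if not np.all(np.isfinite(e_arr)):
        raise ValueError("experience must be finite")
    if np.any(e_arr < 0):
        raise ValueError("experience must be >= 0")
    out = p.m + p.K / (1.0 + np.exp(-(p.alpha * e_arr - p.beta)))
    return out if isinstance(e, np.ndarray) else float(out)


def simple_reward(p: LearningCurveParams) -> float:
    """Per-step reward on simple flowers; constant, no learning."""
    return p.s


def breakeven_experience(p: LearningCurveParams) -> int:
    """Smallest integer experience at which complex flowers beat simple ones.

    Solves ``c(e) > s`` for the least integer ``e >= 0``.  Raises if
    ``s >= K + m`` (complex flowers never become profitable).
    """
    if p.s >= p.K + p.m:
        raise ValueError(
            f"complex flowers never beat simple ones: s={p.s} >= K+m={p.K + p.m}"
        )
    if complex_reward(0.0, p) > p.s:
        return 0
    # c(e) > s  <=>  e > (beta - log(K/(s-m) - 1)) / alpha   (for m < s)
    e_star = (p.beta - math.log(p.K / (p.s - p.m) - 1.0)) / p.alpha
    e = max(0, math.floor(e_star))
    while complex_reward(float(e), p) <= p.s:  # guard against fp edge cases
        e += 1
    return e
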