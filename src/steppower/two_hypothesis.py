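"""Closed-form power analysis for global tests of two hypotheses.

The global test rejects the intersection null H1 ∩ H2 when the larger
p-value falls below c1*alpha or the smaller below c2*alpha, with
c1 >= c2 >= 0.  Exact size alpha under independent uniforms is equivalent
to the constraint (1 - 2 c2) + c1 (2 c2 - c1) alpha = 0, which pins c2 to
c1 and makes the search for optimal constants one-dimensional.  Under the
single-parameter step model for the p-values the rejection probability is
piecewise polynomial in (c1, c2, f1, f2), so maximal power and the
maximizing constants come out in closed form; the normal-shift model
needs a (still one-dimensional) numerical search.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.stats import norm

__all__ = [
    "ConstantPair",
    "c2_from_c1",
    "size_residual",
    "rejection_probability_2",
    "max_power_one_false",
    "max_power_two_false",
    "optimal_pair_one_false",
    "optimal_pair_two_false",
    "normal_rejection_probability_2",
    "optimize_normal_pair",
]

_SIZE_TOL = 1e-10


def size_residual(c1: float, c2: float, alpha: float) -> float:
    """Left-hand side of the exact-size identity (zero means size alpha)."""
    return (1.0 - 2.0 * c2) + c1 * (2.0 * c2 - c1) * alpha


@dataclass(frozen=True)
class ConstantPair:
    """Critical constants (c1, c2) for the two-hypothesis global test.

    ``exact_size`` marks pairs satisfying the size identity to 1e-10;
    ``degenerate`` marks a pair returned from a flat optimization problem
    where every exact-size pair is equally good.
    """

    c1: float
    c2: float
    alpha: float
    degenerate: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError(f"alpha must lie in (0, 1), got {self.alpha}")
        if self.c2 < 0 or self.c1 < 0:
            raise ValueError("critical constants must be nonnegative")
        if self.c1 < self.c2 - 1e-12:
            raise ValueError(
                f"monotonicity requires c1 >= c2, got ({self.c1}, {self.c2})")

    @property
    def exact_size(self) -> bool:
        return abs(size_residual(self.c1, self.c2, self.alpha)) <= _SIZE_TOL


def c2_from_c1(c1: float, alpha: float) -> float:
    """Solve the exact-size identity for c2: c2 = (1 - c1^2 a)/(2 (1 - c1 a)).

    Valid for c1 in [1, 1/sqrt(alpha)], on which c2 decreases from 1/2
    (the Simes pair) to 0.
    """
    hi = 1.0 / math.sqrt(alpha)
    if not (1.0 - 1e-12 <= c1 <= hi + 1e-12):
        raise ValueError(
            f"c1={c1} outside the admissible interval [1, 1/sqrt(alpha)]"
            f" = [1, {hi:.6g}]")
    c2 = (1.0 - c1 * c1 * alpha) / (2.0 * (1.0 - c1 * alpha))
    if -1e-9 < c2 < 0.0:  # roundoff at the c1 = 1/sqrt(alpha) endpoint
        c2 = 0.0
    return c2


def rejection_probability_2(f1: float, f2: float, pair: ConstantPair) -> float:
    """Probability of rejecting the global null for two independent
    single-parameter step models with heights f1, f2.

    Evaluates the three-branch piecewise polynomial expression, branching
    on how f1, f2 compare with 1/(c1 alpha) and 1/(c2 alpha); the inputs
    are sorted so f1 <= f2.
    """
    if f1 < 1.0 or f2 < 1.0:
        raise ValueError("step-model parameters must satisfy f >= 1")
    f1, f2 = sorted((f1, f2))
    c1, c2, a = pair.c1, pair.c2, pair.alpha
    inv_c1 = (1.0 / (c1 * a)) if c1 > 0 else math.inf
    inv_c2 = (1.0 / (c2 * a)) if c2 > 0 else math.inf
    if f1 >= inv_c1 or f2 >= inv_c2:
        return 1.0
    if f2 <= inv_c1:
        val = c2 * (f1 + f2) * a + c1 * (c1 - 2.0 * c2) * f1 * f2 * a * a
    else:
        val = (c1 * f1 + c2 * f2) * a - c1 * c2 * f1 * f2 * a * a
    return float(min(max(val, 0.0), 1.0))


def max_power_one_false(f: float, alpha: float) -> float:
    """Maximal power over exact-size pairs with one false null (effect f).

    Three regimes in f: small effects (f <= 1/sqrt(alpha)) give f*alpha,
    moderate effects give (1 + f^2 alpha)/(2 f), and beyond
    (1 + sqrt(1-alpha))/alpha the test attains power one.
    """
    if f < 1.0:
        raise ValueError("f must be >= 1")
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie in (0, 1)")
    if f <= 1.0 / math.sqrt(alpha):
        return f * alpha
    if f <= (1.0 + math.sqrt(1.0 - alpha)) / alpha:
        return (1.0 + f * f * alpha) / (2.0 * f)
    return 1.0


def max_power_two_false(f: float, alpha: float) -> float:
    """Maximal power with both nulls false at common effect f: f^2 alpha
    up to f = 1/sqrt(alpha), then one."""
    if f < 1.0:
        raise ValueError("f must be >= 1")
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie in (0, 1)")
    if f <= 1.0 / math.sqrt(alpha):
        return f * f * alpha
    return 1.0


def optimal_pair_one_false(f: float, alpha: float) -> ConstantPair:
    """Exact-size pair maximizing power when one of the two nulls is false.

    Small effects (f <= 1/sqrt(alpha)): (1/sqrt(alpha), 0).  Moderate
    effects: c1 = 1/(f alpha), c2 = (f^2 alpha - 1)/(2 alpha f (f - 1)).
    Large effects (f > (1 + sqrt(1-alpha))/alpha): any pair with
    c2 >= 1/(f alpha) attains power one; the exact-size pair with
    c2 = 1/(f alpha) is returned by convention.
    """
    if f < 1.0:
        raise ValueError("f must be >= 1")
    root_a = 1.0 / math.sqrt(alpha)
    if f <= root_a:
        return ConstantPair(c1=root_a, c2=0.0, alpha=alpha)
    if f <= (1.0 + math.sqrt(1.0 - alpha)) / alpha:
        c1 = 1.0 / (f * alpha)
        c2 = (f * f * alpha - 1.0) / (2.0 * alpha * f * (f - 1.0))
        return ConstantPair(c1=c1, c2=c2, alpha=alpha)
    # power saturates at 1; pick the smallest c2 that achieves it
    c2 = 1.0 / (f * alpha)
    c1 = c2 + math.sqrt(c2 * c2 + (1.0 - 2.0 * c2) / alpha)
    return ConstantPair(c1=c1, c2=c2, alpha=alpha)


def optimal_pair_two_false(alpha: float) -> ConstantPair:
    """Uniformly best exact-size pair when both nulls are false:
    c1 = 1/sqrt(alpha), c2 = 0, for every effect size f."""
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie in (0, 1)")
    return ConstantPair(c1=1.0 / math.sqrt(alpha), c2=0.0, alpha=alpha)


def normal_rejection_probability_2(delta: float, pair: ConstantPair) -> float:
    """Rejection probability under one N(delta,1) and one N(0,1) statistic.

    Closed reduction of the double integral over the rejection region:
    c1 a Phi(z1 + delta) + c2 a (1 - Phi(z1 + delta)) + (1 - c1 a) Phi(z2 + delta)
    with z_i = Phi^{-1}(c_i alpha).
    """
    c1, c2, a = pair.c1, pair.c2, pair.alpha
    if c1 * a >= 1.0 or c2 * a >= 1.0:
        raise ValueError("need c_i * alpha < 1 for the normal model")
    z1 = norm.ppf(c1 * a)
    z2 = norm.ppf(c2 * a) if c2 > 0 else -math.inf
    term = (c1 * a * norm.cdf(z1 + delta)
            + c2 * a * (1.0 - norm.cdf(z1 + delta))
            + (1.0 - c1 * a) * (norm.cdf(z2 + delta) if c2 > 0 else 0.0))
    return float(min(max(term, 0.0), 1.0))


def optimize_normal_pair(delta: float, alpha: float = 0.05,
                         grid_points: int = 200) -> ConstantPair:
    """Maximize the normal-model rejection probability over exact-size pairs.

    Substitutes c2 = c2_from_c1(c1) and searches c1 on [1, 1/sqrt(alpha)]
    with a grid pre-scan followed by bounded scalar minimization; the
    objective is smooth but can have regime kinks.  delta = 0 makes the
    objective flat at alpha; the Simes pair (1, 0.5) is returned with a
    degeneracy flag.
    """
    if delta < 0:
        raise ValueError("delta must be nonnegative")
    if delta == 0:
        return ConstantPair(c1=1.0, c2=0.5, alpha=alpha, degenerate=True)
    hi = 1.0 / math.sqrt(alpha)

    def objective(c1: float) -> float:
        pair = ConstantPair(c1=c1, c2=c2_from_c1(c1, alpha), alpha=alpha)
        return -normal_rejection_probability_2(delta, pair)

    grid = np.linspace(1.0, hi, grid_points)
    vals = [objective(c) for c in grid]
    k = int(np.argmin(vals))
    lo_b = grid[max(k - 1, 0)]
    hi_b = grid[min(k + 1, grid_points - 1)]
    res = minimize_scalar(objective, bounds=(lo_b, hi_b), method="bounded",
                          options={"xatol": 1e-10})
    c1 = float(res.x)
    if objective(c1) > vals[k]:  # pre-scan beat the local refine
        c1 = float(grid[k])
    return ConstantPair(c1=c1, c2=c2_from_c1(c1, alpha), alpha=alpha)
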