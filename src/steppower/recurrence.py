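"""Exact power of the n-hypothesis global test via a probability recurrence.

The global test rejects the intersection null when the i-th largest
p-value falls below c_i * alpha for some i.  With m of the n hypotheses
false and their p-values following the single-parameter step model with a
common height f (true nulls are uniform), let B[n, m, i] be the
probability that the first such exceedance happens exactly at index i
(i = n + 1 meaning no rejection at all).  Conditioning on whether the
smallest p-value comes from a true or a false null yields

    B[n, m, i] = (n - m)/(n - i + 1) * (c_i a ∧ 1) * B[n-1, m, i]
               + m/(n - i + 1) * (f c_i a ∧ 1) * B[n-1, m-1, i],

so the full table fills with arithmetic only, and

    Power(n, m) = sum_{i=1..n} B[n, m, i].

m = 0 gives the type-I error of the test; Simes constants
c_i = (n - i + 1)/n give exactly alpha.  Since the false-null p-values
have all their mass below 1/f, the power saturates at one as soon as
f >= 1/(c_{n+1-m} alpha), which motivates the flat-constant construction
solved by :func:`flat_constant`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.stats import binom
from scipy.special import comb

__all__ = [
    "GlobalTestConfig",
    "BTable",
    "build_b_table",
    "power",
    "type1_error",
    "flat_constant",
    "approx_flat_constant",
    "full_power_threshold",
]


@dataclass(frozen=True)
class GlobalTestConfig:
    """An n-hypothesis global test plus the effect configuration.

    Parameters
    ----------
    n : int
        Number of hypotheses.
    m : int
        Number of false nulls (0 <= m <= n); each false null's p-value
        follows the single-parameter step model with height ``f``.
    f : float
        Common step-model height (>= 1) of the false nulls; f = 1 makes
        every hypothesis null.
    alpha : float
        Significance level in (0, 1).
    constants : tuple of float
        Critical constants c_1 ... c_n, compared against the ordered
        p-values from the largest down.  c_i * alpha > 1 is allowed (the
        comparison is capped at probability one).
    """

    n: int
    m: int
    f: float
    alpha: float
    constants: tuple

    def __init__(self, n, m, f, alpha, constants):
        constants = tuple(float(c) for c in constants)
        if n < 1:
            raise ValueError("n must be >= 1")
        if not 0 <= m <= n:
            raise ValueError(f"m must lie in [0, {n}], got {m}")
        if f < 1.0:
            raise ValueError("f must be >= 1")
        if not (0.0 < alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")
        if len(constants) != n:
            raise ValueError(
                f"need {n} critical constants, got {len(constants)}")
        if any(c < 0 for c in constants):
            raise ValueError("critical constants must be nonnegative")
        object.__setattr__(self, "n", int(n))
        object.__setattr__(self, "m", int(m))
        object.__setattr__(self, "f", float(f))
        object.__setattr__(self, "alpha", float(alpha))
        object.__setattr__(self, "constants", constants)

    @property
    def monotone(self) -> bool:
        c = self.constants
        return all(c[i] >= c[i + 1] for i in range(len(c) - 1))


class BTable:
    """Triangular table of first-exceedance probabilities.

    ``table[(n', m', i)]`` is the probability, for the sub-problem with n'
    hypotheses of which m' are false, that the first rejection occurs at
    ordered index i (i = n' + 1: no rejection).  Layers over i partition
    the sample space, so each (n', m') slice sums to one.
    """

    def __init__(self, entries: dict, config: GlobalTestConfig):
        self.entries = entries
        self.config = config

    def __getitem__(self, key):
        nn, mm, i = key
        return self.entries.get((nn, mm, i), 0.0)

    def layer(self, nn: int, mm: int) -> np.ndarray:
        return np.array([self[(nn, mm, i)] for i in range(1, nn + 2)])

    def layer_sum(self, nn: int, mm: int) -> float:
        return float(self.layer(nn, mm).sum())


def build_b_table(config: GlobalTestConfig) -> BTable:
    """Fill the B table bottom-up over the number of hypotheses.

    Base cases at a single hypothesis: a true null is rejected with
    probability c_1 a ∧ 1, a false null with probability f c_1 a ∧ 1.
    The accept-all entry i = n' + 1 is the residual of the partition,
    which keeps every layer summing to one exactly.

    The factorization behind the recurrence requires monotone constants.
    A non-monotone set defines the same rejection region as its monotone
    canonicalization (each c_k < c_{k+1} raised to c_{k+1}), so that
    canonicalization is applied first; the result is exact for arbitrary
    constant sets.
    """
    n, m, f, a = config.n, config.m, config.f, config.alpha
    c = list(config.constants)
    for k in range(n - 2, -1, -1):  # suffix max: power-preserving monotone set
        if c[k] < c[k + 1]:
            c[k] = c[k + 1]
    ca = [min(ci * a, 1.0) for ci in c]          # true-null exceedance probs
    fca = [min(f * ci * a, 1.0) for ci in c]     # false-null exceedance probs

    B: dict = {}
    B[(1, 0, 1)] = ca[0]
    B[(1, 0, 2)] = 1.0 - ca[0]
    if m >= 1:
        B[(1, 1, 1)] = fca[0]
        B[(1, 1, 2)] = 1.0 - fca[0]

    for nn in range(2, n + 1):
        for mm in range(0, min(m, nn) + 1):
            total = 0.0
            for i in range(1, nn + 1):
                w = nn - i + 1
                prev_true = B.get((nn - 1, mm, i), 0.0) if mm <= nn - 1 else 0.0
                prev_false = B.get((nn - 1, mm - 1, i), 0.0) if mm >= 1 else 0.0
                val = ((nn - mm) / w) * ca[i - 1] * prev_true \
                    + (mm / w) * fca[i - 1] * prev_false
                val = min(max(val, 0.0), 1.0)
                B[(nn, mm, i)] = val
                total += val
            B[(nn, mm, nn + 1)] = min(max(1.0 - total, 0.0), 1.0)
    return BTable(B, config)


def power(config: GlobalTestConfig) -> float:
    """Rejection probability of the global test: sum of the rejection
    layers of the B table (type-I error when m = 0)."""
    table = build_b_table(config)
    n, m = config.n, config.m
    return float(np.sum([table[(n, m, i)] for i in range(1, n + 1)]))


def type1_error(constants, alpha: float) -> tuple:
    """Type-I error of the global test under the full null, and whether it
    respects the level (error <= alpha + 1e-10)."""
    constants = tuple(constants)
    cfg = GlobalTestConfig(n=len(constants), m=0, f=1.0, alpha=alpha,
                           constants=constants)
    err = power(cfg)
    return err, err <= alpha + 1e-10


def flat_constant(n: int, m: int, alpha: float) -> float:
    """Largest common constant c for c_1 = ... = c_{n+1-m} = c (rest zero)
    controlling the type-I error at alpha.

    The error of this flat-top test under the global null is the binomial
    upper tail Pr(Bin(n, c alpha) >= m); it increases in c, so the sizing
    equation has a unique root, found by bisection on x = c alpha in (0, 1].
    """
    if not 1 <= m <= n:
        raise ValueError("need 1 <= m <= n")
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie in (0, 1)")

    def tail(x: float) -> float:
        return float(binom.sf(m - 1, n, x)) - alpha

    x = brentq(tail, 1e-300, 1.0, xtol=1e-14)
    return float(x) / alpha


def approx_flat_constant(n: int, m: int, alpha: float) -> float:
    """Leading-term approximation c ≈ 1 / (C(n, m) alpha^{m-1})^{1/m}."""
    if not 1 <= m <= n:
        raise ValueError("need 1 <= m <= n")
    return float((comb(n, m, exact=True) * alpha ** (m - 1)) ** (-1.0 / m))


def full_power_threshold(n: int, m: int, alpha: float) -> float:
    """Approximate effect size beyond which the flat-top test attains
    power one: f ≳ (C(n, m)/alpha)^{1/m}."""
    if not 1 <= m <= n:
        raise ValueError("need 1 <= m <= n")
    return float((comb(n, m, exact=True) / alpha) ** (1.0 / m))
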