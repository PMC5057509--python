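"""Monte-Carlo oracle for the global test.

Draws p-vectors from an independent product model, applies the ordered
comparison p_(n-i+1) <= c_i * alpha, and reports the empirical rejection
rate with its binomial standard error.  This is the simulation practice
the closed forms replace; here it serves to validate them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .constants import ConstantSet
from .models import IndependentProductModel

__all__ = ["SimulationResult", "empirical_rejection", "rejects"]


@dataclass(frozen=True)
class SimulationResult:
    estimate: float
    standard_error: float
    reps: int
    seed: int

    def agrees_with(self, value: float, n_se: float = 3.0) -> bool:
        """Whether ``value`` lies within n_se standard errors of the estimate."""
        return abs(self.estimate - value) <= n_se * max(self.standard_error, 1e-12)


def rejects(pvals: np.ndarray, constants: ConstantSet, alpha: float) -> np.ndarray:
    """Boolean rejection indicator per row of a (reps, n) p-value array.

    Row p-values are sorted descending so column i-1 holds p_(n-i+1), then
    compared elementwise against c_i * alpha.
    """
    pvals = np.atleast_2d(np.asarray(pvals, dtype=float))
    c = np.asarray(constants.values, dtype=float)
    if pvals.shape[1] != c.size:
        raise ValueError(
            f"p-vectors have {pvals.shape[1]} coordinates but "
            f"{c.size} critical constants were given")
    ordered = np.sort(pvals, axis=1)[:, ::-1]
    return np.any(ordered <= c * alpha, axis=1)


def empirical_rejection(model: IndependentProductModel, constants: ConstantSet,
                        alpha: float, reps: int = 100_000,
                        seed: int = 0) -> SimulationResult:
    """Empirical rejection probability of the global test under ``model``."""
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if model.n != len(constants):
        raise ValueError(
            f"model has {model.n} components but {len(constants)} constants")
    pvals = model.sample(reps, seed=seed)
    est = float(np.mean(rejects(pvals, constants, alpha)))
    se = math.sqrt(est * (1.0 - est) / reps)
    return SimulationResult(estimate=est, standard_error=se, reps=reps, seed=seed)
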