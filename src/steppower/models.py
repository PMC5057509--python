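"""P-value distribution models under the alternative hypothesis.

A one-sided z-test with standardized shift ``delta`` induces a p-value
distribution on (0, 1); this module provides that distribution
(:class:`NormalPValueModel`), two step-function approximations to it
(:class:`TwoPieceStepModel`, :class:`SimplifiedStepModel`), products of
independent components (:class:`IndependentProductModel`), and the
moment-matching calibration that picks step-model parameters to mimic the
normal model.  Step densities are piecewise constant, so downstream power
calculations reduce to arithmetic instead of quadrature.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence, Union

import numpy as np
from scipy import integrate, optimize
from scipy.stats import norm

__all__ = [
    "NormalPValueModel",
    "TwoPieceStepModel",
    "SimplifiedStepModel",
    "IndependentProductModel",
    "MomentSummary",
    "match_mean",
    "match_mean_variance",
    "model_from_dict",
]

_QUAD_ABSTOL = 1e-10


@dataclass(frozen=True)
class MomentSummary:
    """Mean and standard deviation of a p-value distribution on [0, 1]."""

    mean: float
    sd: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.mean <= 1.0:
            raise ValueError(f"mean must lie in [0, 1], got {self.mean}")
        if not 0.0 <= self.sd <= 0.5 + 1e-12:
            raise ValueError(f"sd must lie in [0, 0.5], got {self.sd}")


@dataclass(frozen=True)
class NormalPValueModel:
    """P-value distribution of a one-sided test of N(0,1) vs N(delta,1).

    The p-value is P = 1 - Phi(X) with X ~ N(delta, 1).  Its density is
    h(p) = phi(Phi^{-1}(p) + delta) / phi(Phi^{-1}(p)), its CDF is
    Phi(Phi^{-1}(p) + delta), and delta = 0 recovers the uniform null
    distribution.

    Parameters
    ----------
    delta : float
        Nonnegative standardized mean shift of the test statistic.
    """

    delta: float

    def __post_init__(self) -> None:
        if not self.delta >= 0:
            raise ValueError(f"delta must be nonnegative, got {self.delta}")

    def pdf(self, p):
        """Density h(p) on the open interval (0, 1)."""
        p = np.asarray(p, dtype=float)
        if np.any(p <= 0) or np.any(p >= 1):
            raise ValueError("pdf is defined for p strictly inside (0, 1)")
        z = norm.ppf(p)
        # phi(z + delta)/phi(z) in log space for stability at extreme p
        out = np.exp(norm.logpdf(z + self.delta) - norm.logpdf(z))
        return out if out.ndim else float(out)

    def cdf(self, p):
        """Pr(P <= p) = Phi(Phi^{-1}(p) + delta)."""
        p = np.asarray(p, dtype=float)
        if np.any(p < 0) or np.any(p > 1):
            raise ValueError("p must lie in [0, 1]")
        out = norm.cdf(norm.ppf(np.clip(p, 0.0, 1.0)) + self.delta)
        return out if out.ndim else float(out)

    def mean(self) -> float:
        """E[P] by quadrature of the mean integral Int Phi(x) phi(x + delta) dx."""
        val, err = integrate.quad(
            lambda x: norm.cdf(x) * norm.pdf(x + self.delta),
            -np.inf, np.inf, epsabs=_QUAD_ABSTOL,
        )
        if err > 1e-8:
            raise RuntimeError(f"mean quadrature did not converge (err={err:g})")
        return val

    def moments(self) -> MomentSummary:
        """Mean and SD by adaptive quadrature (absolute tolerance 1e-10)."""
        m = self.mean()
        e2, err = integrate.quad(
            lambda x: norm.cdf(x) ** 2 * norm.pdf(x + self.delta),
            -np.inf, np.inf, epsabs=_QUAD_ABSTOL,
        )
        if err > 1e-8:
            raise RuntimeError(f"variance quadrature did not converge (err={err:g})")
        var = max(e2 - m * m, 0.0)
        return MomentSummary(mean=m, sd=math.sqrt(var))

    def sample(self, count: int, seed: int) -> np.ndarray:
        """Draw i.i.d. p-values via the tail transform P = Phi(-(Z + delta))."""
        if count < 1:
            raise ValueError("count must be >= 1")
        rng = np.random.default_rng(seed)
        return norm.cdf(-(rng.standard_normal(count) + self.delta))

    def to_dict(self) -> dict:
        return {"type": "normal", "delta": self.delta}


@dataclass(frozen=True)
class TwoPieceStepModel:
    """Two-level step density: height f on [0, t], height g on (t, 1].

    The breakpoint t = (1 - g)/(f - g) is the unique point making the
    density integrate to one.  Requires 0 <= g <= 1 <= f with f > g; f is
    the density boost on small p-values and encodes the effect size.
    """

    f: float
    g: float
    degenerate: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        if not (0.0 <= self.g <= 1.0 <= self.f):
            raise ValueError(f"need 0 <= g <= 1 <= f, got f={self.f}, g={self.g}")
        if not self.f > self.g:
            raise ValueError("degenerate f == g: use f=1, g=0 for the uniform case")

    @property
    def breakpoint(self) -> float:
        return (1.0 - self.g) / (self.f - self.g)

    def pdf(self, p):
        p = np.asarray(p, dtype=float)
        if np.any(p < 0) or np.any(p > 1):
            raise ValueError("p must lie in [0, 1]")
        out = np.where(p <= self.breakpoint, self.f, self.g)
        return out if out.ndim else float(out)

    def cdf(self, p):
        p = np.asarray(p, dtype=float)
        if np.any(p < 0) or np.any(p > 1):
            raise ValueError("p must lie in [0, 1]")
        t = self.breakpoint
        out = np.where(p <= t, self.f * p, self.f * t + self.g * (p - t))
        out = np.clip(out, 0.0, 1.0)
        return out if out.ndim else float(out)

    def ppf(self, q):
        """Piecewise-linear inverse CDF (mass f*t sits below the breakpoint)."""
        q = np.asarray(q, dtype=float)
        t = self.breakpoint
        mass_low = self.f * t
        with np.errstate(divide="ignore", invalid="ignore"):
            hi = np.where(self.g > 0, t + (q - mass_low) / self.g, t)
        out = np.where(q <= mass_low, q / self.f, hi)
        out = np.clip(out, 0.0, 1.0)
        return out if out.ndim else float(out)

    def moments(self) -> MomentSummary:
        # E[P] from the closed form; E[P^2] from the density (the piecewise
        # integral), which reproduces the reference moment table.
        t = self.breakpoint
        mean = (1.0 - 2.0 * self.g + self.f * self.g) / (2.0 * (self.f - self.g))
        e2 = (self.g + (self.f - self.g) * t ** 3) / 3.0
        var = max(e2 - mean * mean, 0.0)
        return MomentSummary(mean=mean, sd=math.sqrt(var))

    def sample(self, count: int, seed: int) -> np.ndarray:
        if count < 1:
            raise ValueError("count must be >= 1")
        rng = np.random.default_rng(seed)
        return self.ppf(rng.random(count))

    def to_dict(self) -> dict:
        return {"type": "step", "f": self.f, "g": self.g}


@dataclass(frozen=True)
class SimplifiedStepModel:
    """Single-parameter step density: height f on [0, 1/f], zero above.

    E[P] = 1/(2f) and var[P] = 1/(12 f^2) in closed form.  f = 1 is the
    uniform null distribution; f -> infinity approaches the Dirac-uniform
    configuration (all mass at 0).
    """

    f: float
    degenerate: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        if not self.f >= 1.0:
            raise ValueError(f"f must be >= 1, got {self.f}")

    @property
    def breakpoint(self) -> float:
        return 1.0 / self.f

    def pdf(self, p):
        p = np.asarray(p, dtype=float)
        if np.any(p < 0) or np.any(p > 1):
            raise ValueError("p must lie in [0, 1]")
        out = np.where(p <= self.breakpoint, self.f, 0.0)
        return out if out.ndim else float(out)

    def cdf(self, p):
        p = np.asarray(p, dtype=float)
        if np.any(p < 0) or np.any(p > 1):
            raise ValueError("p must lie in [0, 1]")
        out = np.minimum(self.f * p, 1.0)
        return out if out.ndim else float(out)

    def ppf(self, q):
        q = np.asarray(q, dtype=float)
        out = q / self.f
        return out if out.ndim else float(out)

    def moments(self) -> MomentSummary:
        return MomentSummary(mean=1.0 / (2.0 * self.f),
                             sd=1.0 / (self.f * math.sqrt(12.0)))

    def sample(self, count: int, seed: int) -> np.ndarray:
        if count < 1:
            raise ValueError("count must be >= 1")
        rng = np.random.default_rng(seed)
        return self.ppf(rng.random(count))

    def to_dict(self) -> dict:
        return {"type": "simplified", "f": self.f}


UnivariateModel = Union[NormalPValueModel, TwoPieceStepModel, SimplifiedStepModel]


@dataclass(frozen=True)
class IndependentProductModel:
    """Joint model for n independent p-values with per-component marginals."""

    components: tuple

    def __init__(self, components: Sequence[UnivariateModel]):
        object.__setattr__(self, "components", tuple(components))
        if not self.components:
            raise ValueError("need at least one component")

    @property
    def n(self) -> int:
        return len(self.components)

    def pdf(self, p: Sequence[float]) -> float:
        p = np.asarray(p, dtype=float)
        if p.shape[-1] != self.n:
            raise ValueError(f"expected {self.n} coordinates, got {p.shape[-1]}")
        return float(np.prod([c.pdf(pi) for c, pi in zip(self.components, p)]))

    def sample(self, count: int, seed: int) -> np.ndarray:
        """(count, n) array of i.i.d. p-vectors; one child seed per component."""
        if count < 1:
            raise ValueError("count must be >= 1")
        seeds = np.random.SeedSequence(seed).spawn(self.n)
        cols = [
            comp.sample(count, seed=int(ss.generate_state(1)[0] % (2 ** 31)))
            for comp, ss in zip(self.components, seeds)
        ]
        return np.column_stack(cols)

    def to_dict(self) -> dict:
        return {"type": "product",
                "components": [c.to_dict() for c in self.components]}


def match_mean(delta: float) -> SimplifiedStepModel:
    """Calibrate the single-parameter step model to the normal model's mean.

    Setting 1/(2f) equal to the normal-model mean gives f = 1/(2 E[P]);
    delta = 0 returns the uniform model f = 1.
    """
    mean = NormalPValueModel(delta).mean()
    return SimplifiedStepModel(f=1.0 / (2.0 * mean))


def match_mean_variance(delta: float) -> TwoPieceStepModel:
    """Calibrate (f, g) so the two-piece step model matches the normal
    model's mean and variance.

    The mean equation is solved for f in terms of g,
    f(g) = (1 - 2g + 2*mean*g)/(2*mean - g), leaving a one-dimensional root
    find in g on [0, min(1, 2*mean)) for the variance equation.  delta = 0
    is degenerate (every moment-matched model is the uniform) and returns
    f=1, g=0 flagged as degenerate via a SimplifiedStepModel-style uniform.
    """
    if delta < 0:
        raise ValueError("delta must be nonnegative")
    if delta == 0:
        # uniform limit; a finite (f, g) pair is ill-conditioned here
        return TwoPieceStepModel(f=1.0 + 1e-12, g=0.0, degenerate=True)
    target = NormalPValueModel(delta).moments()
    mu, var = target.mean, target.sd ** 2

    def f_of_g(g: float) -> float:
        return (1.0 - 2.0 * g + 2.0 * mu * g) / (2.0 * mu - g)

    def var_residual(g: float) -> float:
        f = f_of_g(g)
        t = (1.0 - g) / (f - g)
        e2 = (g + (f - g) * t ** 3) / 3.0
        return e2 - mu * mu - var

    g_hi = min(1.0, 2.0 * mu) - 1e-9
    lo, hi = var_residual(0.0), var_residual(g_hi)
    if lo * hi > 0:
        raise RuntimeError(
            f"no (f, g) bracket for delta={delta}: residuals ({lo:g}, {hi:g})")
    g = optimize.brentq(var_residual, 0.0, g_hi, xtol=1e-14)
    return TwoPieceStepModel(f=f_of_g(g), g=g)


def model_from_dict(data: dict) -> Union[UnivariateModel, IndependentProductModel]:
    """Rebuild a model from its flat JSON form (inverse of ``to_dict``)."""
    kind = data.get("type")
    if kind == "normal":
        return NormalPValueModel(delta=float(data["delta"]))
    if kind == "step":
        return TwoPieceStepModel(f=float(data["f"]), g=float(data["g"]))
    if kind == "simplified":
        return SimplifiedStepModel(f=float(data["f"]))
    if kind == "product":
        return IndependentProductModel(
            [model_from_dict(c) for c in data["components"]])
    raise ValueError(f"unknown model type {kind!r}")
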