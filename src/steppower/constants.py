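"""Critical-constant families and the monotone canonicalization.

Multiple testing procedures compare the ordered p-values, from the
largest down, against c_i * alpha.  Established choices satisfy the
monotonicity requirement c_1 >= c_2 >= ... >= c_n; a set violating it can
always be replaced by a monotone set with an identical rejection region
(raise each offending c_k to its right neighbour), so nothing is lost by
restricting attention to monotone sets.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["ConstantSet", "simes_constants", "check_monotone", "canonicalize"]


@dataclass(frozen=True)
class ConstantSet:
    """An ordered set of nonnegative critical constants with a provenance
    label (``simes``, ``flat-top``, ``custom`` or ``canonicalized``)."""

    values: tuple
    provenance: str = "custom"

    def __init__(self, values, provenance: str = "custom"):
        values = tuple(float(v) for v in values)
        if not values:
            raise ValueError("need at least one constant")
        if any(v < 0 for v in values):
            raise ValueError("critical constants must be nonnegative")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "provenance", provenance)

    def __len__(self) -> int:
        return len(self.values)

    def __iter__(self):
        return iter(self.values)


def simes_constants(n: int) -> ConstantSet:
    """Simes constants c_i = (n - i + 1)/n, exactly sized at alpha for
    independent uniform p-values."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return ConstantSet(tuple((n - i + 1) / n for i in range(1, n + 1)),
                       provenance="simes")


def check_monotone(cs: ConstantSet) -> tuple:
    """Return (monotone, strict): non-increasing, and strictly decreasing."""
    v = cs.values
    monotone = all(v[i] >= v[i + 1] for i in range(len(v) - 1))
    strict = all(v[i] > v[i + 1] for i in range(len(v) - 1))
    return monotone, strict


def canonicalize(cs: ConstantSet) -> ConstantSet:
    """Monotone set with the same rejection region (hence identical power
    and type-I error).

    A single right-to-left sweep replaces each c_k < c_{k+1} by c_{k+1};
    the event {p_(n+1-k) <= c_k alpha} was already implied by
    {p_(n+1-(k+1)) <= c_{k+1} alpha} whenever c_k < c_{k+1}, so the union
    defining the test is unchanged.  Idempotent.
    """
    v = list(cs.values)
    for k in range(len(v) - 2, -1, -1):
        if v[k] < v[k + 1]:
            v[k] = v[k + 1]
    out = tuple(v)
    if out == cs.values:
        return cs
    return ConstantSet(out, provenance="canonicalized")
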