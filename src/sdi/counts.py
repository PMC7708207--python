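"""Core data containers: count vectors, abundance (probability) vectors,
and entropy estimates.

A :class:`CountVector` holds the observed category counts ``x_1..x_S``
for one stratum.  Its ``n`` is the divisor used by the estimators: by
default the vector total ``sum(x)``, but in the binomial sampling design
(each ``x_i ~ Binomial(n, p_i)`` independently) it records the binomial
size instead, which is then the correct divisor for ``p̂_i = x_i / n``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import InvalidInputError

__all__ = [
    "CountVector",
    "AbundanceVector",
    "EntropyEstimate",
    "resolve_base",
]

#: tolerance for the simplex check on normalized abundance vectors
_SIMPLEX_TOL = 1e-12


def resolve_base(base) -> float:
    """Normalize a log-base specification to a float.

    Accepts 2, 10, the float ``math.e`` or the strings ``"2"``, ``"e"``,
    ``"10"``.  Only these three bases are supported.
    """
    if isinstance(base, str):
        base = base.strip().lower()
        if base == "e":
            return math.e
        try:
            base = float(base)
        except ValueError as exc:
            raise InvalidInputError(f"unsupported log base: {base!r}") from exc
    b = float(base)
    if b in (2.0, 10.0) or math.isclose(b, math.e):
        return b
    raise InvalidInputError(f"unsupported log base: {base!r} (use 2, 'e' or 10)")


def base_label(base: float) -> str:
    if base == 2.0:
        return "2"
    if base == 10.0:
        return "10"
    return "e"


@dataclass(frozen=True)
class CountVector:
    """Observed counts for the S categories of one stratum.

    Parameters
    ----------
    counts
        Non-negative integers, one per category; at least one positive.
    n
        Divisor for relative abundances.  Defaults to ``sum(counts)``.
        Under the independent-binomial design, pass the binomial size
        (which must be at least ``max(counts)``).
    labels
        Optional category names, one per count.
    """

    counts: tuple[int, ...]
    n: int = 0
    labels: tuple[str, ...] | None = None

    def __init__(self, counts: Sequence[int], n: int | None = None,
                 labels: Sequence[str] | None = None):
        counts = tuple(int(c) for c in counts)
        if len(counts) == 0:
            raise InvalidInputError("count vector must have at least one category")
        if any(c < 0 for c in counts):
            raise InvalidInputError(f"counts must be non-negative, got {counts}")
        if not any(c > 0 for c in counts):
            raise InvalidInputError("at least one count must be positive")
        total = sum(counts)
        if n is None:
            n = total
        n = int(n)
        if n <= 0:
            raise InvalidInputError("n must be a positive integer")
        if n < max(counts):
            raise InvalidInputError(
                f"n={n} is smaller than the largest count {max(counts)}")
        if labels is not None:
            labels = tuple(str(l) for l in labels)
            if len(labels) != len(counts):
                raise InvalidInputError("labels length must match counts length")
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "n", n)
        object.__setattr__(self, "labels", labels)

    @property
    def S(self) -> int:
        """Number of categories (richness slots, including zero counts)."""
        return len(self.counts)

    @property
    def total(self) -> int:
        return sum(self.counts)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.counts, dtype=float)


@dataclass(frozen=True)
class AbundanceVector:
    """A vector of category probabilities ``p_i`` in [0, 1].

    ``normalized=True`` asserts the simplex constraint ``sum(p) == 1``
    (checked to 1e-12).  The Bayesian posterior and the numerical-study
    design deliberately do *not* impose that constraint, so most
    internally produced vectors carry ``normalized=False``.
    """

    probs: tuple[float, ...]
    normalized: bool = False

    def __init__(self, probs: Sequence[float], normalized: bool = False):
        probs = tuple(float(p) for p in probs)
        if len(probs) == 0:
            raise InvalidInputError("abundance vector must be non-empty")
        for p in probs:
            if not (0.0 <= p <= 1.0) or math.isnan(p):
                raise InvalidInputError(f"probability {p} outside [0, 1]")
        if normalized and abs(sum(probs) - 1.0) > _SIMPLEX_TOL:
            raise InvalidInputError(
                f"normalized flag set but sum(p) = {sum(probs)!r} != 1")
        object.__setattr__(self, "probs", probs)
        object.__setattr__(self, "normalized", normalized)

    @property
    def S(self) -> int:
        return len(self.probs)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.probs, dtype=float)


@dataclass(frozen=True)
class EntropyEstimate:
    """A Shannon-index estimate: point value, variance, provenance.

    ``method`` is one of ``plugin`` (H at p̂), ``corrected`` (delta-method
    bias-corrected mean) or ``bayes`` (posterior mean via MCMC).
    ``variance`` is ``None`` when the method reports a point only.
    """

    point: float
    variance: float | None
    method: str
    base: float
    n_used: int
    label: str | None = field(default=None, compare=False)

    def __post_init__(self):
        if self.method not in ("plugin", "corrected", "bayes"):
            raise InvalidInputError(f"unknown method {self.method!r}")
        if self.variance is not None and self.variance < 0:
            raise InvalidInputError("variance must be non-negative")

    @property
    def se(self) -> float | None:
        return None if self.variance is None else math.sqrt(self.variance)

    def to_record(self, stratum: str | None = None, S: int | None = None) -> dict:
        return {
            "stratum": stratum if stratum is not None else self.label,
            "method": self.method,
            "base": base_label(self.base),
            "point": self.point,
            "variance": self.variance,
            "n": self.n_used,
            "S": S,
        }
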