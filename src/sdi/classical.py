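"""Classical (frequentist) estimation of Shannon's diversity index.

For counts ``x_1..x_S`` with divisor ``n`` and MLE abundances
``p̂_i = x_i / n``, the index in log base ``b`` is

    H(p̂) = -Σ p̂_i log_b p̂_i                                (plug-in)

with the delta-method bias-corrected mean and variance

    Ĥ    = H(p̂) - Σ p̂_i (1 - p̂_i) / (2n)
    V(Ĥ) = (1/n) Σ p̂_i (1 - p̂_i) { [1 + log_b(n p̂_i)]² + (log_b n)² }

Two conventions are deliberate and load-bearing: the additive bias
correction uses the raw factor ``(1 - p̂)/(2n)`` in *natural* units (it
is not rescaled by ``ln b``), and the variance uses the chosen base in
both log factors.  Zero counts contribute nothing anywhere
(``0·log 0 := 0`` and ``p̂(1-p̂) = 0``) but still count toward S.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np

from .counts import AbundanceVector, CountVector, EntropyEstimate, resolve_base
from .errors import InvalidInputError

__all__ = [
    "mle_probs",
    "shannon_index",
    "plugin_entropy",
    "corrected_entropy",
    "entropy_variance",
    "delta_mean_xlogx",
    "delta_var_xlogx",
]


def mle_probs(counts: CountVector) -> AbundanceVector:
    """Maximum-likelihood abundances p̂_i = x_i / n.

    The result carries ``normalized=True`` only when ``n`` equals the
    vector total (the multinomial reading); under the binomial design
    with ``n > sum(x)`` the p̂ need not sum to one.
    """
    probs = [x / counts.n for x in counts.counts]
    return AbundanceVector(probs, normalized=(counts.n == counts.total))


def shannon_index(p: Sequence[float] | AbundanceVector | np.ndarray,
                  base=2) -> float:
    """H(p) = -Σ p_i log_b p_i with 0·log 0 := 0.

    Accepts any probability-like vector; the simplex constraint is not
    required (the Bayesian draws are unconstrained).
    """
    b = resolve_base(base)
    arr = p.as_array() if isinstance(p, AbundanceVector) else np.asarray(p, dtype=float)
    pos = arr[arr > 0]
    return float(-(pos * (np.log(pos) / math.log(b))).sum())


def plugin_entropy(counts: CountVector, base=2) -> EntropyEstimate:
    """Plug-in Shannon index H(p̂); point estimate only."""
    b = resolve_base(base)
    return EntropyEstimate(point=shannon_index(mle_probs(counts), b),
                           variance=None, method="plugin", base=b,
                           n_used=counts.n)


def corrected_entropy(counts: CountVector, base=2) -> EntropyEstimate:
    """Delta-method mean of H: plug-in minus Σ p̂(1-p̂)/(2n).

    The correction term is a pure number (not divided by ln base); see
    the module docstring.
    """
    b = resolve_base(base)
    n = counts.n
    phat = mle_probs(counts).as_array()
    correction = float((phat * (1.0 - phat)).sum() / (2.0 * n))
    return EntropyEstimate(point=shannon_index(phat, b) - correction,
                           variance=None, method="corrected", base=b,
                           n_used=n)


def entropy_variance(counts: CountVector, base=2) -> float:
    """Delta-method variance of the plug-in index.

    (1/n) Σ_{x_i>0} p̂(1-p̂){[1 + log_b x_i]² + (log_b n)²}; note
    n·p̂_i = x_i.  Terms with x_i = 0 vanish identically.
    """
    b = resolve_base(base)
    n = counts.n
    logb = math.log(b)
    x = counts.as_array()
    phat = x / n
    mask = x > 0
    if not mask.any():  # unreachable: CountVector requires a positive count
        return 0.0
    lx = np.log(x[mask]) / logb
    ln_n = math.log(n) / logb
    terms = phat[mask] * (1.0 - phat[mask]) * ((1.0 + lx) ** 2 + ln_n ** 2)
    return float(terms.sum() / n)


def delta_mean_xlogx(n: int, p: float) -> float:
    """Second-order delta-method mean of X ln X, X ~ Binomial(n, p).

    E[X ln X] ≈ np·ln(np) + (1-p)/2 (natural log).  Returns 0 at p = 0.
    """
    _check_np(n, p)
    if p == 0.0:
        return 0.0
    return n * p * math.log(n * p) + (1.0 - p) / 2.0


def delta_var_xlogx(n: int, p: float) -> float:
    """First-order delta-method variance of X ln X, X ~ Binomial(n, p).

    V[X ln X] ≈ [1 + ln(np)]²·np(1-p); zero at p in {0, 1}.
    """
    _check_np(n, p)
    if p in (0.0, 1.0):
        return 0.0
    return (1.0 + math.log(n * p)) ** 2 * n * p * (1.0 - p)


def _check_np(n: int, p: float) -> None:
    if n < 1:
        raise InvalidInputError(f"n must be >= 1, got {n}")
    if not (0.0 <= p <= 1.0):
        raise InvalidInputError(f"p must lie in [0, 1], got {p}")
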