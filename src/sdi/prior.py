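"""The probability-matching prior for Shannon's index and its posterior.

For independent ``X_i ~ Binomial(n, p_i)`` the prior that makes one-sided
posterior credible limits for ``H(p) = -Σ p_i ln p_i`` agree with their
frequentist coverage to first order is

    q(p) ∝ { Σ_i (1 + ln p_i)² p_i(1-p_i) }^{1/2}
           · Π_i [ p_i(1-p_i) |1 + ln p_i| ]^{-1},   0 < p_i < 1.

It follows from the matching condition Σ_i ∂/∂p_i [φ_i(p) q(p)] = 0,
where φ = D_H I^{-1} / sqrt(D_H I^{-1} D_H^T) is the Fisher-normalized
entropy gradient; :func:`matching_condition_residual` certifies that
identity numerically.  The derivation fixes natural logarithms inside
the prior regardless of the base used to report H.

Two numerical realities of this density are handled by
:class:`PriorGuard`: it is singular on the hyperplanes ``p_i = e^{-1}``
(where ``1 + ln p_i = 0``) and at the cube boundary, and for S >= 2 the
hyperplane singularity is non-integrable.  For sampling the factor
``|1 + ln p_i|`` is floored and the support is shrunk slightly away from
the boundary; the matching-condition check disables the floor and avoids
the hyperplanes instead.  The per-orthant sign of ``Π (1 + ln p_i)`` is
dropped (a density must be non-negative); the matching condition is
unaffected because each product ``φ_i q`` stays locally constant in
``p_i`` in every orthant.

The posterior is ``h(p | x) ∝ L(p | x) q(p)`` with the independent
binomial likelihood ``L = Π p_i^{x_i} (1-p_i)^{n-x_i}``.  No simplex
constraint is imposed: the prior, the posterior and the numerical-study
design all treat the ``p_i`` as free coordinates in ``(0, 1)^S``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .counts import AbundanceVector, CountVector
from .errors import BoundaryError, DegenerateInputError, InvalidInputError

__all__ = [
    "PriorGuard",
    "PosteriorTarget",
    "log_prior",
    "prior_density",
    "log_posterior",
    "fisher_inverse_diag",
    "entropy_gradient",
    "phi_vector",
    "matching_condition_residual",
]


@dataclass(frozen=True)
class PriorGuard:
    """Numerical guards for the matching prior.

    eps_boundary
        The density is treated as zero within this distance of 0 and 1
        (the prior diverges like 1/p at the edges; with zero counts the
        posterior inherits a non-integrable 1/p there too).
    eps_singularity
        Floor applied to |1 + ln p_i| so the target stays bounded on the
        hyperplanes p_i = e^{-1}.
    """

    eps_boundary: float = 1e-4
    eps_singularity: float = 1e-8

    def __post_init__(self):
        for name in ("eps_boundary", "eps_singularity"):
            v = getattr(self, name)
            if not (0.0 < v <= 1e-3):
                raise InvalidInputError(f"{name} must lie in (0, 1e-3], got {v}")
        if self.eps_boundary >= 0.5:
            raise InvalidInputError("eps_boundary must be < 0.5")


def _as_prob_array(p: Sequence[float] | AbundanceVector | np.ndarray) -> np.ndarray:
    arr = p.as_array() if isinstance(p, AbundanceVector) else np.asarray(p, dtype=float)
    if arr.ndim != 1 or arr.size == 0:
        raise InvalidInputError("p must be a non-empty 1-d probability vector")
    if np.any(arr < 0.0) or np.any(arr > 1.0) or np.any(np.isnan(arr)):
        raise InvalidInputError(f"probabilities outside [0, 1]: {arr}")
    return arr


def log_prior(p, guard: PriorGuard | None = None) -> float:
    """Log of the unnormalized matching-prior density (natural logs).

    Returns -inf outside the guarded open cube
    ``(eps_boundary, 1 - eps_boundary)^S``.
    """
    guard = guard or PriorGuard()
    arr = _as_prob_array(p)
    if np.any(arr <= guard.eps_boundary) or np.any(arr >= 1.0 - guard.eps_boundary):
        return -math.inf
    lp = np.log(arr)
    t = 1.0 + lp                        # gamma_i = -t_i
    pq = arr * (1.0 - arr)
    sum_term = float((t * t * pq).sum())
    floor = np.maximum(np.abs(t), guard.eps_singularity)
    return 0.5 * math.log(sum_term) - float(np.log(pq).sum() + np.log(floor).sum())


def prior_density(p, eps_singularity: float = 0.0) -> float:
    """Unnormalized q(p) evaluated directly (no boundary guard).

    With ``eps_singularity=0`` this is the exact density used in the
    matching-condition check; it diverges on p_i = e^{-1}.
    """
    arr = _as_prob_array(p)
    if np.any(arr <= 0.0) or np.any(arr >= 1.0):
        raise InvalidInputError("prior density requires interior p")
    t = 1.0 + np.log(arr)
    pq = arr * (1.0 - arr)
    denom = pq * np.maximum(np.abs(t), eps_singularity)
    return math.sqrt(float((t * t * pq).sum())) / float(np.prod(denom))


@dataclass(frozen=True)
class PosteriorTarget:
    """Unnormalized log posterior log L(p|x) + log q(p) for MH sampling."""

    counts: CountVector
    guard: PriorGuard = PriorGuard()

    @property
    def dim(self) -> int:
        return self.counts.S

    def log_likelihood(self, p) -> float:
        arr = _as_prob_array(p)
        if arr.size != self.dim:
            raise InvalidInputError(
                f"p has {arr.size} coordinates, counts have {self.dim}")
        if np.any(arr <= 0.0) or np.any(arr >= 1.0):
            return -math.inf
        x = self.counts.as_array()
        n = self.counts.n
        return float((x * np.log(arr) + (n - x) * np.log1p(-arr)).sum())

    def log_density(self, p) -> float:
        lp = log_prior(p, self.guard)
        if lp == -math.inf:
            return -math.inf
        return self.log_likelihood(p) + lp

    # -- incremental interface used by the component-wise sampler --------
    # log h(p) =  Σ_i ll_i  +  0.5 ln(Σ_i a_i)  -  Σ_i d_i   within the
    # guard box, where for coordinate value v:
    #   ll_i = x_i ln v + (n - x_i) ln(1 - v)
    #   a_i  = (1 + ln v)^2 v(1 - v)
    #   d_i  = ln[v(1 - v)] + ln max(|1 + ln v|, eps_singularity)
    def coord_terms(self, i: int, v: float) -> tuple[float, float, float] | None:
        """Per-coordinate terms (ll, a, d), or None outside the guard box."""
        g = self.guard
        if not (g.eps_boundary < v < 1.0 - g.eps_boundary):
            return None
        lv = math.log(v)
        l1m = math.log1p(-v)
        t = 1.0 + lv
        pq = v * (1.0 - v)
        x = self.counts.counts[i]
        ll = x * lv + (self.counts.n - x) * l1m
        a = t * t * pq
        d = math.log(pq) + math.log(max(abs(t), g.eps_singularity))
        return ll, a, d


def log_posterior(p, target: PosteriorTarget) -> float:
    """Convenience wrapper: unnormalized log h(p | x)."""
    return target.log_density(p)


def fisher_inverse_diag(p, n: int) -> np.ndarray:
    """Diagonal of the inverse Fisher information: λ_i = p_i(1-p_i)/n."""
    arr = _as_prob_array(p)
    if n < 1:
        raise InvalidInputError(f"n must be >= 1, got {n}")
    if np.any(arr <= 0.0) or np.any(arr >= 1.0):
        raise BoundaryError("Fisher information inverse requires p in (0, 1)")
    return arr * (1.0 - arr) / n


def entropy_gradient(p) -> np.ndarray:
    """Gradient of H(p) = -Σ p ln p: γ_i = -(ln p_i + 1)."""
    arr = _as_prob_array(p)
    if np.any(arr <= 0.0):
        raise BoundaryError("entropy gradient requires p > 0")
    return -(np.log(arr) + 1.0)


def phi_vector(p, n: int) -> np.ndarray:
    """Fisher-normalized entropy gradient φ_i = γ_i λ_i / sqrt(Σ γ²λ).

    Satisfies Σ φ_i² / λ_i = 1 (i.e. φᵀ I φ = 1).  Degenerate when every
    p_i = e^{-1} (zero gradient).
    """
    gamma = entropy_gradient(p)
    lam = fisher_inverse_diag(p, n)
    norm_sq = float((gamma * gamma * lam).sum())
    if norm_sq == 0.0:
        raise DegenerateInputError(
            "entropy gradient vanishes (all p_i = 1/e); phi is undefined")
    return gamma * lam / math.sqrt(norm_sq)


_E_INV = math.exp(-1.0)


def matching_condition_residual(
    p,
    n: int,
    h: float = 1e-5,
    prior: Callable[[np.ndarray], float] | None = None,
    normalized: bool = True,
) -> float:
    """Central-difference check of Σ_i ∂/∂p_i [φ_i(p) q(p)] = 0.

    ``prior`` is a density q (not its log); defaults to the exact
    matching prior with the singularity floor disabled.  With
    ``normalized=True`` (default) the residual is divided by
    ``max_i |φ_i q|`` at p, which is the scale-free quantity the
    matching contract bounds (<= 1e-4 for the true prior; a perturbed,
    non-matching prior fails at > 1e-2).
    """
    arr = _as_prob_array(p)
    if not (1e-7 <= h <= 1e-4):
        raise InvalidInputError(f"step h must lie in [1e-7, 1e-4], got {h}")
    if np.any(arr <= 10 * h) or np.any(arr >= 1.0 - 10 * h):
        raise InvalidInputError("p too close to the boundary for the step size")
    if np.any(np.abs(arr - _E_INV) <= 10 * h):
        raise InvalidInputError(
            "p too close to the singular hyperplane p_i = 1/e")
    q = prior if prior is not None else (lambda v: prior_density(v, 0.0))

    def phi_q(v: np.ndarray) -> np.ndarray:
        return phi_vector(v, n) * q(v)

    residual = 0.0
    for i in range(arr.size):
        up = arr.copy()
        dn = arr.copy()
        up[i] += h
        dn[i] -= h
        residual += (phi_q(up)[i] - phi_q(dn)[i]) / (2.0 * h)
    if not normalized:
        return residual
    scale = float(np.max(np.abs(phi_q(arr))))
    return residual / scale
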