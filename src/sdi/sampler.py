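"""Component-wise Metropolis–Hastings sampling of the SDI posterior.

The chain initializes every coordinate from Uniform(0,1) and then sweeps
the coordinates i = 1..S in turn, proposing a new value for one
coordinate at a time while evaluating the *full joint* target in the
acceptance ratio (the sqrt-sum factor of the matching prior couples the
coordinates, so a per-coordinate density does not factorize).  Two
proposals are available:

``uniform``
    Independent Uniform(0,1) proposals.  The proposal density cancels
    from the Metropolis–Hastings ratio, which reduces to the target
    ratio.  This is the default and the closest reading of a sampler
    built from Uniform(0,1) draws.
``rw``
    Reflected random walk of half-width ``rw_width``; symmetric, so the
    ratio again reduces to the target ratio.

Posterior summaries of H(p) are the empirical mean and (population)
variance of H computed on each retained draw, without renormalizing the
draw — the posterior lives on the open cube, not the simplex.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .counts import EntropyEstimate, resolve_base
from .errors import InvalidInputError, SamplerFailureError
from .prior import PosteriorTarget

__all__ = [
    "MCMCConfig",
    "Chain",
    "FunctionTarget",
    "sample_posterior",
    "posterior_entropy",
    "diagnostics",
]

_MAX_INIT_TRIES = 1000
_CHUNK = 8192


@dataclass(frozen=True)
class MCMCConfig:
    """Sampler settings.

    Defaults mirror the full-scale runs (N = 500,000 retained draws
    after a 10,000-sweep burn-in); tests and the simulation harness use
    scaled-down N with fixed seeds.
    """

    n_samples: int = 500_000
    burn_in: int = 10_000
    seed: int = 0
    proposal: str = "uniform"
    rw_width: float = 0.1
    thin: int = 1

    def __post_init__(self):
        if self.n_samples < 1:
            raise InvalidInputError("n_samples must be >= 1")
        if self.burn_in < 0:
            raise InvalidInputError("burn_in must be >= 0")
        if self.thin < 1:
            raise InvalidInputError("thin must be >= 1")
        if self.proposal not in ("uniform", "rw"):
            raise InvalidInputError(f"unknown proposal {self.proposal!r}")
        if self.proposal == "rw" and not (0.0 < self.rw_width <= 0.5):
            raise InvalidInputError("rw_width must lie in (0, 0.5]")


@dataclass(frozen=True)
class FunctionTarget:
    """Adapter making any log-density usable by the same MH machinery.

    Used for sampler validation against analytically known targets
    (e.g. Beta densities).
    """

    dim: int
    log_density_fn: Callable[[np.ndarray], float]

    def log_density(self, p) -> float:
        return self.log_density_fn(np.asarray(p, dtype=float))


@dataclass(frozen=True)
class Chain:
    """Retained MCMC draws and per-draw entropies.

    ``h_draws`` holds H(p^(t)) in log base ``base``; ``n_used`` echoes
    the data total when the target carries counts.
    """

    draws: np.ndarray
    h_draws: np.ndarray
    acceptance_rate: float
    config: MCMCConfig
    base: float
    n_used: int | None = None

    def __post_init__(self):
        if len(self.draws) != len(self.h_draws):
            raise InvalidInputError("draws and h_draws lengths differ")
        if not (0.0 < self.acceptance_rate <= 1.0):
            raise InvalidInputError("acceptance_rate must lie in (0, 1]")

    def __len__(self) -> int:
        return len(self.h_draws)

    def to_dataframe(self) -> pd.DataFrame:
        """Chain as a tidy frame (t, p_1..p_S, H_t) for external diagnostics."""
        S = self.draws.shape[1]
        df = pd.DataFrame(self.draws, columns=[f"p_{i + 1}" for i in range(S)])
        df.insert(0, "t", np.arange(1, len(df) + 1))
        df["H_t"] = self.h_draws
        return df


def sample_posterior(target, config: MCMCConfig, base=2) -> Chain:
    """Run the component-wise MH sampler and return the retained chain.

    ``target`` is a :class:`~sdi.prior.PosteriorTarget` (fast incremental
    path) or any object with ``dim`` and ``log_density`` (generic path).
    Fully reproducible: the same seed, target and config give a
    bit-identical chain.
    """
    b = resolve_base(base)
    S = target.dim
    rng = np.random.default_rng(config.seed)

    incremental = isinstance(target, PosteriorTarget)

    # -- initialization: coordinates from Uniform(0,1), retried until the
    #    joint density is finite ---------------------------------------
    for _ in range(_MAX_INIT_TRIES):
        p = rng.random(S)
        if incremental:
            terms = [target.coord_terms(i, p[i]) for i in range(S)]
            if all(t is not None for t in terms):
                break
        else:
            if math.isfinite(target.log_density(p)):
                break
    else:
        raise SamplerFailureError(
            f"no finite starting point found in {_MAX_INIT_TRIES} tries")

    total_sweeps = config.burn_in + config.n_samples * config.thin
    n_keep = config.n_samples
    draws = np.empty((n_keep, S))
    h_draws = np.empty(n_keep)
    log_b = math.log(b)
    accepted = 0
    kept = 0

    p = list(map(float, p))
    is_rw = config.proposal == "rw"
    w = config.rw_width
    log_ = math.log

    if incremental:
        ll = [t[0] for t in terms]
        a = [t[1] for t in terms]
        d = [t[2] for t in terms]
        A = sum(a)
        coord_terms = target.coord_terms
    else:
        logpost = target.log_density(np.asarray(p))

    sweep = 0
    while sweep < total_sweeps:
        chunk = min(_CHUNK, total_sweeps - sweep)
        u_prop = rng.random((chunk, S))
        u_acc = rng.random((chunk, S))
        for t_ in range(chunk):
            for i in range(S):
                u = u_prop[t_, i]
                if is_rw:
                    cand = p[i] + w * (2.0 * u - 1.0)
                    if cand < 0.0:
                        cand = -cand
                    elif cand > 1.0:
                        cand = 2.0 - cand
                else:
                    cand = u
                if incremental:
                    new = coord_terms(i, cand)
                    if new is None:
                        continue
                    ll_n, a_n, d_n = new
                    A_n = A - a[i] + a_n
                    delta = (ll_n - ll[i]) - (d_n - d[i]) \
                        + 0.5 * (log_(A_n) - log_(A))
                    if delta >= 0.0 or log_(u_acc[t_, i]) < delta:
                        p[i] = cand
                        ll[i], a[i], d[i], A = ll_n, a_n, d_n, A_n
                        accepted += 1
                else:
                    old = p[i]
                    p[i] = cand
                    lp_new = target.log_density(np.asarray(p))
                    delta = lp_new - logpost
                    if delta >= 0.0 or log_(u_acc[t_, i]) < delta:
                        logpost = lp_new
                        accepted += 1
                    else:
                        p[i] = old
            s = sweep + t_
            if s >= config.burn_in and (s - config.burn_in) % config.thin == 0:
                draws[kept] = p
                h = 0.0
                for v in p:
                    if v > 0.0:
                        h -= v * log_(v)
                h_draws[kept] = h / log_b
                kept += 1
        sweep += chunk

    if accepted == 0:
        raise SamplerFailureError("no proposal was ever accepted")
    n_used = target.counts.n if incremental else None
    return Chain(draws=draws, h_draws=h_draws,
                 acceptance_rate=accepted / (total_sweeps * S),
                 config=config, base=b, n_used=n_used)


def posterior_entropy(chain: Chain, base=None) -> EntropyEstimate:
    """Posterior mean and variance of H from the retained draws.

    Mean is (1/N) Σ H^(t); variance is the population second moment
    minus the squared mean.  Draws are used as-is (no renormalization).
    """
    if len(chain) == 0:
        raise InvalidInputError("empty chain")
    b = chain.base if base is None else resolve_base(base)
    if b == chain.base:
        h = chain.h_draws
    else:
        pr = chain.draws
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(pr > 0.0, pr * np.log(pr), 0.0)
        h = -terms.sum(axis=1) / math.log(b)
    mean = float(h.mean())
    var = float((h * h).mean() - mean * mean)
    return EntropyEstimate(point=mean, variance=max(var, 0.0), method="bayes",
                           base=b, n_used=chain.n_used or len(chain))


def diagnostics(chain: Chain) -> dict:
    """Mixing summaries: acceptance rate, lag-1 autocorrelation of the
    H draws, and a batch-means effective sample size.

    Reported for logging only; a degenerate (constant) chain gets
    autocorrelation 0 and ESS 1.
    """
    if len(chain) == 0:
        raise InvalidInputError("empty chain")
    h = chain.h_draws
    n = len(h)
    out = {"acceptance_rate": chain.acceptance_rate,
           "n_samples": n, "lag1_autocorr": 0.0, "ess": 1.0}
    s2 = float(h.var())
    if n < 2 or s2 == 0.0:
        return out
    c = h - h.mean()
    out["lag1_autocorr"] = float((c[:-1] * c[1:]).mean() / s2)
    b = max(int(math.sqrt(n)), 2)
    nb = n // b
    if nb >= 2:
        bm = h[: nb * b].reshape(nb, b).mean(axis=1)
        asymp = b * float(bm.var(ddof=1))
        if asymp > 0.0:
            out["ess"] = float(min(max(n * s2 / asymp, 1.0), n))
        else:
            out["ess"] = float(n)
    return out
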