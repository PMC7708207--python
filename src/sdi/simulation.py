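"""Monte-Carlo comparison of the classical and Bayesian SDI estimators.

The design: true abundances ``p_i`` are drawn independently and
uniformly from a stated range (no simplex constraint — the ranges
(0.6, 0.8) etc. make Σp > 1 routine and intended), counts are simulated
as independent ``Binomial(n, p_i)``, and both estimators are applied to
each replicate.  Cells of the default grid cross
S ∈ {2, 3, 4} × p-range ∈ {(0.1,0.2), (0.3,0.5), (0.6,0.8)} ×
n ∈ {10, 50, 100}.

Replicates in which every simulated count is zero carry no information
about diversity and leave the estimators undefined; the generator
redraws such replicates, i.e. the study conditions on at least one
observed individual (only relevant at the smallest n with the lowest
abundance range, where the all-zero probability is a few percent).

Reproducibility: replicate r of a cell uses seed ``spec.seed + r`` for
both the data draw and its (fresh) MCMC chain; the default grid spaces
cell seeds ``10_000`` apart.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from itertools import product
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import classical
from .counts import AbundanceVector, CountVector, resolve_base
from .errors import InvalidInputError, SamplerFailureError
from .prior import PosteriorTarget, PriorGuard
from .sampler import MCMCConfig, posterior_entropy, sample_posterior

__all__ = [
    "SimulationSpec",
    "SimulationCell",
    "draw_true_p",
    "simulate_counts",
    "run_cell",
    "run_table",
    "default_grid",
]

DEFAULT_P_RANGES = ((0.1, 0.2), (0.3, 0.5), (0.6, 0.8))
DEFAULT_S_VALUES = (2, 3, 4)
DEFAULT_N_VALUES = (10, 50, 100)

_MAX_REDRAWS = 1000


@dataclass(frozen=True)
class SimulationSpec:
    """One (S, p-range, n) cell of the comparison grid."""

    S: int
    p_range: tuple[float, float]
    n: int
    reps: int = 100
    mcmc: MCMCConfig = MCMCConfig(n_samples=20_000, burn_in=2_000)
    base: float = 2.0
    seed: int = 0
    classical_estimator: str = "corrected"

    def __post_init__(self):
        a, b = self.p_range
        if not (0.0 < a < b < 1.0):
            raise InvalidInputError(f"p_range must satisfy 0 < a < b < 1, got {self.p_range}")
        if self.S < 1 or self.n < 2 or self.reps < 1:
            raise InvalidInputError("need S >= 1, n >= 2, reps >= 1")
        if self.classical_estimator not in ("corrected", "plugin"):
            raise InvalidInputError(
                f"unknown classical estimator {self.classical_estimator!r}")
        object.__setattr__(self, "base", resolve_base(self.base))


@dataclass(frozen=True)
class SimulationCell:
    """Across-replicate averages for one cell."""

    mean_classical: float
    mean_bayes: float
    var_classical: float
    var_bayes: float
    reps_used: int
    spec: SimulationSpec

    def __post_init__(self):
        if self.var_classical < 0 or self.var_bayes < 0:
            raise InvalidInputError("variances must be non-negative")


def draw_true_p(spec: SimulationSpec, rng: np.random.Generator) -> AbundanceVector:
    """Independent Uniform(a, b) abundances; not simplex-normalized."""
    a, b = spec.p_range
    return AbundanceVector(rng.uniform(a, b, size=spec.S), normalized=False)


def simulate_counts(p: AbundanceVector | Sequence[float], n: int,
                    rng: np.random.Generator) -> CountVector:
    """Independent Binomial(n, p_i) counts; ``n`` (the binomial size, the
    estimator's divisor in this design) is recorded as the vector total.

    Redraws the rare all-zero outcome (see module docstring).
    """
    arr = p.as_array() if isinstance(p, AbundanceVector) else np.asarray(p, dtype=float)
    if np.any(arr <= 0.0) or np.any(arr >= 1.0):
        raise InvalidInputError("simulate_counts requires p in (0, 1)")
    for _ in range(_MAX_REDRAWS):
        x = rng.binomial(n, arr)
        if x.any():
            return CountVector(x.tolist(), n=n)
    raise SamplerFailureError("could not draw a non-empty count vector")


def run_cell(spec: SimulationSpec, guard: PriorGuard | None = None) -> SimulationCell:
    """Run one grid cell: per replicate, draw p, simulate counts, apply
    both estimators (fresh MH chain each time), then average."""
    guard = guard or PriorGuard()
    point_fn = (classical.corrected_entropy if spec.classical_estimator == "corrected"
                else classical.plugin_entropy)
    h_c, h_b, v_c, v_b = [], [], [], []
    for rep in range(spec.reps):
        rep_seed = spec.seed + rep
        rng = np.random.default_rng(rep_seed)
        p = draw_true_p(spec, rng)
        counts = simulate_counts(p, spec.n, rng)
        h_c.append(point_fn(counts, spec.base).point)
        v_c.append(classical.entropy_variance(counts, spec.base))
        chain = sample_posterior(PosteriorTarget(counts, guard),
                                 replace(spec.mcmc, seed=rep_seed),
                                 base=spec.base)
        post = posterior_entropy(chain)
        h_b.append(post.point)
        v_b.append(post.variance)
    return SimulationCell(
        mean_classical=float(np.mean(h_c)), mean_bayes=float(np.mean(h_b)),
        var_classical=float(np.mean(v_c)), var_bayes=float(np.mean(v_b)),
        reps_used=spec.reps, spec=spec)


def run_table(grid: Iterable[SimulationSpec],
              guard: PriorGuard | None = None) -> pd.DataFrame:
    """Evaluate every cell and return the comparison table.

    Columns mirror the report layout: S, p-range, n, then the average
    classical/Bayesian estimates and variances.
    """
    grid = list(grid)
    if not grid:
        raise InvalidInputError("empty simulation grid")
    rows = []
    for spec in grid:
        cell = run_cell(spec, guard)
        rows.append({
            "S": spec.S, "p_low": spec.p_range[0], "p_high": spec.p_range[1],
            "n": spec.n, "reps": cell.reps_used,
            "H_classical": cell.mean_classical, "H_bayes": cell.mean_bayes,
            "V_classical": cell.var_classical, "V_bayes": cell.var_bayes,
        })
    return pd.DataFrame(rows)


def default_grid(reps: int = 100,
                 mcmc: MCMCConfig | None = None,
                 base=2,
                 seed: int = 0,
                 S_values: Sequence[int] = DEFAULT_S_VALUES,
                 p_ranges: Sequence[tuple[float, float]] = DEFAULT_P_RANGES,
                 n_values: Sequence[int] = DEFAULT_N_VALUES) -> list[SimulationSpec]:
    """The study grid, one spec per (S, p-range, n) combination."""
    mcmc = mcmc or MCMCConfig(n_samples=20_000, burn_in=2_000)
    specs = []
    for idx, (S, pr, n) in enumerate(product(S_values, p_ranges, n_values)):
        specs.append(SimulationSpec(S=S, p_range=tuple(pr), n=n, reps=reps,
                                    mcmc=mcmc, base=base,
                                    seed=seed + 10_000 * idx))
    return specs
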