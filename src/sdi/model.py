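"""Model/Results front end.

:class:`ShannonDiversityModel` wraps one count vector; ``fit()`` returns
a results object carrying the point estimate, its variance, and a
``summary()`` table — classical (delta-method) or Bayesian
(matching-prior posterior via MCMC) depending on ``method``.

    >>> from sdi import ShannonDiversityModel
    >>> res = ShannonDiversityModel([2, 2, 3]).fit()
    >>> round(res.point, 2), round(res.variance, 4)
    (1.51, 1.2023)
"""

from __future__ import annotations

import math
from typing import Sequence

from . import classical
from .counts import CountVector, EntropyEstimate, base_label, resolve_base
from .errors import InvalidInputError
from .prior import PosteriorTarget, PriorGuard
from .sampler import Chain, MCMCConfig, diagnostics, posterior_entropy, sample_posterior
from .tables import CountTable

__all__ = ["ShannonDiversityModel", "ClassicalSDIResults", "BayesianSDIResults"]


class ShannonDiversityModel:
    """Shannon diversity of one stratum's category counts.

    Parameters
    ----------
    counts
        A :class:`~sdi.counts.CountVector` or a plain sequence of
        non-negative integers.
    base
        Log base for reporting H (2, 'e' or 10; default 2).
    label
        Optional stratum name carried into results and summaries.
    """

    def __init__(self, counts: CountVector | Sequence[int], base=2,
                 label: str | None = None):
        if not isinstance(counts, CountVector):
            counts = CountVector(counts)
        self.counts = counts
        self.base = resolve_base(base)
        self.label = label

    @classmethod
    def from_table(cls, table: CountTable, stratum: str | None = None,
                   category: str | None = None, base=2) -> "ShannonDiversityModel":
        """Build a model from one row (stratum) or one column (category)."""
        if (stratum is None) == (category is None):
            raise InvalidInputError("give exactly one of stratum or category")
        if stratum is not None:
            return cls(table.row_vector(stratum), base=base, label=stratum)
        return cls(table.col_vector(category), base=base, label=category)

    @classmethod
    def from_dataframe(cls, df, stratum: str, base=2) -> "ShannonDiversityModel":
        """Build from a pandas DataFrame shaped strata × categories."""
        return cls.from_table(CountTable(df.astype(int)), stratum=stratum, base=base)

    @property
    def nobs(self) -> int:
        return self.counts.n

    @property
    def S(self) -> int:
        return self.counts.S

    def fit(self, method: str = "classical", mcmc: MCMCConfig | None = None,
            guard: PriorGuard | None = None):
        """Estimate H.

        ``method='classical'`` (default) returns the delta-method
        bias-corrected estimate with its variance; ``'plugin'`` the raw
        plug-in point; ``'bayes'`` runs the MH sampler on the
        matching-prior posterior (``mcmc`` settings, ``guard`` numerical
        guards).
        """
        if method in ("classical", "plugin"):
            est = (classical.corrected_entropy if method == "classical"
                   else classical.plugin_entropy)(self.counts, self.base)
            var = classical.entropy_variance(self.counts, self.base)
            return ClassicalSDIResults(self, est, var)
        if method == "bayes":
            target = PosteriorTarget(self.counts, guard or PriorGuard())
            chain = sample_posterior(target, mcmc or MCMCConfig(), base=self.base)
            return BayesianSDIResults(self, chain)
        raise InvalidInputError(f"unknown method {method!r}")


class _BaseResults:
    """Shared surface: point, variance, se, summary()."""

    model: ShannonDiversityModel
    estimate: EntropyEstimate

    @property
    def point(self) -> float:
        return self.estimate.point

    @property
    def variance(self) -> float | None:
        return self.estimate.variance

    @property
    def se(self) -> float | None:
        return self.estimate.se

    @property
    def method(self) -> str:
        return self.estimate.method

    def _rows(self) -> list[tuple[str, str]]:
        m = self.model
        rows = [
            ("Stratum", m.label or "-"),
            ("Categories (S)", str(m.S)),
            ("Sample size (n)", str(m.nobs)),
            ("Log base", base_label(m.base)),
            ("Method", self.method),
            ("H estimate", f"{self.point:.4f}"),
        ]
        if self.variance is not None:
            rows += [("Variance", f"{self.variance:.4f}"),
                     ("Std. error", f"{self.se:.4f}")]
        return rows

    def summary(self) -> str:
        rows = self._rows()
        width = max(len(k) for k, _ in rows)
        lines = ["Shannon Diversity Index", "=" * 38]
        lines += [f"{k:<{width}}  {v}" for k, v in rows]
        lines.append("=" * 38)
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        v = "None" if self.variance is None else f"{self.variance:.4g}"
        return (f"<{type(self).__name__} H={self.point:.4f} "
                f"var={v} method={self.method}>")


class ClassicalSDIResults(_BaseResults):
    """Delta-method results: bias-corrected (or plug-in) H and variance."""

    def __init__(self, model: ShannonDiversityModel, estimate: EntropyEstimate,
                 variance: float):
        self.model = model
        self.estimate = EntropyEstimate(
            point=estimate.point, variance=variance, method=estimate.method,
            base=estimate.base, n_used=estimate.n_used, label=model.label)
        self.plugin = classical.plugin_entropy(model.counts, model.base).point

    @property
    def bias_correction(self) -> float:
        """Σ p̂(1-p̂)/(2n), the amount subtracted from the plug-in value."""
        return self.plugin - self.point if self.method == "corrected" else 0.0


class BayesianSDIResults(_BaseResults):
    """Posterior results: mean/variance of H over the retained chain."""

    def __init__(self, model: ShannonDiversityModel, chain: Chain):
        self.model = model
        self.chain = chain
        est = posterior_entropy(chain)
        self.estimate = EntropyEstimate(
            point=est.point, variance=est.variance, method="bayes",
            base=est.base, n_used=model.nobs, label=model.label)
        self.diagnostics = diagnostics(chain)

    def _rows(self):
        rows = super()._rows()
        d = self.diagnostics
        rows += [
            ("MCMC draws (N)", str(len(self.chain))),
            ("Burn-in", str(self.chain.config.burn_in)),
            ("Seed", str(self.chain.config.seed)),
            ("Acceptance rate", f"{d['acceptance_rate']:.3f}"),
            ("ESS (batch means)", f"{d['ess']:.0f}"),
        ]
        return rows
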