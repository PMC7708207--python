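# Methods

## Estimands and data model

A stratum has `S` categories with abundance probabilities
`p = (p_1, …, p_S)` and observed counts `x_i`, modelled as independent
`Binomial(n, p_i)`.  The quantity of interest is Shannon's diversity
index `H(p) = -Σ p_i log_b p_i`, reported in a user-chosen log base
(default 2).  Two divisor conventions coexist and are both supported by
`CountVector`:

* **survey tables** — `n` is the slice total `Σ x_i`, so `p̂` lies on
  the simplex (a district row uses its row total; an age-class column
  uses its column total);
* **binomial design** — `n` is the common binomial size, `p̂_i = x_i/n`
  need not sum to one.  This is the convention of the simulation study.

## Classical estimator

The plug-in index is evaluated at `p̂_i = x_i/n`, with `0·log 0 := 0` so
zero-count categories are retained in `S` but contribute nothing.  The
delta-method expansion of `g(X) = X ln X` about `E X = np` gives

* mean of `X ln X`:  `np·ln(np) + (1-p)/2`,
* variance of `X ln X`:  `[1 + ln(np)]² np(1-p)`,

from which the bias-corrected mean and the variance of `H(p̂)` in the
README follow.  Two conventions are fixed deliberately:

1. the additive bias correction `Σ p̂(1-p̂)/(2n)` is a pure number and is
   **not** rescaled when `H` is reported in base 2 or 10;
2. the variance uses the chosen base in **both** log factors,
   `[1 + log_b x_i]²` and `(log_b n)²`.

These choices reproduce the published classical analysis of the bundled
Delhi table cell-for-cell at printed precision (one cell of that table,
East Delhi's mean, prints 1.56 where the formula gives 1.5546; the
discrepancy is documented in the acceptance test and left as is — no
alternative convention was chased to force a match).

## The matching prior

The prior `q(p)` in the README is the solution of the first-order
probability-matching condition for the scalar functional `H(p)`:
`Σ_i ∂/∂p_i [φ_i(p) q(p)] = 0` with
`φ = D_H I⁻¹ / (D_H I⁻¹ D_Hᵀ)^{1/2}`, where `D_H` has entries
`γ_i = -(ln p_i + 1)` and `I⁻¹ = diag(p_i(1-p_i)/n)`.  The package does
not re-derive the prior; it certifies the condition numerically:
`matching_condition_residual` forms the central-difference divergence of
`φ q` and checks it vanishes (relative to `max_i |φ_i q|`, tolerance
1e-4, step `h = 1e-5`) on interior points, while a perturbed prior
`q·p_1` fails by orders of magnitude.  The identity holds per orthant of
the signs of `(1 + ln p_i)`, which is why the implementation may take
`|1 + ln p_i|` (a density must be non-negative) without disturbing it.

Three properties of `q` demand engineering care:

* **hyperplane singularity** — `q` diverges like `1/|1 + ln p_i|` on
  `p_i = e^{-1}`, and for `S ≥ 2` that divergence is non-integrable.
  For sampling, `|1 + ln p_i|` is floored at `eps_singularity`
  (default 1e-8) so the target is bounded; the matching-condition check
  runs with the floor disabled and keeps `10h` away from the
  hyperplanes.
* **boundary divergence** — the factors `[p(1-p)]^{-1}` (and, with a
  zero count, the posterior's `p^{x-1}`) are non-integrable at 0 and 1;
  the support is shrunk to `(eps_boundary, 1-eps_boundary)`
  (default 1e-4), outside which the log-density is `-inf`.
* **no simplex constraint** — the prior, posterior and simulation
  design treat the `p_i` as free coordinates of `(0,1)^S`.  Posterior
  draws are therefore not renormalized, and posterior means of `H` may
  exceed `log_b S`.

Natural logarithms are used throughout the prior (the derivation fixes
them via `γ`); the report base enters only when summarizing `H`.

## Sampler

Component-wise Metropolis–Hastings: each sweep updates coordinates
`i = 1..S` in turn, evaluating the full joint density in the acceptance
ratio (the sqrt-sum factor couples coordinates, so no per-coordinate
factorization exists).  The default proposal is independent
Uniform(0,1) per coordinate — the proposal density then cancels from
the ratio — with a reflected random-walk alternative (`rw_width`,
symmetric) for concentrated posteriors.  Initial states are drawn
coordinate-wise from Uniform(0,1) and redrawn (up to 1000 times) until
the target is finite.  Full-scale defaults are N = 500,000 retained
draws after a 10,000-sweep burn-in; the test suite and simulation
harness run N = 20,000–50,000 with burn-in 2,000–5,000, sizes at which
the batch-means effective sample size is already in the hundreds to
thousands for every bundled analysis.  Chains are bit-reproducible
given (target, config, seed); the `PosteriorTarget` fast path updates
per-coordinate terms incrementally and is tested to agree exactly with
a full-density evaluation of the same chain.

Posterior summaries are the empirical mean of `H(p^(t))` and its
population variance over retained draws.  Diagnostics (acceptance rate,
lag-1 autocorrelation, batch-means ESS) are reported, never asserted; a
degenerate constant chain reports ESS 1.

The sampler core is validated against closed-form oracles (Beta(2,2)
moments through the same machinery, large-count concentration at the
plug-in estimate) rather than against itself.

## Simulation harness

Each cell of the comparison grid draws `p_i ~ Uniform(a, b)`
independently (ranges (0.1,0.2), (0.3,0.5), (0.6,0.8); S ∈ {2,3,4};
n ∈ {10,50,100}), simulates binomial counts, and applies both
estimators, averaging over replicates.  Replicate `r` of a cell seeds
both its data draw and its fresh MCMC chain with `spec.seed + r`; the
default grid spaces cell seeds 10,000 apart.  The all-zero count vector
(probability a few percent only at n = 10 with the (0.1, 0.2) range) is
redrawn, i.e. the study conditions on observing at least one
individual, since neither estimator is defined on an empty sample.

The generator emulates the independent-binomial design exactly; it does
not emulate features of real survey data — chain-referral recruitment,
cluster correlation between categories, overdispersion, or
simplex-constrained compositions.  Passing tests therefore demonstrate
correctness of the estimators under the stated design, not robustness
of the index to survey artefacts.

The harness reproduces the design's two qualitative findings at reduced
scale (50 replicates, N = 20,000): the Bayesian posterior variance is
smaller than the delta-method variance in essentially every cell, and
the gap between the two point estimates shrinks as n grows.  Printed
cell values from any particular larger run are not targets; replicate
noise at 50 reps is a few percent of the cell means.

## Known limitations and open choices

* The proposal distribution is a genuine free choice; posterior *point*
  summaries are insensitive to it at stationarity, but poorly mixed
  chains (tiny `rw_width`, short runs) can report inflated entropy
  because the Uniform(0,1)^S initial law has higher entropy than most
  posteriors.  The bundled analyses assert stationary-chain properties
  (orderings, variance dominance) rather than sampler-dependent digits.
  For the Delhi age-class columns the stationary posterior means track
  the classical ordering (11-14 highest); previously published Bayesian
  values for those columns are far above the classical estimates in the
  way an under-converged chain would be, and a per-coordinate
  quadrature of the posterior agrees with our sampler, so the package
  reports the stationary answer.
* The floored singularity means a chain can in principle visit the
  `e^{-1}` spike and linger; with the default floor (1e-8) and the
  run lengths used here the entry probability per chain is ~1e-4, and
  no bundled seed exhibits it.  Raising `eps_singularity` trades
  fidelity to the stated prior for robustness.
* The matching property is first-order and derived under the
  independent-binomial model; nothing is claimed for multinomial
  (simplex-constrained) sampling.
* `delta_mean_xlogx`/`delta_var_xlogx` are second/first-order
  approximations; their Monte-Carlo validation at n = 1000, p = 0.3
  bounds the relative error at a few percent, but accuracy degrades for
  `np` near 0 where `X ln X` is strongly skewed.
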