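# sdi — Shannon diversity estimation for count data

`sdi` estimates Shannon's diversity index (SDI) from category count
vectors — species in an ecological community, or, in the bundled
application, age classes of substance-using street children surveyed
across the nine districts of Delhi.  It is aimed at biostatisticians and
epidemiologists who want both a **classical** (delta-method) estimate
with an honest variance and a **Bayesian** estimate under a
probability-matching prior, plus the machinery to compare the two by
simulation.

## The model

There are `S` categories with abundance probabilities `p_i`, and counts
`x_i ~ Binomial(n, p_i)` observed independently.  The index is

```
H(p) = -Σ_i p_i log_b p_i          (log base b ∈ {2, e, 10}; default 2)
```

**Classical.**  With `p̂_i = x_i/n`, a second-order delta-method
expansion of `X log X` gives the bias-corrected mean and variance

```
Ĥ    = H(p̂) - Σ_i p̂_i(1-p̂_i)/(2n)
V(Ĥ) = (1/n) Σ_i p̂_i(1-p̂_i) { [1 + log_b(x_i)]² + (log_b n)² }
```

**Bayesian.**  The prior on `p` is chosen so that posterior credible
statements for `H` match frequentist coverage to first order
(a Datta–Ghosh-type matching condition `Σ_i ∂/∂p_i [φ_i q] = 0`, where
`φ` is the Fisher-normalized entropy gradient):

```
q(p) ∝ { Σ_i (1+ln p_i)² p_i(1-p_i) }^{1/2} · Π_i [ p_i(1-p_i) |1+ln p_i| ]^{-1}
```

The posterior `h(p|x) ∝ L(p|x) q(p)` has no closed form; a
component-wise Metropolis–Hastings sampler draws from it and summarizes
the posterior mean and variance of `H(p)`.  No simplex constraint is
imposed on `p` — see `docs/methods.md` for why, and for the numerical
guards around the prior's singularities.

## Worked example

```python
>>> from sdi import ShannonDiversityModel, delhi_fixture, MCMCConfig
>>> table = delhi_fixture()                    # 9 districts x 3 age classes
>>> m = ShannonDiversityModel.from_table(table, stratum="Central Delhi")
>>> print(m.fit().summary())
Shannon Diversity Index
======================================
Stratum          Central Delhi
Categories (S)   3
Sample size (n)  7
Log base         2
Method           corrected
H estimate       1.5100
Variance         1.2023
Std. error       1.0965
======================================
```

Central Delhi's seven children spread almost evenly over the three age
classes, so the corrected index (1.51) sits near its maximum
`log2 3 ≈ 1.58`; the delta-method variance is large because n = 7.  The
Bayesian fit of the same stratum:

```python
>>> res = m.fit("bayes", mcmc=MCMCConfig(n_samples=50_000, burn_in=5_000, seed=1))
>>> round(res.point, 2), round(res.variance, 4)
(1.52, 0.0064)
```

The posterior mean agrees with the classical estimate while its
variance is two orders of magnitude smaller — the pattern that holds on
every district and throughout the simulation grid.

The same analyses run from the shell:

```
sdi estimate --method classical --method bayes --samples 50000 --seed 1
sdi simulate --reps 50 --samples 20000 --seed 0
sdi synth --p 0.2,0.5,0.3 --n 1000 --reps 1 --seed 3 --out demo
sdi delhi-demo --bayes
```

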