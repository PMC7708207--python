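"""Matching prior, posterior target, and the Fisher/φ machinery."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from sdi import (
    BoundaryError,
    CountVector,
    DegenerateInputError,
    InvalidInputError,
    PosteriorTarget,
    PriorGuard,
    entropy_gradient,
    fisher_inverse_diag,
    log_posterior,
    log_prior,
    matching_condition_residual,
    phi_vector,
    prior_density,
)

E_INV = math.exp(-1.0)

interior_probs = st.lists(
    st.floats(0.02, 0.98).filter(lambda p: abs(p - E_INV) > 1e-3),
    min_size=1, max_size=5)


class TestLogPrior:
    def test_s2_direct_formula(self):
        # independent evaluation of the density expression at (0.5, 0.5)
        p = 0.5
        t = 1.0 + math.log(p)
        expected = math.log(
            math.sqrt(2 * t * t * p * (1 - p)) / (p * (1 - p) * abs(t)) ** 2)
        assert log_prior([0.5, 0.5]) == pytest.approx(expected, abs=1e-12)

    def test_s1_reduces_to_closed_form(self):
        # the (1 + ln p) factors cancel for S = 1: q = [p(1-p)]^{-1/2}
        for p in (0.1, 0.3, 0.55, 0.9):
            assert log_prior([p]) == pytest.approx(
                -0.5 * math.log(p * (1 - p)), abs=1e-12)

    def test_density_grows_approaching_singular_line(self):
        near = log_prior([E_INV + 1e-4, 0.5])
        far = log_prior([E_INV + 1e-2, 0.5])
        assert near > far

    def test_boundary_guard_gives_neg_inf(self):
        guard = PriorGuard(eps_boundary=1e-3)
        assert log_prior([5e-4, 0.5], guard) == -math.inf
        assert log_prior([0.5, 1 - 5e-4], guard) == -math.inf

    def test_invalid_probability_raises(self):
        with pytest.raises(InvalidInputError):
            log_prior([1.2, 0.5])

    @given(interior_probs, st.randoms(use_true_random=False))
    def test_permutation_invariance(self, ps, rnd):
        perm = list(ps)
        rnd.shuffle(perm)
        assert log_prior(ps) == pytest.approx(log_prior(perm), abs=1e-9)


class TestLogPosterior:
    def test_sum_of_parts(self):
        counts = CountVector([3, 7], n=10)
        target = PosteriorTarget(counts)
        p = np.array([0.3, 0.7])
        loglik = (3 * math.log(0.3) + 7 * math.log(0.7)
                  + 7 * math.log(0.7) + 3 * math.log(0.3))
        assert log_posterior(p, target) == pytest.approx(
            loglik + log_prior(p, target.guard), abs=1e-10)

    def test_likelihood_dominance_at_mle(self):
        target = PosteriorTarget(CountVector([5, 5]))
        assert log_posterior([0.5, 0.5], target) > log_posterior([0.9, 0.9], target)

    def test_guard_boundary_is_neg_inf(self):
        target = PosteriorTarget(CountVector([5, 5]),
                                 PriorGuard(eps_boundary=1e-3))
        assert log_posterior([1e-3, 0.5], target) == -math.inf

    def test_coord_terms_recompose_log_density(self):
        # incremental sampler terms must sum to the full joint density
        target = PosteriorTarget(CountVector([2, 0, 9], n=12))
        p = np.array([0.21, 0.05, 0.83])
        terms = [target.coord_terms(i, p[i]) for i in range(3)]
        ll = sum(t[0] for t in terms)
        A = sum(t[1] for t in terms)
        d = sum(t[2] for t in terms)
        assert ll + 0.5 * math.log(A) - d == pytest.approx(
            target.log_density(p), abs=1e-10)


class TestFisherMachinery:
    def test_inverse_diag_examples(self):
        assert fisher_inverse_diag([0.5], 10)[0] == pytest.approx(0.025)
        lam = fisher_inverse_diag([0.2, 0.8], 5)
        assert lam == pytest.approx([0.032, 0.032])

    def test_boundary_error(self):
        with pytest.raises(BoundaryError):
            fisher_inverse_diag([0.0, 0.5], 10)

    def test_inverse_diag_matches_empirical_information(self, rng):
        # oracle: empirical Fisher info from simulated binomial scores
        n, p, reps = 100, 0.3, 100_000
        y = rng.binomial(n, p, size=reps)
        score = y / p - (n - y) / (1 - p)
        emp_inverse = 1.0 / np.mean(score ** 2)
        assert fisher_inverse_diag([p], n)[0] == pytest.approx(
            emp_inverse, rel=0.02)

    def test_entropy_gradient_examples(self):
        assert entropy_gradient([E_INV])[0] == pytest.approx(0.0, abs=1e-15)
        assert entropy_gradient([1.0])[0] == pytest.approx(-1.0)

    def test_entropy_gradient_matches_central_differences(self):
        p = np.array([0.2, 0.5, 0.3])
        h = 1e-6

        def H(v):
            return float(-(v * np.log(v)).sum())

        for i in range(3):
            up, dn = p.copy(), p.copy()
            up[i] += h
            dn[i] -= h
            fd = (H(up) - H(dn)) / (2 * h)
            assert entropy_gradient(p)[i] == pytest.approx(fd, abs=1e-6)


class TestPhiVector:
    @given(interior_probs, st.integers(1, 200))
    def test_fisher_normalization_identity(self, ps, n):
        phi = phi_vector(ps, n)
        lam = fisher_inverse_diag(ps, n)
        assert float((phi ** 2 / lam).sum()) == pytest.approx(1.0, abs=1e-12)

    def test_s1_reduction(self):
        for p in (0.1, 0.55, 0.9):
            lam = p * (1 - p) / 20
            gamma = -(math.log(p) + 1.0)
            expected = math.copysign(math.sqrt(lam), gamma)
            assert phi_vector([p], 20)[0] == pytest.approx(expected, abs=1e-14)

    def test_direct_quotient(self):
        p, n = np.array([0.2, 0.6]), 20
        gamma = -(np.log(p) + 1.0)
        lam = p * (1 - p) / n
        expected = gamma * lam / math.sqrt(float((gamma ** 2 * lam).sum()))
        assert phi_vector(p, n) == pytest.approx(expected, abs=1e-14)

    def test_degenerate_gradient(self):
        with pytest.raises(DegenerateInputError):
            phi_vector([E_INV, E_INV], 10)


class TestMatchingCondition:
    @pytest.mark.parametrize("p, n", [
        ((0.15, 0.6), 10),
        ((0.1, 0.5, 0.8), 25),
        ((0.2, 0.55, 0.7, 0.9), 40),
    ])
    def test_residual_vanishes_for_matching_prior(self, p, n):
        assert abs(matching_condition_residual(p, n)) <= 1e-4

    @pytest.mark.parametrize("p, n", [
        ((0.15, 0.6), 10),
        ((0.1, 0.5, 0.8), 25),
    ])
    def test_perturbed_prior_fails(self, p, n):
        # negative control: q*(p) = q(p) p_1 is not a matching prior
        perturbed = lambda v: prior_density(v, 0.0) * v[0]
        assert abs(matching_condition_residual(p, n, prior=perturbed)) > 1e-2

    def test_precondition_near_singularity(self):
        with pytest.raises(InvalidInputError):
            matching_condition_residual((E_INV + 1e-6, 0.5), 10, h=1e-5)

    def test_precondition_near_boundary(self):
        with pytest.raises(InvalidInputError):
            matching_condition_residual((1e-5, 0.5), 10, h=1e-5)
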