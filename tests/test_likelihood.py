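"""Sample covariance, Gaussian log-likelihood and the penalized objective."""

import numpy as np
import pytest

from conftest import random_spd
from tfglasso.core import BlockIndex, DynamicGraphSpec, block_entries
from tfglasso.likelihood import (ExpressionPanel, PenaltyConfig,
                                 fusion_penalty, log_likelihood,
                                 penalized_objective, sample_covariance,
                                 sparsity_penalty)


def make_panel(data, p, T, k=None):
    spec = DynamicGraphSpec(p=p, T=T, k=T - 1 if k is None else k)
    return ExpressionPanel(np.asarray(data, float), spec)


class TestSampleCovariance:
    def test_two_point_example(self):
        S, ybar = sample_covariance(make_panel([[1, 0], [-1, 0]], 2, 1))
        assert np.allclose(S, [[1, 0], [0, 0]])
        assert np.allclose(ybar, [0, 0])

    def test_identical_rows_zero(self):
        S, _ = sample_covariance(make_panel([[3.0, 1.0, 2.0]] * 4, 3, 1))
        assert np.allclose(S, 0)

    def test_matches_elementwise_double_sum(self, rng):
        Y = rng.normal(size=(5, 3))
        S, ybar = sample_covariance(make_panel(Y, 3, 1))
        n = 5
        for a in range(3):
            for b in range(3):
                expected = sum(
                    (Y[k, a] - Y[:, a].mean()) * (Y[k, b] - Y[:, b].mean())
                    for k in range(n)
                ) / n
                assert S[a, b] == pytest.approx(expected)

    def test_divisor_is_n_not_nminus1(self, rng):
        Y = rng.normal(size=(6, 2))
        S, _ = sample_covariance(make_panel(Y, 2, 1))
        assert np.allclose(S, np.cov(Y.T, ddof=0))
        assert not np.allclose(S, np.cov(Y.T, ddof=1))

    def test_rejects_single_replicate(self):
        with pytest.raises(ValueError):
            sample_covariance(make_panel([[1.0, 2.0]], 2, 1))

    def test_rejects_nonfinite(self):
        with pytest.raises(ValueError):
            make_panel([[1.0, np.nan], [0.0, 1.0]], 2, 1)


class TestLogLikelihood:
    def test_identity_closed_form(self):
        d = 4
        assert log_likelihood(np.eye(d), np.eye(d), n=2) == pytest.approx(-d)

    def test_scalar_closed_form(self):
        assert log_likelihood([[2.0]], [[0.5]], n=2) == pytest.approx(np.log(2) - 1)

    def test_term_by_term_oracle(self, rng):
        d = 3
        theta = random_spd(d, rng) + np.eye(d)
        S = random_spd(d, rng)
        mu, ybar = rng.normal(size=d), rng.normal(size=d)
        n = 7
        expected = 0.5 * n * (
            np.log(np.linalg.det(theta))
            - np.trace(S @ theta)
            - (mu - ybar) @ theta @ (mu - ybar)
        )
        got = log_likelihood(theta, S, n, mu=mu, ybar=ybar)
        assert got == pytest.approx(expected, rel=1e-10)

    def test_quadratic_term_vanishes_at_mle_mean(self, rng):
        theta = random_spd(2, rng) + np.eye(2)
        S = random_spd(2, rng)
        y = rng.normal(size=2)
        assert log_likelihood(theta, S, 5, mu=y, ybar=y) == pytest.approx(
            log_likelihood(theta, S, 5)
        )

    def test_rejects_indefinite(self):
        with pytest.raises(np.linalg.LinAlgError):
            log_likelihood(np.diag([1.0, -1.0]), np.eye(2), n=2)


def brute_force_fusion(theta, spec):
    """Fusion penalty by direct block enumeration (both triangles)."""
    total = 0.0
    for l in range(spec.k + 1):
        for s in range(1, spec.T - l):
            if spec.p < 2:
                continue
            a = block_entries(BlockIndex(l, s, "N"), spec)
            b = block_entries(BlockIndex(l, s + 1, "N"), spec)

            def key(e):
                (i, j) = e
                return (i % spec.p, j % spec.p)

            am = {key(e): theta[e] for e in a}
            bm = {key(e): theta[e] for e in b}
            # block_entries lists upper-triangle positions once; the
            # penalty counts both triangles
            total += 2.0 * sum(abs(am[k2] - bm[k2]) for k2 in am)
    return total


class TestPenalizedObjective:
    def test_identity_unpenalized(self):
        spec = DynamicGraphSpec(p=2, T=2, k=1)
        assert penalized_objective(
            np.eye(4), np.eye(4), PenaltyConfig(0.0, 0.0), spec
        ) == pytest.approx(4.0)

    def test_two_by_two_closed_form(self):
        # both-triangle convention: the 0.5 off-diagonal is counted twice
        spec = DynamicGraphSpec(p=2, T=1, k=0)
        theta = np.array([[1.0, 0.5], [0.5, 1.0]])
        got = penalized_objective(theta, np.eye(2), PenaltyConfig(2.0, 0.0), spec)
        assert got == pytest.approx(-np.log(0.75) + 2.0 + 2.0 * (2 * 0.5))

    def test_fusion_block_contribution(self):
        spec = DynamicGraphSpec(p=2, T=2, k=1)
        theta = np.eye(4) * 2
        theta[0, 1] = theta[1, 0] = 0.3  # N_0^1
        theta[2, 3] = theta[3, 2] = 0.1  # N_0^2
        pen = PenaltyConfig(0.0, 10.0)
        base = penalized_objective(theta, np.eye(4), PenaltyConfig(0, 0), spec)
        got = penalized_objective(theta, np.eye(4), pen, spec)
        assert got - base == pytest.approx(2 * 10.0 * abs(0.3 - 0.1))
        assert fusion_penalty(theta, spec) == pytest.approx(brute_force_fusion(theta, spec))

    def test_fusion_matches_brute_force_random(self, rng):
        spec = DynamicGraphSpec(p=3, T=4, k=1)
        theta = random_spd(spec.d, rng)
        assert fusion_penalty(theta, spec) == pytest.approx(
            brute_force_fusion(theta, spec), rel=1e-10
        )

    def test_unpenalized_objective_is_scaled_negative_loglik(self, rng):
        spec = DynamicGraphSpec(p=2, T=3, k=2)
        theta = random_spd(spec.d, rng) + np.eye(spec.d)
        S = random_spd(spec.d, rng)
        n = 9
        obj = penalized_objective(theta, S, PenaltyConfig(0, 0), spec)
        assert obj + log_likelihood(theta, S, n) * 2.0 / n == pytest.approx(0.0, abs=1e-9)

    def test_fusion_invariant_to_common_block_shift(self):
        spec = DynamicGraphSpec(p=2, T=3, k=1)
        theta = np.eye(6) * 3
        vals = [0.4, 0.1, -0.2]
        for s, v in enumerate(vals):
            theta[2 * s, 2 * s + 1] = theta[2 * s + 1, 2 * s] = v
        before = fusion_penalty(theta, spec)
        for s in range(3):
            theta[2 * s, 2 * s + 1] += 0.7
            theta[2 * s + 1, 2 * s] += 0.7
        assert fusion_penalty(theta, spec) == pytest.approx(before)

    def test_convexity_spot_check(self, rng):
        spec = DynamicGraphSpec(p=2, T=2, k=1)
        pen = PenaltyConfig(0.3, 0.2)
        S = random_spd(4, rng)
        for _ in range(10):
            A = random_spd(4, rng) + 0.5 * np.eye(4)
            B = random_spd(4, rng) + 0.5 * np.eye(4)
            a = float(rng.uniform(0.1, 0.9))
            f = lambda M: penalized_objective(M, S, pen, spec)
            assert f(a * A + (1 - a) * B) <= a * f(A) + (1 - a) * f(B) + 1e-9

    def test_diagonal_penalty_flag(self):
        spec = DynamicGraphSpec(p=2, T=1, k=0)
        theta = np.diag([2.0, 3.0])
        off = penalized_objective(theta, np.eye(2), PenaltyConfig(1.0, 0.0), spec)
        on = penalized_objective(
            theta, np.eye(2), PenaltyConfig(1.0, 0.0, penalize_diagonal=True), spec
        )
        assert on - off == pytest.approx(5.0)
        assert sparsity_penalty(theta, spec, True) == pytest.approx(5.0)


def test_penalty_config_validation():
    with pytest.raises(ValueError):
        PenaltyConfig(-0.1, 0.0)
    with pytest.raises(ValueError):
        PenaltyConfig(0.1, -1.0)
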