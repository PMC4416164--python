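"""Solver contracts: analytic limits, oracle agreement, KKT certification."""

import warnings

import numpy as np
import pytest

from _reference import reference_solve
from conftest import random_spd
from tfglasso.core import DynamicGraphSpec, ar_mask, block_structure
from tfglasso.likelihood import PenaltyConfig, penalized_objective
from tfglasso.solver import extract_edges, fit, kkt_residual, refit_mle


class TestAnalyticLimits:
    def test_identity_covariance_gives_identity(self):
        spec = DynamicGraphSpec(p=2, T=2, k=1)
        for lam1, lam2 in [(0.0, 0.0), (0.5, 0.0), (0.3, 0.7), (2.0, 2.0)]:
            est = fit(np.eye(4), spec, PenaltyConfig(lam1, lam2))
            assert np.allclose(est.theta_hat, np.eye(4), atol=1e-8)
            assert est.kkt_residual < 1e-6

    def test_two_by_two_zero_threshold(self):
        """KKT: the off-diagonal is zero exactly when |s_ij| <= lambda1."""
        spec = DynamicGraphSpec(p=2, T=1, k=0)
        S = np.array([[1.0, 0.3], [0.3, 1.0]])
        assert fit(S, spec, PenaltyConfig(0.3)).theta_hat[0, 1] == 0.0
        assert fit(S, spec, PenaltyConfig(0.31)).theta_hat[0, 1] == 0.0
        assert fit(S, spec, PenaltyConfig(0.29)).theta_hat[0, 1] != 0.0

    def test_large_lambda1_gives_diagonal(self, rng):
        spec = DynamicGraphSpec(p=3, T=2, k=1)
        S = random_spd(6, rng) + 0.5 * np.eye(6)
        lam = float(np.abs(S - np.diag(np.diag(S))).max())
        est = fit(S, spec, PenaltyConfig(lam))
        assert np.allclose(est.theta_hat, np.diag(1.0 / np.diag(S)), atol=1e-7)

    def test_large_lambda2_gives_time_homogeneous_blocks(self, rng):
        spec = DynamicGraphSpec(p=3, T=3, k=1)
        S = random_spd(9, rng) + 0.2 * np.eye(9)
        est = fit(S, spec, PenaltyConfig(0.05, 1e4 * float(np.abs(S).max())))
        st = block_structure(spec)
        free = est.theta_hat[st.rows, st.cols]
        for chains in st.n_chains.values():
            if chains.shape[1] >= 2:
                assert np.abs(np.diff(free[chains], axis=1)).max() < 1e-6

    def test_reduces_to_graphical_lasso(self, rng):
        """lambda2=0, k=T-1 equals a standard graphical-lasso solution."""
        from sklearn.covariance import graphical_lasso

        spec = DynamicGraphSpec(p=2, T=3, k=2)
        S = random_spd(6, rng) + 0.3 * np.eye(6)
        lam = 0.08
        est = fit(S, spec, PenaltyConfig(lam, 0.0))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, prec = graphical_lasso(S, alpha=lam, tol=1e-12, max_iter=2000)
        assert np.abs(est.theta_hat - prec).max() < 1e-5


class TestOracleAgreement:
    @pytest.mark.parametrize("seed", range(5))
    def test_matches_reference_solver(self, seed):
        rng = np.random.default_rng(seed)
        p, T = int(rng.integers(1, 4)), int(rng.integers(1, 4))
        spec = DynamicGraphSpec(p=p, T=T, k=int(rng.integers(0, T)))
        S = random_spd(spec.d, rng)
        pen = PenaltyConfig(float(rng.uniform(0.02, 0.4)), float(rng.uniform(0, 0.4)))
        est = fit(S, spec, pen)
        _, obj_ref = reference_solve(S, spec, pen)
        assert est.objective_value == pytest.approx(obj_ref, rel=1e-5, abs=1e-7)
        assert est.kkt_residual < 1e-5


class TestKKTResidual:
    def test_zero_at_unpenalized_mle(self, rng):
        spec = DynamicGraphSpec(p=2, T=2, k=1)
        S = random_spd(4, rng) + 0.5 * np.eye(4)
        est = fit(S, spec, PenaltyConfig(0.0, 0.0))
        assert np.abs(est.theta_hat - np.linalg.inv(S)).max() < 1e-6
        assert est.kkt_residual < 1e-6

    def test_zero_for_identity_any_lambda(self):
        spec = DynamicGraphSpec(p=2, T=2, k=1)
        est = fit(np.eye(4), spec, PenaltyConfig(0.7, 0.9))
        assert kkt_residual(est, np.eye(4)) < 1e-8

    def test_positive_after_perturbation(self, rng):
        spec = DynamicGraphSpec(p=2, T=2, k=1)
        S = random_spd(4, rng) + 0.5 * np.eye(4)
        est = fit(S, spec, PenaltyConfig(0.05, 0.05))
        base = kkt_residual(est, S)
        est.theta_hat = est.theta_hat.copy()
        est.theta_hat[0, 1] += 0.1
        est.theta_hat[1, 0] += 0.1
        assert kkt_residual(est, S) > max(10 * base, 1e-3)


class TestFitContracts:
    def test_masked_positions_exactly_zero(self, rng):
        spec = DynamicGraphSpec(p=3, T=3, k=1)
        S = random_spd(9, rng) + 0.2 * np.eye(9)
        est = fit(S, spec, PenaltyConfig(0.1, 0.1))
        assert np.all(est.theta_hat[ar_mask(spec)] == 0.0)

    def test_symmetric_positive_definite_and_objective(self, rng):
        spec = DynamicGraphSpec(p=2, T=3, k=1)
        S = random_spd(6, rng) + 0.2 * np.eye(6)
        pen = PenaltyConfig(0.1, 0.2)
        est = fit(S, spec, pen)
        assert np.abs(est.theta_hat - est.theta_hat.T).max() < 1e-10
        assert np.linalg.eigvalsh(est.theta_hat)[0] > 0
        assert est.objective_value == pytest.approx(
            penalized_objective(est.theta_hat, S, pen, spec), abs=1e-8
        )

    def test_deterministic(self, rng):
        spec = DynamicGraphSpec(p=2, T=2, k=1)
        S = random_spd(4, rng) + 0.2 * np.eye(4)
        a = fit(S, spec, PenaltyConfig(0.1, 0.1))
        b = fit(S, spec, PenaltyConfig(0.1, 0.1))
        assert np.array_equal(a.theta_hat, b.theta_hat)
        assert a.iterations == b.iterations

    def test_warm_start_does_not_change_solution(self, rng):
        spec = DynamicGraphSpec(p=3, T=2, k=1)
        S = random_spd(6, rng) + 0.2 * np.eye(6)
        cold = fit(S, spec, PenaltyConfig(0.1, 0.05))
        other = fit(S, spec, PenaltyConfig(0.2, 0.05))
        warm = fit(S, spec, PenaltyConfig(0.1, 0.05), warm_start=other.warm_start)
        assert np.abs(cold.theta_hat - warm.theta_hat).max() < 1e-6

    def test_rejects_asymmetric_covariance(self):
        spec = DynamicGraphSpec(p=2, T=1, k=0)
        with pytest.raises(ValueError):
            fit(np.array([[1.0, 0.5], [0.2, 1.0]]), spec, PenaltyConfig(0.1))

    def test_rejects_unpenalized_singular_covariance(self):
        spec = DynamicGraphSpec(p=2, T=1, k=0)
        S = np.ones((2, 2))
        with pytest.raises(ValueError):
            fit(S, spec, PenaltyConfig(0.0))

    def test_edge_count_monotone_in_lambda1(self, rng):
        spec = DynamicGraphSpec(p=3, T=2, k=1)
        S = random_spd(6, rng) + 0.2 * np.eye(6)
        counts = []
        warm = None
        for lam in np.geomspace(0.01, 1.0, 8) * float(np.abs(S).max()):
            est = fit(S, spec, PenaltyConfig(float(lam), 0.02), warm_start=warm)
            warm = est.warm_start
            counts.append(len(extract_edges(est)))
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_nonconvergence_warns_and_flags(self, rng):
        spec = DynamicGraphSpec(p=3, T=2, k=1)
        S = random_spd(6, rng) + 0.2 * np.eye(6)
        with pytest.warns(UserWarning):
            est = fit(S, spec, PenaltyConfig(0.1, 0.1), max_iter=3, compute_kkt=False)
        assert not est.converged


class TestExtractEdges:
    def test_identity_estimate_has_no_edges(self):
        spec = DynamicGraphSpec(p=3, T=2, k=1)
        est = fit(np.eye(6), spec, PenaltyConfig(0.1))
        assert len(extract_edges(est)) == 0

    def test_infinite_tolerance_empty(self, rng):
        spec = DynamicGraphSpec(p=3, T=2, k=1)
        S = random_spd(6, rng) + 0.2 * np.eye(6)
        est = fit(S, spec, PenaltyConfig(0.01))
        assert len(extract_edges(est, tol=np.inf)) == 0
        with pytest.raises(ValueError):
            extract_edges(est, tol=-1.0)


class TestRefit:
    def test_refit_preserves_support_and_improves_likelihood(self, rng):
        spec = DynamicGraphSpec(p=3, T=2, k=1)
        S = random_spd(6, rng) + 0.2 * np.eye(6)
        est = fit(S, spec, PenaltyConfig(0.15, 0.05))
        edges = extract_edges(est)
        theta_r = refit_mle(S, spec, edges, theta0=est.theta_hat)
        support = np.zeros((6, 6), dtype=bool)
        for i, j in edges.edges:
            support[i, j] = support[j, i] = True
        support[np.diag_indices(6)] = True
        assert np.all(theta_r[~support] == 0.0)
        ll = lambda th: np.linalg.slogdet(th)[1] - np.sum(S * th)
        assert ll(theta_r) >= ll(est.theta_hat) - 1e-8
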