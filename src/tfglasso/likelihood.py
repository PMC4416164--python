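"""Gaussian likelihood and the fused-lasso penalized objective.

The estimator minimizes, over symmetric positive-definite ``Theta`` obeying
the AR(k) zero constraints,

    -log det Theta + Tr(S Theta) + lambda1 * P1(Theta) + lambda2 * P2(Theta)

where ``S`` is the sample covariance (divisor ``n``), ``P1`` is the
off-diagonal l1 norm and ``P2`` sums the absolute entry-wise differences
between corresponding network blocks at consecutive start times,
``sum_l sum_s ||N_l^s - N_l^{s+1}||_1``.  Both penalties count each
unordered entry pair over both triangles (the standard graphical-lasso
convention), so an off-diagonal of a 2x2 problem is zeroed exactly when
``|s_ij| <= lambda1``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import DynamicGraphSpec, ar_mask, block_structure

__all__ = [
    "ExpressionPanel",
    "PenaltyConfig",
    "sample_covariance",
    "log_likelihood",
    "penalized_objective",
    "fusion_penalty",
    "sparsity_penalty",
]


@dataclass
class ExpressionPanel:
    """n replicates x d observations (d = p*T, vertex-index column order)."""

    data: np.ndarray
    spec: DynamicGraphSpec
    replicate_ids: tuple = field(default=None)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("panel data must be a 2-D array")
        if self.data.shape[1] != self.spec.d:
            raise ValueError(
                f"panel has {self.data.shape[1]} columns, spec requires d={self.spec.d}"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("panel contains non-finite values")
        if self.replicate_ids is None:
            self.replicate_ids = tuple(f"r{i + 1}" for i in range(self.n))
        else:
            self.replicate_ids = tuple(str(r) for r in self.replicate_ids)
            if len(self.replicate_ids) != self.n:
                raise ValueError("replicate_ids length mismatch")

    @property
    def n(self) -> int:
        return self.data.shape[0]


@dataclass(frozen=True)
class PenaltyConfig:
    """Tuning parameters: lambda1 (sparsity), lambda2 (fusion/persistence)."""

    lambda1: float
    lambda2: float = 0.0
    penalize_diagonal: bool = False

    def __post_init__(self):
        if self.lambda1 < 0 or self.lambda2 < 0:
            raise ValueError("tuning parameters must be non-negative")


def sample_covariance(panel: ExpressionPanel) -> tuple[np.ndarray, np.ndarray]:
    """Sample covariance with divisor n, and the sample mean.

    Returns ``(S, ybar)`` where ``S = sum_k (y_k - ybar)(y_k - ybar)^t / n``.
    """
    if panel.n < 2:
        raise ValueError(f"sample covariance requires n >= 2 replicates, got n={panel.n}")
    Y = panel.data
    ybar = Y.mean(axis=0)
    R = Y - ybar
    S = R.T @ R / panel.n
    return 0.5 * (S + S.T), ybar


def _check_spd(theta: np.ndarray) -> float:
    sign, logdet = np.linalg.slogdet(theta)
    if sign <= 0 or not np.isfinite(logdet):
        raise np.linalg.LinAlgError("theta is not positive definite")
    return logdet


def log_likelihood(theta, S, n, mu=None, ybar=None) -> float:
    """Gaussian log-likelihood n/2 {log|Theta| - Tr(S Theta) - (mu-ybar)' Theta (mu-ybar)}.

    With ``mu = ybar`` (the MLE of the mean) the quadratic term vanishes;
    that is the default.
    """
    theta = np.asarray(theta, dtype=float)
    S = np.asarray(S, dtype=float)
    logdet = _check_spd(theta)
    quad = 0.0
    if mu is not None and ybar is not None:
        delta = np.asarray(mu, dtype=float) - np.asarray(ybar, dtype=float)
        quad = float(delta @ theta @ delta)
    return 0.5 * n * (logdet - float(np.sum(S * theta)) - quad)


def sparsity_penalty(theta: np.ndarray, spec: DynamicGraphSpec, penalize_diagonal: bool = False) -> float:
    """P1: l1 norm of the off-diagonal (both triangles; diagonal optional)."""
    theta = np.asarray(theta, dtype=float)
    off = np.abs(theta).sum() - np.abs(np.diag(theta)).sum()
    if penalize_diagonal:
        off += np.abs(np.diag(theta)).sum()
    return float(off)


def fusion_penalty(theta: np.ndarray, spec: DynamicGraphSpec) -> float:
    """P2: sum over lags l <= k of ||N_l^s - N_l^{s+1}||_1 over consecutive s.

    Only network (distinct-gene) blocks are fused; each entry-pair
    difference is counted over both triangles, matching P1's convention.
    """
    theta = np.asarray(theta, dtype=float)
    st = block_structure(spec)
    free = st.gather(theta)
    total = 0.0
    for chains in st.n_chains.values():
        if chains.shape[1] < 2:
            continue
        vals = free[chains]
        total += 2.0 * float(np.abs(np.diff(vals, axis=1)).sum())
    return total


def penalized_objective(theta, S, penalty: PenaltyConfig, spec: DynamicGraphSpec) -> float:
    """-log|Theta| + Tr(S Theta) + lambda1 P1 + lambda2 P2."""
    theta = np.asarray(theta, dtype=float)
    S = np.asarray(S, dtype=float)
    logdet = _check_spd(theta)
    value = -logdet + float(np.sum(S * theta))
    if penalty.lambda1 > 0 or penalty.penalize_diagonal:
        value += penalty.lambda1 * sparsity_penalty(theta, spec, penalty.penalize_diagonal)
    if penalty.lambda2 > 0:
        value += penalty.lambda2 * fusion_penalty(theta, spec)
    return value


def is_feasible(theta: np.ndarray, spec: DynamicGraphSpec, tol: float = 0.0) -> bool:
    """True if theta vanishes on every AR(k)-masked position."""
    mask = ar_mask(spec)
    return bool(np.all(np.abs(np.asarray(theta)[mask]) <= tol))
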