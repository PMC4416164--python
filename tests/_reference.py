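"""Independent reference solver for the penalized likelihood program.

Solves the same convex program as ``tfglasso.solver.fit`` by a completely
different method: the non-smooth l1/fusion terms are replaced by the
smooth surrogate ``sqrt(x^2 + delta^2)`` and the resulting strictly convex
smooth problem is minimized by damped Newton with an explicit Hessian,
driving ``delta`` down a continuation path (1e-1 ... 1e-9).  The surrogate
over-estimates each absolute value by at most ``delta``, so the final true
objective is within ``delta * (number of penalized terms) * lambda`` of the
optimum -- far below the 1e-5 relative tolerance the cross-checks use.
Only suitable for small dimensions (dense Hessian over the free entries).
"""

from __future__ import annotations

import numpy as np

from tfglasso.core import DynamicGraphSpec, block_structure
from tfglasso.likelihood import PenaltyConfig, penalized_objective


def _params_to_theta(x, st, d):
    n_free = st.n_free
    theta = st.scatter(x[:n_free])
    theta[np.diag_indices(d)] = x[n_free:]
    return theta


def _fusion_pairs(st):
    """(index_a, index_b) arrays of consecutive chain positions (fused)."""
    a, b = [], []
    for chains in st.n_chains.values():
        if chains.shape[1] < 2:
            continue
        a.append(chains[:, :-1].ravel())
        b.append(chains[:, 1:].ravel())
    if not a:
        return np.empty(0, dtype=int), np.empty(0, dtype=int)
    return np.concatenate(a), np.concatenate(b)


def reference_solve(
    S: np.ndarray,
    spec: DynamicGraphSpec,
    penalty: PenaltyConfig,
    max_newton: int = 200,
) -> tuple[np.ndarray, float]:
    """Minimize the penalized objective; returns (theta, objective).

    The objective returned is the exact (non-smoothed) penalized objective
    evaluated at the continuation solution.
    """
    S = np.asarray(S, dtype=float)
    d = spec.d
    st = block_structure(spec)
    n_free = st.n_free
    n_par = n_free + d
    lam1, lam2 = penalty.lambda1, penalty.lambda2
    fa, fb = _fusion_pairs(st)

    # start at a strictly feasible diagonal matrix
    x = np.zeros(n_par)
    x[n_free:] = 1.0 / np.maximum(np.diag(S), 1e-3)

    def smooth_parts(x, delta):
        theta = _params_to_theta(x, st, d)
        sign, logdet = np.linalg.slogdet(theta)
        if sign <= 0:
            return None
        W = np.linalg.inv(theta)
        W = 0.5 * (W + W.T)
        f = -logdet + float(np.sum(S * theta))
        xo = x[:n_free]
        # l1 surrogate: both triangles -> factor 2 per free position
        s1 = np.sqrt(xo * xo + delta * delta)
        f += 2.0 * lam1 * float(np.sum(s1)) if lam1 else 0.0
        diffs = xo[fb] - xo[fa] if len(fa) else np.empty(0)
        s2 = np.sqrt(diffs * diffs + delta * delta)
        f += 2.0 * lam2 * float(np.sum(s2)) if lam2 else 0.0

        g = np.empty(n_par)
        G = S - W
        g[:n_free] = 2.0 * G[st.rows, st.cols]
        g[n_free:] = np.diag(G)
        if lam1:
            g[:n_free] += 2.0 * lam1 * xo / s1
        if lam2 and len(fa):
            fg = 2.0 * lam2 * diffs / s2
            np.add.at(g, fb, fg)
            np.add.at(g, fa, -fg)
        return theta, W, f, g, s1, (diffs, s2)

    delta_path = [1e-1, 1e-2, 1e-3, 1e-4, 1e-5, 1e-6, 1e-7, 1e-8, 1e-9]
    rows, cols = st.rows, st.cols
    for delta in delta_path:
        for _ in range(max_newton):
            parts = smooth_parts(x, delta)
            theta, W, f, g, s1, (diffs, s2) = parts
            # Hessian of -logdet via d^2 = tr(W M_a W M_b)
            # build matrix of W-products over parameter basis
            H = np.empty((n_par, n_par))
            # precompute W columns for basis matrices
            for a in range(n_par):
                if a < n_free:
                    i, j = rows[a], cols[a]
                    P = np.outer(W[:, i], W[j, :]) + np.outer(W[:, j], W[i, :])
                else:
                    i = a - n_free
                    P = np.outer(W[:, i], W[i, :])
                h = np.empty(n_par)
                h[:n_free] = P[rows, cols] + P[cols, rows]
                h[n_free:] = np.diag(P)
                H[a] = h
            if lam1:
                H[np.arange(n_free), np.arange(n_free)] += (
                    2.0 * lam1 * delta * delta / s1**3
                )
            if lam2 and len(fa):
                w2 = 2.0 * lam2 * delta * delta / s2**3
                np.add.at(H, (fa, fa), w2)
                np.add.at(H, (fb, fb), w2)
                np.add.at(H, (fa, fb), -w2)
                np.add.at(H, (fb, fa), -w2)
            H[np.diag_indices(n_par)] += 1e-12
            try:
                step = np.linalg.solve(H, -g)
            except np.linalg.LinAlgError:
                step = -g
            # backtracking line search with PD safeguard
            t = 1.0
            ok = False
            for _ in range(60):
                trial = x + t * step
                p2 = smooth_parts(trial, delta)
                if p2 is not None and p2[2] <= f + 1e-4 * t * float(g @ step):
                    x = trial
                    ok = True
                    break
                t *= 0.5
            gnorm = float(np.max(np.abs(g)))
            if not ok or gnorm < max(1e-12, delta * 1e-3):
                break

    theta = _params_to_theta(x, st, d)
    return theta, penalized_objective(theta, S, penalty, spec)
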