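"""Tuning-parameter selection: information-criterion grids and stability selection.

The (lambda1, lambda2) pair is chosen by minimizing AIC, AICc or BIC over a
grid, where the degrees of freedom count each nonzero free off-diagonal of
the estimate once (upper triangle) plus the d diagonal entries -- the
standard graphical-lasso convention.  A coarse-grid-plus-refinement
heuristic keeps the number of fits small, and stability selection
(repeated half-sample refits) yields a more stable final graph.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import DynamicEdgeSet
from .likelihood import ExpressionPanel, PenaltyConfig, sample_covariance
from .solver import PrecisionEstimate, extract_edges, fit, refit_mle

__all__ = [
    "SelectionResult",
    "information_criterion",
    "default_grid",
    "grid_search",
    "heuristic_search",
    "stability_selection",
]

CRITERIA = ("aic", "aicc", "bic")


@dataclass
class SelectionResult:
    """Outcome of a (lambda1, lambda2) grid search."""

    grid: list[tuple[float, float]]
    scores: pd.DataFrame  # columns: lambda1, lambda2, df, edges, aic, aicc, bic, converged
    best: dict[str, tuple[float, float]]
    estimates: dict[tuple[float, float], PrecisionEstimate] = field(default=None, repr=False)
    stable_edges: DynamicEdgeSet | None = None
    frequencies: dict | None = None

    def best_estimate(self, criterion: str = "bic") -> PrecisionEstimate:
        return self.estimates[self.best[criterion.lower()]]


def degrees_of_freedom(est: PrecisionEstimate) -> int:
    """Nonzero free upper-triangle off-diagonals (at the edge tolerance) + d."""
    return len(extract_edges(est)) + est.spec.d


def information_criterion(est: PrecisionEstimate, S, n: int, which: str) -> float:
    """AIC / AICc / BIC of a fitted precision matrix.

    Uses the profile log-likelihood at mu-hat = ybar,
    ``l = n/2 (log|Theta| - Tr(S Theta))`` and df = selected edges + d.
    The AICc small-sample correction counts only the selected edges (the d
    diagonal entries are present in every candidate model, and counting
    them would leave AICc undefined whenever d >= n - 1, i.e. in exactly
    the high-dimensional regime the model targets); it returns +inf
    (flagged, excluded from the argmin) when the edge count reaches n - 1.
    """
    which = which.lower()
    if which not in CRITERIA:
        raise ValueError(f"criterion must be one of {CRITERIA}, got {which!r}")
    theta = est.theta_hat
    sign, logdet = np.linalg.slogdet(theta)
    if sign <= 0:
        raise np.linalg.LinAlgError("estimate is not positive definite")
    ll = 0.5 * n * (logdet - float(np.sum(np.asarray(S) * theta)))
    df = degrees_of_freedom(est)
    aic = -2.0 * ll + 2.0 * df
    if which == "aic":
        return aic
    if which == "bic":
        return -2.0 * ll + math.log(n) * df
    df_edges = df - est.spec.d
    if df_edges >= n - 1:
        return math.inf
    return aic + 2.0 * df_edges * (df_edges + 1) / (n - df_edges - 1)


def _profile_ll(theta, S, n: int) -> float:
    sign, logdet = np.linalg.slogdet(theta)
    if sign <= 0:
        raise np.linalg.LinAlgError("estimate is not positive definite")
    return 0.5 * n * (logdet - float(np.sum(np.asarray(S) * theta)))


def _ic_from_ll(ll: float, n_edges: int, d: int, n: int) -> dict:
    df = n_edges + d
    aic = -2.0 * ll + 2.0 * df
    aicc = math.inf if n_edges >= n - 1 else aic + 2.0 * n_edges * (n_edges + 1) / (n - n_edges - 1)
    return {"aic": aic, "aicc": aicc, "bic": -2.0 * ll + math.log(n) * df}


def default_grid(S, n1: int = 10, n2: int = 5) -> list[tuple[float, float]]:
    """Logarithmic (lambda1, lambda2) grid spanning the empty-to-full path.

    lambda1 takes ``n1`` log-spaced values in [0.01, 1] * max off-diagonal
    |S| (at the top of which the estimate is diagonal); lambda2 takes 0
    plus ``n2`` log-spaced values on the same scale.
    """
    S = np.asarray(S)
    off = np.abs(S - np.diag(np.diag(S)))
    smax = float(off.max()) if off.size else 1.0
    if smax <= 0:
        smax = 1.0
    l1s = np.geomspace(0.01 * smax, smax, n1)
    l2s = [0.0] + list(np.geomspace(0.01 * smax, smax, n2))
    return [(float(a), float(b)) for a in l1s for b in l2s]


def grid_search(
    panel: ExpressionPanel,
    grid: list[tuple[float, float]] | None = None,
    criteria=CRITERIA,
    *,
    penalize_diagonal: bool = False,
    keep_estimates: bool = True,
    refit_scores: bool = True,
    _refit_cache: dict | None = None,
    **fit_opts,
) -> SelectionResult:
    """Fit every (lambda1, lambda2) pair and score information criteria.

    Fits are warm-started along the grid (which does not change any
    solution beyond solver tolerance); non-converged fits are flagged and
    excluded from the argmin.  With ``refit_scores`` (the default) the
    likelihood entering the criteria is that of the support-constrained
    unpenalized refit of each fit's selected support, removing the l1
    shrinkage bias from model comparison; distinct supports along the grid
    are refit once and cached.
    """
    if grid is not None and len(grid) == 0:
        raise ValueError("grid must be non-empty")
    S, _ = sample_covariance(panel)
    if grid is None:
        grid = default_grid(S)
    fit_opts.setdefault("compute_kkt", False)
    refit_opts = {"tol": fit_opts.pop("refit_tol", 1e-6),
                  "max_iter": fit_opts.pop("refit_max_iter", 400)}
    criteria = [c.lower() for c in criteria]

    rows = []
    estimates: dict[tuple[float, float], PrecisionEstimate] = {}
    refit_cache = _refit_cache if _refit_cache is not None else {}
    warm = None
    for lam1, lam2 in grid:
        est = fit(S, panel.spec, PenaltyConfig(lam1, lam2, penalize_diagonal),
                  warm_start=warm, **fit_opts)
        warm = est.warm_start
        edges = extract_edges(est)
        if refit_scores:
            key = edges.edges
            if key not in refit_cache:
                refit_cache[key] = _profile_ll(
                    refit_mle(S, panel.spec, edges, theta0=est.theta_hat, **refit_opts),
                    S, panel.n)
            ll = refit_cache[key]
        else:
            ll = _profile_ll(est.theta_hat, S, panel.n)
        row = {"lambda1": lam1, "lambda2": lam2,
               "df": len(edges) + panel.spec.d, "edges": len(edges),
               "converged": est.converged,
               **_ic_from_ll(ll, len(edges), panel.spec.d, panel.n)}
        rows.append(row)
        if keep_estimates:
            estimates[(lam1, lam2)] = est
    scores = pd.DataFrame(rows)
    ok = scores[scores["converged"]]
    if ok.empty:
        raise RuntimeError("no fit on the grid converged")
    best = {}
    for c in criteria:
        finite = ok[np.isfinite(ok[c])]
        cand = finite if not finite.empty else ok
        i = cand[c].idxmin()
        best[c] = (float(scores.loc[i, "lambda1"]), float(scores.loc[i, "lambda2"]))
    return SelectionResult(grid=list(grid), scores=scores, best=best,
                           estimates=estimates if keep_estimates else None)


def _refine_values(v: float, values: np.ndarray) -> list[float]:
    """One halving step in log space around a selected grid value."""
    pos = sorted(set(x for x in values if x > 0))
    out = {v}
    if v == 0.0:
        if pos:
            out.add(pos[0] / 2.0)
        return sorted(out)
    if len(pos) >= 2:
        step = math.sqrt(pos[1] / pos[0])
    else:
        step = math.sqrt(10.0)
    out.update((v / step, v * step))
    return sorted(out)


def heuristic_search(
    panel: ExpressionPanel,
    criterion: str = "bic",
    *,
    n1: int = 6,
    n2: int = 3,
    refine: bool = True,
    **fit_opts,
) -> SelectionResult:
    """Coarse grid search followed by one local halving refinement.

    Scores all three criteria on the union of coarse and refined grids;
    refinement is driven by ``criterion``.
    """
    S, _ = sample_covariance(panel)
    coarse = default_grid(S, n1=n1, n2=n2)
    cache: dict = {}
    res = grid_search(panel, coarse, _refit_cache=cache, **fit_opts)
    if not refine:
        return res
    l1s = np.array(sorted({g[0] for g in coarse}))
    l2s = np.array(sorted({g[1] for g in coarse}))
    seen = set(coarse)
    extra = []
    anchors = {res.best[c.lower()] for c in (criterion, *CRITERIA)}
    for b1, b2 in anchors:
        for a in _refine_values(b1, l1s):
            for b in _refine_values(b2, l2s):
                if (a, b) not in seen:
                    extra.append((a, b))
                    seen.add((a, b))
    # support-gap pass: the edge-count path can collapse within one coarse
    # step, hiding the sparse fits AICc needs; bisect large support gaps.
    n = panel.n
    for l2v, sub in res.scores.groupby("lambda2"):
        sub = sub.sort_values("lambda1")
        e = sub["edges"].to_numpy()
        l1v = sub["lambda1"].to_numpy()
        for i in range(len(e) - 1):
            gap_spans_sparse = e[i] >= n - 1 and e[i + 1] < max(1, (n - 1) // 4)
            if gap_spans_sparse:
                for frac in (1.0 / 3.0, 2.0 / 3.0):
                    a = float(l1v[i] * (l1v[i + 1] / l1v[i]) ** frac)
                    if (a, float(l2v)) not in seen:
                        extra.append((a, float(l2v)))
                        seen.add((a, float(l2v)))
    if not extra:
        return res
    res2 = grid_search(panel, extra, _refit_cache=cache, **fit_opts)
    scores = pd.concat([res.scores, res2.scores], ignore_index=True)
    estimates = {**(res.estimates or {}), **(res2.estimates or {})}
    ok = scores[scores["converged"]]
    best = {}
    for c in CRITERIA:
        finite = ok[np.isfinite(ok[c])]
        cand = finite if not finite.empty else ok
        i = cand[c].idxmin()
        best[c] = (float(scores.loc[i, "lambda1"]), float(scores.loc[i, "lambda2"]))
    return SelectionResult(grid=res.grid + extra, scores=scores, best=best,
                           estimates=estimates or None)


def stability_selection(
    panel: ExpressionPanel,
    penalty: PenaltyConfig,
    B: int = 100,
    threshold: float = 0.8,
    seed: int | None = None,
    **fit_opts,
) -> tuple[DynamicEdgeSet, dict]:
    """Half-sample stability selection at a fixed penalty.

    Draws ``B`` subsamples of size floor(n/2) without replacement, refits,
    and keeps edges selected in at least ``threshold`` of the subsamples.
    Returns ``(stable_edges, frequency_by_edge)``.
    """
    if B < 2:
        raise ValueError("B must be >= 2")
    if panel.n < 4:
        raise ValueError("stability selection requires n >= 4")
    if not 0.5 < threshold <= 1.0:
        raise ValueError("threshold must lie in (0.5, 1]")
    rng = np.random.default_rng(seed)
    m = panel.n // 2
    counts: dict[tuple[int, int], int] = {}
    fit_opts.setdefault("compute_kkt", False)
    for _ in range(B):
        idx = rng.choice(panel.n, size=m, replace=False)
        sub = ExpressionPanel(panel.data[idx], panel.spec,
                              tuple(panel.replicate_ids[i] for i in idx))
        Ssub, _ = sample_covariance(sub)
        est = fit(Ssub, panel.spec, penalty, **fit_opts)
        for e in extract_edges(est).edges:
            counts[e] = counts.get(e, 0) + 1
    freqs = {e: c / B for e, c in counts.items()}
    stable = DynamicEdgeSet(panel.spec, [e for e, f in freqs.items() if f >= threshold])
    return stable, freqs
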