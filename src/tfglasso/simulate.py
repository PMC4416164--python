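"""Synthetic dynamic Gaussian graphical model generator.

Emulates replicated time-course expression panels: i.i.d. zero-mean
multivariate normal draws of dimension p*T whose precision matrix has the
block AR(k) structure -- sparse lag-0 gene networks that drift slowly
across time (a few random edge flips per step, optionally a burst of
rewiring at a regime change), constant same-gene lag-1 persistence
entries, and zero blocks beyond lag k.  Positive definiteness is enforced
by diagonal dominance (row absolute sum plus a margin), which preserves
the intended support exactly.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .core import DynamicEdgeSet, DynamicGraphSpec, ar_mask
from .likelihood import ExpressionPanel

__all__ = ["SimulationConfig", "make_truth", "sample_panel", "scenario_table2",
           "scenario_regime_change"]


@dataclass(frozen=True)
class SimulationConfig:
    """Generator settings for one synthetic dynamic GGM dataset.

    Parameters
    ----------
    spec : dimensions (p, T, k).
    n : number of replicates to draw.
    base_density : expected fraction of present lag-0 gene-pair edges.
    change_rate : number of random edge flips between consecutive times.
    regime_change_at : optional 1-based time s; a rewiring burst is applied
        on the transition s -> s+1.
    regime_burst_frac : fraction of active edges rewired at the regime
        change (that many random removals plus as many additions).
    edge_weight : largest magnitude of nonzero network entries (sign
        random per gene pair, value constant while an edge persists).
    edge_weight_spread : magnitudes are drawn uniformly from
        [edge_weight * (1 - spread), edge_weight]; 0 gives constant
        strength, larger values a graded mix of strong and weak edges.
    persistence_weight : value of the same-gene lag-1 entries.
    diag_boost : diagonal dominance margin added to each row's absolute sum.
    seed : RNG seed.
    """

    spec: DynamicGraphSpec
    n: int = 50
    base_density: float = 0.02
    change_rate: int = 1
    regime_change_at: int | None = None
    regime_burst_frac: float = 0.3
    edge_weight: float = 1.0
    edge_weight_spread: float = 0.75
    persistence_weight: float = 0.5
    diag_boost: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.base_density < 1.0:
            raise ValueError("base_density must lie in (0, 1)")
        if self.edge_weight == 0.0:
            raise ValueError("edge_weight must be nonzero")
        if not 0.0 <= self.edge_weight_spread < 1.0:
            raise ValueError("edge_weight_spread must lie in [0, 1)")
        if self.diag_boost <= 0.0:
            raise ValueError("diag_boost must be positive")
        if self.change_rate < 0:
            raise ValueError("change_rate must be non-negative")
        if self.regime_change_at is not None and not 1 <= self.regime_change_at < self.spec.T:
            raise ValueError("regime_change_at must satisfy 1 <= s < T")


def make_truth(config: SimulationConfig) -> tuple[np.ndarray, DynamicEdgeSet]:
    """Build a ground-truth precision matrix and its exact support.

    The initial lag-0 support is Bernoulli(base_density) over gene pairs;
    each subsequent time point flips ``change_rate`` randomly chosen pairs
    (plus a burst at the regime change).  Returns ``(Theta, truth_edges)``
    with Theta certified symmetric positive definite.
    """
    spec = config.spec
    p, T, k, d = spec.p, spec.T, spec.k, spec.d
    rng = np.random.default_rng(config.seed)
    pairs = list(itertools.combinations(range(p), 2))
    n_pairs = len(pairs)
    if n_pairs == 0 and config.base_density > 0 and p > 1:
        raise ValueError("no gene pairs available")

    lo = config.edge_weight * (1.0 - config.edge_weight_spread)
    weights = (rng.uniform(min(lo, config.edge_weight), max(lo, config.edge_weight), size=n_pairs)
               * rng.choice([-1.0, 1.0], size=n_pairs))
    active = rng.random(n_pairs) < config.base_density
    supports = [active.copy()]
    for s in range(1, T):
        active = active.copy()
        n_flips = config.change_rate
        if config.regime_change_at is not None and s == config.regime_change_at:
            burst = int(round(config.regime_burst_frac * active.sum()))
            on = np.flatnonzero(active)
            off = np.flatnonzero(~active)
            burst = min(burst, len(on), len(off))
            if burst > 0:
                active[rng.choice(on, size=burst, replace=False)] = False
                active[rng.choice(off, size=burst, replace=False)] = True
        if n_flips > n_pairs:
            raise ValueError("change_rate exceeds the number of gene pairs")
        if n_flips > 0 and n_pairs > 0:
            flip = rng.choice(n_pairs, size=n_flips, replace=False)
            active[flip] = ~active[flip]
        supports.append(active.copy())

    Theta = np.zeros((d, d))
    for s, act in enumerate(supports):
        for idx in np.flatnonzero(act):
            g, h = pairs[idx]
            i, j = s * p + g, s * p + h
            Theta[i, j] = Theta[j, i] = weights[idx]
    if k >= 1 and T >= 2:
        for s in range(T - 1):
            for g in range(p):
                i, j = s * p + g, (s + 1) * p + g
                Theta[i, j] = Theta[j, i] = config.persistence_weight
    rowsum = np.abs(Theta).sum(axis=1)
    Theta[np.diag_indices(d)] = rowsum + config.diag_boost

    assert not np.any(Theta[ar_mask(spec)]), "generator violated the AR(k) mask"
    ev_min = np.linalg.eigvalsh(Theta)[0]
    assert ev_min > 0, f"generated precision matrix not PD (min eig {ev_min})"

    rows, cols = np.where(np.triu(Theta, 1) != 0)
    return Theta, DynamicEdgeSet(spec, zip(rows.tolist(), cols.tolist()))


def sample_panel(Theta_true: np.ndarray, n: int, seed, spec: DynamicGraphSpec) -> ExpressionPanel:
    """Draw n i.i.d. replicates from N(0, Theta^{-1})."""
    Theta_true = np.asarray(Theta_true, dtype=float)
    try:
        L = np.linalg.cholesky(Theta_true)
    except np.linalg.LinAlgError as e:
        raise np.linalg.LinAlgError("Theta_true must be positive definite") from e
    rng = np.random.default_rng(seed)
    Z = rng.standard_normal((n, Theta_true.shape[0]))
    # y = L^{-T} z has covariance (L L^T)^{-1} = Theta^{-1}
    Y = np.linalg.solve(L.T, Z.T).T
    return ExpressionPanel(Y, spec)


def scenario_table2(
    p_values=(20, 40, 60, 80),
    reps: int = 100,
    master_seed: int = 0,
    n: int = 50,
    T: int = 3,
    k: int = 1,
    **config_overrides,
):
    """Datasets for the varying-network-size study: n=50, T=3, AR(1).

    Yields ``(config, Theta_true, truth_edges, panel)`` tuples, ``reps``
    datasets per network size, each with its own deterministic seed spawned
    from ``master_seed``.  In every scenario n < pT (fewer replicates than
    random variables).
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    ss = np.random.SeedSequence(master_seed)
    for p in p_values:
        spec = DynamicGraphSpec(p=p, T=T, k=k)
        for child in ss.spawn(reps):
            seed_truth, seed_panel = child.generate_state(2) >> np.uint32(1)
            config = SimulationConfig(spec=spec, n=n, seed=int(seed_truth),
                                      **config_overrides)
            Theta, edges = make_truth(config)
            panel = sample_panel(Theta, n, int(seed_panel), spec)
            yield config, Theta, edges, panel


def scenario_regime_change(
    reps: int = 20,
    master_seed: int = 0,
    p: int = 15,
    T: int = 6,
    n: int = 100,
    change_at: int = 3,
    **config_overrides,
):
    """Datasets with an abrupt network rewiring between two time points.

    Six time points by default with the regime change on the 3 -> 4
    transition and n = 100 replicates; the network is kept sparse and
    well conditioned (density 0.06, light persistence) so the burst of
    rewired edges, not estimation noise, dominates the transition
    profile.  Yields ``(config, Theta_true, truth_edges, panel)``.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    config_overrides.setdefault("base_density", 0.06)
    config_overrides.setdefault("persistence_weight", 0.25)
    spec = DynamicGraphSpec(p=p, T=T, k=1)
    ss = np.random.SeedSequence(master_seed)
    for child in ss.spawn(reps):
        seed_truth, seed_panel = child.generate_state(2) >> np.uint32(1)
        config = SimulationConfig(spec=spec, n=n, regime_change_at=change_at,
                                  seed=int(seed_truth), **config_overrides)
        Theta, edges = make_truth(config)
        panel = sample_panel(Theta, n, int(seed_panel), spec)
        yield config, Theta, edges, panel
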