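"""Vertex ordering and block structure of dynamic Gaussian graphical models.

A dynamic Gaussian graphical model places one vertex per (gene, time point)
pair, so a panel of ``p`` genes observed at ``T`` time points yields a
``d = p*T`` dimensional multivariate normal.  Vertices are sorted by time
point and, within a time point, by gene, which partitions the precision
matrix into blocks indexed by time lag ``l``:

* ``S_l^s`` -- "self-self" entries linking gene ``g`` at time ``s`` to the
  same gene at time ``s+l`` (for ``l=0`` this is the main diagonal);
* ``N_l^s`` -- "network" entries linking distinct genes between times ``s``
  and ``s+l``.

The autoregressive order ``k`` constrains every block at lag ``l > k`` to
zero: genes are conditionally uncorrelated across lags larger than ``k``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterator

import numpy as np

__all__ = [
    "DynamicGraphSpec",
    "BlockIndex",
    "DynamicEdgeSet",
    "BlockStructure",
    "vertex_index",
    "block_entries",
    "ar_mask",
    "iter_blocks",
    "block_structure",
]


@dataclass(frozen=True)
class DynamicGraphSpec:
    """Dimensions and labelling of a dynamic graph over genes x time points.

    Parameters
    ----------
    p : number of genes.
    T : number of time points.
    k : autoregressive order; precision blocks at lag > k are zero.
    gene_ids, time_labels : optional user-facing labels (defaults g1..gp,
        t1..tT).  Internally everything is 0-based ordinals.
    """

    p: int
    T: int
    k: int = 1
    gene_ids: tuple = field(default=None)
    time_labels: tuple = field(default=None)

    def __post_init__(self):
        if self.p < 1:
            raise ValueError(f"p must be >= 1, got {self.p}")
        if self.T < 1:
            raise ValueError(f"T must be >= 1, got {self.T}")
        if not 0 <= self.k <= self.T - 1:
            raise ValueError(f"k must satisfy 0 <= k <= T-1, got k={self.k}, T={self.T}")
        genes = self.gene_ids
        if genes is None:
            genes = tuple(f"g{i + 1}" for i in range(self.p))
        else:
            genes = tuple(str(g) for g in genes)
        times = self.time_labels
        if times is None:
            times = tuple(f"t{i + 1}" for i in range(self.T))
        else:
            times = tuple(str(t) for t in times)
        if len(genes) != self.p or len(set(genes)) != self.p:
            raise ValueError("gene_ids must contain exactly p distinct labels")
        if len(times) != self.T or len(set(times)) != self.T:
            raise ValueError("time_labels must contain exactly T distinct labels")
        object.__setattr__(self, "gene_ids", genes)
        object.__setattr__(self, "time_labels", times)

    @property
    def d(self) -> int:
        """Total dimension p*T of the model."""
        return self.p * self.T

    def vertex_index(self, g: int, s: int) -> int:
        return vertex_index(g, s, self)

    def unravel(self, idx: int) -> tuple[int, int]:
        """Inverse of :func:`vertex_index`: flat ordinal -> (gene, time)."""
        if not 0 <= idx < self.d:
            raise IndexError(f"vertex index {idx} out of range for d={self.d}")
        return idx % self.p, idx // self.p

    def vertex_label(self, idx: int) -> tuple[str, str]:
        g, s = self.unravel(idx)
        return self.gene_ids[g], self.time_labels[s]


def vertex_index(g: int, s: int, spec: DynamicGraphSpec) -> int:
    """Flat ordinal of gene ``g`` (0-based) at time ``s`` (0-based)."""
    if not 0 <= g < spec.p:
        raise IndexError(f"gene ordinal {g} out of range [0, {spec.p})")
    if not 0 <= s < spec.T:
        raise IndexError(f"time ordinal {s} out of range [0, {spec.T})")
    return s * spec.p + g


@dataclass(frozen=True)
class BlockIndex:
    """One block of the precision matrix: lag ``l``, start time ``s``, kind.

    ``s`` is 1-based (``1 <= s <= T-l``) to match the usual notation
    ``N_l^s`` / ``S_l^s``; ``kind`` is ``"N"`` (distinct-gene network
    entries) or ``"S"`` (same-gene persistence entries).
    """

    l: int
    s: int
    kind: str

    def __post_init__(self):
        if self.kind not in ("N", "S"):
            raise ValueError(f"kind must be 'N' or 'S', got {self.kind!r}")
        if self.l < 0:
            raise IndexError(f"lag must be non-negative, got {self.l}")
        if self.s < 1:
            raise IndexError(f"block time index is 1-based, got {self.s}")


def block_entries(b: BlockIndex, spec: DynamicGraphSpec) -> set[tuple[int, int]]:
    """Matrix positions of block ``b`` under the vertex ordering.

    Positions are returned with ``row < col``, except the lag-0 S block
    (the main diagonal) which returns ``row == col``.
    """
    if b.l > spec.T - 1 or b.s > spec.T - b.l:
        raise IndexError(f"block {b} out of range for T={spec.T}")
    t0, t1 = b.s - 1, b.s - 1 + b.l
    if b.kind == "S":
        return {(vertex_index(g, t0, spec), vertex_index(g, t1, spec)) for g in range(spec.p)}
    if b.l == 0:
        return {
            (vertex_index(g, t0, spec), vertex_index(h, t0, spec))
            for g, h in itertools.combinations(range(spec.p), 2)
        }
    return {
        (vertex_index(g, t0, spec), vertex_index(h, t1, spec))
        for g in range(spec.p)
        for h in range(spec.p)
        if g != h
    }


def iter_blocks(spec: DynamicGraphSpec) -> Iterator[BlockIndex]:
    """All valid blocks (every lag, including those beyond k)."""
    for l in range(spec.T):
        for s in range(1, spec.T - l + 1):
            yield BlockIndex(l, s, "S")
            if spec.p > 1:
                yield BlockIndex(l, s, "N")


def ar_mask(spec: DynamicGraphSpec) -> np.ndarray:
    """Boolean d x d mask, True where the AR(k) constraint forces zeros.

    True exactly on entries whose time lag exceeds ``k``; symmetric; the
    main diagonal is never masked.
    """
    times = np.arange(spec.d) // spec.p
    return np.abs(times[:, None] - times[None, :]) > spec.k


class DynamicEdgeSet:
    """A set of undirected edges of a dynamic graph.

    Edges are stored as frozenset of ``(i, j)`` flat vertex-index pairs with
    ``i < j``.  No self loops; every edge must respect the AR(k) bound
    ``|s - s'| <= k`` of the owning spec.
    """

    def __init__(self, spec: DynamicGraphSpec, edges=()):
        pairs = set()
        for i, j in edges:
            i, j = int(i), int(j)
            if i == j:
                raise ValueError(f"self-loop at vertex {i}")
            if i > j:
                i, j = j, i
            if not 0 <= i < spec.d and 0 <= j < spec.d:
                raise ValueError(f"edge ({i},{j}) out of range for d={spec.d}")
            if abs(j // spec.p - i // spec.p) > spec.k:
                raise ValueError(
                    f"edge ({i},{j}) spans lag {abs(j // spec.p - i // spec.p)} > k={spec.k}"
                )
            pairs.add((i, j))
        self.spec = spec
        self.edges = frozenset(pairs)

    @classmethod
    def from_matrix(cls, theta: np.ndarray, spec: DynamicGraphSpec, tol: float = 0.0) -> "DynamicEdgeSet":
        """Edges where ``|theta_ij| > tol * max(1, sqrt(|theta_ii theta_jj|))``."""
        theta = np.asarray(theta, dtype=float)
        if theta.shape != (spec.d, spec.d):
            raise ValueError(f"theta must be {spec.d}x{spec.d}")
        dg = np.sqrt(np.abs(np.diag(theta)[:, None] * np.diag(theta)[None, :]))
        scale = np.maximum(1.0, dg)
        hit = np.abs(theta) > tol * scale
        hit &= ~ar_mask(spec)
        rows, cols = np.where(np.triu(hit, 1))
        return cls(spec, zip(rows.tolist(), cols.tolist()))

    def block_edges(self, l: int, s: int) -> set[tuple[int, int]]:
        """Edges inside network block N_l^s, as 1-based gene pairs.

        Lag-0 pairs are unordered ``(g, g')`` with ``g < g'``; for ``l > 0``
        the first gene is at time ``s`` and the second at ``s + l``.
        """
        out = set()
        p = self.spec.p
        for i, j in self.edges:
            gi, si = i % p, i // p
            gj, sj = j % p, j // p
            if si == s - 1 and sj == s - 1 + l and gi != gj:
                if l == 0:
                    out.add((min(gi, gj) + 1, max(gi, gj) + 1))
                else:
                    out.add((gi + 1, gj + 1))
        return out

    def transition_counts(self) -> list[int]:
        """Symmetric-difference size of consecutive lag-0 networks N_0^s."""
        return [
            len(self.block_edges(0, s) ^ self.block_edges(0, s + 1))
            for s in range(1, self.spec.T)
        ]

    def labelled(self) -> list[tuple[str, str, str, str]]:
        """Edges as (gene_a, time_a, gene_b, time_b) label tuples."""
        return [self.spec.vertex_label(i) + self.spec.vertex_label(j) for i, j in sorted(self.edges)]

    def __len__(self):
        return len(self.edges)

    def __contains__(self, pair):
        i, j = pair
        return (min(i, j), max(i, j)) in self.edges

    def __iter__(self):
        return iter(sorted(self.edges))

    def __eq__(self, other):
        return isinstance(other, DynamicEdgeSet) and self.edges == other.edges

    def __repr__(self):
        return f"DynamicEdgeSet({len(self.edges)} edges, d={self.spec.d})"


class BlockStructure:
    """Precomputed index arrays for the free (unmasked) entries of Theta.

    Attributes
    ----------
    rows, cols : flat arrays of the free upper-triangle off-diagonal
        positions (AR(k)-masked positions excluded).
    n_chains : dict ``lag -> (n_pairs, T-lag)`` integer array of indices
        into rows/cols; each row is one gene pair's network-entry chain
        across start times, the unit the fused penalty acts along.
    s_chains : like n_chains but for same-gene persistence entries at lags
        1..k (never fused).
    """

    def __init__(self, spec: DynamicGraphSpec):
        self.spec = spec
        p, T, k = spec.p, spec.T, spec.k
        pos: dict[tuple[int, int], int] = {}
        rows, cols = [], []

        def add(i, j):
            pos[(i, j)] = len(rows)
            rows.append(i)
            cols.append(j)

        self.n_chains: dict[int, np.ndarray] = {}
        self.s_chains: dict[int, np.ndarray] = {}
        for l in range(k + 1):
            if p > 1:
                if l == 0:
                    gene_pairs = list(itertools.combinations(range(p), 2))
                else:
                    gene_pairs = [(g, h) for g in range(p) for h in range(p) if g != h]
                chains = np.empty((len(gene_pairs), T - l), dtype=np.int64)
                for c, (g, h) in enumerate(gene_pairs):
                    for s in range(T - l):
                        i, j = s * p + g, (s + l) * p + h
                        add(i, j)
                        chains[c, s] = pos[(i, j)]
                self.n_chains[l] = chains
            if l >= 1:
                chains = np.empty((p, T - l), dtype=np.int64)
                for g in range(p):
                    for s in range(T - l):
                        i, j = s * p + g, (s + l) * p + g
                        add(i, j)
                        chains[g, s] = pos[(i, j)]
                self.s_chains[l] = chains

        self.rows = np.asarray(rows, dtype=np.int64)
        self.cols = np.asarray(cols, dtype=np.int64)
        self.position_index = pos

    @property
    def n_free(self) -> int:
        """Number of free off-diagonal upper-triangle positions."""
        return len(self.rows)

    def gather(self, M: np.ndarray) -> np.ndarray:
        """Free upper-triangle entries of a d x d matrix as a flat vector."""
        return M[self.rows, self.cols]

    def scatter(self, values: np.ndarray) -> np.ndarray:
        """Symmetric d x d matrix (zero diagonal) from a free-entry vector."""
        M = np.zeros((self.spec.d, self.spec.d))
        M[self.rows, self.cols] = values
        M[self.cols, self.rows] = values
        return M


@lru_cache(maxsize=64)
def _cached_structure(spec: DynamicGraphSpec) -> BlockStructure:
    return BlockStructure(spec)


def block_structure(spec: DynamicGraphSpec) -> BlockStructure:
    """Shared, cached :class:`BlockStructure` for a spec."""
    return _cached_structure(spec)
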