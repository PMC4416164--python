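"""Readers and writers for expression panels, matrices and dynamic graphs.

Panels travel as delimited text in either layout:

* wide -- one row per replicate, columns named ``gene@time`` in any order
  (an optional ``replicate`` column carries replicate ids);
* long -- columns ``replicate, gene, time, value``, one row per cell.

Graphs are written as tab-separated edge lists (gene_a, time_a, gene_b,
time_b, lag, theta_value) and as GraphML with gene/time node attributes;
per-consecutive-time intersection and change views of the lag-0 networks
are emitted alongside.  Missing or duplicate cells are rejected, never
imputed.
"""

from __future__ import annotations

import hashlib
import json
import sys
import time
from dataclasses import dataclass, asdict
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .core import DynamicEdgeSet, DynamicGraphSpec
from .likelihood import ExpressionPanel

__all__ = [
    "read_panel",
    "write_panel",
    "read_matrix",
    "write_matrix",
    "write_graph",
    "read_edge_list",
    "transition_views",
    "RunManifest",
]


def _sorted_times(times: list[str]) -> list[str]:
    try:
        return sorted(times, key=float)
    except ValueError:
        return times  # keep first-appearance order for non-numeric labels


def _sep(path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def read_panel(path, layout: str = "auto", spec: DynamicGraphSpec | None = None) -> ExpressionPanel:
    """Read a replicate-by-gene-by-time panel from a delimited text file.

    ``layout`` is ``wide``, ``long`` or ``auto`` (detected from the
    header).  Every replicate x gene x time cell must be present exactly
    once; offending cells are named in the error.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep(path))
    if layout == "auto":
        layout = "long" if {"replicate", "gene", "time", "value"} <= set(df.columns) else "wide"

    if layout == "wide":
        rep_col = None
        for cand in ("replicate", "replicate_id"):
            if cand in df.columns:
                rep_col = cand
        value_cols = [c for c in df.columns if c != rep_col]
        parsed = []
        for c in value_cols:
            if "@" not in c:
                raise ValueError(f"wide column {c!r} is not of the form gene@time")
            g, t = c.rsplit("@", 1)
            parsed.append((c, g, t))
        genes = list(dict.fromkeys(g for _, g, _ in parsed))
        times = _sorted_times(list(dict.fromkeys(t for _, _, t in parsed)))
        long = df.melt(id_vars=[rep_col] if rep_col else None,
                       value_vars=value_cols, var_name="col", value_name="value")
        long[["gene", "time"]] = long["col"].str.rsplit("@", n=1, expand=True)
        if rep_col is None:
            reps_per_col = len(df)
            long["replicate"] = np.tile(np.arange(1, reps_per_col + 1),
                                        len(value_cols)).astype(str)
        else:
            long = long.rename(columns={rep_col: "replicate"})
        long = long[["replicate", "gene", "time", "value"]]
    else:
        missing_cols = {"replicate", "gene", "time", "value"} - set(df.columns)
        if missing_cols:
            raise ValueError(f"long layout requires columns {sorted(missing_cols)}")
        long = df[["replicate", "gene", "time", "value"]].copy()
        genes = list(dict.fromkeys(long["gene"].astype(str)))
        times = _sorted_times(list(dict.fromkeys(long["time"].astype(str))))

    long["replicate"] = long["replicate"].astype(str)
    long["gene"] = long["gene"].astype(str)
    long["time"] = long["time"].astype(str)
    vals = pd.to_numeric(long["value"], errors="coerce")
    if vals.isna().any():
        bad = long.index[vals.isna()].tolist()[:10]
        raise ValueError(f"non-numeric values at rows {bad}")
    long["value"] = vals

    if spec is not None:
        genes, times = list(spec.gene_ids), list(spec.time_labels)
    reps = list(dict.fromkeys(long["replicate"]))

    dup = long.duplicated(subset=["replicate", "gene", "time"])
    if dup.any():
        offenders = long.loc[dup, ["replicate", "gene", "time"]].head(10).values.tolist()
        raise ValueError(f"duplicate cells: {offenders}")
    expected = len(reps) * len(genes) * len(times)
    if len(long) != expected:
        have = set(map(tuple, long[["replicate", "gene", "time"]].values))
        missing = [(r, g, t) for r in reps for g in genes for t in times
                   if (r, g, t) not in have][:10]
        raise ValueError(f"missing cells (first {len(missing)}): {missing}")

    out_spec = spec or DynamicGraphSpec(p=len(genes), T=len(times), k=min(1, len(times) - 1),
                                        gene_ids=tuple(genes), time_labels=tuple(times))
    pivot = long.pivot_table(index="replicate", columns=["time", "gene"], values="value")
    pivot = pivot.reindex(index=reps,
                          columns=pd.MultiIndex.from_product([times, genes]))
    return ExpressionPanel(pivot.to_numpy(), out_spec, tuple(reps))


def write_panel(panel: ExpressionPanel, path, layout: str = "wide") -> None:
    path = Path(path)
    spec = panel.spec
    if layout == "wide":
        cols = [f"{g}@{t}" for t in spec.time_labels for g in spec.gene_ids]
        df = pd.DataFrame(panel.data, columns=cols)
        df.insert(0, "replicate", panel.replicate_ids)
    elif layout == "long":
        rows = []
        for r, rep in enumerate(panel.replicate_ids):
            for j in range(spec.d):
                g, t = spec.vertex_label(j)
                rows.append((rep, g, t, panel.data[r, j]))
        df = pd.DataFrame(rows, columns=["replicate", "gene", "time", "value"])
    else:
        raise ValueError(f"unknown layout {layout!r}")
    df.to_csv(path, sep=_sep(path), index=False, float_format="%.12g")


def write_matrix(M: np.ndarray, path, labels=None) -> None:
    df = pd.DataFrame(M, index=labels, columns=labels)
    df.to_csv(path, sep=_sep(path), float_format="%.12g")


def read_matrix(path) -> np.ndarray:
    return pd.read_csv(path, sep=_sep(path), index_col=0).to_numpy()


def transition_views(edges: DynamicEdgeSet) -> dict:
    """Intersection and change views of consecutive lag-0 networks.

    For every transition s -> s+1 returns the shared gene pairs, the pairs
    removed, and the pairs added (1-based gene ordinals).
    """
    views = {}
    for s in range(1, edges.spec.T):
        a, b = edges.block_edges(0, s), edges.block_edges(0, s + 1)
        views[(s, s + 1)] = {
            "intersection": a & b,
            "removed": a - b,
            "added": b - a,
        }
    return views


def write_graph(edges: DynamicEdgeSet, path, theta: np.ndarray | None = None,
                fmt: str = "tsv") -> None:
    """Write a dynamic edge set as an edge list TSV or GraphML.

    The TSV writer also emits ``<stem>_transitions.tsv`` with the
    intersection/removed/added views of consecutive lag-0 networks.
    """
    path = Path(path)
    spec = edges.spec
    if fmt == "tsv":
        rows = []
        for i, j in edges:
            ga, ta = spec.vertex_label(i)
            gb, tb = spec.vertex_label(j)
            lag = abs(j // spec.p - i // spec.p)
            val = float(theta[i, j]) if theta is not None else np.nan
            rows.append((ga, ta, gb, tb, lag, val))
        df = pd.DataFrame(rows, columns=["gene_a", "time_a", "gene_b", "time_b",
                                         "lag", "theta_value"])
        df.to_csv(path, sep="\t", index=False, float_format="%.12g")
        trows = []
        for (s0, s1), v in transition_views(edges).items():
            for kind in ("intersection", "removed", "added"):
                for g, h in sorted(v[kind]):
                    trows.append((s0, s1, kind, spec.gene_ids[g - 1], spec.gene_ids[h - 1]))
        pd.DataFrame(trows, columns=["time_from", "time_to", "view", "gene_a", "gene_b"]).to_csv(
            path.with_name(path.stem + "_transitions.tsv"), sep="\t", index=False)
    elif fmt == "graphml":
        g = nx.Graph()
        for idx in range(spec.d):
            gene, tlab = spec.vertex_label(idx)
            g.add_node(idx, gene=gene, time=tlab)
        for i, j in edges:
            w = float(theta[i, j]) if theta is not None else 1.0
            g.add_edge(i, j, theta_value=w)
        nx.write_graphml(g, path)
    else:
        raise ValueError(f"unknown format {fmt!r}")


def read_edge_list(path, spec: DynamicGraphSpec) -> DynamicEdgeSet:
    df = pd.read_csv(path, sep="\t")
    gi = {g: i for i, g in enumerate(spec.gene_ids)}
    ti = {t: i for i, t in enumerate(spec.time_labels)}
    pairs = []
    for _, r in df.iterrows():
        i = ti[str(r["time_a"])] * spec.p + gi[str(r["gene_a"])]
        j = ti[str(r["time_b"])] * spec.p + gi[str(r["gene_b"])]
        pairs.append((i, j))
    return DynamicEdgeSet(spec, pairs)


@dataclass
class RunManifest:
    """Reproducibility record emitted by every CLI run."""

    command: str
    parameters: dict
    seed: int | None
    version: str
    input_digests: dict
    timestamp: str

    @classmethod
    def create(cls, command: str, parameters: dict, seed=None, inputs=()) -> "RunManifest":
        from . import __version__

        digests = {}
        for p in inputs:
            p = Path(p)
            digests[str(p)] = hashlib.sha256(p.read_bytes()).hexdigest()
        return cls(command=command, parameters=parameters, seed=seed,
                   version=__version__, input_digests=digests,
                   timestamp=time.strftime("%Y-%m-%dT%H:%M:%S"))

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, default=str) + "\n")
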