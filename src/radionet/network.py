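"""Cluster-cluster correlation adjacency and the weighted radiomic graph.

The adjacency entry (i, j) is the Pearson correlation between the two
clusters' statistic vectors, clipped to the [0, 1] range (no correlation ->
no edge). Edges carry ``weight = COR`` and ``length = D = 1 - COR``; the
geodesic distance between nodes is the shortest path over edge lengths.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .clustering import ClusterProfile

__all__ = [
    "AdjacencyMatrix",
    "RadiomicGraph",
    "correlation_matrix",
    "auto_threshold",
    "build_graph",
    "geodesic_distances",
]


@dataclass
class AdjacencyMatrix:
    """Symmetric cluster-correlation matrix with unit diagonal, entries in [0, 1]."""

    cor: np.ndarray
    cluster_ids: list[int]

    def __post_init__(self) -> None:
        self.cor = np.asarray(self.cor, dtype=float)
        n = len(self.cluster_ids)
        if self.cor.shape != (n, n):
            raise ValueError("cor must be square over cluster_ids")
        if not np.allclose(self.cor, self.cor.T, atol=1e-12):
            raise ValueError("adjacency must be symmetric")
        if not np.allclose(np.diag(self.cor), 1.0, atol=1e-12):
            raise ValueError("adjacency diagonal must be 1")
        if self.cor.min() < -1e-12 or self.cor.max() > 1 + 1e-12:
            raise ValueError("adjacency entries must lie in [0, 1]")
        self.cor = np.clip(self.cor, 0.0, 1.0)

    @property
    def n(self) -> int:
        return self.cor.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.cor, index=self.cluster_ids, columns=self.cluster_ids)


@dataclass
class RadiomicGraph:
    """Weighted graph over clusters: edge iff COR > edge_threshold, with
    ``weight = COR`` and ``length = 1 - COR`` on every edge."""

    graph: nx.Graph
    edge_threshold: float
    cluster_ids: list[int]

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_set(self) -> set[tuple[int, int]]:
        return {tuple(sorted(e)) for e in self.graph.edges()}

    def to_edge_frame(self) -> pd.DataFrame:
        rows = [
            (u, v, d["weight"], d["length"])
            for u, v, d in sorted(self.graph.edges(data=True))
        ]
        return pd.DataFrame(rows, columns=["source", "target", "weight", "length"])


def _transform_profiles(profiles: list[ClusterProfile], mode: str) -> np.ndarray:
    p = np.vstack([pr.stats for pr in profiles])
    if mode == "mean":
        p = p[:, 0::6]  # mean statistic of every feature
    elif mode not in ("zscore", "raw"):
        raise ValueError(f"unknown correlation mode {mode!r}")
    if mode in ("zscore", "mean"):
        mu = p.mean(axis=0)
        sd = p.std(axis=0)
        sd = np.where(sd == 0, 1.0, sd)
        p = (p - mu) / sd
    return p


def correlation_matrix(
    profiles: list[ClusterProfile], mode: str = "raw"
) -> AdjacencyMatrix:
    """Pearson correlation between cluster statistic vectors, negatives
    clipped to 0.

    ``mode``: ``"raw"`` (default) correlates the untransformed statistic
    vectors — the heterogeneous scales of the statistics make this behave
    like a (negated) profile distance, which is what lets intermediate
    tissue sit *between* the two tissue blocks rather than aligning with
    one of them; ``"zscore"`` z-scores every statistic across clusters
    before correlating (direction-like similarity); ``"mean"`` uses only
    the per-feature means (z-scored).

    Identical profiles correlate at exactly 1. A cluster whose transformed
    statistic vector has zero variance (correlation undefined) raises unless
    all profiles are identical.
    """
    if len(profiles) < 2:
        raise ValueError("need at least 2 cluster profiles")
    lengths = {pr.stats.shape[0] for pr in profiles}
    if len(lengths) != 1:
        raise ValueError("profiles have unequal statistic vector lengths")

    raw = np.vstack([pr.stats for pr in profiles])
    x = _transform_profiles(profiles, mode)
    n = x.shape[0]
    sd = x.std(axis=1)

    identical = np.isclose(raw[:, None, :], raw[None, :, :], atol=1e-12).all(axis=2)

    for i in np.nonzero(sd == 0)[0]:
        if not identical[i].all():
            raise ValueError(
                f"cluster {profiles[i].cluster_id} has a zero-variance statistic "
                "vector; correlation is undefined"
            )

    if (sd == 0).all():
        cor = np.ones((n, n))
    else:
        with np.errstate(invalid="ignore"):
            cor = np.corrcoef(x)
        cor = np.nan_to_num(cor, nan=0.0)
        cor[identical] = 1.0
    cor = np.clip(cor, 0.0, 1.0)
    np.fill_diagonal(cor, 1.0)
    cor = (cor + cor.T) / 2.0
    return AdjacencyMatrix(cor=cor, cluster_ids=[pr.cluster_id for pr in profiles])


def auto_threshold(adj: AdjacencyMatrix, target_density: float = 0.20) -> float:
    """Edge threshold achieving at most the requested edge density.

    Picks the cut between the m-th and (m+1)-th largest off-diagonal
    correlations, where ``m = floor(target_density * n_pairs)`` (so very
    small graphs may legitimately end up with no edges); ties at the cut
    admit all tied pairs.
    """
    if not 0 < target_density <= 1:
        raise ValueError("target_density must be in (0, 1]")
    iu = np.triu_indices(adj.n, k=1)
    vals = np.sort(adj.cor[iu])[::-1]
    m = int(np.floor(target_density * len(vals)))
    if m <= 0:
        return float(min(1.0 - 1e-9, vals[0] + 1e-9)) if len(vals) else 0.999
    if m >= len(vals):
        t = vals[-1] - 1e-9
    else:
        t = (vals[m - 1] + vals[m]) / 2.0 if vals[m] < vals[m - 1] else vals[m - 1] - 1e-9
    return float(min(max(t, 0.0), 1.0 - 1e-12))


def build_graph(
    adj: AdjacencyMatrix,
    edge_threshold: float = 0.5,
    sizes: dict[int, int] | list[int] | None = None,
) -> RadiomicGraph:
    """Cast an edge between every cluster pair with COR strictly above the
    threshold; the graph may be disconnected."""
    if not 0 <= edge_threshold < 1:
        raise ValueError(f"edge_threshold must be in [0, 1); got {edge_threshold}")
    g = nx.Graph()
    ids = adj.cluster_ids
    if sizes is None:
        size_of = {cid: 1 for cid in ids}
    elif isinstance(sizes, dict):
        size_of = {cid: int(sizes[cid]) for cid in ids}
    else:
        size_of = {cid: int(s) for cid, s in zip(ids, sizes)}
    for cid in ids:
        g.add_node(cid, size=size_of[cid])
    for a in range(adj.n):
        for b in range(a + 1, adj.n):
            c = adj.cor[a, b]
            if c > edge_threshold:
                g.add_edge(ids[a], ids[b], weight=float(c), length=float(1.0 - c))
    return RadiomicGraph(graph=g, edge_threshold=float(edge_threshold), cluster_ids=list(ids))


def geodesic_distances(rgraph: RadiomicGraph) -> pd.DataFrame:
    """All-pairs shortest-path distance over edge lengths ``D = 1 - COR``;
    ``inf`` between disconnected nodes, 0 on the diagonal."""
    ids = rgraph.cluster_ids
    idx = {cid: i for i, cid in enumerate(ids)}
    n = len(ids)
    out = np.full((n, n), np.inf)
    np.fill_diagonal(out, 0.0)
    for src, dists in nx.all_pairs_dijkstra_path_length(rgraph.graph, weight="length"):
        for dst, d in dists.items():
            out[idx[src], idx[dst]] = d
    return pd.DataFrame(out, index=ids, columns=ids)
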