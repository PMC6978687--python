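"""Node-level topology: normalized metrics, role taxonomy, subnetwork
extraction, intra-subnetwork degree hierarchy, and the cluster-number
overfitting sweep.

Roles follow a strict precedence ``bridge > hub > authority >
cluster_member > unclassified``: a bridge couples high betweenness with low
degree; a hub is a very-high-degree aggregator; an authority is a node in
the upper degree quantile; a cluster member sits in a locally dense
neighbourhood (high clustering coefficient).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .clustering import ClusterAssignment, cluster_profiles, cluster_voxels
from .network import RadiomicGraph, auto_threshold, build_graph, correlation_matrix
from .volume_stack import VoxelTable

__all__ = [
    "NodeMetrics",
    "NodeClassification",
    "ClassificationThresholds",
    "SweepConfig",
    "KSweepReport",
    "node_metrics",
    "classify_nodes",
    "extract_subnetworks",
    "degree_stratify",
    "k_sweep",
]

ROLES = ("bridge", "hub", "authority", "cluster_member", "unclassified")


def _minmax(values: np.ndarray) -> np.ndarray:
    lo, hi = values.min(), values.max()
    if hi - lo == 0:
        return np.zeros_like(values, dtype=float)
    return (values - lo) / (hi - lo)


@dataclass
class NodeMetrics:
    """Raw and min-max-normalized per-node metrics, aligned with ``nodes``."""

    nodes: list[int]
    degree_raw: np.ndarray
    degree: np.ndarray
    cc: np.ndarray
    betweenness_raw: np.ndarray
    betweenness: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "degree_raw": self.degree_raw,
                "degree": self.degree,
                "cc": self.cc,
                "betweenness_raw": self.betweenness_raw,
                "betweenness": self.betweenness,
            },
            index=pd.Index(self.nodes, name="cluster_id"),
        )


@dataclass
class ClassificationThresholds:
    """Cut-offs on min-max-normalized metrics. ``cc_hi``, ``bet_hi`` and
    ``deg_lo`` are the published working points; ``deg_hi`` (hub) and
    ``authority_quantile`` are configurable extrapolations."""

    cc_hi: float = 0.75
    bet_hi: float = 0.80
    deg_lo: float = 0.20
    deg_hi: float = 0.80
    authority_quantile: float = 0.75

    def validate(self) -> None:
        for name in ("cc_hi", "bet_hi", "deg_lo", "deg_hi", "authority_quantile"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"threshold {name}={v} outside [0, 1]")


@dataclass
class NodeClassification:
    """One role per node plus (after subnetwork extraction) a subnetwork id.

    ``subnetwork_id`` is None for bridges; components smaller than the major
    threshold are flagged as satellite groups.
    """

    nodes: list[int]
    role: dict[int, str]
    subnetwork_id: dict[int, int | None] = field(default_factory=dict)
    satellite: dict[int, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for node in self.nodes:
            if self.role.get(node) not in ROLES:
                raise ValueError(f"node {node} has invalid role {self.role.get(node)!r}")

    def nodes_with_role(self, role: str) -> list[int]:
        return [n for n in self.nodes if self.role[n] == role]

    def subnetwork_nodes(self, sid: int) -> list[int]:
        return [n for n in self.nodes if self.subnetwork_id.get(n) == sid]

    def major_subnetworks(self) -> list[int]:
        sids = {
            sid
            for n, sid in self.subnetwork_id.items()
            if sid is not None and not self.satellite.get(n, False)
        }
        return sorted(sids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "role": [self.role[n] for n in self.nodes],
                "subnetwork_id": [self.subnetwork_id.get(n) for n in self.nodes],
                "satellite": [bool(self.satellite.get(n, False)) for n in self.nodes],
            },
            index=pd.Index(self.nodes, name="cluster_id"),
        )


def node_metrics(rgraph: RadiomicGraph) -> NodeMetrics:
    """Weighted degree (strength), unweighted local clustering coefficient,
    and betweenness over shortest paths with edge lengths ``D = 1 - COR``.

    Betweenness is first normalized by ``(n-1)(n-2)/2``; degree and
    betweenness are then min-max scaled over nodes to [0, 1].
    """
    g = rgraph.graph
    if g.number_of_nodes() < 2:
        raise ValueError("node metrics require a graph with at least 2 nodes")
    nodes = list(g.nodes())
    degree_raw = np.array([g.degree(n, weight="weight") for n in nodes], dtype=float)
    cc = np.array([nx.clustering(g, n) for n in nodes], dtype=float)
    bet = nx.betweenness_centrality(g, normalized=True, weight="length")
    betweenness_raw = np.array([bet[n] for n in nodes], dtype=float)
    return NodeMetrics(
        nodes=nodes,
        degree_raw=degree_raw,
        degree=_minmax(degree_raw),
        cc=cc,
        betweenness_raw=betweenness_raw,
        betweenness=_minmax(betweenness_raw),
    )


def classify_nodes(
    metrics: NodeMetrics,
    thresholds: ClassificationThresholds | None = None,
) -> NodeClassification:
    """Assign exactly one role per node with precedence
    ``bridge > hub > authority > cluster_member > unclassified``."""
    thr = thresholds or ClassificationThresholds()
    thr.validate()
    deg = metrics.degree
    authority_cut = float(np.quantile(deg, thr.authority_quantile))
    role: dict[int, str] = {}
    for i, node in enumerate(metrics.nodes):
        if metrics.betweenness[i] > thr.bet_hi and deg[i] < thr.deg_lo:
            role[node] = "bridge"
        elif deg[i] > thr.deg_hi:
            role[node] = "hub"
        elif deg[i] > authority_cut and deg[i] > 0:
            role[node] = "authority"
        elif metrics.cc[i] > thr.cc_hi:
            role[node] = "cluster_member"
        else:
            role[node] = "unclassified"
    return NodeClassification(nodes=list(metrics.nodes), role=role)


def extract_subnetworks(
    rgraph: RadiomicGraph,
    classification: NodeClassification,
    min_size: int = 3,
) -> NodeClassification:
    """Remove bridge nodes; the remaining connected components become
    subnetworks, ids assigned by descending size (1-based). Components with
    fewer than ``min_size`` nodes are kept but flagged as satellite groups;
    bridges get ``subnetwork_id = None``."""
    bridges = set(classification.nodes_with_role("bridge"))
    residual = rgraph.graph.subgraph([n for n in rgraph.graph.nodes() if n not in bridges])
    components = sorted(
        nx.connected_components(residual),
        key=lambda c: (-len(c), min(c)),
    )
    subnetwork_id: dict[int, int | None] = {n: None for n in classification.nodes}
    satellite: dict[int, bool] = {n: False for n in classification.nodes}
    for sid, comp in enumerate(components, start=1):
        is_satellite = len(comp) < min_size
        for node in comp:
            subnetwork_id[node] = sid
            satellite[node] = is_satellite
    return NodeClassification(
        nodes=list(classification.nodes),
        role=dict(classification.role),
        subnetwork_id=subnetwork_id,
        satellite=satellite,
    )


def degree_stratify(
    rgraph: RadiomicGraph,
    classification: NodeClassification,
    subnetwork_id: int,
    n_groups: int = 4,
) -> dict[int, int]:
    """Split one subnetwork's nodes into ``n_groups`` degree strata.

    Nodes are ranked by weighted degree (ties broken by node id) and cut into
    equal-rank groups, 1 = lowest degree. Degenerate cases degrade to fewer
    groups with a warning; all-equal degrees collapse to a single group.
    """
    members = classification.subnetwork_nodes(subnetwork_id)
    if not members:
        raise ValueError(f"subnetwork {subnetwork_id} is empty")
    g = rgraph.graph
    degrees = np.array([g.degree(n, weight="weight") for n in members], dtype=float)
    if np.allclose(degrees, degrees[0]):
        if n_groups > 1 and len(members) > 1:
            warnings.warn(
                "all degrees equal in subnetwork; single stratum returned",
                stacklevel=2,
            )
        return {n: 1 for n in members}
    k = min(n_groups, len(members))
    if k < n_groups:
        warnings.warn(
            f"subnetwork {subnetwork_id} has {len(members)} nodes < {n_groups} groups; "
            f"using {k}",
            stacklevel=2,
        )
    order = sorted(range(len(members)), key=lambda i: (degrees[i], members[i]))
    out: dict[int, int] = {}
    for gi, chunk in enumerate(np.array_split(order, k), start=1):
        for i in chunk:
            out[members[i]] = gi
    return out


# --------------------------------------------------------------------------
# k-sweep overfitting diagnostic
# --------------------------------------------------------------------------


@dataclass
class SweepConfig:
    """Configuration shared by every k in the sweep."""

    method: str = "kmeans"
    standardize: bool = True
    cor_mode: str = "raw"
    edge_threshold: float | str = "auto"  # a float, or "auto" for density targeting
    target_density: float = 0.20
    n_reseeds: int = 5
    n_init: int = 10
    eps: float = 1e-9
    randomness_flag: float = 0.8
    stability_flag: float = 0.5


@dataclass
class KSweepReport:
    """Per-k randomness/stability diagnostics plus the flagged overfitting
    onset (the smallest k whose network looks random or unstable)."""

    frame: pd.DataFrame
    overfit_onset: int | None
    config: SweepConfig

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    def plot(self, path) -> None:
        """Diagnostic plot (edge count, mean cc vs density, randomness and
        stability against k). Requires matplotlib."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, axes = plt.subplots(1, 3, figsize=(12, 3.5))
        k = self.frame["k"]
        axes[0].plot(k, self.frame["edge_count"], "o-")
        axes[0].set(xlabel="k", ylabel="edges")
        axes[1].plot(k, self.frame["mean_cc"], "o-", label="mean cc")
        axes[1].plot(k, self.frame["density"], "s--", label="density")
        axes[1].set(xlabel="k")
        axes[1].legend()
        axes[2].plot(k, self.frame["randomness_score"].clip(upper=2), "o-",
                     label="randomness (clipped)")
        axes[2].plot(k, self.frame["stability"], "s--", label="stability")
        axes[2].axhline(self.config.randomness_flag, color="0.6", ls=":")
        axes[2].set(xlabel="k")
        axes[2].legend()
        if self.overfit_onset is not None:
            for ax in axes:
                ax.axvline(self.overfit_onset, color="r", ls=":", lw=1)
        fig.tight_layout()
        fig.savefig(path, dpi=110)
        plt.close(fig)


def _graph_at_k(
    table: VoxelTable, k: int, seed: int, cfg: SweepConfig
) -> tuple[ClusterAssignment, RadiomicGraph]:
    assignment = cluster_voxels(
        table, k, seed=seed, method=cfg.method, standardize=cfg.standardize,
        n_init=cfg.n_init,
    )
    profiles = cluster_profiles(table, assignment)
    adj = correlation_matrix(profiles, mode=cfg.cor_mode)
    if cfg.edge_threshold == "auto":
        thr = auto_threshold(adj, cfg.target_density)
    else:
        thr = float(cfg.edge_threshold)
    sizes = {p.cluster_id: p.size for p in profiles}
    return assignment, build_graph(adj, edge_threshold=thr, sizes=sizes)


def _matched_edge_jaccard(
    base: ClusterAssignment,
    base_edges: set[tuple[int, int]],
    other: ClusterAssignment,
    other_edges: set[tuple[int, int]],
) -> float:
    """Jaccard overlap of two edge sets after matching the second clustering's
    labels onto the first by maximal voxel overlap (Hungarian assignment)."""
    contingency = np.zeros((base.k, other.k))
    np.add.at(contingency, (base.labels, other.labels), 1)
    rows, cols = linear_sum_assignment(-contingency)
    mapping = {int(c): int(r) for r, c in zip(rows, cols)}
    # unmatched labels (k mismatch after compaction) map outside base's space
    next_id = base.k
    for c in range(other.k):
        if c not in mapping:
            mapping[c] = next_id
            next_id += 1
    mapped = {tuple(sorted((mapping[u], mapping[v]))) for u, v in other_edges}
    union = base_edges | mapped
    if not union:
        return 1.0
    return len(base_edges & mapped) / len(union)


def _randomness_score(rgraph: RadiomicGraph, eps: float) -> tuple[float, float, float]:
    """(score, mean_cc, density): score = density / max(mean_cc, eps), the
    ratio of the Erdos-Renyi clustering expectation (the density) to the
    observed mean clustering coefficient. Structured networks score well
    below 1; random-looking ones approach or exceed it."""
    g = rgraph.graph
    n = g.number_of_nodes()
    m = g.number_of_edges()
    density = 2.0 * m / (n * (n - 1)) if n > 1 else 0.0
    mean_cc = float(np.mean(list(nx.clustering(g).values()))) if n else 0.0
    score = 0.0 if density == 0 else density / max(mean_cc, eps)
    return score, mean_cc, density


def k_sweep(
    table: VoxelTable,
    k_values: list[int],
    seed: int = 0,
    config: SweepConfig | None = None,
) -> KSweepReport:
    """Run clustering -> network -> diagnostics for every k and flag the
    overfitting onset.

    For each k the randomness score compares the observed mean clustering
    coefficient with its Erdos-Renyi expectation at the same density, and the
    stability is the mean label-matched edge Jaccard over reseeded reruns.
    The onset is the smallest k with ``randomness >= randomness_flag`` or
    ``stability < stability_flag``.
    """
    cfg = config or SweepConfig()
    ks = sorted(set(int(k) for k in k_values))
    if len(ks) < 2:
        raise ValueError("k_sweep requires at least 2 distinct k values")
    if ks[-1] >= table.n_rows:
        raise ValueError(f"largest k={ks[-1]} must be below row count {table.n_rows}")

    records = []
    onset = None
    for k in ks:
        base_assign, base_graph = _graph_at_k(table, k, seed, cfg)
        base_edges = base_graph.edge_set()
        score, mean_cc, density = _randomness_score(base_graph, cfg.eps)
        jaccards = []
        for r in range(cfg.n_reseeds):
            other_assign, other_graph = _graph_at_k(table, k, seed + 1 + r, cfg)
            jaccards.append(
                _matched_edge_jaccard(
                    base_assign, base_edges, other_assign, other_graph.edge_set()
                )
            )
        stability = float(np.mean(jaccards))
        records.append(
            {
                "k": k,
                "randomness_score": score,
                "edge_count": base_graph.n_edges,
                "mean_cc": mean_cc,
                "density": density,
                "stability": stability,
            }
        )
        if onset is None and (
            score >= cfg.randomness_flag or stability < cfg.stability_flag
        ):
            onset = k
    return KSweepReport(frame=pd.DataFrame(records), overfit_onset=onset, config=cfg)
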