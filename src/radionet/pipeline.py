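"""End-to-end orchestration: phantom or NIfTI inputs -> voxel table ->
clustering -> correlation network -> topology -> back-projected label
volumes, behind one config object, plus node-to-voxel back-projection.

Output label scheme (one integer volume): major subnetworks get 1..m by
descending size, satellite groups continue the numbering, bridges get the
next label. A second volume overlays the degree hierarchy of one subnetwork
as ``10 + group``.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .clustering import (
    ClusterAssignment,
    cluster_profiles,
    cluster_voxels,
    profiles_to_frame,
)
from .network import auto_threshold, build_graph, correlation_matrix
from .phantom import PhantomSpec, default_spec, generate_phantom
from .topology import (
    ClassificationThresholds,
    SweepConfig,
    classify_nodes,
    degree_stratify,
    extract_subnetworks,
    k_sweep,
    node_metrics,
)
from .volume_stack import (
    FeatureVolume,
    LabelVolume,
    VoxelTable,
    build_voxel_table,
    load_feature_volumes,
    load_manifest,
    scatter_to_grid,
)

__all__ = [
    "PipelineConfig",
    "PipelineResult",
    "backproject",
    "run_pipeline",
    "subnetwork_identity",
]

log = logging.getLogger("radionet")


def backproject(
    assignment: ClusterAssignment,
    node_labels: dict[int, int],
    table: VoxelTable,
    legend: dict[int, str] | None = None,
) -> LabelVolume:
    """Map each masked voxel to its cluster's node label on the image grid.

    Unmasked voxels get 0. Raises if any cluster lacks a node label. The
    original spatial resolution is preserved: one voxel in, one voxel out.
    """
    missing = [c for c in range(assignment.k) if c not in node_labels]
    if missing:
        raise ValueError(f"no node label for cluster(s): {missing}")
    lut = np.zeros(assignment.k, dtype=np.int32)
    for cid, lab in node_labels.items():
        if 0 <= cid < assignment.k:
            lut[cid] = lab
    voxel_labels = lut[assignment.labels]
    data = scatter_to_grid(table, voxel_labels, fill=0, dtype=np.int32)
    return LabelVolume(
        data=data,
        spacing=table.spacing,
        affine=table.affine,
        legend=dict(legend or {}),
    )


def subnetwork_identity(
    tissue_labels: LabelVolume,
    reference: LabelVolume,
    names_by_ref_label: dict[int, str],
) -> dict[int, str]:
    """Name each back-projected label by majority overlap with a reference
    label volume (phantom ground truth or an anatomy mask); never guessed
    from topology alone."""
    out: dict[int, str] = {}
    for lab in np.unique(tissue_labels.data):
        if lab == 0:
            continue
        ref_vals = reference.data[tissue_labels.data == lab]
        if ref_vals.size == 0:
            continue
        counts = np.bincount(ref_vals)
        majority = int(np.argmax(counts))
        out[int(lab)] = names_by_ref_label.get(majority, f"reference_{majority}")
    return out


@dataclass
class PipelineConfig:
    """Everything needed to reproduce a run. Exactly one of ``manifest`` /
    ``phantom`` provides the input volumes."""

    manifest: str | Path | None = None
    phantom: PhantomSpec | str | Path | None = None
    mask_path: str | Path | None = None
    k: int = 20
    k_values: list[int] | None = None  # if set, run the sweep as well
    method: str = "kmeans"
    standardize: bool = True
    seed: int = 0
    cor_mode: str = "raw"
    edge_threshold: float | str = "auto"  # float or "auto"
    target_density: float = 0.20
    thresholds: ClassificationThresholds = field(default_factory=ClassificationThresholds)
    min_subnetwork_size: int = 3
    n_groups: int = 4
    hierarchy_subnetwork: int | str = "auto"  # subnetwork id, or "auto"
    out_dir: str | Path = "radionet_out"

    def validate(self) -> None:
        if (self.manifest is None) == (self.phantom is None):
            raise ValueError("exactly one of manifest / phantom must be given")
        self.thresholds.validate()
        if self.edge_threshold != "auto" and not 0 <= float(self.edge_threshold) < 1:
            raise ValueError("edge_threshold must be 'auto' or in [0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text())
        thr = d.pop("thresholds", None)
        phantom = d.pop("phantom", None)
        if isinstance(phantom, dict):
            phantom = PhantomSpec.from_dict(phantom)
        cfg = cls(phantom=phantom, **d)
        if thr:
            cfg.thresholds = ClassificationThresholds(**thr)
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if isinstance(self.phantom, PhantomSpec):
            d["phantom"] = self.phantom.to_dict()
        elif self.phantom is not None:
            d["phantom"] = str(self.phantom)
        if self.manifest is not None:
            d["manifest"] = str(self.manifest)
        if self.mask_path is not None:
            d["mask_path"] = str(self.mask_path)
        d["out_dir"] = str(self.out_dir)
        d["thresholds"] = dataclasses.asdict(self.thresholds)
        return d


@dataclass
class PipelineResult:
    """Paths to every artifact plus run bookkeeping."""

    out_dir: Path
    n_voxels: int
    n_nodes: int
    n_edges: int
    edge_threshold: float
    subnetworks: list[int]
    bridge_nodes: list[int]
    tissue_labels: LabelVolume
    hierarchy_labels: LabelVolume | None
    paths: dict[str, Path]
    overfit_onset: int | None = None


def _stage(name: str, started: dict) -> None:
    now = time.perf_counter()
    if started.get("_last") is not None:
        log.info("stage %-16s %.2fs", started["_name"], now - started["_last"])
        started[started["_name"]] = now - started["_last"]
    started["_last"] = now
    started["_name"] = name


def _load_inputs(config: PipelineConfig) -> tuple[FeatureVolume, LabelVolume | None]:
    if config.phantom is not None:
        spec = config.phantom
        if not isinstance(spec, PhantomSpec):
            spec = PhantomSpec.from_yaml(spec)
        volume, truth = generate_phantom(spec)
        return volume, truth
    names, paths = load_manifest(config.manifest)
    volume = load_feature_volumes(paths, mask_path=config.mask_path, feature_names=names)
    return volume, None


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full chain and write all artifacts under
    ``config.out_dir``. Fully deterministic given the config."""
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    timings: dict = {"_last": None, "_name": None}

    _stage("load", timings)
    volume, ground_truth = _load_inputs(config)

    _stage("table", timings)
    table = build_voxel_table(volume)

    overfit_onset = None
    sweep_path = None
    if config.k_values:
        _stage("sweep", timings)
        sweep_cfg = SweepConfig(
            method=config.method,
            standardize=config.standardize,
            cor_mode=config.cor_mode,
            edge_threshold=config.edge_threshold,
            target_density=config.target_density,
        )
        report = k_sweep(table, config.k_values, seed=config.seed, config=sweep_cfg)
        overfit_onset = report.overfit_onset
        sweep_path = out_dir / "k_sweep.csv"
        report.to_csv(sweep_path)

    _stage("cluster", timings)
    assignment = cluster_voxels(
        table, config.k, seed=config.seed, method=config.method,
        standardize=config.standardize,
    )
    _stage("profiles", timings)
    profiles = cluster_profiles(table, assignment)

    _stage("network", timings)
    adj = correlation_matrix(profiles, mode=config.cor_mode)
    if config.edge_threshold == "auto":
        threshold = auto_threshold(adj, config.target_density)
    else:
        threshold = float(config.edge_threshold)
    sizes = {p.cluster_id: p.size for p in profiles}
    rgraph = build_graph(adj, edge_threshold=threshold, sizes=sizes)

    _stage("topology", timings)
    metrics = node_metrics(rgraph)
    classification = classify_nodes(metrics, config.thresholds)
    classification = extract_subnetworks(
        rgraph, classification, min_size=config.min_subnetwork_size
    )

    majors = classification.major_subnetworks()
    all_sids = sorted(
        {s for s in classification.subnetwork_id.values() if s is not None}
    )
    bridge_label = (max(all_sids) if all_sids else 0) + 1
    legend = {0: "unmasked"}
    for sid in all_sids:
        any_node = classification.subnetwork_nodes(sid)[0]
        kind = "satellite" if classification.satellite.get(any_node) else "subnetwork"
        legend[sid] = f"{kind}-{sid}"
    legend[bridge_label] = "bridge"

    node_labels = {
        n: (classification.subnetwork_id[n] if classification.subnetwork_id[n] is not None
            else bridge_label)
        for n in classification.nodes
    }

    _stage("backproject", timings)
    tissue = backproject(assignment, node_labels, table, legend=legend)

    # degree hierarchy of one subnetwork, overlaid as 10 + group
    hierarchy = None
    hier_sid = None
    target = config.hierarchy_subnetwork
    if target == "auto":
        if ground_truth is not None and majors:
            # pick the subnetwork with majority overlap on the tumor class,
            # never guessed from topology alone
            tumor_labels = {
                lab for lab, name in ground_truth.legend.items() if name == "tumor"
            }
            names = subnetwork_identity(
                tissue, ground_truth, dict(ground_truth.legend)
            )
            for sid in majors:
                if names.get(sid) == "tumor" and tumor_labels:
                    hier_sid = sid
                    break
        if hier_sid is None:
            hier_sid = majors[-1] if majors else None  # smallest major subnetwork
    elif target is not None:
        hier_sid = int(target)
    if hier_sid is not None and classification.subnetwork_nodes(hier_sid):
        _stage("hierarchy", timings)
        groups = degree_stratify(
            rgraph, classification, hier_sid, n_groups=config.n_groups
        )
        hier_node_labels = {
            n: (10 + groups[n]) if n in groups else node_labels[n]
            for n in classification.nodes
        }
        hier_legend = dict(legend)
        for gi in sorted(set(groups.values())):
            hier_legend[10 + gi] = f"degree-group-{gi}"
        hierarchy = backproject(assignment, hier_node_labels, table, legend=hier_legend)

    _stage("write", timings)
    paths: dict[str, Path] = {}
    paths["tissue_labels"] = tissue.save(out_dir / "tissue_labels.nii")
    if hierarchy is not None:
        paths["hierarchy_labels"] = hierarchy.save(out_dir / "hierarchy_labels.nii")
    cluster_vol = backproject(
        assignment,
        {c: c + 1 for c in range(assignment.k)},
        table,
        legend={0: "unmasked", **{c + 1: f"cluster-{c}" for c in range(assignment.k)}},
    )
    paths["cluster_labels"] = cluster_vol.save(out_dir / "cluster_labels.nii")
    if ground_truth is not None:
        paths["ground_truth"] = ground_truth.save(out_dir / "ground_truth.nii")

    profiles_frame = profiles_to_frame(profiles, table.feature_names)
    paths["profiles"] = out_dir / "cluster_profiles.csv"
    profiles_frame.to_csv(paths["profiles"])

    nodes_frame = metrics.to_frame().join(classification.to_frame())
    nodes_frame["label"] = [node_labels[n] for n in nodes_frame.index]
    paths["nodes"] = out_dir / "node_metrics.csv"
    nodes_frame.to_csv(paths["nodes"])

    paths["adjacency"] = out_dir / "adjacency.csv"
    adj.to_frame().to_csv(paths["adjacency"])
    paths["edges"] = out_dir / "edges.tsv"
    rgraph.to_edge_frame().to_csv(paths["edges"], sep="\t", index=False)
    paths["graphml"] = out_dir / "graph.graphml"
    nx.write_graphml(rgraph.graph, paths["graphml"])
    if sweep_path is not None:
        paths["k_sweep"] = sweep_path

    _stage("done", timings)
    timings.pop("_last", None)
    timings.pop("_name", None)

    record = {
        "config": config.to_dict(),
        "versions": {
            "radionet": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "networkx": nx.__version__,
        },
        "n_voxels": int(table.n_rows),
        "n_features": int(table.n_features),
        "n_nodes": int(rgraph.n_nodes),
        "n_edges": int(rgraph.n_edges),
        "edge_threshold": float(threshold),
        "subnetworks": [int(s) for s in majors],
        "bridge_nodes": [int(n) for n in classification.nodes_with_role("bridge")],
        "overfit_onset": overfit_onset,
        "legend": {int(k): v for k, v in legend.items()},
        "stage_seconds": {k: round(v, 3) for k, v in timings.items()},
    }
    paths["run_record"] = out_dir / "run_record.json"
    paths["run_record"].write_text(json.dumps(record, indent=2, sort_keys=True))

    return PipelineResult(
        out_dir=out_dir,
        n_voxels=table.n_rows,
        n_nodes=rgraph.n_nodes,
        n_edges=rgraph.n_edges,
        edge_threshold=float(threshold),
        subnetworks=majors,
        bridge_nodes=classification.nodes_with_role("bridge"),
        tissue_labels=tissue,
        hierarchy_labels=hierarchy,
        paths=paths,
        overfit_onset=overfit_onset,
    )
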