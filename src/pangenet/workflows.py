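"""End-to-end "three graphs" workflow and its configuration.

A single config drives: genome-genome similarity graph (threshold + k-NN +
MCL + enrichment), gene-gene co-occurrence graph (frequency filter +
threshold + optional k-NN + MCL + profiles), and the gene synteny graph
(low-weight edge removal, largest component, core-edge contraction,
Louvain, gene-cluster overlay).  Frequency cutoffs are configured as
fractions and resolved against the population size at run time; every run
writes a manifest with content hashes and the transform logs so it can be
reproduced bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import io as pio
from .clustering import louvain_cluster, mcl_cluster
from .enrichment import enrichment_analysis, gene_cluster_profiles, write_enrichment_tsv
from .errors import PangenetError, UsageError, ValidationError
from .similarity import pairwise_similarity, similarity_graph
from .simulate import SyntheticPangenomeConfig, simulate_pangenome
from .synteny import build_synteny_graph, overlay_clusters
from .transforms import (
    TransformLog,
    contract_core_edges,
    filter_edges_min_weight,
    filter_nodes_by_frequency,
    keep_largest_component,
    knn_sparsify,
)


def resolve_fraction_cutoffs(
    n_genomes: int, low_frac: float, high_frac: float
) -> tuple[int, int]:
    """Turn fraction bounds into integer genome-count cutoffs.

    Returns ``(W_lo, W_hi)`` such that weights strictly below ``W_lo``
    cover fewer than ``low_frac`` of the genomes and weights strictly
    above ``W_hi`` cover more than ``high_frac`` of them
    (``W_lo = ceil(low_frac * n)``, ``W_hi = floor(high_frac * n)``).
    """
    if not (0.0 <= low_frac <= high_frac <= 1.0):
        raise UsageError("need 0 <= low_frac <= high_frac <= 1")
    # round defensively: 0.29 * 100 style float error must not shift a cutoff
    low = round(low_frac * n_genomes, 9)
    high = round(high_frac * n_genomes, 9)
    return int(math.ceil(low)), int(math.floor(high))


@dataclass
class WorkflowConfig:
    output_dir: Path
    seed: int = 0
    input: dict = field(default_factory=dict)
    genome_graph: dict = field(default_factory=dict)
    gene_graph: dict = field(default_factory=dict)
    synteny: dict = field(default_factory=dict)
    enrichment: dict = field(default_factory=dict)
    profiles: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "WorkflowConfig":
        path = Path(path)
        if not path.exists():
            raise ValidationError(f"config file does not exist: {path}")
        with path.open(encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if "output_dir" not in raw:
            raise ValidationError("config must set output_dir")
        return cls(
            output_dir=Path(raw["output_dir"]),
            seed=int(raw.get("seed", 0)),
            input=raw.get("input", {}),
            genome_graph=raw.get("genome_graph", {}),
            gene_graph=raw.get("gene_graph", {}),
            synteny=raw.get("synteny", {}),
            enrichment=raw.get("enrichment", {}),
            profiles=raw.get("profiles", {}),
        )


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    with path.open("rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            digest.update(chunk)
    return digest.hexdigest()


def _load_inputs(config: WorkflowConfig):
    spec = config.input
    if "simulate" in spec:
        sim_kwargs = dict(spec["simulate"] or {})
        sim_kwargs.setdefault("seed", config.seed)
        dataset = simulate_pangenome(SyntheticPangenomeConfig(**sim_kwargs))
        return dataset.matrix, dataset.metadata, dataset.orders
    if "matrix" not in spec:
        raise ValidationError("config input must provide 'matrix' or 'simulate'")
    matrix_path = Path(spec["matrix"])
    if not matrix_path.exists():
        raise ValidationError(f"input file does not exist: {matrix_path}")
    matrix = pio.read_presence_absence(
        matrix_path,
        spec.get("dialect", "rtab"),
        identity_threshold=float(spec.get("identity_threshold", 90.0)),
    )
    metadata = None
    if spec.get("metadata"):
        metadata = pio.read_metadata(
            spec["metadata"], id_column=spec.get("id_column", "genome")
        )
    orders = None
    if spec.get("orders"):
        orders = pio.read_gene_orders(spec["orders"])
    return matrix, metadata, orders


def run_workflow(config: WorkflowConfig) -> dict:
    """Run the full three-graph workflow; returns the manifest dict."""
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "artifacts": {},
        "parameters": {},
        "transform_logs": {},
        "failed_stage": None,
    }

    def register(name: str, path: Path) -> None:
        manifest["artifacts"][name] = {
            "path": str(path.relative_to(out_dir)),
            "sha256": _sha256(path),
        }

    stage = "load_inputs"
    try:
        matrix, metadata, orders = _load_inputs(config)
        n_genomes = matrix.n_genomes
        manifest["n_genomes"] = n_genomes
        matrix_path = out_dir / "matrix.rtab"
        matrix.to_rtab(matrix_path)
        register("matrix", matrix_path)

        # ------------------------------------------------------------------
        stage = "genome_graph"
        gg = config.genome_graph
        sim = pairwise_similarity(
            matrix,
            axis="genomes",
            metric=gg.get("metric", "jaccard"),
            accessory_only=bool(gg.get("accessory_only", True)),
            core_fraction=float(gg.get("core_fraction", 1.0)),
        )
        log = TransformLog()
        graph = similarity_graph(sim, min_weight=float(gg.get("min_weight", 0.5)))
        if gg.get("knn"):
            graph = knn_sparsify(graph, int(gg["knn"]), log=log)
        genome_clusters = mcl_cluster(graph, inflation=float(gg.get("inflation", 2.0)))
        genome_clusters.name = "mcl_cluster"
        for node, label in genome_clusters.labels.items():
            graph.nodes[node]["cluster"] = label
        if metadata is not None:
            for node in graph.nodes:
                for attr in metadata.attributes:
                    graph.nodes[node][attr] = metadata.get(node, attr)
        pio.write_layout(
            graph,
            [genome_clusters] + ([metadata] if metadata is not None else []),
            out_dir / "genome_graph.layout",
        )
        pio.export_graph(graph, "graphml", out_dir / "genome_graph.graphml")
        genome_clusters.to_tsv(out_dir / "genome_clusters.tsv", node_column="genome")
        register("genome_graph_layout", out_dir / "genome_graph.layout")
        register("genome_graph_graphml", out_dir / "genome_graph.graphml")
        register("genome_clusters", out_dir / "genome_clusters.tsv")
        manifest["transform_logs"]["genome_graph"] = [
            vars(r) for r in log.records
        ]
        manifest["parameters"]["genome_graph"] = dict(gg)

        # ------------------------------------------------------------------
        stage = "enrichment"
        if metadata is not None:
            attr = config.enrichment.get("attribute") or (
                metadata.attributes[0] if metadata.attributes else None
            )
            if attr is not None:
                results, _ = enrichment_analysis(
                    genome_clusters.labels,
                    metadata.column(attr),
                    alpha=float(config.enrichment.get("alpha", 0.05)),
                    adjust=config.enrichment.get("adjust", "bh"),
                )
                write_enrichment_tsv(results, out_dir / "enrichment.tsv")
                register("enrichment", out_dir / "enrichment.tsv")
                manifest["parameters"]["enrichment"] = {
                    "attribute": attr,
                    **config.enrichment,
                }

        # ------------------------------------------------------------------
        stage = "gene_graph"
        ge = config.gene_graph
        lo_frac = float(ge.get("min_frac", 0.01))
        hi_frac = float(ge.get("max_frac", 0.99))
        filtered = filter_nodes_by_frequency(matrix, n_genomes, lo_frac, hi_frac)
        gene_log = TransformLog()
        gene_sim = pairwise_similarity(
            filtered, axis="genes", metric=ge.get("metric", "jaccard")
        )
        gene_graph = similarity_graph(
            gene_sim, min_weight=float(ge.get("min_weight", 0.55))
        )
        if ge.get("knn"):
            gene_graph = knn_sparsify(gene_graph, int(ge["knn"]), log=gene_log)
        gene_clusters = mcl_cluster(gene_graph, inflation=float(ge.get("inflation", 1.5)))
        gene_clusters.name = "gene_cluster"
        for node, label in gene_clusters.labels.items():
            gene_graph.nodes[node]["cluster"] = label
        pio.write_layout(gene_graph, gene_clusters, out_dir / "gene_graph.layout")
        pio.export_graph(gene_graph, "graphml", out_dir / "gene_graph.graphml")
        gene_clusters.to_tsv(out_dir / "gene_clusters.tsv", node_column="gene")
        register("gene_graph_layout", out_dir / "gene_graph.layout")
        register("gene_graph_graphml", out_dir / "gene_graph.graphml")
        register("gene_clusters", out_dir / "gene_clusters.tsv")
        manifest["transform_logs"]["gene_graph"] = [vars(r) for r in gene_log.records]
        manifest["parameters"]["gene_graph"] = dict(ge)

        # ------------------------------------------------------------------
        stage = "profiles"
        profile = gene_cluster_profiles(
            matrix,
            gene_clusters,
            metadata=metadata,
            order_by=config.profiles.get("order_by") if metadata is not None else None,
        )
        profile.to_tsv(out_dir / "gene_cluster_profiles.tsv")
        register("gene_cluster_profiles", out_dir / "gene_cluster_profiles.tsv")

        # ------------------------------------------------------------------
        stage = "synteny_graph"
        if orders is not None:
            sy = config.synteny
            syn_log = TransformLog()
            syn = build_synteny_graph(orders)
            w_lo, w_hi = resolve_fraction_cutoffs(
                n_genomes,
                float(sy.get("low_frac", 0.01)),
                float(sy.get("high_frac", 0.99)),
            )
            manifest["parameters"]["synteny"] = {
                **sy,
                "resolved_low_cutoff": w_lo,
                "resolved_high_cutoff": w_hi,
            }
            if w_lo > 1:
                # remove edges supported by fewer than w_lo genomes
                syn = filter_edges_min_weight(syn, w_lo - 1, log=syn_log)
            syn = keep_largest_component(syn, log=syn_log)
            if sy.get("contract", True):
                syn = contract_core_edges(syn, w_hi, log=syn_log)
            min_node_frac = float(sy.get("min_node_frac", 0.0))
            if min_node_frac > 0:
                syn = filter_nodes_by_frequency(
                    syn, n_genomes, min_frac=min_node_frac, log=syn_log
                )
            syn_clusters = louvain_cluster(
                syn,
                granularity=float(sy.get("granularity", 0.4)),
                seed=config.seed,
            )
            syn_clusters.name = "louvain_cluster"
            for node, label in syn_clusters.labels.items():
                syn.nodes[node]["cluster"] = label
            syn = overlay_clusters(syn, gene_clusters, attribute_name="gene_cluster")
            pio.export_graph(syn, "layout", out_dir / "synteny_graph.layout")
            pio.export_graph(syn, "graphml", out_dir / "synteny_graph.graphml")
            syn_clusters.to_tsv(out_dir / "synteny_clusters.tsv", node_column="node")
            syn_log.to_tsv(out_dir / "synteny_transform_log.tsv")
            register("synteny_graph_layout", out_dir / "synteny_graph.layout")
            register("synteny_graph_graphml", out_dir / "synteny_graph.graphml")
            register("synteny_clusters", out_dir / "synteny_clusters.tsv")
            register("synteny_transform_log", out_dir / "synteny_transform_log.tsv")
            manifest["transform_logs"]["synteny_graph"] = [
                vars(r) for r in syn_log.records
            ]
    except PangenetError as exc:
        manifest["failed_stage"] = stage
        _write_manifest(manifest, out_dir)
        raise PangenetError(f"workflow stage {stage!r} failed: {exc}") from exc

    _write_manifest(manifest, out_dir)
    return manifest


def _write_manifest(manifest: dict, out_dir: Path) -> None:
    with (out_dir / "manifest.json").open("w", encoding="utf-8", newline="\n") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
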