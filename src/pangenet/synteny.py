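"""Gene-adjacency (synteny) networks.

Nodes are gene families; an edge's weight counts the genomes in which the
two families are observed adjacent on a replicon (capped at once per
genome, so weights are genome counts and fraction-based contraction rules
are well-defined).  Nodes carry ``frequency`` (genomes containing the
family) and ``member_genes`` (constituent families after contraction).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx

from .errors import ValidationError
from .io import GeneFamilyMap, WeightedEdgeList

logger = logging.getLogger(__name__)


@dataclass
class Contig:
    """An ordered run of gene-family ids on one replicon."""

    genes: list[str]
    circular: bool = False

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValidationError("contig gene list must be non-empty")


#: genome id -> list of contigs
GeneOrders = dict[str, list[Contig]]


def gene_orders_from_gff(
    gff_paths: Mapping[str, str | Path],
    family_map: GeneFamilyMap,
    feature_types: Sequence[str] = ("CDS",),
    circular_contigs: frozenset[str] = frozenset(),
) -> GeneOrders:
    """Derive per-genome gene orders from GFF3 annotation files.

    Features are sorted by start coordinate per contig (ties by end then
    feature id); strand is ignored.  Feature ids absent from ``family_map``
    are skipped with a counted warning; a genome with zero mapped features
    is an error.
    """
    import gffutils

    orders: GeneOrders = {}
    for genome_id, path in gff_paths.items():
        db = gffutils.create_db(
            str(path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
        )
        by_contig: dict[str, list[tuple[int, int, str, str]]] = {}
        skipped = 0
        for ftype in feature_types:
            for feature in db.features_of_type(ftype):
                fid = feature.id
                if fid not in family_map:
                    skipped += 1
                    continue
                by_contig.setdefault(feature.seqid, []).append(
                    (feature.start, feature.end, fid, family_map[fid])
                )
        if skipped:
            logger.warning(
                "%s: skipped %d feature(s) missing from the family map",
                genome_id,
                skipped,
            )
        contigs = []
        for seqid in sorted(by_contig):
            entries = sorted(by_contig[seqid])
            contigs.append(
                Contig(
                    genes=[fam for _, _, _, fam in entries],
                    circular=seqid in circular_contigs,
                )
            )
        if not contigs:
            raise ValidationError(f"{genome_id}: no mapped features in {path}")
        orders[genome_id] = contigs
    return orders


def _contig_adjacencies(contig: Contig) -> set[frozenset[str]]:
    pairs: set[frozenset[str]] = set()
    genes = contig.genes
    n = len(genes)
    if n < 2:
        return pairs
    span = n if contig.circular else n - 1
    for i in range(span):
        a, b = genes[i], genes[(i + 1) % n]
        if a != b:  # tandem repeats of one family carry no self-loop
            pairs.add(frozenset((a, b)))
    return pairs


def build_synteny_graph(orders: GeneOrders) -> nx.Graph:
    """Count adjacency support across genomes and assemble the graph.

    A given unordered family pair contributes at most once per genome,
    circular contigs close the last-first adjacency, and self-adjacencies
    are dropped.  Node frequency counts genomes carrying the family at
    least once.
    """
    if not orders:
        raise ValidationError("no gene orders supplied")
    graph = nx.Graph(n_genomes=len(orders))
    freq: dict[str, int] = {}
    weight: dict[frozenset[str], int] = {}
    for genome_id in orders:
        seen: set[str] = set()
        pairs: set[frozenset[str]] = set()
        for contig in orders[genome_id]:
            seen.update(contig.genes)
            pairs |= _contig_adjacencies(contig)
        for fam in seen:
            freq[fam] = freq.get(fam, 0) + 1
        for pair in pairs:
            weight[pair] = weight.get(pair, 0) + 1
    for fam in sorted(freq):
        graph.add_node(fam, frequency=freq[fam], member_genes=[fam])
    for pair in sorted(weight, key=sorted):
        a, b = sorted(pair)
        graph.add_edge(a, b, weight=weight[pair])
    return graph


def synteny_from_edge_list(
    edges: WeightedEdgeList, n_genomes: int | None = None
) -> nx.Graph:
    """Build a synteny graph from a pre-computed (PIRATE-style) edge list.

    Frequencies are unknown in this route; weights exceeding ``n_genomes``
    are clamped with a warning, since adjacency weights are genome counts.
    """
    if not edges:
        raise ValidationError("empty edge list")
    graph = nx.Graph()
    if n_genomes is not None:
        graph.graph["n_genomes"] = n_genomes
    clamped = 0
    for a, b, w in edges:
        if n_genomes is not None and w > n_genomes:
            w = float(n_genomes)
            clamped += 1
        if graph.has_edge(a, b):
            graph[a][b]["weight"] += w
        else:
            graph.add_edge(a, b, weight=w)
    if clamped:
        logger.warning("clamped %d edge weight(s) exceeding n_genomes=%s", clamped, n_genomes)
    for node in graph.nodes:
        graph.nodes[node]["member_genes"] = [node]
    return graph


def overlay_clusters(
    graph: nx.Graph, assignment, attribute_name: str = "gene_cluster"
) -> nx.Graph:
    """Annotate synteny nodes with gene-cluster labels.

    Plain nodes get their family's label; merged (post-contraction) nodes
    get the multiset of member labels plus a majority label.  Families
    absent from the assignment are labelled ``"unassigned"``.
    """
    labels = assignment.labels if hasattr(assignment, "labels") else dict(assignment)
    out = graph.copy()
    for node, data in out.nodes(data=True):
        members = data.get("member_genes", [node])
        member_labels = [str(labels.get(m, "unassigned")) for m in members]
        counts: dict[str, int] = {}
        for lab in member_labels:
            counts[lab] = counts.get(lab, 0) + 1
        # majority; ties prefer an assigned label, then the smallest
        majority = min(
            counts,
            key=lambda lab: (-counts[lab], lab == "unassigned", lab),
        )
        data[attribute_name] = majority
        data[f"{attribute_name}_members"] = member_labels
    return out
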