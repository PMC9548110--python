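"""Seed-deterministic synthetic pangenome generator.

Produces the statistical structure the analyses expect without any
download: clonal lineages with lineage-restricted accessory gene blocks,
sporadically carried mobile-element blocks independent of lineage, core
genes at frequency 1, single-genome noise genes, and per-genome circular
gene orders in which each carried block is spliced contiguously at a fixed
locus of the core backbone.

All randomness flows from one ``numpy`` Generator seeded once; draws
happen in a documented fixed order (splice loci, then lineage-block
carriage, then mobile-element probabilities and carriage, then singleton
placement), so identical configs give bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import UsageError, ValidationError
from .io import MISSING, GenePresenceAbsenceMatrix, MetadataTable
from .synteny import Contig, GeneOrders


@dataclass
class SyntheticPangenomeConfig:
    n_lineages: int = 3
    genomes_per_lineage: int = 20
    n_core: int = 200
    blocks_per_lineage: int = 3
    block_size: int = 10
    p_in: float = 0.95
    p_leak: float = 0.02
    n_mge: int = 4
    mge_size: int = 8
    p_mge_range: tuple[float, float] = (0.05, 0.4)
    n_singletons: int = 30
    seed: int = 0

    def validate(self) -> None:
        if self.n_lineages < 1 or self.genomes_per_lineage < 2:
            raise UsageError("need >= 1 lineage with >= 2 genomes each")
        for name in ("n_core", "blocks_per_lineage", "block_size", "n_mge",
                     "mge_size", "n_singletons"):
            if getattr(self, name) < 0:
                raise UsageError(f"{name} must be non-negative")
        for p in (self.p_in, self.p_leak, *self.p_mge_range):
            if not 0.0 <= p <= 1.0:
                raise UsageError("probabilities must lie in [0, 1]")
        if self.p_mge_range[0] > self.p_mge_range[1]:
            raise UsageError("p_mge_range must be (low, high) with low <= high")
        n_loci = (
            self.n_lineages * self.blocks_per_lineage
            + self.n_mge
            + self.n_singletons
        )
        if self.n_core < max(n_loci, 3):
            raise UsageError(
                f"n_core={self.n_core} too small to host {n_loci} splice loci"
            )


@dataclass
class SyntheticDataset:
    matrix: GenePresenceAbsenceMatrix
    metadata: MetadataTable
    orders: GeneOrders
    genome_lineage: dict[str, str]
    gene_block: dict[str, str]  # block label, "core" or "singleton"
    config: SyntheticPangenomeConfig = field(repr=False, default=None)


def simulate_pangenome(config: SyntheticPangenomeConfig) -> SyntheticDataset:
    """Generate a synthetic pangenome dataset (matrix, metadata, orders, truth)."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    n_genomes = config.n_lineages * config.genomes_per_lineage
    genome_ids = [
        f"L{l + 1}_G{g + 1:03d}"
        for l in range(config.n_lineages)
        for g in range(config.genomes_per_lineage)
    ]
    lineage_of = {
        gid: f"L{l + 1}"
        for l in range(config.n_lineages)
        for gid in genome_ids[
            l * config.genomes_per_lineage : (l + 1) * config.genomes_per_lineage
        ]
    }

    core_genes = [f"core_{i + 1:04d}" for i in range(config.n_core)]
    blocks: list[tuple[str, list[str], int | None]] = []  # (label, genes, lineage)
    for l in range(config.n_lineages):
        for b in range(config.blocks_per_lineage):
            label = f"L{l + 1}_block{b + 1}"
            genes = [f"{label}_g{i + 1:02d}" for i in range(config.block_size)]
            blocks.append((label, genes, l))
    for m in range(config.n_mge):
        label = f"mge{m + 1}"
        genes = [f"{label}_g{i + 1:02d}" for i in range(config.mge_size)]
        blocks.append((label, genes, None))
    singletons = [f"sing_{i + 1:03d}" for i in range(config.n_singletons)]

    # draw 1: distinct splice loci on the core backbone (block after core[locus])
    n_loci = len(blocks) + len(singletons)
    loci = rng.choice(config.n_core, size=n_loci, replace=False) if n_loci else np.array([], int)
    block_locus = {blocks[i][0]: int(loci[i]) for i in range(len(blocks))}
    singleton_locus = {
        s: int(loci[len(blocks) + i]) for i, s in enumerate(singletons)
    }

    # draw 2: lineage-block carriage, one Bernoulli per (genome, block)
    carriage: dict[str, np.ndarray] = {}
    for label, _, lineage in blocks:
        if lineage is None:
            continue
        probs = np.full(n_genomes, config.p_leak)
        start = lineage * config.genomes_per_lineage
        probs[start : start + config.genomes_per_lineage] = config.p_in
        carriage[label] = rng.random(n_genomes) < probs

    # draw 3: per-element carriage probability, then carriage (lineage-blind)
    for label, _, lineage in blocks:
        if lineage is not None:
            continue
        low, high = config.p_mge_range
        p = rng.uniform(low, high)
        carriage[label] = rng.random(n_genomes) < p

    # draw 4: each singleton lands in exactly one genome
    singleton_home = {
        s: int(rng.integers(n_genomes)) for s in singletons
    }

    gene_ids = list(core_genes)
    gene_block: dict[str, str] = {g: "core" for g in core_genes}
    for label, genes, _ in blocks:
        gene_ids.extend(genes)
        for g in genes:
            gene_block[g] = label
    gene_ids.extend(singletons)
    for s in singletons:
        gene_block[s] = "singleton"

    values = np.zeros((n_genomes, len(gene_ids)), dtype=np.int8)
    col = {g: j for j, g in enumerate(gene_ids)}
    values[:, : config.n_core] = 1
    for label, genes, _ in blocks:
        rows = np.flatnonzero(carriage[label])
        for g in genes:
            values[rows, col[g]] = 1
    for s, home in singleton_home.items():
        values[home, col[s]] = 1

    # drop genes that happened to land nowhere (possible at low probabilities)
    keep = values.sum(axis=0) > 0
    kept_ids = [g for g, k in zip(gene_ids, keep) if k]
    matrix = GenePresenceAbsenceMatrix(
        genome_ids=genome_ids, gene_ids=kept_ids, values=values[:, keep]
    )
    gene_block = {g: gene_block[g] for g in kept_ids}

    # circular gene orders: core backbone + carried blocks spliced at loci
    orders: GeneOrders = {}
    # insertion plan per locus, high positions first so indices stay valid
    inserts_by_locus: dict[int, list[tuple[str, list[str]]]] = {}
    for label, genes, _ in blocks:
        inserts_by_locus.setdefault(block_locus[label], []).append((label, genes))
    for gi, gid in enumerate(genome_ids):
        order = list(core_genes)
        plan: list[tuple[int, list[str]]] = []
        for locus, items in inserts_by_locus.items():
            for label, genes in items:
                if carriage[label][gi]:
                    plan.append((locus, genes))
        for s in singletons:
            if singleton_home[s] == gi:
                plan.append((singleton_locus[s], [s]))
        for locus, genes in sorted(plan, key=lambda t: -t[0]):
            order[locus + 1 : locus + 1] = genes
        orders[gid] = [Contig(genes=order, circular=True)]

    # metadata: lineage plus a host label; lineage 1 is split over two hosts
    records = {}
    for gi, gid in enumerate(genome_ids):
        lineage = lineage_of[gid]
        if lineage == "L1":
            host = "hostA" if (gi % 2 == 0) else "hostB"
        else:
            host = f"host{lineage[1:]}"
        records[gid] = {"lineage": lineage, "host": host}
    metadata = MetadataTable(attributes=["lineage", "host"], records=records)

    return SyntheticDataset(
        matrix=matrix,
        metadata=metadata,
        orders=orders,
        genome_lineage=dict(lineage_of),
        gene_block=gene_block,
        config=config,
    )


def _pairwise_f1(truth: dict, predicted: dict) -> float:
    """Pairwise precision/recall F1 between two labelings of the same items."""
    items = sorted(truth)
    if len(items) < 2:
        raise ValidationError("need at least 2 items for pairwise F1")
    t = {}
    p = {}
    for it in items:
        t.setdefault(truth[it], []).append(it)
        p.setdefault(predicted[it], []).append(it)
    # contingency-based pair counts
    index_p = {it: predicted[it] for it in items}
    same_both = 0
    for members in t.values():
        by_pred: dict = {}
        for it in members:
            by_pred[index_p[it]] = by_pred.get(index_p[it], 0) + 1
        same_both += sum(c * (c - 1) // 2 for c in by_pred.values())
    same_truth = sum(len(m) * (len(m) - 1) // 2 for m in t.values())
    same_pred = sum(len(m) * (len(m) - 1) // 2 for m in p.values())
    if same_truth == 0 and same_pred == 0:
        return 1.0
    precision = same_both / same_pred if same_pred else 0.0
    recall = same_both / same_truth if same_truth else 0.0
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


def truth_metrics(
    dataset: SyntheticDataset,
    genome_clusters=None,
    gene_clusters=None,
) -> dict[str, float]:
    """Recovery scores against the planted structure.

    Returns ``lineage_ari`` (Adjusted Rand Index of genome clusters vs the
    planted lineages) and/or ``block_f1`` (pairwise F1 of gene clusters vs
    the planted blocks, core and singleton genes excluded).
    """
    from sklearn.metrics import adjusted_rand_score

    out: dict[str, float] = {}
    if genome_clusters is not None:
        labels = (
            genome_clusters.labels
            if hasattr(genome_clusters, "labels")
            else dict(genome_clusters)
        )
        genomes = [g for g in dataset.matrix.genome_ids if g in labels]
        if len(genomes) < len(dataset.matrix.genome_ids):
            raise ValidationError("genome clustering does not cover all genomes")
        truth = [dataset.genome_lineage[g] for g in genomes]
        pred = [labels[g] for g in genomes]
        out["lineage_ari"] = float(adjusted_rand_score(truth, pred))
    if gene_clusters is not None:
        labels = (
            gene_clusters.labels
            if hasattr(gene_clusters, "labels")
            else dict(gene_clusters)
        )
        block_genes = {
            g: b
            for g, b in dataset.gene_block.items()
            if b not in ("core", "singleton")
        }
        covered = {g: labels[g] for g in block_genes if g in labels}
        # genes filtered out upstream count as their own singleton clusters
        next_label = -1
        for g in block_genes:
            if g not in covered:
                covered[g] = f"missing_{next_label}"
                next_label -= 1
        out["block_f1"] = _pairwise_f1(block_genes, covered)
    return out
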