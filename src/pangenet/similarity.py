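"""Pairwise similarity over genomes or genes and similarity-graph assembly.

All metrics are defined on binary presence vectors and return values on a
"larger = more similar" scale so that every downstream graph shares one
weight contract:

* ``jaccard``:      |u & v| / |u | v|  (0 when the union is empty)
* ``cosine``:       |u & v| / sqrt(|u| * |v|)
* ``euclidean_sim``: 1 / (1 + d) with d the Euclidean distance between the
  binary vectors; this transform is a package convention, chosen so that
  the Euclidean metric also yields positive edge weights.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .errors import UsageError, ValidationError
from .io import GenePresenceAbsenceMatrix

METRICS = ("jaccard", "cosine", "euclidean_sim")


@dataclass
class SimilarityMatrix:
    """Symmetric similarity matrix over an ordered list of items."""

    item_ids: list[str]
    values: np.ndarray
    metric: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.item_ids)
        if self.values.shape != (n, n):
            raise ValidationError("similarity matrix shape mismatch")
        if not np.allclose(self.values, self.values.T):
            raise ValidationError("similarity matrix must be symmetric")


def pairwise_similarity(
    matrix: GenePresenceAbsenceMatrix,
    axis: str = "genomes",
    metric: str = "jaccard",
    accessory_only: bool = False,
    core_fraction: float = 1.0,
) -> SimilarityMatrix:
    """Compute all pairwise similarities along one axis of the matrix.

    Parameters
    ----------
    axis:
        ``genomes`` compares matrix rows; ``genes`` compares columns (the
        same matrix "inverted").
    accessory_only:
        For ``axis='genomes'``: exclude gene families present in at least
        ``core_fraction`` of genomes before computing (default: only the
        100%-frequency families are excluded).
    """
    if metric not in METRICS:
        raise UsageError(f"unknown metric {metric!r}; expected one of {METRICS}")
    if axis == "genomes":
        ids = list(matrix.genome_ids)
        values = matrix.values.astype(np.int64)
        if accessory_only:
            if not (0.0 < core_fraction <= 1.0):
                raise UsageError("core_fraction must be in (0, 1]")
            freq = values.sum(axis=0)
            keep = freq < core_fraction * matrix.n_genomes if core_fraction < 1.0 \
                else freq < matrix.n_genomes
            values = values[:, keep]
    elif axis == "genes":
        ids = list(matrix.gene_ids)
        values = matrix.values.astype(np.int64).T
    else:
        raise UsageError(f"unknown axis {axis!r}; expected 'genomes' or 'genes'")
    if len(ids) < 2:
        raise ValidationError(f"need at least 2 items on axis {axis!r}")

    inter = values @ values.T
    sizes = values.sum(axis=1)
    if metric == "jaccard":
        union = sizes[:, None] + sizes[None, :] - inter
        with np.errstate(divide="ignore", invalid="ignore"):
            sim = np.where(union > 0, inter / np.maximum(union, 1), 0.0)
    elif metric == "cosine":
        denom = np.sqrt(np.outer(sizes, sizes))
        with np.errstate(divide="ignore", invalid="ignore"):
            sim = np.where(denom > 0, inter / np.maximum(denom, 1e-300), 0.0)
    else:  # euclidean_sim
        sq = sizes[:, None] + sizes[None, :] - 2 * inter
        sim = 1.0 / (1.0 + np.sqrt(np.maximum(sq, 0)))
    np.fill_diagonal(sim, np.where(sizes > 0, 1.0, 0.0 if metric != "euclidean_sim" else 1.0))
    return SimilarityMatrix(item_ids=ids, values=sim, metric=metric)


def similarity_graph(sim: SimilarityMatrix, min_weight: float = 0.0) -> nx.Graph:
    """Materialize a weighted graph with an edge wherever similarity
    strictly exceeds ``min_weight`` (matching the "JSC > t" convention).

    Every item becomes a node even if it ends up isolated.
    """
    if min_weight < 0:
        raise UsageError("min_weight must be >= 0")
    graph = nx.Graph()
    graph.add_nodes_from(sim.item_ids)
    n = len(sim.item_ids)
    iu, ju = np.triu_indices(n, k=1)
    weights = sim.values[iu, ju]
    mask = weights > min_weight
    for i, j, w in zip(iu[mask], ju[mask], weights[mask]):
        graph.add_edge(sim.item_ids[i], sim.item_ids[j], weight=float(w))
    return graph
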