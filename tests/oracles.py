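"""Independent reference implementations used only as test oracles.

Each oracle takes a deliberately different route from the package code it
checks: set arithmetic instead of matrix products, exhaustive enumeration
instead of vectorized filters, exact integer/Fraction arithmetic instead
of floating point, whole-matrix iteration instead of per-component runs.
"""

from __future__ import annotations

import math
from fractions import Fraction

import networkx as nx
import numpy as np

# ---------------------------------------------------------------------------
# pairwise similarity via explicit sets
# ---------------------------------------------------------------------------


def set_similarity(row_u, row_v, metric: str) -> float:
    u = {i for i, x in enumerate(row_u) if x}
    v = {i for i, x in enumerate(row_v) if x}
    inter = len(u & v)
    union = len(u | v)
    if metric == "jaccard":
        return inter / union if union else 0.0
    if metric == "cosine":
        return inter / math.sqrt(len(u) * len(v)) if u and v else 0.0
    if metric == "euclidean_sim":
        d = math.sqrt(len(u) + len(v) - 2 * inter)
        return 1.0 / (1.0 + d)
    raise ValueError(metric)


# ---------------------------------------------------------------------------
# exhaustive k-NN
# ---------------------------------------------------------------------------


def exhaustive_knn_edges(graph: nx.Graph, k: int, mutual: bool = False) -> set:
    """Materialize every node's fully sorted edge list and pick top-k."""
    top = {}
    for node in graph.nodes:
        full = sorted(
            ((data["weight"], str(partner), partner) for partner, data in graph[node].items()),
            key=lambda t: (-t[0], t[1]),
        )
        top[node] = {partner for _, _, partner in full[:k]}
    surviving = set()
    for a, b in graph.edges:
        in_a, in_b = b in top[a], a in top[b]
        if (in_a and in_b) if mutual else (in_a or in_b):
            surviving.add(frozenset((a, b)))
    return surviving


# ---------------------------------------------------------------------------
# Fisher exact test by exact integer enumeration
# ---------------------------------------------------------------------------


def fisher_p_exact(table) -> float:
    """Two-sided p by enumerating all tables with the observed margins.

    Probabilities are exact integers (up to the common denominator);
    inclusion uses the same 1e-7 relative slack rule as the contract.
    """
    (a, b), (c, d) = table
    r1, c1, n = a + b, a + c, a + b + c + d
    if r1 == 0 or c1 == 0 or r1 == n or c1 == n:
        return 1.0
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    weights = {
        x: math.comb(c1, x) * math.comb(n - c1, r1 - x) for x in range(lo, hi + 1)
    }
    total = sum(weights.values())
    cutoff = Fraction(weights[a]) * (1 + Fraction(1, 10**7))
    numerator = sum(w for w in weights.values() if w <= cutoff)
    return float(Fraction(numerator, total))


def iter_all_tables(max_total: int):
    """Yield every 2x2 table of non-negative integers with sum <= max_total."""
    for n in range(max_total + 1):
        for a in range(n + 1):
            for b in range(n - a + 1):
                for c in range(n - a - b + 1):
                    yield ((a, b), (c, n - a - b - c))


# ---------------------------------------------------------------------------
# whole-matrix MCL reference
# ---------------------------------------------------------------------------


def reference_mcl_partition(
    graph: nx.Graph,
    inflation: float,
    prune: float = 1e-6,
    tol: float = 1e-8,
    max_iter: int = 200,
) -> set:
    """Classical MCL run on the whole adjacency matrix at once.

    Returns the partition as a set of frozensets.  Cluster extraction
    walks the converged matrix row by row and merges overlapping supports
    with plain python sets (no union-find).
    """
    nodes = sorted(graph.nodes, key=str)
    if not nodes:
        return set()
    adjacency = nx.to_numpy_array(graph, nodelist=nodes, weight="weight")
    for i in range(len(nodes)):
        incident = adjacency[i].max()
        adjacency[i, i] = incident if incident > 0 else 1.0
    matrix = adjacency / adjacency.sum(axis=0)
    for _ in range(max_iter):
        prev = matrix
        matrix = np.linalg.matrix_power(matrix, 2)
        matrix = matrix**inflation
        matrix = np.where(matrix < prune, 0.0, matrix)
        colsum = matrix.sum(axis=0)
        colsum[colsum == 0] = 1.0
        matrix = matrix / colsum
        if np.max(np.abs(matrix - prev)) < tol:
            break
    clusters: list[set] = []
    for i in range(len(nodes)):
        support = {j for j in range(len(nodes)) if matrix[i, j] > 0}
        if not support:
            continue
        overlapping = [cl for cl in clusters if cl & support]
        for cl in overlapping:
            clusters.remove(cl)
            support |= cl
        clusters.append(support)
    covered = set().union(*clusters) if clusters else set()
    for j in range(len(nodes)):
        if j not in covered:
            clusters.append({j})
    return {frozenset(nodes[j] for j in cl) for cl in clusters}


# ---------------------------------------------------------------------------
# brute-force maximum-modularity partition
# ---------------------------------------------------------------------------


def iter_partitions(items: list):
    """All set partitions of ``items`` (Bell-number many)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for partition in iter_partitions(rest):
        for i in range(len(partition)):
            yield partition[:i] + [[first] + partition[i]] + partition[i + 1 :]
        yield [[first]] + partition


def modularity_value(graph: nx.Graph, partition, gamma: float = 1.0) -> float:
    """Newman modularity with resolution gamma, written from the formula."""
    two_m = 2.0 * sum(d["weight"] for _, _, d in graph.edges(data=True))
    if two_m == 0:
        return 0.0
    degree = {n: sum(d["weight"] for _, _, d in graph.edges(n, data=True)) for n in graph}
    q = 0.0
    for community in partition:
        for u in community:
            for v in community:
                a_uv = graph[u][v]["weight"] if graph.has_edge(u, v) else 0.0
                q += a_uv - gamma * degree[u] * degree[v] / two_m
    return q / two_m


def best_modularity_partitions(graph: nx.Graph, gamma: float = 1.0):
    """Return (max Q, list of arg-max partitions as sets of frozensets)."""
    best_q = -math.inf
    best: list = []
    for partition in iter_partitions(sorted(graph.nodes, key=str)):
        q = modularity_value(graph, partition, gamma)
        key = {frozenset(c) for c in partition}
        if q > best_q + 1e-12:
            best_q, best = q, [key]
        elif abs(q - best_q) <= 1e-12:
            best.append(key)
    return best_q, best


# ---------------------------------------------------------------------------
# brute-force synteny adjacency counting
# ---------------------------------------------------------------------------


def brute_synteny_counts(orders):
    """Per-genome adjacency sets, unioned into counts; plain loops."""
    pair_counts: dict = {}
    frequencies: dict = {}
    for genome in orders:
        pairs = set()
        present = set()
        for contig in orders[genome]:
            genes = contig.genes
            present.update(genes)
            positions = range(len(genes)) if contig.circular else range(len(genes) - 1)
            if len(genes) < 2:
                continue
            for i in positions:
                a = genes[i]
                b = genes[(i + 1) % len(genes)]
                if a != b:
                    pairs.add(frozenset((a, b)))
        for pair in pairs:
            pair_counts[pair] = pair_counts.get(pair, 0) + 1
        for gene in present:
            frequencies[gene] = frequencies.get(gene, 0) + 1
    return pair_counts, frequencies
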