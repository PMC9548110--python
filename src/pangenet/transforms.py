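"""Graph-reduction operators: edge thresholds, k-NN sparsification,
frequency filters, component pruning, attribute selection and contraction
of high-conservation edges.

Every operator is pure (returns a new graph) and, when given a
:class:`TransformLog`, appends a replayable record, so a pipeline can be
audited and reproduced exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx

from .errors import ValidationError
from .io import GenePresenceAbsenceMatrix


@dataclass
class TransformRecord:
    op: str
    params: dict
    nodes_removed: int
    edges_removed: int
    edges_added: int

    def __post_init__(self) -> None:
        if min(self.nodes_removed, self.edges_removed, self.edges_added) < 0:
            raise ValidationError("transform counts must be non-negative")


@dataclass
class TransformLog:
    """Ordered, replayable list of transform records."""

    records: list[TransformRecord] = field(default_factory=list)

    def append(self, record: TransformRecord) -> None:
        self.records.append(record)

    def replay(self, graph: nx.Graph) -> nx.Graph:
        """Re-apply every recorded operation to ``graph`` in order."""
        for record in self.records:
            op = _REGISTRY[record.op]
            graph = op(graph, **record.params)
        return graph

    def to_tsv(self, path: str | Path) -> None:
        with Path(path).open("w", encoding="utf-8", newline="\n") as fh:
            fh.write("op\tparams\tnodes_removed\tedges_removed\tedges_added\n")
            for r in self.records:
                params = ",".join(f"{k}={v}" for k, v in sorted(r.params.items()))
                fh.write(
                    f"{r.op}\t{params}\t{r.nodes_removed}\t{r.edges_removed}\t{r.edges_added}\n"
                )


def _log(log, op, params, before: nx.Graph, after: nx.Graph) -> None:
    if log is None:
        return
    removed_e = before.number_of_edges() - after.number_of_edges()
    log.append(
        TransformRecord(
            op=op,
            params=params,
            nodes_removed=before.number_of_nodes() - after.number_of_nodes(),
            edges_removed=max(removed_e, 0),
            edges_added=max(-removed_e, 0),
        )
    )


def filter_edges_min_weight(
    graph: nx.Graph, w: float, log: TransformLog | None = None
) -> nx.Graph:
    """Keep only edges with weight strictly greater than ``w``.

    Nodes are retained even when they become isolated.
    """
    out = graph.copy()
    drop = [(a, b) for a, b, d in out.edges(data=True) if not d["weight"] > w]
    out.remove_edges_from(drop)
    _log(log, "filter_edges_min_weight", {"w": w}, graph, out)
    return out


def knn_sparsify(
    graph: nx.Graph,
    k: int,
    mutual: bool = False,
    log: TransformLog | None = None,
) -> nx.Graph:
    """k-nearest-neighbour edge filter.

    Each node ranks its incident edges by descending weight (ties broken
    by lexicographically smaller partner id); an edge survives when it is
    in the top-k list of at least one endpoint (union semantics), or of
    both endpoints when ``mutual`` is set.
    """
    if k < 1:
        raise ValidationError("k must be >= 1")
    top: dict = {}
    for node in graph.nodes:
        ranked = sorted(
            graph[node].items(), key=lambda item: (-item[1]["weight"], str(item[0]))
        )
        top[node] = {partner for partner, _ in ranked[:k]}
    out = graph.copy()
    drop = []
    for a, b in out.edges:
        in_a = b in top[a]
        in_b = a in top[b]
        keep = (in_a and in_b) if mutual else (in_a or in_b)
        if not keep:
            drop.append((a, b))
    out.remove_edges_from(drop)
    _log(log, "knn_sparsify", {"k": k, "mutual": mutual}, graph, out)
    return out


def filter_nodes_by_frequency(
    obj,
    n_genomes: int,
    min_frac: float = 0.0,
    max_frac: float = 1.0,
    log: TransformLog | None = None,
):
    """Drop genes whose genome frequency falls strictly outside
    [min_frac, max_frac] of the population.

    Accepts either a graph whose nodes carry a ``frequency`` attribute or a
    presence/absence matrix (column sums are the frequencies).
    """
    if isinstance(obj, GenePresenceAbsenceMatrix):
        freq = obj.gene_frequencies()
        keep = [
            g
            for g, f in zip(obj.gene_ids, freq)
            if not (f / n_genomes > max_frac or f / n_genomes < min_frac)
        ]
        return obj.select_genes(keep)
    graph: nx.Graph = obj
    missing = [n for n, d in graph.nodes(data=True) if "frequency" not in d]
    if missing:
        raise ValidationError(
            f"{len(missing)} node(s) lack the 'frequency' attribute, e.g. {missing[:5]}"
        )
    out = graph.copy()
    drop = [
        n
        for n, d in out.nodes(data=True)
        if d["frequency"] / n_genomes > max_frac or d["frequency"] / n_genomes < min_frac
    ]
    out.remove_nodes_from(drop)
    _log(
        log,
        "filter_nodes_by_frequency",
        {"n_genomes": n_genomes, "min_frac": min_frac, "max_frac": max_frac},
        graph,
        out,
    )
    return out


def filter_small_components(
    graph: nx.Graph, min_size: int, log: TransformLog | None = None
) -> nx.Graph:
    """Remove connected components with fewer than ``min_size`` nodes."""
    out = graph.copy()
    for component in list(nx.connected_components(out)):
        if len(component) < min_size:
            out.remove_nodes_from(component)
    _log(log, "filter_small_components", {"min_size": min_size}, graph, out)
    return out


def keep_largest_component(
    graph: nx.Graph, log: TransformLog | None = None
) -> nx.Graph:
    """Keep only the largest connected component.

    Ties are broken in favour of the component containing the
    lexicographically smallest node id.
    """
    if graph.number_of_nodes() == 0:
        raise ValidationError("cannot take the largest component of an empty graph")
    components = sorted(
        nx.connected_components(graph),
        key=lambda c: (-len(c), min(str(n) for n in c)),
    )
    out = graph.subgraph(components[0]).copy()
    _log(log, "keep_largest_component", {}, graph, out)
    return out


def contract_core_edges(
    graph: nx.Graph,
    w_min: float,
    merge: str = "max",
    log: TransformLog | None = None,
) -> nx.Graph:
    """Contract every edge with weight strictly greater than ``w_min``.

    Contraction is transitive: chains of qualifying edges collapse into a
    single node named after the lexicographically smallest member.  The
    merged node's ``member_genes`` is the union of its constituents' member
    lists (multiplicity = list length) and its ``frequency`` is the
    maximum constituent frequency.  Parallel edges arising from merges
    combine by MAX weight by default ("observed adjacent in W genomes");
    ``merge='sum'`` is available.
    """
    if merge not in ("max", "sum"):
        raise ValidationError(f"unknown parallel-edge merge rule {merge!r}")

    parent: dict = {n: n for n in graph.nodes}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b, d in graph.edges(data=True):
        if d["weight"] > w_min:
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[ra] = rb

    groups: dict = {}
    for node in graph.nodes:
        groups.setdefault(find(node), []).append(node)

    out = nx.Graph()
    out.graph.update(graph.graph)
    rep_of: dict = {}
    for members in groups.values():
        member_genes: list = []
        freqs: list = []
        for m in sorted(members, key=str):
            data = graph.nodes[m]
            member_genes.extend(data.get("member_genes", [m]))
            if "frequency" in data:
                freqs.append(data["frequency"])
        rep = min((str(g) for g in member_genes))
        for m in members:
            rep_of[m] = rep
        attrs = {"member_genes": sorted(member_genes, key=str)}
        if freqs:
            attrs["frequency"] = max(freqs)
        out.add_node(rep, **attrs)

    for a, b, d in graph.edges(data=True):
        ra, rb = rep_of[a], rep_of[b]
        if ra == rb:
            continue
        w = d["weight"]
        if out.has_edge(ra, rb):
            old = out[ra][rb]["weight"]
            out[ra][rb]["weight"] = max(old, w) if merge == "max" else old + w
        else:
            out.add_edge(ra, rb, weight=w)
    _log(log, "contract_core_edges", {"w_min": w_min, "merge": merge}, graph, out)
    return out


def select_nodes_by_attribute(
    graph: nx.Graph,
    attribute: str,
    values,
    log: TransformLog | None = None,
) -> nx.Graph:
    """Induced subgraph on nodes whose ``attribute`` value is in ``values``."""
    if graph.number_of_nodes() and not any(
        attribute in d for _, d in graph.nodes(data=True)
    ):
        raise ValidationError(f"no node carries attribute {attribute!r}")
    values = set(values)
    keep = [n for n, d in graph.nodes(data=True) if d.get(attribute) in values]
    out = graph.subgraph(keep).copy()
    _log(log, "select_nodes_by_attribute", {"attribute": attribute, "values": sorted(values, key=str)}, graph, out)
    return out


_REGISTRY = {
    "filter_edges_min_weight": filter_edges_min_weight,
    "knn_sparsify": knn_sparsify,
    "filter_nodes_by_frequency": filter_nodes_by_frequency,
    "filter_small_components": filter_small_components,
    "keep_largest_component": keep_largest_component,
    "contract_core_edges": contract_core_edges,
    "select_nodes_by_attribute": select_nodes_by_attribute,
}
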