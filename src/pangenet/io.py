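"""Readers and writers for pangenome-tool outputs, metadata and graphs.

Supported inputs
----------------
* Roary-style ``gene_presence_absence.csv`` (any non-empty genome cell
  means "present"; paralog lists collapse to 1),
* binary Rtab tables (genes x genomes, tab separated, entries 0/1),
* PIRATE-style gene-family tables carrying a per-family ``threshold``
  column (rows are filtered to one identity threshold on load),
* PIRATE-style ``.edges`` lists (three whitespace-delimited columns),
* delimited metadata tables keyed by a genome-id column.

Supported graph outputs: the legacy BioLayout/Graphia ``.layout`` dialect
(edge lines plus ``//NODECLASS`` annotation records), GraphML, and plain
TSV edge lists.  Every writer is paired with a parser so round-trips can
be asserted.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .errors import FormatError, UsageError, ValidationError

logger = logging.getLogger(__name__)

#: sentinel used for missing metadata values throughout the package
MISSING = "NA"

# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class GenePresenceAbsenceMatrix:
    """Binary genomes x gene-families matrix.

    Rows are genomes, columns are gene families; a cell is 1 when at least
    one member of the family occurs in that genome.  All similarity
    computations (both orientations) read from this single structure.
    """

    genome_ids: list[str]
    gene_ids: list[str]
    values: np.ndarray
    gene_annotations: dict[str, str] = field(default_factory=dict)
    identity_threshold: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int8)
        if self.values.ndim != 2:
            raise ValidationError("matrix values must be two-dimensional")
        n, m = self.values.shape
        if n != len(self.genome_ids):
            raise ValidationError(
                f"row count {n} != number of genome ids {len(self.genome_ids)}"
            )
        if m != len(self.gene_ids):
            raise ValidationError(
                f"column count {m} != number of gene ids {len(self.gene_ids)}"
            )
        if len(set(self.genome_ids)) != n:
            raise ValidationError("duplicate genome identifiers")
        if len(set(self.gene_ids)) != m:
            raise ValidationError("duplicate gene identifiers")
        bad = ~np.isin(self.values, (0, 1))
        if bad.any():
            raise ValidationError("matrix contains entries other than 0/1")

    @property
    def n_genomes(self) -> int:
        return len(self.genome_ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def gene_frequencies(self) -> np.ndarray:
        """Number of genomes carrying each gene family (column sums)."""
        return self.values.sum(axis=0)

    def drop_empty_genes(self) -> "GenePresenceAbsenceMatrix":
        """Return a copy without all-zero gene columns (logged)."""
        freq = self.gene_frequencies()
        keep = freq > 0
        dropped = int((~keep).sum())
        if dropped:
            logger.info("dropping %d gene families absent everywhere", dropped)
        gene_ids = [g for g, k in zip(self.gene_ids, keep) if k]
        ann = {g: self.gene_annotations[g] for g in gene_ids if g in self.gene_annotations}
        return GenePresenceAbsenceMatrix(
            genome_ids=list(self.genome_ids),
            gene_ids=gene_ids,
            values=self.values[:, keep],
            gene_annotations=ann,
            identity_threshold=self.identity_threshold,
        )

    def select_genes(self, gene_ids: Sequence[str]) -> "GenePresenceAbsenceMatrix":
        index = {g: j for j, g in enumerate(self.gene_ids)}
        try:
            cols = [index[g] for g in gene_ids]
        except KeyError as exc:  # pragma: no cover - defensive
            raise ValidationError(f"unknown gene id {exc.args[0]!r}") from exc
        ann = {g: self.gene_annotations[g] for g in gene_ids if g in self.gene_annotations}
        return GenePresenceAbsenceMatrix(
            genome_ids=list(self.genome_ids),
            gene_ids=list(gene_ids),
            values=self.values[:, cols],
            gene_annotations=ann,
            identity_threshold=self.identity_threshold,
        )

    def to_rtab(self, path: str | Path) -> None:
        """Serialize as an Rtab table (genes x genomes, tab separated)."""
        path = Path(path)
        with path.open("w", encoding="utf-8", newline="\n") as fh:
            fh.write("Gene\t" + "\t".join(self.genome_ids) + "\n")
            for j, gene in enumerate(self.gene_ids):
                row = "\t".join(str(int(v)) for v in self.values[:, j])
                fh.write(f"{gene}\t{row}\n")


@dataclass
class MetadataTable:
    """Per-genome categorical attributes; missing values hold ``MISSING``."""

    attributes: list[str]
    records: dict[str, dict[str, str]]

    def __post_init__(self) -> None:
        if any(not a for a in self.attributes):
            raise ValidationError("attribute names must be non-empty")

    @property
    def genome_ids(self) -> list[str]:
        return list(self.records)

    def get(self, genome_id: str, attribute: str) -> str:
        return self.records.get(genome_id, {}).get(attribute, MISSING)

    def column(self, attribute: str) -> dict[str, str]:
        """Mapping genome -> value for one attribute."""
        if attribute not in self.attributes:
            raise ValidationError(f"unknown metadata attribute {attribute!r}")
        return {g: rec.get(attribute, MISSING) for g, rec in self.records.items()}


#: (node_a, node_b, weight) triples; node_a != node_b, weight finite > 0
WeightedEdgeList = list[tuple[str, str, float]]

#: allele id -> gene family id
GeneFamilyMap = Mapping[str, str]


# ---------------------------------------------------------------------------
# presence/absence matrix readers
# ---------------------------------------------------------------------------

# Roary's gene_presence_absence.csv leading metadata columns
_ROARY_META_COLUMNS = {
    "Gene",
    "Non-unique Gene name",
    "Annotation",
    "No. isolates",
    "No. sequences",
    "Avg sequences per isolate",
    "Genome Fragment",
    "Order within Fragment",
    "Accessory Fragment",
    "Accessory Order with Fragment",
    "QC",
    "Min group size nuc",
    "Max group size nuc",
    "Avg group size nuc",
}

# PIRATE gene_families table leading metadata columns
_PIRATE_META_COLUMNS = {
    "allele_name",
    "gene_family",
    "consensus_gene_name",
    "consensus_product",
    "threshold",
    "alleles_at_maximum_threshold",
    "number_genomes",
    "average_dose",
    "min_dose",
    "max_dose",
    "genomes_containing_fissions",
    "genomes_containing_duplications",
    "number_fission_loci",
    "number_duplicated_loci",
    "no_loci",
    "products",
    "gene_names",
    "min_length(bp)",
    "max_length(bp)",
    "average_length(bp)",
    "cluster",
    "cluster_order",
}


def _check_duplicate_columns(names: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for name in names:
        if name in seen:
            raise ValidationError(f"duplicate {what} column {name!r}")
        seen.add(name)


def read_presence_absence(
    path: str | Path,
    dialect: str,
    identity_threshold: float = 90.0,
) -> GenePresenceAbsenceMatrix:
    """Load a gene presence/absence matrix.

    Parameters
    ----------
    path:
        Input file.
    dialect:
        One of ``roary_csv``, ``rtab`` or ``pirate``.
    identity_threshold:
        For the ``pirate`` dialect only: keep families called at this
        percent-identity threshold (default 90).
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"input file does not exist: {path}")
    if dialect == "rtab":
        matrix = _read_rtab(path)
    elif dialect == "roary_csv":
        matrix = _read_roary_csv(path)
    elif dialect == "pirate":
        matrix = _read_pirate(path, identity_threshold)
    else:
        raise UsageError(f"unknown presence/absence dialect {dialect!r}")
    return matrix.drop_empty_genes()


def _read_rtab(path: Path) -> GenePresenceAbsenceMatrix:
    with path.open(encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n")
        if not header:
            raise FormatError(f"{path}: empty file (line 1)")
        columns = header.split("\t")
        genome_ids = columns[1:]
        if not genome_ids:
            raise FormatError(f"{path}: no genome columns in header (line 1)")
        _check_duplicate_columns(genome_ids, "genome")
        gene_ids: list[str] = []
        rows: list[list[int]] = []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != len(columns):
                raise FormatError(
                    f"{path}: line {lineno} has {len(parts)} fields, expected {len(columns)}"
                )
            gene_ids.append(parts[0])
            try:
                row = [int(v) for v in parts[1:]]
            except ValueError as exc:
                raise FormatError(f"{path}: non-integer cell at line {lineno}") from exc
            if any(v not in (0, 1) for v in row):
                raise FormatError(f"{path}: cell outside {{0,1}} at line {lineno}")
            rows.append(row)
    if len(set(gene_ids)) != len(gene_ids):
        raise ValidationError(f"{path}: duplicate gene identifiers")
    # Rtab is genes x genomes; transpose to the genomes x genes contract
    values = np.array(rows, dtype=np.int8).T if rows else np.zeros((len(genome_ids), 0), np.int8)
    return GenePresenceAbsenceMatrix(genome_ids=genome_ids, gene_ids=gene_ids, values=values)


def _read_roary_csv(path: Path) -> GenePresenceAbsenceMatrix:
    try:
        frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    except Exception as exc:
        raise FormatError(f"{path}: cannot parse as CSV: {exc}") from exc
    if "Gene" not in frame.columns:
        raise FormatError(f"{path}: missing 'Gene' column (line 1)")
    _check_duplicate_columns(list(frame.columns), "genome")
    genome_cols = [c for c in frame.columns if c not in _ROARY_META_COLUMNS]
    if not genome_cols:
        raise FormatError(f"{path}: no genome columns found")
    gene_ids = frame["Gene"].tolist()
    if len(set(gene_ids)) != len(gene_ids):
        raise ValidationError(f"{path}: duplicate gene identifiers")
    # any non-empty cell means present; paralog lists ("a;b") collapse to 1
    values = (frame[genome_cols].to_numpy() != "").astype(np.int8).T
    annotations = {}
    if "Annotation" in frame.columns:
        annotations = {
            g: a for g, a in zip(gene_ids, frame["Annotation"].tolist()) if a
        }
    return GenePresenceAbsenceMatrix(
        genome_ids=genome_cols,
        gene_ids=gene_ids,
        values=values,
        gene_annotations=annotations,
    )


def _read_pirate(path: Path, identity_threshold: float) -> GenePresenceAbsenceMatrix:
    try:
        frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except Exception as exc:
        raise FormatError(f"{path}: cannot parse as TSV: {exc}") from exc
    for required in ("gene_family", "threshold"):
        if required not in frame.columns:
            raise FormatError(f"{path}: missing {required!r} column (line 1)")
    _check_duplicate_columns(list(frame.columns), "genome")
    genome_cols = [c for c in frame.columns if c not in _PIRATE_META_COLUMNS]
    if not genome_cols:
        raise FormatError(f"{path}: no genome columns found")
    thresholds = pd.to_numeric(frame["threshold"], errors="coerce")
    keep = thresholds == identity_threshold
    frame = frame.loc[keep]
    if frame.empty:
        raise ValidationError(
            f"{path}: no families called at identity threshold {identity_threshold}"
        )
    gene_ids = frame["gene_family"].tolist()
    if len(set(gene_ids)) != len(gene_ids):
        raise ValidationError(f"{path}: duplicate gene family identifiers")
    values = (frame[genome_cols].to_numpy() != "").astype(np.int8).T
    annotations = {}
    if "consensus_product" in frame.columns:
        annotations = {
            g: a for g, a in zip(gene_ids, frame["consensus_product"].tolist()) if a
        }
    return GenePresenceAbsenceMatrix(
        genome_ids=genome_cols,
        gene_ids=gene_ids,
        values=values,
        gene_annotations=annotations,
        identity_threshold=identity_threshold,
    )


# ---------------------------------------------------------------------------
# edge lists and allele collapsing
# ---------------------------------------------------------------------------


def read_edge_list(path: str | Path) -> WeightedEdgeList:
    """Read a PIRATE-style ``.edges`` file.

    Three whitespace/tab-delimited columns (source, target, weight); an
    optional header is auto-detected by a non-numeric third field.
    Self-pairs are dropped (logged).
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"input file does not exist: {path}")
    edges: WeightedEdgeList = []
    dropped_self = 0
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) < 3:
                raise FormatError(f"{path}: line {lineno} has fewer than 3 fields")
            a, b, raw_w = parts[0], parts[1], parts[2]
            try:
                w = float(raw_w)
            except ValueError:
                if lineno == 1:  # header row
                    continue
                raise FormatError(f"{path}: non-numeric weight at line {lineno}")
            if not math.isfinite(w) or w <= 0:
                raise FormatError(f"{path}: weight must be finite and > 0 (line {lineno})")
            if a == b:
                dropped_self += 1
                continue
            edges.append((a, b, w))
    if dropped_self:
        logger.info("dropped %d self-pair edge(s) on load", dropped_self)
    return edges


def collapse_alleles_to_families(
    edges: WeightedEdgeList, family_map: GeneFamilyMap
) -> WeightedEdgeList:
    """Rename allele endpoints to their gene families.

    Edges that become self-loops are removed (logged); parallel edges are
    merged by summing weights.  Every allele must be present in the map.
    """
    missing = sorted(
        {n for a, b, _ in edges for n in (a, b) if n not in family_map}
    )
    if missing:
        raise ValidationError(
            "alleles missing from the family map: " + ", ".join(missing[:20])
        )
    merged: dict[tuple[str, str], float] = {}
    dropped_self = 0
    dropped_weight = 0.0
    for a, b, w in edges:
        fa, fb = family_map[a], family_map[b]
        if fa == fb:
            dropped_self += 1
            dropped_weight += w
            continue
        key = (fa, fb) if fa < fb else (fb, fa)
        merged[key] = merged.get(key, 0.0) + w
    if dropped_self:
        logger.info(
            "collapse removed %d self-loop edge(s) (total weight %g)",
            dropped_self,
            dropped_weight,
        )
    return [(a, b, w) for (a, b), w in merged.items()]


# ---------------------------------------------------------------------------
# metadata
# ---------------------------------------------------------------------------


def read_metadata(path: str | Path, id_column: str = "genome") -> MetadataTable:
    """Read a delimited metadata table keyed by ``id_column``.

    The delimiter is sniffed (tab wins over comma).  Empty cells become the
    explicit ``MISSING`` sentinel rather than being dropped.
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"input file does not exist: {path}")
    with path.open(encoding="utf-8") as fh:
        first = fh.readline()
    sep = "\t" if "\t" in first else ","
    try:
        frame = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    except Exception as exc:
        raise FormatError(f"{path}: cannot parse metadata: {exc}") from exc
    if id_column not in frame.columns:
        raise ValidationError(
            f"{path}: expected genome-id column {id_column!r}, "
            f"found {list(frame.columns)}"
        )
    ids = frame[id_column].tolist()
    if len(set(ids)) != len(ids):
        dupes = sorted({g for g in ids if ids.count(g) > 1})
        raise ValidationError(f"{path}: duplicated genome id(s): {dupes}")
    attributes = [c for c in frame.columns if c != id_column]
    records = {}
    for _, row in frame.iterrows():
        records[row[id_column]] = {
            a: (row[a] if row[a] != "" else MISSING) for a in attributes
        }
    return MetadataTable(attributes=attributes, records=records)


# ---------------------------------------------------------------------------
# graph writers / parsers
# ---------------------------------------------------------------------------


def _format_weight(w: float) -> str:
    """Render a weight so it can never be mistaken for a node token."""
    text = f"{float(w):.12g}"
    if "." not in text and "e" not in text and "inf" not in text:
        text += ".0"
    return text


def _quote(token: str) -> str:
    if '"' in token:
        raise ValidationError(
            f"name {token!r} contains a quote character; sanitize upstream"
        )
    return f'"{token}"'


def _annotation_records(
    graph: nx.Graph, annotations
) -> Iterable[tuple[str, str, str]]:
    """Yield (node, value, attribute) records for .layout NODECLASS lines."""
    from .clustering import ClusterAssignment  # local import to avoid a cycle

    if annotations is None:
        return
    items = annotations if isinstance(annotations, (list, tuple)) else [annotations]
    for ann in items:
        if isinstance(ann, MetadataTable):
            for node in graph.nodes:
                for attr in ann.attributes:
                    yield str(node), ann.get(str(node), attr), attr
        elif isinstance(ann, ClusterAssignment):
            attr = ann.name or f"{ann.method}_cluster"
            for node in graph.nodes:
                if node in ann.labels:
                    yield str(node), str(ann.labels[node]), attr
        elif isinstance(ann, Mapping):  # attribute name -> {node: value}
            for attr, column in ann.items():
                for node, value in column.items():
                    if node in graph:
                        yield str(node), str(value), str(attr)
        else:
            raise UsageError(f"unsupported annotation object {type(ann).__name__}")


def write_layout(graph: nx.Graph, annotations, path: str | Path) -> None:
    """Write the Graphia/BioLayout ``.layout`` subset.

    Edge lines are ``"a" "b" <weight>``; annotations are
    ``//NODECLASS "node" "value" "attribute"`` records.
    """
    if graph.number_of_nodes() == 0:
        raise ValidationError("refusing to write an empty graph")
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        for a, b, data in sorted(graph.edges(data=True), key=lambda e: (str(e[0]), str(e[1]))):
            a, b = sorted((str(a), str(b)))
            fh.write(f"{_quote(a)} {_quote(b)} {_format_weight(data['weight'])}\n")
        for node, value, attr in _annotation_records(graph, annotations):
            fh.write(f"//NODECLASS {_quote(node)} {_quote(value)} {_quote(attr)}\n")


def parse_layout(path: str | Path) -> tuple[nx.Graph, dict[str, dict[str, str]]]:
    """Parse a ``.layout`` file written by :func:`write_layout`.

    Returns the graph and a node -> {attribute: value} annotation map.
    """
    path = Path(path)
    graph = nx.Graph()
    annotations: dict[str, dict[str, str]] = {}
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("//NODECLASS"):
                fields = next(csv.reader([line[len("//NODECLASS "):]], delimiter=" "))
                if len(fields) != 3:
                    raise FormatError(f"{path}: malformed NODECLASS at line {lineno}")
                node, value, attr = fields
                annotations.setdefault(node, {})[attr] = value
            elif line.startswith("//"):
                continue  # other Graphia directives are ignored
            else:
                fields = next(csv.reader([line], delimiter=" "))
                if len(fields) != 3:
                    raise FormatError(f"{path}: malformed edge line {lineno}")
                a, b, raw_w = fields
                try:
                    w = float(raw_w)
                except ValueError as exc:
                    raise FormatError(f"{path}: bad weight at line {lineno}") from exc
                graph.add_edge(a, b, weight=w)
    return graph, annotations


def export_graph(graph: nx.Graph, fmt: str, path: str | Path) -> None:
    """Export a graph as ``graphml``, ``edge_tsv`` or ``layout``.

    Exporting an empty graph is an error (it almost always means the
    upstream filters removed everything).
    """
    if graph.number_of_nodes() == 0:
        raise ValidationError("refusing to export an empty graph")
    path = Path(path)
    if fmt == "graphml":
        out = nx.Graph()
        for node, data in graph.nodes(data=True):
            out.add_node(str(node), **_graphml_safe(data))
        for a, b, data in graph.edges(data=True):
            out.add_edge(str(a), str(b), **_graphml_safe(data))
        nx.write_graphml(out, path)
    elif fmt == "edge_tsv":
        with path.open("w", encoding="utf-8", newline="\n") as fh:
            fh.write("source\ttarget\tweight\n")
            for a, b, data in sorted(
                graph.edges(data=True), key=lambda e: (str(e[0]), str(e[1]))
            ):
                a, b = sorted((str(a), str(b)))
                fh.write(f"{a}\t{b}\t{_format_weight(data['weight'])}\n")
    elif fmt == "layout":
        columns: dict[str, dict[str, str]] = {}
        for node, data in graph.nodes(data=True):
            for attr, value in data.items():
                if isinstance(value, (list, tuple, set)):
                    value = ";".join(str(v) for v in value)
                columns.setdefault(attr, {})[str(node)] = str(value)
        write_layout(graph, columns or None, path)
    else:
        raise UsageError(f"unknown export format {fmt!r}")


def _graphml_safe(data: Mapping) -> dict:
    safe = {}
    for key, value in data.items():
        if isinstance(value, (list, tuple, set)):
            safe[key] = ";".join(str(v) for v in value)
        elif isinstance(value, (str, int, float, bool)) or value is None:
            if value is not None:
                safe[key] = value
        else:
            safe[key] = str(value)
    return safe


# ---------------------------------------------------------------------------
# gene orders (used by the synteny module and the simulator)
# ---------------------------------------------------------------------------


def write_gene_orders(orders, path: str | Path) -> None:
    """Serialize GeneOrders as TSV: genome, contig index, circular, genes."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("genome\tcontig\tcircular\tgenes\n")
        for genome_id, contigs in orders.items():
            for i, contig in enumerate(contigs):
                flag = "1" if contig.circular else "0"
                fh.write(f"{genome_id}\t{i}\t{flag}\t{','.join(contig.genes)}\n")


def read_gene_orders(path: str | Path):
    """Read the TSV produced by :func:`write_gene_orders`."""
    from .synteny import Contig  # local import to avoid a cycle

    path = Path(path)
    if not path.exists():
        raise ValidationError(f"input file does not exist: {path}")
    orders: dict[str, list] = {}
    with path.open(encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:4] != ["genome", "contig", "circular", "genes"]:
            raise FormatError(f"{path}: unexpected gene-orders header {header}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise FormatError(f"{path}: malformed line {lineno}")
            genome_id, _, flag, genes = parts
            orders.setdefault(genome_id, []).append(
                Contig(genes=genes.split(","), circular=flag == "1")
            )
    return orders
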