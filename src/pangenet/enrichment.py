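"""Cluster-versus-metadata enrichment and gene-cluster distribution profiles.

The enrichment kernel is the two-sided Fisher exact test: with the table's
margins fixed, the p-value sums the hypergeometric probabilities of every
table at least as extreme (probability no greater than the observed
table's, with a small relative slack so equal-probability tables are
included despite floating-point noise).  P-values from all pairs tested in
one call are adjusted together, Benjamini-Hochberg by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from pathlib import Path

import numpy as np
from scipy.special import gammaln

from .errors import UsageError, ValidationError
from .io import MISSING, GenePresenceAbsenceMatrix

_SLACK = 1e-7


@dataclass
class EnrichmentResult:
    value_a: str
    value_b: str
    table: tuple[int, int, int, int]  # (a&b, a&!b, !a&b, !a&!b)
    odds_ratio: float
    p: float
    adj_p: float
    significant: bool


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p-value for a 2x2 count table.

    ``table`` is ``[[n11, n10], [n01, n00]]``.  Degenerate margins give 1.
    """
    flat = np.asarray(table, dtype=float).ravel()
    if flat.shape != (4,):
        raise ValidationError("table must be 2x2")
    if (flat < 0).any() or not np.allclose(flat, np.round(flat)):
        raise ValidationError("table entries must be non-negative integers")
    n11, n10, n01, n00 = (int(v) for v in np.round(flat))
    r1 = n11 + n10
    c1 = n11 + n01
    total = n11 + n10 + n01 + n00
    if r1 == 0 or c1 == 0 or r1 == total or c1 == total:
        return 1.0
    support = np.arange(max(0, r1 + c1 - total), min(r1, c1) + 1)
    # hypergeometric pmf over the support, via log-binomials
    log_pmf = (
        _log_comb(c1, support)
        + _log_comb(total - c1, r1 - support)
        - _log_comb(total, r1)
    )
    pmf = np.exp(log_pmf)
    observed = pmf[n11 - support[0]]
    p = float(pmf[pmf <= observed * (1.0 + _SLACK)].sum())
    return min(p, 1.0)


def _log_comb(n, k) -> np.ndarray:
    n = np.asarray(n, dtype=float)
    k = np.asarray(k, dtype=float)
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def odds_ratio_2x2(table) -> float:
    (n11, n10), (n01, n00) = table
    if n10 * n01 == 0:
        return float("inf") if n11 * n00 > 0 else float("nan")
    return (n11 * n00) / (n10 * n01)


def benjamini_hochberg(pvalues) -> np.ndarray:
    """BH step-up adjusted p-values, clipped to <= 1, order preserving."""
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    # enforce monotonicity from the largest rank downwards
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.clip(adjusted, 0.0, 1.0)
    return out


def bonferroni(pvalues) -> np.ndarray:
    p = np.asarray(pvalues, dtype=float)
    return np.clip(p * p.size, 0.0, 1.0)


def enrichment_analysis(
    attr_a: dict,
    attr_b: dict,
    alpha: float = 0.05,
    adjust: str = "bh",
    include_missing: bool = False,
) -> tuple[list[EnrichmentResult], dict[str, bool]]:
    """Fisher enrichment between two categorical node attributes.

    One test is run per (value_a, value_b) pair over the universe of nodes
    carrying both attributes; nodes whose value is the ``"NA"`` sentinel
    are excluded unless ``include_missing``.  Returns the per-pair results
    (adjusted across all pairs tested in this call) and, per value of
    ``attr_a``, whether it is significantly associated with at least one
    value of ``attr_b``.
    """
    if adjust not in ("bh", "bonferroni"):
        raise UsageError(f"unknown adjustment {adjust!r}")
    universe = sorted(set(attr_a) & set(attr_b), key=str)
    if not include_missing:
        universe = [
            n for n in universe if attr_a[n] != MISSING and attr_b[n] != MISSING
        ]
    if not universe:
        raise ValidationError("empty node universe for enrichment")
    values_a = sorted({str(attr_a[n]) for n in universe})
    values_b = sorted({str(attr_b[n]) for n in universe})
    tests = []
    for va, vb in product(values_a, values_b):
        n11 = n10 = n01 = n00 = 0
        for node in universe:
            in_a = str(attr_a[node]) == va
            in_b = str(attr_b[node]) == vb
            if in_a and in_b:
                n11 += 1
            elif in_a:
                n10 += 1
            elif in_b:
                n01 += 1
            else:
                n00 += 1
        table = ((n11, n10), (n01, n00))
        tests.append((va, vb, table, fisher_exact_2x2(table)))
    raw = [t[3] for t in tests]
    adj = benjamini_hochberg(raw) if adjust == "bh" else bonferroni(raw)
    results = []
    any_significant: dict[str, bool] = {va: False for va in values_a}
    for (va, vb, table, p), ap in zip(tests, adj):
        significant = bool(ap < alpha)
        results.append(
            EnrichmentResult(
                value_a=va,
                value_b=vb,
                table=(table[0][0], table[0][1], table[1][0], table[1][1]),
                odds_ratio=odds_ratio_2x2(table),
                p=p,
                adj_p=float(ap),
                significant=significant,
            )
        )
        if significant:
            any_significant[va] = True
    return results, any_significant


def write_enrichment_tsv(results, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("value_a\tvalue_b\tn11\tn10\tn01\tn00\todds_ratio\tp\tadj_p\tsignificant\n")
        for r in results:
            fh.write(
                f"{r.value_a}\t{r.value_b}\t{r.table[0]}\t{r.table[1]}\t{r.table[2]}\t"
                f"{r.table[3]}\t{r.odds_ratio:.6g}\t{r.p:.6g}\t{r.adj_p:.6g}\t"
                f"{int(r.significant)}\n"
            )


# ---------------------------------------------------------------------------
# gene-cluster distribution profiles
# ---------------------------------------------------------------------------


@dataclass
class GeneClusterProfile:
    """Per-cluster, per-genome proportion of the cluster's genes present."""

    cluster_labels: list[int]
    genome_ids: list[str]
    values: np.ndarray  # clusters x genomes, in [0, 1]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.cluster_labels), len(self.genome_ids)):
            raise ValidationError("profile shape mismatch")
        if (self.values < 0).any() or (self.values > 1).any():
            raise ValidationError("profile proportions must lie in [0, 1]")

    def to_tsv(self, path: str | Path) -> None:
        with Path(path).open("w", encoding="utf-8", newline="\n") as fh:
            fh.write("cluster\tgenome\tproportion\n")
            for i, label in enumerate(self.cluster_labels):
                for j, genome in enumerate(self.genome_ids):
                    fh.write(f"{label}\t{genome}\t{self.values[i, j]:.6g}\n")


def gene_cluster_profiles(
    matrix: GenePresenceAbsenceMatrix,
    assignment,
    metadata=None,
    order_by=None,
    clusters=None,
) -> GeneClusterProfile:
    """Compute the per-genome proportion of each gene cluster's genes.

    ``assignment`` maps gene ids (a subset of the matrix's columns) to
    cluster labels.  Genomes are ordered by the ``order_by`` metadata
    attributes (then id) when given, otherwise kept in matrix order.
    """
    labels = assignment.labels if hasattr(assignment, "labels") else dict(assignment)
    gene_index = {g: j for j, g in enumerate(matrix.gene_ids)}
    by_cluster: dict[int, list[int]] = {}
    for gene, label in labels.items():
        if gene in gene_index:
            by_cluster.setdefault(label, []).append(gene_index[gene])
    wanted = sorted(set(labels.values())) if clusters is None else list(clusters)
    for label in wanted:
        if not by_cluster.get(label):
            raise ValidationError(f"cluster {label!r} has no genes in the matrix")
    genome_ids = list(matrix.genome_ids)
    if order_by:
        if metadata is None:
            raise UsageError("order_by requires a metadata table")
        genome_ids.sort(key=lambda g: tuple(metadata.get(g, a) for a in order_by) + (g,))
    row_index = {g: i for i, g in enumerate(matrix.genome_ids)}
    rows = [row_index[g] for g in genome_ids]
    values = np.empty((len(wanted), len(genome_ids)))
    for i, label in enumerate(wanted):
        cols = by_cluster[label]
        values[i] = matrix.values[np.ix_(rows, cols)].sum(axis=1) / len(cols)
    return GeneClusterProfile(
        cluster_labels=list(wanted), genome_ids=genome_ids, values=values
    )


def plot_profiles(
    profile: GeneClusterProfile,
    annotations=None,
    path: str | Path = "profiles.png",
    tracks=None,
) -> Path:
    """Render one bar panel per cluster and always write the numeric TSV twin.

    Returns the path of the TSV (the figure lands at ``path``).
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    path = Path(path)
    tsv_path = path.with_suffix(".tsv")
    profile.to_tsv(tsv_path)

    n_clusters = len(profile.cluster_labels)
    track_attrs = list(tracks or (annotations.attributes if annotations else []))
    fig, axes = plt.subplots(
        n_clusters,
        1,
        figsize=(max(6.0, len(profile.genome_ids) * 0.08), 1.6 * n_clusters + 1),
        squeeze=False,
        sharex=True,
    )
    x = np.arange(len(profile.genome_ids))
    for i, label in enumerate(profile.cluster_labels):
        ax = axes[i][0]
        ax.bar(x, profile.values[i], width=1.0, color="#3b6ea5")
        ax.set_ylim(0, 1.05)
        ax.set_ylabel(f"cluster {label}", fontsize=8)
        ax.set_xticks([])
    if annotations is not None and track_attrs:
        ax = axes[-1][0]
        for t, attr in enumerate(track_attrs):
            values = [annotations.get(g, attr) for g in profile.genome_ids]
            palette = {v: k for k, v in enumerate(sorted(set(values)))}
            cmap = plt.get_cmap("tab20")
            for j, v in enumerate(values):
                ax.add_patch(
                    plt.Rectangle(
                        (j - 0.5, -0.12 * (t + 1)),
                        1.0,
                        0.1,
                        color=cmap(palette[v] % 20),
                        clip_on=False,
                    )
                )
        ax.set_ylim(0, 1.05)
    fig.suptitle("Gene cluster distribution profiles")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return tsv_path
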