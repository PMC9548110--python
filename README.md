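# pangenet

Graph-based bacterial pangenome analysis. From a binary gene
presence/absence matrix and gene-order information, `pangenet` builds the
three standard pangenome networks —

* **genome–genome similarity** (nodes = genomes, edges weighted by the
  Jaccard similarity of accessory gene content; cosine and a
  Euclidean-derived similarity are also available),
* **gene–gene co-occurrence** (the same matrix inverted: nodes = gene
  families, edges weighted by the Jaccard similarity of their genome
  sets),
* **gene synteny** (nodes = gene families, edge weights count the genomes
  in which two families are adjacent on a replicon),

then filters them (strict edge-weight thresholds, union- or
mutual-semantics k-NN sparsification, gene-frequency bounds, component
pruning, contraction of high-conservation edges), clusters them (an
in-package deterministic MCL implementation and seeded Louvain), tests
cluster–metadata association with adjusted Fisher exact tests, and
computes per-genome gene-cluster distribution profiles. Graphs export to
Graphia/BioLayout `.layout`, GraphML, and TSV edge lists.

A seed-deterministic synthetic-pangenome generator (clonal lineages with
lineage-restricted accessory blocks, lineage-independent mobile-element
blocks, core genes at frequency 1, circular per-genome gene orders) makes
the whole pipeline testable without any external data.

## Test

```sh
python -m pytest -q tests/
```

The suite includes independent oracles (set-arithmetic similarity,
exhaustive k-NN enumeration, exact-integer Fisher enumeration, a
whole-matrix MCL reference, brute-force maximum-modularity partitions)
and an acceptance suite (`tests/test_acceptance.py`).

## CLI

```sh
pangenet simulate --seed 7 --out data/                 # synthetic dataset
pangenet convert --in gpa.csv --dialect roary_csv --out matrix.rtab
pangenet genome-graph --matrix matrix.rtab --min-weight 0.8 --knn 8 --out genomes.layout
pangenet gene-graph   --matrix matrix.rtab --min-weight 0.55 --out genes.layout
pangenet synteny --orders data/orders.tsv --out synteny.layout
pangenet transform --graph synteny.layout --ops "min-edge=7,largest,contract=770" --out small.layout
pangenet cluster --graph genomes.layout --method mcl --inflation 2.0 --out clusters.tsv
pangenet enrich --nodes nodes.tsv --id-column node --a cluster --b CC --out enrichment.tsv
pangenet profiles --matrix matrix.rtab --clusters gene_clusters.tsv \
    --metadata data/metadata.tsv --order lineage,host --out profiles.png
pangenet run --config workflow.yaml                    # full three-graph workflow
```

`pangenet run` reads a YAML config (input paths or a `simulate:` block,
per-graph parameter blocks with fraction-based frequency cutoffs, output
directory, seed) and writes all graphs, cluster tables, the enrichment
table, profile TSVs, transform logs and a `manifest.json` with content
hashes; reruns with the same config and seed are bit-identical.

Presence/absence dialects: Roary `gene_presence_absence.csv` (any
non-empty genome cell ⇒ present), binary Rtab, and PIRATE gene-family
tables (rows filtered to one identity threshold, default 90). Synteny
input: per-genome gene-order TSVs, GFF3 annotations plus an
allele→family map, or PIRATE-style `.edges` lists.

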