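# markerpanels

Discovery of single- and multi-gene marker panels that isolate a cell
cluster from its background in high-throughput expression data (e.g.
single-cell RNA-seq).

For a chosen cluster, every gene — and its negation track, so absence of
expression can act as a marker — is scored with the XL-constrained minimal
hypergeometric (XL-mHG) threshold test: cells are sorted by decreasing
expression, every admissible prefix is scored with a hypergeometric tail,
and the minimizing threshold gives both an exact enrichment p-value (via a
dynamic program over arrangement lattices) and an expression cutoff used to
binarize the gene. The cluster-specific binary matrix then drives an
exhaustive (or heuristically restricted) enumeration of 2-, 3-, and 4-gene
AND-panels via matrix multiplications, ranked by hypergeometric enrichment
and, for pairs, a Cluster-Clear-Score that rewards panels which clean out
contaminating clusters relative to their lead gene.

A simulation benchmark (Gaussian and shifted negative-binomial single-gene
engines, Gaussian and noisy Poisson–Gamma count matrix engines) compares the
XL-mHG ranking with standard DE tests (Welch's t, Wilcoxon rank-sum,
Kolmogorov–Smirnov, logistic-regression LRT) and with tree-ensemble
classifiers, scored by the scaled sum of ranks (SSR) of planted good
markers.

## CLI

```sh
# generate a small toy dataset
markerpanels fixtures --out demo --seed 1

# full per-cluster analysis (singles + pairs + triples)
markerpanels run --matrix demo/matrix.tsv --clusters demo/clusters.tsv \
    --coords demo/coords.tsv --panel-sizes 1,2,3 --output demo_out

# heuristic mode for large inputs
markerpanels run --matrix demo/matrix.tsv --clusters demo/clusters.tsv \
    --heuristic --core-size 50 --panel-sizes 1,2 --output demo_out2

# simulation benchmark
markerpanels simulate --engine gaussian --effect-grid 0,1,2,3,4 \
    --n 5000 --runs 100 --out bench.tsv
```

Inputs: a dense genes-by-cells TSV/CSV (`--transpose` for cells-by-genes),
or a MatrixMarket `.mtx` triplet with `--sparse-rows`/`--sparse-cols` id
files; a two-column cell/cluster table; optional 2-D coordinates for plots
and an optional gene list restricting the search space. No normalization is
applied internally.

Each cluster gets its own output directory with `singles/` (three ranked
TSV tables), `pairs/`, `triples/`, `quads/` ranked panel tables, and a run
log.

## Package layout

- `markerpanels.xlmhg` — the threshold test: ranking with conservative tie
  handling, statistic minimization under X/L constraints, exact DP p-value
  (log-space, batched).
- `markerpanels.singles` — per-cluster gene statistics: negation tracks,
  slide-up binarization, TP/TN rates, log2 fold change, rank aggregation
  and filters.
- `markerpanels.panels` — pair/triple/quad enumeration from binary matrix
  products, hypergeometric ranking, Cluster-Clear-Score, heuristic core
  candidate generation, output caps.
- `markerpanels.simulate` — simulation engines, DE test suite, logistic
  LRT, SSR, benchmark drivers.
- `markerpanels.io` / `markerpanels.cli` — file formats, per-cluster
  orchestration, command line.
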