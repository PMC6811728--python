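"""File I/O and per-cluster orchestration.

Accepts dense TSV/CSV expression matrices (genes as rows by default) or a
MatrixMarket sparse triplet with separate row/column id files, plus a
two-column cell-to-cluster table and optional 2-D visualization coordinates.
No normalization is applied internally; that is the caller's responsibility.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__, panels, singles
from .panels import (
    DEFAULT_CORE_SIZE,
    filter_binary,
    heuristic_candidates,
    output_limits,
    rank_pairs,
    rank_quads,
    rank_triples,
)
from .singles import (
    ClusterAssignment,
    ExpressionMatrix,
    compute_gene_stats,
    rank_single_genes,
)
from .xlmhg import XLParams, default_xl

__all__ = ["RunConfig", "load_inputs", "run_all_clusters"]

log = logging.getLogger("markerpanels")

PANEL_COLUMNS = [
    "genes",
    "hypergeom_pvalue",
    "tp_rate",
    "tn_rate",
    "ccs",
    "final_rank",
]


@dataclass
class RunConfig:
    """Everything needed for a full per-cluster marker-panel run."""

    matrix_path: str | Path
    clusters_path: str | Path
    output_dir: str | Path
    coords_path: str | Path | None = None
    gene_list_path: str | Path | None = None
    sparse_rows_path: str | Path | None = None
    sparse_cols_path: str | Path | None = None
    x_param: int | None = None
    l_param: int | None = None
    panel_sizes: tuple[int, ...] = (1, 2)
    heuristic: bool = False
    core_size: int = DEFAULT_CORE_SIZE
    seed: int = 0
    plot: bool = False
    transpose: bool = False

    def __post_init__(self) -> None:
        self.panel_sizes = tuple(sorted(set(int(s) for s in self.panel_sizes)))
        if not self.panel_sizes:
            raise ValueError("panel_sizes must be non-empty")
        if any(s not in (1, 2, 3, 4) for s in self.panel_sizes):
            raise ValueError("panel sizes must be within {1, 2, 3, 4}")
        if self.core_size < 1:
            raise ValueError("core_size must be >= 1")


# ---------------------------------------------------------------------------
# loading
# ---------------------------------------------------------------------------

def _read_table(path: Path) -> pd.DataFrame:
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    return pd.read_csv(path, sep=sep, index_col=0)


def load_expression(
    path: str | Path,
    rows_path: str | Path | None = None,
    cols_path: str | Path | None = None,
    transpose: bool = False,
) -> ExpressionMatrix:
    """Load a dense TSV/CSV matrix, or a MatrixMarket triplet when row/col id
    files are given.  ``transpose`` flips a cells-by-genes input."""
    path = Path(path)
    if path.suffix.lower() == ".mtx":
        if rows_path is None or cols_path is None:
            raise ValueError("sparse input needs row and column id files")
        from scipy.io import mmread

        values = np.asarray(mmread(str(path)).todense(), dtype=np.float64)
        gene_ids = Path(rows_path).read_text().split()
        cell_ids = Path(cols_path).read_text().split()
        df = pd.DataFrame(values, index=gene_ids, columns=cell_ids)
    else:
        df = _read_table(path)
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
    if transpose:
        df = df.T
    if df.index.duplicated().any():
        raise ValueError("duplicate gene ids in expression matrix")
    return ExpressionMatrix.from_dataframe(df)


def load_clusters(path: str | Path) -> ClusterAssignment:
    """Two-column (cell, cluster) TSV/CSV; a 'cell<sep>cluster' header row is
    optional."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, header=None, dtype=str)
    if df.shape[1] < 2:
        raise ValueError("cluster table needs two columns: cell, cluster")
    if list(df.iloc[0, :2]) == ["cell", "cluster"]:
        df = df.iloc[1:]
    return ClusterAssignment(dict(zip(df.iloc[:, 0], df.iloc[:, 1])))


def load_coordinates(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0)
    df.index = df.index.astype(str)
    if df.shape[1] < 2:
        raise ValueError("coordinates need two columns per cell")
    return df.iloc[:, :2]


def load_inputs(
    config: RunConfig,
) -> tuple[ExpressionMatrix, ClusterAssignment, pd.DataFrame | None, list[str] | None]:
    """Load and reconcile all inputs; cells absent from either the matrix or
    the cluster table are dropped (and counted in the log)."""
    matrix = load_expression(
        config.matrix_path,
        rows_path=config.sparse_rows_path,
        cols_path=config.sparse_cols_path,
        transpose=config.transpose,
    )
    clusters = load_clusters(config.clusters_path)
    common = [c for c in matrix.cell_ids if c in clusters.assignments]
    if not common:
        raise ValueError("no overlapping cell ids between matrix and clusters")
    dropped = matrix.n_cells - len(common)
    if dropped:
        log.warning("dropping %d cells absent from the cluster table", dropped)
        idx = {c: i for i, c in enumerate(matrix.cell_ids)}
        cols = [idx[c] for c in common]
        matrix = ExpressionMatrix(matrix.values[:, cols], matrix.gene_ids, common)
    clusters = ClusterAssignment(
        {c: clusters.assignments[c] for c in common}
    )
    gene_list: list[str] | None = None
    if config.gene_list_path is not None:
        gene_list = Path(config.gene_list_path).read_text().split()
        matrix = matrix.restrict_genes(gene_list)
        if matrix.n_genes == 0:
            raise ValueError("gene list removed every gene")
    coords = None
    if config.coords_path is not None:
        coords = load_coordinates(config.coords_path)
    return matrix, clusters, coords, gene_list


# ---------------------------------------------------------------------------
# output
# ---------------------------------------------------------------------------

def panel_records_frame(records: Sequence[panels.PanelRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "genes": ["+".join(r.genes) for r in records],
            "hypergeom_pvalue": [r.hypergeom_pvalue for r in records],
            "tp_rate": [r.tp_rate for r in records],
            "tn_rate": [r.tn_rate for r in records],
            "ccs": [r.ccs for r in records],
            "final_rank": [r.final_rank for r in records],
        },
        columns=PANEL_COLUMNS,
    )


def _write(df: pd.DataFrame, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)


def run_cluster(
    matrix: ExpressionMatrix,
    clusters: ClusterAssignment,
    K: str,
    out_dir: Path,
    params: XLParams | None = None,
    panel_sizes: Sequence[int] = (1, 2),
    heuristic: bool = False,
    core_size: int = DEFAULT_CORE_SIZE,
    coords: pd.DataFrame | None = None,
    plot: bool = False,
) -> None:
    """Single-gene stats, panel rankings, and table output for one cluster."""
    stats, binary = compute_gene_stats(matrix, clusters, K, params=params)
    ranked_all, ranked_pos, full = rank_single_genes(stats)
    if 1 in panel_sizes:
        _write(ranked_all, out_dir / "singles" / "ranked_all.tsv")
        _write(ranked_pos, out_dir / "singles" / "ranked_positive.tsv")
        _write(full, out_dir / "singles" / "all_stats.tsv")

    member = clusters.mask(matrix.cell_ids, K)
    fbm = filter_binary(binary, stats, member)
    cluster_labels = clusters.labels_for(matrix.cell_ids)

    # core = best single genes by XL-mHG p-value among retained genes
    by_pvalue = sorted(
        fbm.gene_ids, key=lambda g: (fbm.single_pvalues[g], g)
    )

    for size, name, runner in (
        (2, "pairs", None),
        (3, "triples", rank_triples),
        (4, "quads", rank_quads),
    ):
        if size not in panel_sizes:
            continue
        candidates = None
        if heuristic:
            candidates = heuristic_candidates(
                by_pvalue, core_size, size, fbm.gene_ids
            )
        if size == 2:
            records = rank_pairs(
                fbm, cluster_labels=cluster_labels, K=K, candidates=candidates
            )
        else:
            records = runner(fbm, candidates=candidates)
        records = output_limits(records)
        _write(panel_records_frame(records), out_dir / name / f"{name}_ranked.tsv")
        if plot and coords is not None and records:
            _plot_top_panels(fbm, records[:10], coords, out_dir / name)


def _plot_top_panels(fbm, records, coords, out_dir: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    xy = coords.reindex(
        [c for c in coords.index]
    )
    for rank_pos, rec in enumerate(records, start=1):
        gidx = {g: i for i, g in enumerate(fbm.gene_ids)}
        mask = np.ones(fbm.n_cells, dtype=bool)
        for g in rec.genes:
            mask &= fbm.values[gidx[g]].astype(bool)
        fig, ax = plt.subplots(figsize=(4, 4))
        ax.scatter(xy.iloc[:, 0], xy.iloc[:, 1], c=np.where(mask, "red", "blue"), s=4)
        ax.set_title("+".join(rec.genes))
        out_dir.mkdir(parents=True, exist_ok=True)
        fig.savefig(out_dir / f"panel_{rank_pos:03d}.png", dpi=80)
        plt.close(fig)


def run_all_clusters(config: RunConfig) -> Path:
    """Independent analysis per cluster; one output directory each."""
    matrix, clusters, coords, _ = load_inputs(config)
    out_root = Path(config.output_dir)
    out_root.mkdir(parents=True, exist_ok=True)
    lines = [
        f"markerpanels {__version__}",
        f"matrix: {config.matrix_path} ({matrix.n_genes} genes x {matrix.n_cells} cells)",
        f"clusters: {config.clusters_path} ({len(clusters.clusters)} clusters)",
        f"panel sizes: {config.panel_sizes}",
        f"mode: {'heuristic' if config.heuristic else 'exhaustive'}"
        + (f" (core size {config.core_size})" if config.heuristic else ""),
        f"X override: {config.x_param}  L override: {config.l_param}",
        f"seed: {config.seed}",
        "note: no normalization is applied internally; inputs are used as given",
    ]
    for K in clusters.clusters:
        m = clusters.size(K)
        if m < 2:
            log.warning("skipping cluster %r of size %d", K, m)
            lines.append(f"cluster {K}: skipped (size {m})")
            continue
        n = matrix.n_cells
        if config.x_param is not None or config.l_param is not None:
            defaults = default_xl(m, n)
            params = XLParams(
                X=config.x_param if config.x_param is not None else defaults.X,
                L=config.l_param if config.l_param is not None else defaults.L,
            )
        else:
            params = None
        run_cluster(
            matrix,
            clusters,
            K,
            out_root / f"cluster_{K}",
            params=params,
            panel_sizes=config.panel_sizes,
            heuristic=config.heuristic,
            core_size=config.core_size,
            coords=coords,
            plot=config.plot,
        )
        lines.append(f"cluster {K}: done (size {m})")
    (out_root / "run_log.txt").write_text("\n".join(lines) + "\n")
    return out_root
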