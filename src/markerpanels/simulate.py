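"""Monte Carlo benchmark engines and scoring.

Single-gene engines (Gaussian, shifted negative binomial) compare the
XL-mHG test with standard two-sample DE tests across effect sizes and sample
sizes.  Matrix engines (Gaussian, noisy Poisson-Gamma counts) plant known
good/poor/non-marker genes in a two-cluster expression matrix and score each
ranking method with the scaled sum of ranks (SSR) of the planted good
markers; SSR = 1 means the good markers fill the top of the list.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import chi2, ks_2samp, ranksums, ttest_ind

from . import xlmhg
from .singles import ExpressionMatrix
from .xlmhg import default_xl

__all__ = [
    "SingleGeneSimConfig",
    "MatrixSimConfig",
    "PoissonGammaConfig",
    "simulate_single_gene",
    "simulate_matrix",
    "de_test_suite",
    "lrt_logistic",
    "lrt_logistic_batch",
    "ssr",
    "rank_by_xlmhg",
    "rank_by_lrt",
    "rank_by_gini",
    "benchmark_curves",
    "classifier_benchmark",
]

DE_TESTS = ("welch_t", "wilcoxon", "ks", "lrt")


# ---------------------------------------------------------------------------
# configurations
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SingleGeneSimConfig:
    """One gene in n cells, a fraction of which form the cluster of interest.

    Gaussian engine: cluster ~ Normal(effect, 1), background ~ Normal(0, 5).
    Negative-binomial engine: background counts ~ NB(1, 0.1) (mean 9),
    cluster counts ~ NB(5, 0.5) shifted by 4 + effect (mean 9 + effect), so
    the mean difference is exactly ``effect``.
    """

    n: int
    effect: float = 0.0
    cluster_fraction: float = 0.1
    engine: str = "gaussian"
    runs: int = 100
    shuffle: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.cluster_fraction < 1.0:
            raise ValueError("cluster_fraction must be in (0, 1)")
        if self.runs < 1:
            raise ValueError("runs must be >= 1")
        if self.engine not in ("gaussian", "negative_binomial"):
            raise ValueError(f"unknown engine {self.engine!r}")


@dataclass(frozen=True)
class MatrixSimConfig:
    """Two-cluster gene-by-cell matrix with planted marker structure.

    5% of genes are good markers, ``poor_fraction`` are poor markers
    (expressed only in a random ``poor_expressed_fraction`` of cluster
    cells), the rest are non-markers.
    """

    n_cells: int = 500
    n_genes: int = 1000
    cluster_fraction: float = 0.1
    good_fraction: float = 0.05
    poor_fraction: float = 0.10
    poor_expressed_fraction: float = 0.10
    # Gaussian engine means (unit sd everywhere); the good-marker separation
    # is parameterized because a cleanly separated default is required for
    # the planted genes to actually be good markers.
    good_mean: float = 5.0
    poor_mean: float = 30.0
    engine: str = "gaussian_matrix"

    def __post_init__(self) -> None:
        if self.good_fraction + self.poor_fraction > 1.0:
            raise ValueError("gene-class fractions exceed 1")
        if not 0.0 < self.poor_expressed_fraction < 1.0:
            raise ValueError("poor_expressed_fraction must be in (0, 1)")
        if self.engine not in ("gaussian_matrix", "poisson_gamma"):
            raise ValueError(f"unknown engine {self.engine!r}")


@dataclass(frozen=True)
class PoissonGammaConfig:
    """Hierarchical count model with per-cell efficiency noise.

    Per gene and population, a mean is drawn from Gamma(shape, rate); true
    counts are Poisson around it; each cell's counts are scaled by an
    efficiency factor ~ Uniform[1-e, 1+e] and Poisson-resampled.  The shape
    defaults read printed exponent shorthands as powers of two.
    """

    rate: float = 0.1
    alpha_good_k: float = 2.0 ** 5
    alpha_good_c: float = 2.0 ** 4
    alpha_non: float = 2.0 ** 4
    alpha_poor_expressed: float = 2.0 ** 10
    alpha_poor_rest: float = 2.0 ** 4
    efficiency_halfwidth: float = 0.2

    def __post_init__(self) -> None:
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        if not 0.0 <= self.efficiency_halfwidth < 1.0:
            raise ValueError("efficiency_halfwidth must be in [0, 1)")


# ---------------------------------------------------------------------------
# engines
# ---------------------------------------------------------------------------

def simulate_single_gene(
    config: SingleGeneSimConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Draw one gene's expression and the 0/1 membership vector."""
    n = config.n
    m = int(round(config.cluster_fraction * n))
    if not 0 < m < n:
        raise ValueError("cluster size out of range for this n")
    if config.engine == "gaussian":
        in_k = rng.normal(config.effect, 1.0, size=m)
        background = rng.normal(0.0, 5.0, size=n - m)
    else:
        background = rng.negative_binomial(1, 0.1, size=n - m).astype(np.float64)
        in_k = rng.negative_binomial(5, 0.5, size=m).astype(np.float64)
        in_k += 4.0 + config.effect
    expr = np.concatenate([in_k, background])
    member = np.concatenate([np.ones(m, dtype=np.int8), np.zeros(n - m, dtype=np.int8)])
    if config.shuffle:
        perm = rng.permutation(n)
        expr, member = expr[perm], member[perm]
    return expr, member


def simulate_matrix(
    config: MatrixSimConfig,
    rng: np.random.Generator,
    pg: PoissonGammaConfig | None = None,
) -> tuple[ExpressionMatrix, np.ndarray, np.ndarray]:
    """Gene-by-cell matrix plus cell membership mask and gene truth classes.

    Returns ``(matrix, member, gene_classes)`` where ``gene_classes`` holds
    'good', 'poor' or 'non' per gene row.
    """
    n, p = config.n_cells, config.n_genes
    m = int(round(config.cluster_fraction * n))
    n_good = int(round(config.good_fraction * p))
    n_poor = int(round(config.poor_fraction * p))
    n_non = p - n_good - n_poor
    member = np.zeros(n, dtype=bool)
    member[:m] = True
    classes = np.array(
        ["good"] * n_good + ["poor"] * n_poor + ["non"] * n_non, dtype=object
    )
    n_expr = max(1, int(round(config.poor_expressed_fraction * m)))

    values = np.empty((p, n))
    if config.engine == "gaussian_matrix":
        values[:] = rng.normal(0.0, 1.0, size=(p, n))
        values[:n_good, member] += config.good_mean
        for g in range(n_good, n_good + n_poor):
            cells = rng.choice(np.flatnonzero(member), size=n_expr, replace=False)
            values[g, cells] += config.poor_mean
    else:
        pg = pg or PoissonGammaConfig()
        scale = 1.0 / pg.rate
        true_counts = np.empty((p, n))
        for g in range(p):
            if classes[g] == "good":
                mu_k = rng.gamma(pg.alpha_good_k, scale)
                mu_c = rng.gamma(pg.alpha_good_c, scale)
                mu = np.where(member, mu_k, mu_c)
            elif classes[g] == "non":
                mu_k = rng.gamma(pg.alpha_non, scale)
                mu_c = rng.gamma(pg.alpha_non, scale)
                mu = np.where(member, mu_k, mu_c)
            else:
                cells = rng.choice(np.flatnonzero(member), size=n_expr, replace=False)
                expressed = np.zeros(n, dtype=bool)
                expressed[cells] = True
                mu_hi = rng.gamma(pg.alpha_poor_expressed, scale)
                mu_lo = rng.gamma(pg.alpha_poor_rest, scale)
                mu = np.where(expressed, mu_hi, mu_lo)
            true_counts[g] = rng.poisson(mu)
        e = pg.efficiency_halfwidth
        efficiency = rng.uniform(1.0 - e, 1.0 + e, size=n)
        values[:] = rng.poisson(efficiency[None, :] * true_counts)

    gene_ids = [f"g{i:04d}" for i in range(p)]
    cell_ids = [f"c{i:04d}" for i in range(n)]
    return ExpressionMatrix(values, gene_ids, cell_ids), member, classes


# ---------------------------------------------------------------------------
# DE tests and the logistic likelihood-ratio test
# ---------------------------------------------------------------------------

def _null_loglik(y: np.ndarray) -> float:
    ybar = y.mean()
    return float(y.size * (ybar * np.log(ybar) + (1 - ybar) * np.log(1 - ybar)))


def lrt_logistic_batch(
    x: np.ndarray, y: np.ndarray, max_iter: int = 60
) -> tuple[np.ndarray, np.ndarray]:
    """Likelihood-ratio test of slope = 0 in a one-feature logistic model,
    vectorized over rows of ``x``.  Damped Newton iterations; under perfect
    separation the statistic converges to its supremum, which is what the
    test needs.  Returns (statistics, p-values) against chi-square(1)."""
    x = np.atleast_2d(np.asarray(x, dtype=np.float64))
    y = np.asarray(y, dtype=np.float64)
    if y.min() < 0 or y.max() > 1:
        raise ValueError("labels must be 0/1")
    if y.sum() == 0 or y.sum() == y.size:
        raise ValueError("both groups must be non-empty")
    g_count, n = x.shape
    ll_null = _null_loglik(y)
    b0 = np.full(g_count, float(np.log(y.mean() / (1 - y.mean()))))
    b1 = np.zeros(g_count)
    for _ in range(max_iter):
        eta = np.clip(b0[:, None] + b1[:, None] * x, -35.0, 35.0)
        mu = expit(eta)
        w = mu * (1.0 - mu)
        r = y[None, :] - mu
        g0 = r.sum(axis=1)
        g1 = (r * x).sum(axis=1)
        h00 = w.sum(axis=1)
        h01 = (w * x).sum(axis=1)
        h11 = (w * x * x).sum(axis=1)
        det = h00 * h11 - h01 * h01
        det = np.where(det > 1e-12, det, 1e-12)
        d0 = (h11 * g0 - h01 * g1) / det
        d1 = (h00 * g1 - h01 * g0) / det
        # damp oversized Newton steps (separation sends coefficients to inf)
        damp = np.maximum(1.0, np.maximum(np.abs(d0), np.abs(d1)) / 5.0)
        b0 += d0 / damp
        b1 += d1 / damp
        if np.max(np.abs(g0)) < 1e-10 and np.max(np.abs(g1)) < 1e-10:
            break
    eta = np.clip(b0[:, None] + b1[:, None] * x, -35.0, 35.0)
    ll = (y[None, :] * eta - np.logaddexp(0.0, eta)).sum(axis=1)
    stat = np.clip(2.0 * (ll - ll_null), 0.0, None)
    return stat, chi2.sf(stat, df=1)


def lrt_logistic(x: Sequence[float], y: Sequence[int]) -> tuple[float, float]:
    """Scalar convenience wrapper around :func:`lrt_logistic_batch`."""
    stat, pv = lrt_logistic_batch(np.asarray(x)[None, :], np.asarray(y))
    return float(stat[0]), float(pv[0])


def de_test_suite(
    expression: Sequence[float], membership: Sequence[int]
) -> dict[str, float]:
    """Welch's t, Wilcoxon rank-sum, Kolmogorov-Smirnov and logistic-LRT
    p-values for one gene.  Constant input degrades to p = 1 with a warning."""
    expr = np.asarray(expression, dtype=np.float64)
    member = np.asarray(membership)
    if member.sum() == 0 or member.sum() == member.size:
        raise ValueError("both groups must be non-empty")
    a, b = expr[member == 1], expr[member == 0]
    if expr.max() == expr.min():
        warnings.warn("constant expression: all tests fall back to p = 1")
        return {t: 1.0 for t in DE_TESTS}
    with np.errstate(invalid="ignore"):
        out = {
            "welch_t": float(ttest_ind(a, b, equal_var=False).pvalue),
            "wilcoxon": float(ranksums(a, b).pvalue),
            "ks": float(ks_2samp(a, b).pvalue),
            "lrt": lrt_logistic(expr, member)[1],
        }
    return {k: (1.0 if np.isnan(v) else v) for k, v in out.items()}


# ---------------------------------------------------------------------------
# rankings and the SSR metric
# ---------------------------------------------------------------------------

def ssr(method_ranking: Sequence[str], good_marker_ids: Sequence[str]) -> float:
    """Scaled sum of ranks: 2 / (s (s+1)) times the summed 1-based ranks of
    the good markers in the method's ranking (1 = optimal)."""
    positions = {g: i + 1 for i, g in enumerate(method_ranking)}
    good = list(good_marker_ids)
    missing = [g for g in good if g not in positions]
    if missing:
        raise ValueError(f"markers missing from ranking: {missing[:3]}")
    s = len(good)
    return 2.0 * sum(positions[g] for g in good) / (s * (s + 1.0))


def _xlmhg_gene_scores(
    values: np.ndarray, member: np.ndarray, X: int, L: int
) -> tuple[np.ndarray, np.ndarray]:
    """(log statistics, p-values) for each gene row."""
    p, n = values.shape
    m = int(member.sum())
    log_stats = np.zeros(p)
    member = np.asarray(member).astype(np.int8)
    for g in range(p):
        row = values[g]
        if row.max() == row.min():
            continue
        ranked = xlmhg.rank_membership(row, member)
        kcum = np.cumsum(ranked.labels)
        log_stats[g], _ = xlmhg._log_statistic_from_kcum(kcum, n, m, X, L)
    pvals = xlmhg.mhg_pvalue_batch(log_stats, n, m, X, L)
    pvals[log_stats == 0.0] = 1.0
    return log_stats, pvals


def rank_by_xlmhg(
    matrix: ExpressionMatrix,
    member: np.ndarray,
    X: int | None = None,
    L: int | None = None,
) -> list[str]:
    """Gene ids ordered by ascending XL-mHG p-value (log statistic breaks
    p-value ties, which matters once p-values underflow)."""
    m, n = int(np.asarray(member).sum()), matrix.n_cells
    defaults = default_xl(m, n)
    X = defaults.X if X is None else X
    L = defaults.L if L is None else L
    log_stats, pvals = _xlmhg_gene_scores(matrix.values, member, X, L)
    order = np.lexsort((np.arange(len(pvals)), log_stats, pvals))
    return [matrix.gene_ids[i] for i in order]


def rank_by_lrt(matrix: ExpressionMatrix, member: np.ndarray) -> list[str]:
    stats, _ = lrt_logistic_batch(matrix.values, np.asarray(member, dtype=float))
    order = np.lexsort((np.arange(len(stats)), -stats))
    return [matrix.gene_ids[i] for i in order]


def rank_by_gini(
    matrix: ExpressionMatrix,
    member: np.ndarray,
    seed: int = 0,
    n_estimators: int = 250,
    extra_trees: bool = False,
) -> list[str]:
    """Gini-importance ranking from a tree ensemble (sqrt-feature subsets)."""
    from sklearn.ensemble import ExtraTreesClassifier, RandomForestClassifier

    cls = ExtraTreesClassifier if extra_trees else RandomForestClassifier
    clf = cls(
        n_estimators=n_estimators,
        max_features="sqrt",
        bootstrap=True,
        random_state=seed,
        n_jobs=1,
    )
    clf.fit(matrix.values.T, np.asarray(member, dtype=int))
    imp = clf.feature_importances_
    order = np.lexsort((np.arange(len(imp)), -imp))
    return [matrix.gene_ids[i] for i in order]


# ---------------------------------------------------------------------------
# benchmark drivers
# ---------------------------------------------------------------------------

def _single_gene_pvalues(
    config: SingleGeneSimConfig, rng: np.random.Generator, methods: Sequence[str]
) -> dict[str, float]:
    expr, member = simulate_single_gene(config, rng)
    out: dict[str, float] = {}
    de = None
    for method in methods:
        if method == "xlmhg":
            out[method] = xlmhg.xlmhg_test(expr, member).pvalue
        else:
            if de is None:
                de = de_test_suite(expr, member)
            out[method] = de[method]
    return out


def benchmark_curves(
    engine: str = "gaussian",
    effect_grid: Sequence[float] | None = None,
    n_grid: Sequence[int] | None = None,
    n: int = 5000,
    effect: float = 1.0,
    runs: int = 100,
    seed: int = 0,
    methods: Sequence[str] = ("xlmhg",) + DE_TESTS,
    cluster_fraction: float = 0.1,
) -> pd.DataFrame:
    """Mean/SD p-value per method along an effect-size or sample-size grid.

    Exactly one of ``effect_grid`` / ``n_grid`` must be given; the other
    dimension is held at ``effect`` / ``n``.
    """
    if (effect_grid is None) == (n_grid is None):
        raise ValueError("provide exactly one of effect_grid / n_grid")
    conditions = (
        [("effect", e, n, e) for e in effect_grid]
        if effect_grid is not None
        else [("n", nn, nn, effect) for nn in n_grid]
    )
    rows = []
    for varied, value, n_cond, eff_cond in conditions:
        config = SingleGeneSimConfig(
            n=int(n_cond),
            effect=float(eff_cond),
            cluster_fraction=cluster_fraction,
            engine=engine,
            runs=runs,
        )
        collected: dict[str, list[float]] = {mth: [] for mth in methods}
        cond_key = 0 if varied == "effect" else 1
        rng = np.random.default_rng([seed, cond_key, int(round(value * 1000))])
        for _ in range(runs):
            for mth, pv in _single_gene_pvalues(config, rng, methods).items():
                collected[mth].append(pv)
        for mth in methods:
            arr = np.array(collected[mth])
            rows.append(
                {
                    "varied": varied,
                    "value": value,
                    "method": mth,
                    "mean_pvalue": arr.mean(),
                    "sd_pvalue": arr.std(ddof=1) if runs > 1 else 0.0,
                }
            )
    return pd.DataFrame(rows)


def classifier_benchmark(
    config: MatrixSimConfig,
    pg: PoissonGammaConfig | None = None,
    runs: int = 20,
    seed: int = 0,
    methods: Sequence[str] = ("xlmhg", "lrt", "forest", "extra_trees"),
) -> pd.DataFrame:
    """Mean/SD SSR per ranking method on the matrix engines."""
    collected: dict[str, list[float]] = {mth: [] for mth in methods}
    rng = np.random.default_rng([seed, 77])
    for run in range(runs):
        matrix, member, classes = simulate_matrix(config, rng, pg=pg)
        good = [g for g, c in zip(matrix.gene_ids, classes) if c == "good"]
        for mth in methods:
            if mth == "xlmhg":
                ranking = rank_by_xlmhg(matrix, member)
            elif mth == "lrt":
                ranking = rank_by_lrt(matrix, member)
            elif mth == "forest":
                ranking = rank_by_gini(matrix, member, seed=seed + run)
            elif mth == "extra_trees":
                ranking = rank_by_gini(
                    matrix, member, seed=seed + run, extra_trees=True
                )
            else:
                raise ValueError(f"unknown method {mth!r}")
            collected[mth].append(ssr(ranking, good))
    rows = [
        {
            "method": mth,
            "mean_ssr": float(np.mean(v)),
            "sd_ssr": float(np.std(v, ddof=1)) if runs > 1 else 0.0,
        }
        for mth, v in collected.items()
    ]
    return pd.DataFrame(rows)
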