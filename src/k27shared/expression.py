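"""Bulk-expression statistics for tumor cohort comparisons.

Covers the bulk transcriptomic toolkit used to compare H3K27M gliomas and
PFA ependymomas: row-wise differential expression (pooled-variance
Student's t with Benjamini–Hochberg correction), the signed ranking metric
``(-log10 q) x diff`` feeding GSEA-preranked, a deterministic
GSEA-preranked implementation with gene-label permutations and meandiv
normalization, probe-to-gene collapsing by maximum reference-cohort mean,
per-gene standard-deviation heterogeneity, kernel-density bimodal
splitting (local minimum between modes), mean splits with co-expression
differences, and ordinary least-squares fits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ExpressionMatrix",
    "DEResult",
    "EnrichmentResult",
    "diff_expression",
    "bh_adjust",
    "rank_metric",
    "gsea_preranked",
    "collapse_probes",
    "sd_heterogeneity",
    "bimodal_split",
    "split_by_mean",
    "coexpression_diff",
    "linear_fit",
]

RANK_METRIC_Q_FLOOR = 1e-300


@dataclass
class ExpressionMatrix:
    """Probes-or-genes x samples matrix of log2 expression values.

    Parameters
    ----------
    values : pandas.DataFrame
        Rows are probes or genes, columns are samples; all values finite.
    probe_map : dict
        probe id -> gene id; must cover every row.  For gene-level
        matrices this is the identity map.
    sample_groups : dict
        sample id -> group label; must cover every column.
    """

    values: pd.DataFrame
    probe_map: dict[str, str] = field(default_factory=dict)
    sample_groups: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise ValueError("expression values must be finite")
        if not self.probe_map:
            self.probe_map = {r: r for r in self.values.index}
        missing = set(self.values.index) - set(self.probe_map)
        if missing:
            raise ValueError(f"probe_map missing rows: {sorted(missing)[:5]}")
        unlabeled = set(self.values.columns) - set(self.sample_groups)
        if unlabeled:
            raise ValueError(f"samples without group label: {sorted(unlabeled)[:5]}")

    def samples_in(self, group: str) -> list[str]:
        return [s for s in self.values.columns if self.sample_groups[s] == group]


@dataclass(frozen=True)
class DEResult:
    """One row's differential-expression summary (group1 minus group2)."""

    gene_id: str
    diff: float
    p: float
    q: float
    rank_score: float
    degenerate: bool = False


@dataclass(frozen=True)
class EnrichmentResult:
    """GSEA-preranked output for one gene set."""

    gene_set: str
    es: float
    nes: float
    p_perm: float
    n_perm: int
    set_size: int


def diff_expression(
    matrix: ExpressionMatrix,
    group_a: str,
    group_b: str,
    welch: bool = False,
) -> list[DEResult]:
    """Row-wise two-sided Student's t between two sample groups.

    Pooled-variance t by default (``welch=True`` switches to Welch).
    ``diff`` is mean(group_a) - mean(group_b) in log2 units; q-values are
    Benjamini–Hochberg over all tested rows and the rank score is
    ``(-log10 q) x diff``.  Rows with zero pooled variance get p = 1 when
    the means agree, and p ~ 0 with a ``degenerate`` flag otherwise.
    """
    a = matrix.values[matrix.samples_in(group_a)].to_numpy(dtype=float)
    b = matrix.values[matrix.samples_in(group_b)].to_numpy(dtype=float)
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise ValueError("each group needs >= 2 samples")
    diff = a.mean(axis=1) - b.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(a, b, axis=1, equal_var=not welch)
    pooled_var = a.var(axis=1, ddof=1) + b.var(axis=1, ddof=1)
    degenerate = np.zeros(len(diff), dtype=bool)
    zero_var = pooled_var == 0
    p = np.asarray(p, dtype=float)
    p[zero_var & (diff == 0)] = 1.0
    bad = zero_var & (diff != 0)
    p[bad] = 0.0
    degenerate[bad] = True
    q = bh_adjust(p)
    return [
        DEResult(
            gene_id=matrix.values.index[i],
            diff=float(diff[i]),
            p=float(p[i]),
            q=float(q[i]),
            rank_score=rank_metric(q[i], diff[i]),
            degenerate=bool(degenerate[i]),
        )
        for i in range(len(diff))
    ]


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (FDR q-values)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def rank_metric(q: float, diff: float, q_floor: float = RANK_METRIC_Q_FLOOR) -> float:
    """Signed GSEA ranking score: ``(-log10 q) x diff``.

    q-values of exactly 0 are clamped to ``q_floor`` (default 1e-300) to
    keep the score finite and order-preserving; a warning is recorded.
    """
    if not np.isfinite(diff):
        raise ValueError("diff must be finite")
    if q < 0 or q > 1:
        raise ValueError(f"q must lie in [0, 1], got {q}")
    if q == 0:
        warnings.warn(
            f"q-value of 0 clamped to {q_floor} in rank metric", stacklevel=2
        )
        q = q_floor
    return float(-np.log10(q) * diff)


def _running_es(
    order: np.ndarray, member: np.ndarray, scores: np.ndarray, weight: float
) -> float:
    """Signed max-deviation of the GSEA running sum for one ordering."""
    hits = member[order]
    w = np.abs(scores[order]) ** weight
    w_hit = np.where(hits, w, 0.0)
    total_hit = w_hit.sum()
    n_miss = len(order) - hits.sum()
    if total_hit == 0:  # all hit scores 0: fall back to equal hit weights
        w_hit = hits.astype(float)
        total_hit = w_hit.sum()
    running = np.cumsum(w_hit / total_hit - (~hits) / n_miss)
    return float(running[np.argmax(np.abs(running))])


def gsea_preranked(
    ranked: dict[str, float],
    gene_set: set[str],
    gene_set_name: str = "gene_set",
    n_perm: int = 1000,
    weight: float = 1.0,
    min_size: int = 15,
    max_size: int = 500,
    seed: int | np.random.Generator = 0,
) -> EnrichmentResult:
    """GSEA-preranked enrichment for one gene set against a ranked universe.

    The running sum walks the universe in descending score order (ties
    broken by gene id); hits increment proportionally to ``|score|^weight``
    and misses decrement uniformly, the enrichment score ES being the
    signed maximum deviation.  Significance comes from gene-label
    permutations (random sets of the same size); NES divides ES by the
    mean magnitude of same-sign permuted scores (meandiv) and the
    permutation p-value is the +1-smoothed same-sign tail fraction.
    """
    genes = np.array(sorted(ranked, key=lambda g: (-ranked[g], g)))
    scores = np.array([ranked[g] for g in genes], dtype=float)
    member = np.isin(genes, sorted(gene_set))
    size = int(member.sum())
    if size == 0:
        raise ValueError("gene set has no genes in the ranked universe")
    if not min_size <= size <= max_size:
        raise ValueError(
            f"gene set size {size} outside [{min_size}, {max_size}]"
        )
    if size == len(genes):
        raise ValueError("gene set covers the whole universe; no misses to score")
    identity = np.arange(len(genes))
    es = _running_es(identity, member, scores, weight)
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    perm_es = np.empty(n_perm)
    for i in range(n_perm):
        perm_member = np.zeros(len(genes), dtype=bool)
        perm_member[rng.choice(len(genes), size=size, replace=False)] = True
        perm_es[i] = _running_es(identity, perm_member, scores, weight)
    same_sign = perm_es > 0 if es > 0 else perm_es < 0
    m = int(same_sign.sum())
    if es == 0:
        nes, p = 0.0, 1.0
    elif m == 0:
        warnings.warn("no same-sign permutations; NES undefined", stacklevel=2)
        nes, p = np.nan, 1.0 / (n_perm + 1)
    else:
        nes = es / np.abs(perm_es[same_sign]).mean()
        r = int((np.abs(perm_es[same_sign]) >= abs(es)).sum())
        p = (r + 1) / (m + 1)
    return EnrichmentResult(
        gene_set=gene_set_name,
        es=es,
        nes=float(nes),
        p_perm=float(p),
        n_perm=n_perm,
        set_size=size,
    )


def collapse_probes(
    matrix: ExpressionMatrix, reference_group: str
) -> ExpressionMatrix:
    """Collapse probes to one row per gene.

    For each gene, keep the probe with the highest mean over the reference
    group's samples (ties break to the lexicographically smallest probe
    id).  Genes with no probes are absent from the output.
    """
    ref_samples = matrix.samples_in(reference_group)
    if not ref_samples:
        raise ValueError(f"no samples in reference group {reference_group!r}")
    ref_means = matrix.values[ref_samples].mean(axis=1)
    best: dict[str, str] = {}
    for probe in sorted(matrix.values.index):
        gene = matrix.probe_map[probe]
        if gene not in best or ref_means[probe] > ref_means[best[gene]]:
            best[gene] = probe
    genes = sorted(best)
    collapsed = matrix.values.loc[[best[g] for g in genes]].copy()
    collapsed.index = genes
    return ExpressionMatrix(
        values=collapsed,
        probe_map={g: g for g in genes},
        sample_groups=dict(matrix.sample_groups),
    )


def sd_heterogeneity(
    matrix_a: ExpressionMatrix,
    matrix_b: ExpressionMatrix,
    genes: set[str] | None = None,
) -> tuple[pd.DataFrame, list[str]]:
    """Per-gene expression standard deviation in two cohorts.

    Restricted to genes present in both matrices (and in ``genes`` when
    given); genes missing from either matrix are returned in the excluded
    list rather than plotted.  Standard deviations use the n-1
    denominator; either matrix having fewer than 2 samples is an error.
    """
    if matrix_a.values.shape[1] < 2 or matrix_b.values.shape[1] < 2:
        raise ValueError("need >= 2 samples per cohort for standard deviations")
    universe = set(genes) if genes is not None else (
        set(matrix_a.values.index) | set(matrix_b.values.index)
    )
    common = sorted(
        universe & set(matrix_a.values.index) & set(matrix_b.values.index)
    )
    excluded = sorted(universe - set(common))
    table = pd.DataFrame(
        {
            "sd_a": matrix_a.values.loc[common].std(axis=1, ddof=1),
            "sd_b": matrix_b.values.loc[common].std(axis=1, ddof=1),
        },
        index=pd.Index(common, name="gene_id"),
    )
    return table, excluded


def bimodal_split(
    values,
    bandwidth: float | str = "silverman",
    grid_size: int = 512,
) -> float | None:
    """Threshold between two expression modes, or None if unimodal.

    A Gaussian kernel density (Silverman bandwidth by default; a float
    fixes the bandwidth factor) is evaluated on a ``grid_size``-point grid
    spanning the data range.  With two or more local maxima the threshold
    is the grid point of minimum density between the two highest modes;
    otherwise None.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 10:
        raise ValueError(f"need >= 10 values, got {x.size}")
    kde = stats.gaussian_kde(x, bw_method=bandwidth)
    grid = np.linspace(x.min(), x.max(), grid_size)
    dens = kde(grid)
    interior = (dens[1:-1] > dens[:-2]) & (dens[1:-1] > dens[2:])
    maxima = list(np.flatnonzero(interior) + 1)
    if dens[0] > dens[1]:
        maxima.insert(0, 0)
    if dens[-1] > dens[-2]:
        maxima.append(grid_size - 1)
    if len(maxima) < 2:
        return None
    top_two = sorted(sorted(maxima, key=lambda i: -dens[i])[:2])
    lo, hi = top_two
    valley = lo + int(np.argmin(dens[lo : hi + 1]))
    return float(grid[valley])


def split_by_mean(values) -> pd.Series:
    """Label samples 'high' (value strictly above the mean) or 'low'."""
    s = pd.Series(values, dtype=float)
    if s.size < 2:
        raise ValueError("need >= 2 values to split at the mean")
    return pd.Series(
        np.where(s > s.mean(), "high", "low"), index=s.index, name="split"
    )


def coexpression_diff(matrix: ExpressionMatrix, labels: pd.Series) -> pd.Series:
    """Per-gene mean('high') - mean('low') given a high/low sample split."""
    high = [s for s in matrix.values.columns if labels[s] == "high"]
    low = [s for s in matrix.values.columns if labels[s] == "low"]
    if not high or not low:
        raise ValueError("both 'high' and 'low' classes must be non-empty")
    return matrix.values[high].mean(axis=1) - matrix.values[low].mean(axis=1)


def linear_fit(x, y) -> tuple[float, float, float]:
    """Ordinary least squares y ~ x: returns (slope, intercept, R^2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError(f"need >= 3 points, got {x.size}")
    if np.var(x) == 0:
        raise ValueError("x has zero variance; slope undefined")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)
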