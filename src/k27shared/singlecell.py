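"""Gene-signature scoring in labeled single-cell expression data.

Two per-cell signature activity scores are provided: the plain mean of
the signature genes' expression values (as used for the enhancer and
H3K27me3-retained signatures in tumor scRNA-seq), and an AUCell-style
recovery AUC computed from each cell's expression ranking over a top-rank
window (default: top 5% of genes).  Scores are compared across cell-type
labels with a Kruskal–Wallis test followed by pairwise rank-sum post-hocs
with Benjamini–Hochberg adjustment.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .expression import bh_adjust

__all__ = [
    "CellExpression",
    "SignatureScoreTable",
    "GroupTestResult",
    "mean_module_score",
    "auc_score",
    "groupwise_test",
]


@dataclass
class CellExpression:
    """Genes x cells expression with per-cell labels.

    ``values`` holds log-normalized expression or raw counts (declare
    which via ``is_raw_counts``); ``cell_type`` and ``tumor`` map every
    cell (column) to its labels.
    """

    values: pd.DataFrame
    cell_type: pd.Series
    tumor: pd.Series
    is_raw_counts: bool = False

    def __post_init__(self) -> None:
        cells = set(self.values.columns)
        for name, labels in (("cell_type", self.cell_type), ("tumor", self.tumor)):
            if not cells <= set(labels.index):
                raise ValueError(f"{name} labels must cover all cells")
        if self.is_raw_counts and (self.values.to_numpy() < 0).any():
            raise ValueError("raw counts must be non-negative")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]


@dataclass
class SignatureScoreTable:
    """Per-cell signature scores with the method that produced them."""

    scores: pd.Series
    method: str  # "mean" or "auc"

    def __post_init__(self) -> None:
        if self.method not in ("mean", "auc"):
            raise ValueError(f"method must be 'mean' or 'auc', got {self.method!r}")
        if self.method == "auc" and (
            (self.scores < 0).any() or (self.scores > 1).any()
        ):
            raise ValueError("AUC scores must lie in [0, 1]")

    def by_group(self, groups: pd.Series) -> pd.DataFrame:
        """Median/mean/count summary of scores per group label."""
        df = pd.DataFrame({"score": self.scores, "group": groups[self.scores.index]})
        return df.groupby("group")["score"].agg(["count", "mean", "median"])


@dataclass(frozen=True)
class GroupTestResult:
    """Kruskal–Wallis comparison of scores across groups with post-hocs."""

    h_statistic: float
    p: float
    pairwise: pd.DataFrame  # columns: group1, group2, p, q


def mean_module_score(
    cells: CellExpression, gene_set: set[str]
) -> SignatureScoreTable:
    """Per-cell arithmetic mean of the signature genes' expression.

    Signature genes absent from the matrix are excluded with a warning;
    a signature with no gene present is an error.
    """
    present = sorted(set(gene_set) & set(cells.values.index))
    missing = sorted(set(gene_set) - set(present))
    if not present:
        raise ValueError("no signature gene present in the expression matrix")
    if missing:
        warnings.warn(
            f"{len(missing)} signature gene(s) absent from matrix "
            f"(e.g. {missing[:3]})",
            stacklevel=2,
        )
    scores = cells.values.loc[present].mean(axis=0)
    scores.name = "score"
    return SignatureScoreTable(scores=scores, method="mean")


def auc_score(
    cells: CellExpression,
    gene_set: set[str],
    top_fraction: float = 0.05,
) -> SignatureScoreTable:
    """AUCell-style per-cell recovery AUC of the signature.

    Each cell's genes are ranked by descending expression (ties broken
    lexicographically by gene id).  The recovery curve counts cumulative
    signature hits over the top ``ceil(top_fraction x n_genes)`` ranks and
    the score is its area normalized to the maximum achievable area, so a
    cell whose signature genes fill the top ranks scores 1 and a cell with
    no signature gene in the window scores 0.  Being rank-based, the score
    is invariant to monotone transforms of a cell's expression values.
    """
    if not 0 < top_fraction < 1:
        raise ValueError(f"top_fraction must be in (0, 1), got {top_fraction}")
    n_genes = cells.n_genes
    window = math.ceil(top_fraction * n_genes)
    if window < 1 or n_genes < 1 / top_fraction:
        raise ValueError(
            f"matrix needs >= {math.ceil(1 / top_fraction)} genes for "
            f"top_fraction={top_fraction}"
        )
    present = sorted(set(gene_set) & set(cells.values.index))
    if not present:
        raise ValueError("no signature gene present in the expression matrix")
    # stable sort on lexicographically pre-sorted genes => deterministic ties
    gene_order = np.argsort(cells.values.index.to_numpy())
    vals = cells.values.to_numpy(dtype=float)[gene_order]
    member = np.isin(cells.values.index.to_numpy()[gene_order], present)
    s_eff = min(len(present), window)
    max_area = sum(min(k, s_eff) for k in range(1, window + 1))
    scores = {}
    for j, cell in enumerate(cells.values.columns):
        order = np.argsort(-vals[:, j], kind="stable")
        hits = member[order[:window]]
        area = int(np.cumsum(hits).sum())
        scores[cell] = area / max_area
    return SignatureScoreTable(
        scores=pd.Series(scores, name="score"), method="auc"
    )


def groupwise_test(
    scores: SignatureScoreTable,
    groups: pd.Series,
    min_cells: int = 2,
) -> GroupTestResult:
    """Kruskal–Wallis H across groups with BH-adjusted rank-sum post-hocs.

    Requires >= 2 groups each with >= ``min_cells`` cells.  If every score
    is identical across all groups the test degenerates to H = 0, p = 1.
    """
    g = groups[scores.scores.index]
    by_group = {
        label: scores.scores[g[g == label].index].to_numpy()
        for label in sorted(g.unique())
    }
    small = [lab for lab, v in by_group.items() if len(v) < min_cells]
    if len(by_group) < 2 or small:
        raise ValueError(
            f"need >= 2 groups with >= {min_cells} cells each"
            + (f"; too few cells in {small}" if small else "")
        )
    pooled = np.concatenate(list(by_group.values()))
    if np.all(pooled == pooled[0]):
        h, p = 0.0, 1.0
    else:
        h, p = stats.kruskal(*by_group.values())
    labels = list(by_group)
    rows = []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            a, b = by_group[labels[i]], by_group[labels[j]]
            if np.all(np.concatenate([a, b]) == a[0]):
                pw = 1.0
            else:
                pw = stats.mannwhitneyu(a, b, alternative="two-sided").pvalue
            rows.append({"group1": labels[i], "group2": labels[j], "p": float(pw)})
    pairwise = pd.DataFrame(rows)
    if len(pairwise):
        pairwise["q"] = bh_adjust(pairwise["p"].to_numpy())
    return GroupTestResult(h_statistic=float(h), p=float(p), pairwise=pairwise)


def aggregate_per_tumor(
    scores: SignatureScoreTable, tumor: pd.Series
) -> SignatureScoreTable:
    """Collapse per-cell scores to per-tumor medians.

    Optional guard against pseudo-replication: cell-level tests treat
    cells from one tumor as independent, which they are not.  Aggregating
    to tumor medians before testing trades power for validity.
    """
    med = scores.scores.groupby(tumor[scores.scores.index]).median()
    med.name = "score"
    return SignatureScoreTable(scores=med, method=scores.method)
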