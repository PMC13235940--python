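"""Depth normalization, marker-gene preselection and gene-list alignment.

Gene preselection is deliberately inclusive: a one-sided rank test per gene
and class (that class stochastically greater than the rest), BH FDR control,
then a cap of the most variable survivors per class.  The learner itself
decides which of the surviving genes end up carrying weight, so this step
only has to shrink the gene space to a trainable size.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

from .data import ExpressionDataset

__all__ = [
    "normalize_log",
    "mannwhitney_one_sided",
    "benjamini_hochberg",
    "select_marker_genes",
    "align_genes",
]


def normalize_log(raw: ExpressionDataset, target_sum: float = 10_000.0) -> ExpressionDataset:
    """Scale each cell to ``target_sum`` total counts, then apply log1p."""
    X = raw.dense()
    if np.any(X < 0):
        raise ValueError("raw counts must be nonnegative")
    totals = X.sum(axis=1)
    bad = totals <= 0
    if bad.any():
        ids = [raw.cells[i] for i in np.flatnonzero(bad)[:10]]
        raise ValueError(f"cells with zero total counts: {ids}")
    X = np.log1p(X * (target_sum / totals[:, None]))
    return ExpressionDataset(X, list(raw.genes), raw.obs.copy())


def mannwhitney_one_sided(group_a: np.ndarray, group_b: np.ndarray) -> tuple[float, float]:
    """One-sided Mann–Whitney U test, H1: ``group_a`` stochastically greater.

    Returns ``(U, p)``.  The p-value is exact (full enumeration) for small
    tie-free samples and a tie-corrected normal approximation otherwise.
    """
    a = np.asarray(group_a, dtype=np.float64)
    b = np.asarray(group_b, dtype=np.float64)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    res = mannwhitneyu(a, b, alternative="greater", method="auto")
    return float(res.statistic), float(res.pvalue)


def benjamini_hochberg(p_values, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Step-up BH: returns (monotone adjusted p-values, reject mask at ``q``)."""
    p = np.asarray(p_values, dtype=np.float64)
    if p.size and (p.min() < 0 or p.max() > 1):
        raise ValueError("p-values must lie in [0, 1]")
    reject, adjusted, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return adjusted, reject


def _column(X: np.ndarray, j: int) -> np.ndarray:
    return X[:, j]


def marker_gene_table(
    data: ExpressionDataset,
    fdr: float = 0.05,
    max_per_class: int = 1000,
) -> pd.DataFrame:
    """Per-gene, per-class test statistics behind :func:`select_marker_genes`.

    Columns: class, gene, U, p, p_adj, norm_var, selected.
    """
    train = data.subset_cells(data.split_mask("train"))
    if train.n_cells == 0:
        raise ValueError("no training cells (check the split column)")
    X = train.dense()
    y = train.labels()
    classes = sorted(pd.unique(pd.Series(y)).tolist(), key=str)
    if len(classes) < 2:
        raise ValueError("need at least two classes among training cells")
    norm_var = X.var(axis=0, ddof=1)
    rows = []
    for cls in classes:
        in_cls = y == cls
        Xa, Xb = X[in_cls], X[~in_cls]
        stats = np.empty((len(data.genes), 2))
        for j in range(len(data.genes)):
            stats[j] = mannwhitney_one_sided(Xa[:, j], Xb[:, j])
        p_adj, reject = benjamini_hochberg(stats[:, 1], q=fdr)
        # rank BH survivors by normalized variance, cap per class;
        # lexicographic gene-symbol order breaks variance ties deterministically
        order = sorted(
            np.flatnonzero(reject),
            key=lambda j: (-norm_var[j], data.genes[j]),
        )
        chosen = set(order[:max_per_class])
        for j in range(len(data.genes)):
            rows.append(
                {
                    "class": cls,
                    "gene": data.genes[j],
                    "U": stats[j, 0],
                    "p": stats[j, 1],
                    "p_adj": p_adj[j],
                    "norm_var": norm_var[j],
                    "rank": order.index(j) if j in chosen else -1,
                    "selected": j in chosen,
                }
            )
    return pd.DataFrame(rows)


def select_marker_genes(
    data: ExpressionDataset,
    fdr: float = 0.05,
    max_per_class: int = 1000,
) -> list[str]:
    """Union of per-class one-vs-rest markers, de-duplicated in stable order.

    Order: class of first appearance, then within-class variance rank.
    Raises if no gene survives FDR control in any class.
    """
    table = marker_gene_table(data, fdr=fdr, max_per_class=max_per_class)
    sel = table[table["selected"]].sort_values(["class", "rank"], kind="stable")
    genes: list[str] = []
    seen: set[str] = set()
    for g in sel["gene"]:
        if g not in seen:
            seen.add(g)
            genes.append(g)
    if not genes:
        raise ValueError(
            f"no gene passed FDR <= {fdr} in any class; "
            "relax the threshold or skip preselection"
        )
    return genes


def align_genes(train_genes: list[str], other_genes: list[str]) -> list[tuple[int, int]]:
    """Matched positions of the gene-list intersection, in training order.

    Used for gene-list-aligned transfer: both the loading matrix and the new
    data are restricted to the shared genes before projection.
    """
    for name, lst in (("train", train_genes), ("other", other_genes)):
        if len(lst) != len(set(lst)):
            raise ValueError(f"duplicate symbols in {name} gene list")
    other_idx = {g: i for i, g in enumerate(other_genes)}
    pairs = [(i, other_idx[g]) for i, g in enumerate(train_genes) if g in other_idx]
    if not pairs:
        raise ValueError("gene lists share no symbols")
    return pairs
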