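"""Interpretability and performance diagnostics for learned gene programs.

Covers the quantities used to judge a loading matrix: Hoyer sparsity of
loading vectors, thresholded gene-set extraction, within-set graph
connectivity and its quantile against random same-size gene sets, rank-based
AUC, and the best-match AUC used to compare external per-gene weight
vectors against discrete gene sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.metrics import roc_auc_score

from .graph import GeneGraph

__all__ = [
    "hoyer_sparsity",
    "GeneSet",
    "GeneSetCollection",
    "extract_gene_sets",
    "connectivity",
    "connectivity_quantile",
    "auc",
    "loading_match_auc",
    "best_match_auc",
    "write_gmt",
]


def hoyer_sparsity(v) -> float:
    """Scale-invariant L1/L2 concentration of a nonnegative vector.

        (sqrt(d) - ||v||_1 / ||v||_2) / (sqrt(d) - 1)  in [0, 1]

    0 for a uniform vector, 1 for a one-hot vector.
    """
    v = np.asarray(v, dtype=np.float64)
    d = v.size
    if d < 2:
        raise ValueError("Hoyer sparsity needs a vector of length >= 2")
    if np.any(v < 0):
        raise ValueError("entries must be nonnegative")
    l2 = np.linalg.norm(v)
    if l2 == 0:
        raise ValueError("all-zero vector has undefined sparsity")
    sd = np.sqrt(d)
    return float((sd - np.abs(v).sum() / l2) / (sd - 1.0))


def _edge_count(A: sp.csr_matrix, idx: np.ndarray, weighted: bool) -> float:
    """Edges among distinct pairs within ``idx``; self-loops excluded."""
    sub = A[np.ix_(idx, idx)].tocoo()
    off = sub.row < sub.col
    if weighted:
        return float(sub.data[off].sum())
    return float(np.count_nonzero(sub.data[off]))


def connectivity(gene_set: list[str], graph: GeneGraph, weighted: bool = False) -> float:
    """Average within-set degree: 2 × (edges in set) / (set size).

    Binary reading by default (an edge counts once when its weight is
    positive); ``weighted=True`` sums edge weights instead.
    """
    if not gene_set:
        raise ValueError("gene set is empty")
    index = graph.index
    unknown = [g for g in gene_set if g not in index]
    if unknown:
        raise KeyError(f"genes absent from graph: {unknown[:5]}")
    idx = np.array([index[g] for g in gene_set])
    return 2.0 * _edge_count(graph.A, idx, weighted) / len(gene_set)


def connectivity_quantile(
    gene_set: list[str],
    graph: GeneGraph,
    n_null: int = 1000,
    seed: int | np.random.Generator = 0,
    weighted: bool = False,
) -> float:
    """Quantile of the set's connectivity among random same-size gene sets.

    Null sets are drawn uniformly without replacement from the graph's gene
    universe; ties use the mid-rank convention
    (#{null < C} + 0.5·#{null = C}) / n_null.
    """
    if n_null < 1:
        raise ValueError("n_null must be >= 1")
    k = len(gene_set)
    if k > graph.n_genes:
        raise ValueError("set larger than the gene universe")
    c_obs = connectivity(gene_set, graph, weighted=weighted)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    null = np.empty(n_null)
    for i in range(n_null):
        idx = rng.choice(graph.n_genes, size=k, replace=False)
        null[i] = 2.0 * _edge_count(graph.A, idx, weighted) / k
    return float((np.sum(null < c_obs) + 0.5 * np.sum(null == c_obs)) / n_null)


@dataclass
class GeneSet:
    """One program's member genes under the loading threshold."""

    program: int
    genes: list[str]

    @property
    def size(self) -> int:
        return len(self.genes)

    def connectivity(self, graph: GeneGraph, weighted: bool = False) -> float:
        return connectivity(self.genes, graph, weighted=weighted)

    def connectivity_quantile(
        self, graph: GeneGraph, n_null: int = 1000, seed=0, weighted: bool = False
    ) -> float:
        return connectivity_quantile(self.genes, graph, n_null=n_null, seed=seed, weighted=weighted)


@dataclass
class GeneSetCollection:
    """Gene sets for all d programs (possibly empty) plus summaries."""

    sets: list[GeneSet]
    threshold: float
    genes: list[str] = field(repr=False)

    @property
    def non_empty_count(self) -> int:
        return sum(1 for s in self.sets if s.size > 0)

    def non_empty(self) -> list[GeneSet]:
        return [s for s in self.sets if s.size > 0]

    def summary(self, graph: GeneGraph | None = None, n_null: int = 1000, seed=0) -> pd.DataFrame:
        rows = []
        for s in self.sets:
            row = {"program": s.program, "size": s.size}
            if graph is not None and s.size > 0:
                row["connectivity"] = s.connectivity(graph)
                row["connectivity_quantile"] = s.connectivity_quantile(graph, n_null=n_null, seed=seed)
            rows.append(row)
        return pd.DataFrame(rows)


def extract_gene_sets(S: np.ndarray, genes: list[str], threshold: float = 0.8) -> GeneSetCollection:
    """Assign a gene to a program iff its loading strictly exceeds ``threshold``.

    With any threshold above 0.5 a gene can belong to at most one program;
    programs without qualifying genes are kept as empty sets so that
    ``non_empty_count`` reports how many programs carry genes at all.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    S = np.asarray(S, dtype=np.float64)
    if S.shape[0] != len(genes):
        raise ValueError("gene list must match loading rows")
    sets = []
    for k in range(S.shape[1]):
        members = [genes[i] for i in np.flatnonzero(S[:, k] > threshold)]
        sets.append(GeneSet(program=k, genes=members))
    return GeneSetCollection(sets=sets, threshold=threshold, genes=list(genes))


def auc(scores, labels) -> float:
    """Rank-based AUC: P(random positive outranks random negative), ties half."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) != 2:
        raise ValueError("AUC needs both classes present")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=np.float64)))


def loading_match_auc(reference_set: list[str], weights, genes: list[str]) -> float:
    """AUC of a per-gene weight vector as a ranking of set membership."""
    member = np.isin(np.asarray(genes), np.asarray(list(reference_set)))
    if member.all() or not member.any():
        raise ValueError("reference set must be a proper non-empty subset of the universe")
    return auc(weights, member.astype(int))


def best_match_auc(reference_set: list[str], loading: np.ndarray, genes: list[str]) -> tuple[int, float]:
    """Best-matching candidate program (by AUC) for a reference gene set."""
    aucs = [loading_match_auc(reference_set, loading[:, k], genes) for k in range(loading.shape[1])]
    k = int(np.argmax(aucs))
    return k, float(aucs[k])


def write_gmt(collection: GeneSetCollection, path: str | Path, prefix: str = "program") -> None:
    """Write non-empty gene sets in GMT format (name, description, genes)."""
    with open(path, "w") as fh:
        for s in collection.non_empty():
            fh.write("\t".join([f"{prefix}_{s.program}", f"threshold>{collection.threshold}", *s.genes]) + "\n")
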