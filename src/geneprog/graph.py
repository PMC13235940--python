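"""Gene–gene annotation graphs: construction, normalization, perturbation.

The graph backbone for program learning is a symmetric, self-looped
adjacency over an ordered gene universe.  Protein-level interaction records
(e.g. BioGRID TAB3 exports) are collapsed to gene-level edges by official
symbol; a generic weighted edge-list entry point covers any other annotation
source that can be written as pairwise similarities.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "GeneGraph",
    "normalize_adjacency",
    "load_biogrid_tab3",
    "load_edge_list",
    "identity_graph",
]

_BIOGRID_COLS = ("Official Symbol Interactor A", "Official Symbol Interactor B")


def normalize_adjacency(A: sp.spmatrix) -> tuple[sp.csr_matrix, np.ndarray, np.ndarray]:
    """Symmetric normalization Ã = D^{-1/2} A D^{-1/2}.

    Returns ``(A_norm, deg, deg_norm)`` where ``deg`` are the (weighted) row
    sums of ``A`` and ``deg_norm`` the row sums of Ã, i.e. the diagonal of
    the degree matrix of Ã used by the cut loss.
    """
    A = sp.csr_matrix(A, dtype=np.float64)
    if (abs(A - A.T) > 1e-12).nnz:
        raise ValueError("adjacency must be symmetric")
    deg = np.asarray(A.sum(axis=1)).ravel()
    if np.any(deg <= 0):
        raise ValueError("every node needs positive degree (add self-connections)")
    d_inv_sqrt = sp.diags(1.0 / np.sqrt(deg))
    A_norm = sp.csr_matrix(d_inv_sqrt @ A @ d_inv_sqrt)
    deg_norm = np.asarray(A_norm.sum(axis=1)).ravel()
    return A_norm, deg, deg_norm


@dataclass
class GeneGraph:
    """Symmetric weighted adjacency over an ordered gene universe.

    ``A`` includes self-connections so the normalization is always finite.
    """

    genes: list[str]
    A: sp.csr_matrix
    A_norm: sp.csr_matrix = field(init=False, repr=False)
    deg: np.ndarray = field(init=False, repr=False)
    deg_norm: np.ndarray = field(init=False, repr=False)

    def __post_init__(self):
        if len(self.genes) != len(set(self.genes)):
            raise ValueError("duplicate gene symbols in graph universe")
        self.A = sp.csr_matrix(self.A, dtype=np.float64)
        if self.A.shape != (len(self.genes), len(self.genes)):
            raise ValueError("adjacency shape does not match gene list")
        if np.any(self.A.diagonal() <= 0):
            raise ValueError("adjacency must carry positive self-connections")
        self.A_norm, self.deg, self.deg_norm = normalize_adjacency(self.A)

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.genes)}

    # -- construction ------------------------------------------------------
    @staticmethod
    def from_edges(
        genes: list[str],
        edges: list[tuple[str, str, float]] | list[tuple[str, str]],
        self_loop_weight: float | None = None,
    ) -> "GeneGraph":
        """Build a graph from an (optionally weighted) undirected edge list.

        Duplicate / reversed records collapse to a single edge (max weight
        wins).  Every gene receives a self-connection; its weight defaults to
        1 for binary graphs and to the maximum edge weight otherwise, so that
        self-influence stays comparable to the strongest neighbor.
        """
        idx = {g: i for i, g in enumerate(genes)}
        p = len(genes)
        weights: dict[tuple[int, int], float] = {}
        for rec in edges:
            a, b = str(rec[0]).strip(), str(rec[1]).strip()
            w = float(rec[2]) if len(rec) > 2 else 1.0
            if a not in idx or b not in idx or a == b:
                continue
            if w < 0:
                raise ValueError("edge weights must be nonnegative")
            key = (min(idx[a], idx[b]), max(idx[a], idx[b]))
            weights[key] = max(weights.get(key, 0.0), w)
        if self_loop_weight is None:
            wmax = max(weights.values(), default=1.0)
            self_loop_weight = wmax if weights and wmax != 1.0 else 1.0
        rows = [k[0] for k in weights] + [k[1] for k in weights] + list(range(p))
        cols = [k[1] for k in weights] + [k[0] for k in weights] + list(range(p))
        vals = list(weights.values()) * 2 + [self_loop_weight] * p
        A = sp.coo_matrix((vals, (rows, cols)), shape=(p, p)).tocsr()
        return GeneGraph(list(genes), A)

    # -- derived graphs ----------------------------------------------------
    def subgraph(self, genes: list[str]) -> "GeneGraph":
        """Restrict to ``genes`` (kept in the given order) and renormalize."""
        idx = self.index
        missing = [g for g in genes if g not in idx]
        if missing:
            raise KeyError(f"genes absent from graph: {missing[:5]}")
        sel = np.array([idx[g] for g in genes])
        return GeneGraph(list(genes), self.A[np.ix_(sel, sel)])

    def perturb(self, fraction: float, seed: int | np.random.Generator) -> "GeneGraph":
        """Rewire a fraction of off-diagonal edges uniformly at random.

        ``round(fraction * n_edges)`` existing edges are removed and replaced
        by the same number of pairs drawn uniformly from those absent after
        the removal (so a removed edge can be re-drawn), preserving edge
        count and self-loops; removed weights are reassigned to the new
        edges.  Used for graph-sensitivity analyses where the data and
        hyperparameters stay fixed while annotation quality degrades.
        """
        if not 0.0 <= fraction <= 1.0:
            raise ValueError("fraction must lie in [0, 1]")
        rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
        coo = sp.triu(self.A, k=1).tocoo()
        edges = list(zip(coo.row.tolist(), coo.col.tolist(), coo.data.tolist()))
        n_swap = int(round(fraction * len(edges)))
        if n_swap == 0:
            return GeneGraph(list(self.genes), self.A.copy())
        p = self.n_genes
        drop_idx = rng.choice(len(edges), size=n_swap, replace=False)
        dropped = {(edges[i][0], edges[i][1]) for i in drop_idx}
        kept = {(r, c): w for r, c, w in edges if (r, c) not in dropped}
        freed = [edges[i][2] for i in sorted(drop_idx)]
        occupied = set(kept)
        new_pairs: set[tuple[int, int]] = set()
        while len(new_pairs) < n_swap:
            i, j = rng.integers(0, p, size=2)
            if i == j:
                continue
            pair = (min(i, j), max(i, j))
            if pair in occupied or pair in new_pairs:
                continue
            new_pairs.add(pair)
        for pair, w in zip(sorted(new_pairs), freed):
            kept[pair] = w
        rows = [k[0] for k in kept] + [k[1] for k in kept] + list(range(p))
        cols = [k[1] for k in kept] + [k[0] for k in kept] + list(range(p))
        diag = self.A.diagonal()
        vals = list(kept.values()) * 2 + list(diag)
        A = sp.coo_matrix((vals, (rows, cols)), shape=(p, p)).tocsr()
        return GeneGraph(list(self.genes), A)

    # -- i/o ----------------------------------------------------------------
    def write_edge_list(self, path: str | Path) -> None:
        """Write off-diagonal edges as a 3-column TSV (gene_a, gene_b, weight)."""
        coo = sp.triu(self.A, k=1).tocoo()
        with open(path, "w") as fh:
            for r, c, w in zip(coo.row, coo.col, coo.data):
                fh.write(f"{self.genes[r]}\t{self.genes[c]}\t{w:g}\n")


def identity_graph(genes: list[str]) -> GeneGraph:
    """Self-loops only; the annotation-free backbone (Ã = I)."""
    return GeneGraph(list(genes), sp.identity(len(genes), format="csr"))


def load_biogrid_tab3(path: str | Path, gene_universe: list[str]) -> GeneGraph:
    """Build a gene-level interaction graph from a BioGRID TAB3 export.

    Nodes are ``gene_universe`` (order preserved).  Any recorded interaction
    between proteins of two distinct genes — isoform records included —
    collapses to a single unweighted gene-level edge, matched case-sensitively
    on the official gene symbols after whitespace trimming.  Genes with no
    recorded partner keep only their self-connection.
    """
    if not gene_universe:
        raise ValueError("gene_universe must be non-empty")
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    try:
        with opener(path, "rt") as fh:
            df = pd.read_csv(fh, sep="\t", usecols=list(_BIOGRID_COLS), dtype=str)
    except (ValueError, KeyError, UnicodeDecodeError, OSError, io.UnsupportedOperation) as exc:
        raise ValueError(f"not a parseable BioGRID TAB3 file: {path}") from exc
    universe = {g.strip() for g in gene_universe}
    a = df[_BIOGRID_COLS[0]].astype(str).str.strip()
    b = df[_BIOGRID_COLS[1]].astype(str).str.strip()
    keep = a.isin(universe) & b.isin(universe) & (a != b)
    edges = list(zip(a[keep], b[keep]))
    return GeneGraph.from_edges([g.strip() for g in gene_universe], edges, self_loop_weight=1.0)


def load_edge_list(path: str | Path, gene_universe: list[str] | None = None) -> GeneGraph:
    """Read a 2- or 3-column TSV edge list (gene_a, gene_b[, weight]).

    Without an explicit universe the node set is the sorted union of symbols
    seen in the file.
    """
    df = pd.read_csv(path, sep="\t", header=None, dtype={0: str, 1: str})
    if df.shape[1] < 2:
        raise ValueError("edge list needs at least two columns")
    if df.shape[1] == 2:
        df[2] = 1.0
    if gene_universe is None:
        gene_universe = sorted(set(df[0].str.strip()) | set(df[1].str.strip()))
    edges = list(zip(df[0], df[1], df[2].astype(float)))
    return GeneGraph.from_edges([g.strip() for g in gene_universe], edges)
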