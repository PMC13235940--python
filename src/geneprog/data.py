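"""Cell × gene expression container with donor/label/split metadata.

A thin dataclass rather than a full AnnData wrapper: the fields the pipeline
needs (donor, label, split) are first-class columns, and conversion to and
from AnnData / MTX+TSV keeps interoperability with the usual single-cell
toolchain.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

__all__ = ["ExpressionDataset", "read_mtx_dir", "read_h5ad"]

OBS_COLUMNS = ("cell_id", "donor_id", "label", "split")


@dataclass
class ExpressionDataset:
    """Expression values (cells × genes) plus per-cell metadata.

    ``obs`` is indexed by cell ID and carries ``donor_id``, ``label`` and an
    optional ``split`` column with values in {train, validation, test}.
    """

    values: np.ndarray | sp.spmatrix
    genes: list[str]
    obs: pd.DataFrame

    def __post_init__(self):
        if len(self.genes) != len(set(self.genes)):
            raise ValueError("duplicate gene symbols")
        n_cells = self.values.shape[0]
        if len(self.obs) != n_cells:
            raise ValueError("obs rows must match cell count")
        if self.values.shape[1] != len(self.genes):
            raise ValueError("gene list must match value columns")
        for col in ("donor_id", "label"):
            if col not in self.obs.columns:
                raise ValueError(f"obs is missing required column '{col}'")
            if self.obs[col].isna().any():
                raise ValueError(f"obs column '{col}' has missing entries")
        if "split" not in self.obs.columns:
            self.obs = self.obs.assign(split="train")

    # -- basic views -------------------------------------------------------
    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def cells(self) -> list[str]:
        return list(self.obs.index)

    def dense(self) -> np.ndarray:
        if sp.issparse(self.values):
            return np.asarray(self.values.todense(), dtype=np.float64)
        return np.asarray(self.values, dtype=np.float64)

    def labels(self) -> np.ndarray:
        return self.obs["label"].to_numpy()

    def donors(self) -> np.ndarray:
        return self.obs["donor_id"].to_numpy()

    def split_mask(self, split: str) -> np.ndarray:
        return (self.obs["split"] == split).to_numpy()

    # -- subsetting ----------------------------------------------------------
    def subset_cells(self, mask: np.ndarray) -> "ExpressionDataset":
        return ExpressionDataset(self.values[mask], list(self.genes), self.obs.loc[mask].copy())

    def subset_genes(self, genes: list[str]) -> "ExpressionDataset":
        idx = {g: i for i, g in enumerate(self.genes)}
        missing = [g for g in genes if g not in idx]
        if missing:
            raise KeyError(f"genes absent from dataset: {missing[:5]}")
        cols = np.array([idx[g] for g in genes])
        return ExpressionDataset(self.values[:, cols], list(genes), self.obs.copy())

    # -- conversions ---------------------------------------------------------
    def to_anndata(self):
        import anndata

        obs = self.obs.copy()
        obs.index = obs.index.astype(str)
        return anndata.AnnData(
            X=self.values.astype(np.float32) if not sp.issparse(self.values) else self.values,
            obs=obs,
            var=pd.DataFrame(index=pd.Index(self.genes, name="gene")),
        )

    @staticmethod
    def from_anndata(adata) -> "ExpressionDataset":
        X = adata.X
        if sp.issparse(X):
            X = sp.csr_matrix(X)
        else:
            X = np.asarray(X)
        return ExpressionDataset(X, list(adata.var_names), adata.obs.copy())

    # -- i/o -----------------------------------------------------------------
    def write_mtx_dir(self, outdir: str | Path) -> None:
        """Write matrix.mtx (genes × cells), genes.tsv and cells.tsv."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        M = self.values.T if sp.issparse(self.values) else sp.csr_matrix(self.values).T
        scipy.io.mmwrite(str(outdir / "matrix.mtx"), sp.coo_matrix(M))
        pd.Series(self.genes).to_csv(outdir / "genes.tsv", sep="\t", index=False, header=False)
        meta = self.obs.copy()
        meta.insert(0, "cell_id", meta.index)
        meta.to_csv(outdir / "cells.tsv", sep="\t", index=False)

    def write_h5ad(self, path: str | Path) -> None:
        self.to_anndata().write_h5ad(Path(path))


def read_mtx_dir(indir: str | Path) -> ExpressionDataset:
    indir = Path(indir)
    M = scipy.io.mmread(str(indir / "matrix.mtx")).tocsr().T.tocsr()
    genes = pd.read_csv(indir / "genes.tsv", sep="\t", header=None)[0].tolist()
    meta = pd.read_csv(indir / "cells.tsv", sep="\t", dtype={"cell_id": str, "donor_id": str})
    meta = meta.set_index("cell_id")
    return ExpressionDataset(M, genes, meta)


def read_h5ad(path: str | Path) -> ExpressionDataset:
    import anndata

    return ExpressionDataset.from_anndata(anndata.read_h5ad(path))


def read_expression(path: str | Path) -> ExpressionDataset:
    """Dispatch on path: a directory means MTX+TSV, a file means h5ad."""
    path = Path(path)
    if path.is_dir():
        return read_mtx_dir(path)
    return read_h5ad(path)
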