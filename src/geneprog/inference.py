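"""Projection, cell scoring, transfer to new gene lists, donor aggregation.

The loading matrix is cell-independent, so a trained model transfers to any
dataset sharing part of its gene list: both the data and the loading matrix
are restricted to the shared genes (in training order) and the projection
proceeds on the submatrices.  Missing genes simply contribute nothing; rows
of the restricted loading matrix are not renormalized by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .data import ExpressionDataset
from .preprocessing import align_genes
from .training import TrainedModel

__all__ = ["project", "score_cells", "aggregate_individuals", "PredictionTable", "predict"]


def project(
    data: ExpressionDataset,
    model: TrainedModel,
    renormalize: bool = False,
) -> np.ndarray:
    """Cells × d program-space representation X·S on the aligned gene subset.

    ``renormalize=True`` rescales the restricted loading rows to sum to one
    (off by default; the plain submatrix product is the reference behaviour).
    """
    pairs = align_genes(model.gene_list, list(data.genes))
    train_idx = np.array([i for i, _ in pairs])
    data_idx = np.array([j for _, j in pairs])
    S = model.loading[train_idx]
    if renormalize:
        S = S / S.sum(axis=1, keepdims=True)
    X = data.dense()[:, data_idx]
    return X @ S


def score_cells(projected: np.ndarray, model: TrainedModel) -> np.ndarray:
    """Prediction scores from the trained head; dropout disabled.

    Binary task: probability of the positive class in [0, 1].  Multiclass:
    an (n, C) probability matrix.  Regression: raw predictions.
    """
    logits = model.head_logits(np.asarray(projected, dtype=np.float64))
    task = model.config.task
    if task == "binary":
        return 1.0 / (1.0 + np.exp(-logits[:, 0]))
    if task == "multiclass":
        z = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)
    return logits[:, 0]


def aggregate_individuals(cell_scores: np.ndarray, donor_of) -> pd.Series:
    """Unweighted mean of cell scores per donor (the individual-level score)."""
    donors = pd.Series(np.asarray(donor_of), name="donor_id")
    if donors.isna().any():
        raise ValueError("every scored cell needs a donor")
    return pd.Series(np.asarray(cell_scores, dtype=np.float64)).groupby(donors.values).mean()


@dataclass
class PredictionTable:
    """Per-cell and per-individual prediction scores with labels."""

    cells: pd.DataFrame        # cell_id, donor_id, label, score
    individuals: pd.DataFrame  # donor_id, label, score

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.cells.to_csv(outdir / "cell_scores.tsv", sep="\t", index=False)
        self.individuals.to_csv(outdir / "individual_scores.tsv", sep="\t", index=False)


def predict(data: ExpressionDataset, model: TrainedModel, renormalize: bool = False) -> PredictionTable:
    """Score every cell and aggregate to individuals.

    Multiclass scores are reduced to per-class probability columns in the
    cell table and averaged per donor column-wise.
    """
    scores = score_cells(project(data, model, renormalize=renormalize), model)
    obs = data.obs
    if scores.ndim == 1:
        cells = pd.DataFrame(
            {
                "cell_id": data.cells,
                "donor_id": obs["donor_id"].to_numpy(),
                "label": obs["label"].to_numpy(),
                "score": scores,
            }
        )
        indiv = (
            cells.groupby("donor_id", as_index=False)
            .agg(label=("label", "first"), score=("score", "mean"))
        )
    else:
        cols = {f"score_{k}": scores[:, k] for k in range(scores.shape[1])}
        cells = pd.DataFrame(
            {
                "cell_id": data.cells,
                "donor_id": obs["donor_id"].to_numpy(),
                "label": obs["label"].to_numpy(),
                **cols,
            }
        )
        indiv = cells.groupby("donor_id", as_index=False).agg(
            label=("label", "first"), **{c: (c, "mean") for c in cols}
        )
    return PredictionTable(cells=cells, individuals=indiv)
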