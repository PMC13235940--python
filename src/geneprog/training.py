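"""Training pipeline: configs, validation splits, w sweeps, model bundles.

Thin, dataset-aware wrappers over :class:`~geneprog.estimator.GeneProgramClassifier`:
they carry gene lists and split tags, serialize trained models as directory
bundles, and implement the diagnostic sweep over the graph-loss weight w.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

from .data import ExpressionDataset
from .estimator import GeneProgramClassifier, head_forward
from .evaluation import extract_gene_sets
from .graph import GeneGraph

__all__ = [
    "TrainConfig",
    "TrainedModel",
    "split_validation",
    "fit",
    "sweep_w",
    "select_w",
]

DEFAULT_W_GRID = (0.0, 0.25, 0.5, 1.0, 2.0, 5.0, 10.0)


@dataclass
class TrainConfig:
    """Hyperparameters; defaults follow the reference configuration."""

    w: float = 2.0
    learning_rate: float = 1e-4
    weight_decay: float = 1e-4
    max_epochs: int = 50_000
    min_epochs: int = 10_000
    patience_epochs: int = 3_000
    dropout_p: float = 0.5
    validation_fraction: float = 0.1
    d: int = 40
    h: int = 64
    n_conv_layers: int = 2
    task: str = "binary"
    ortho_target: str = "scaled"
    early_stopping_metric: str = "classification"
    seed: int = 0
    w_grid: tuple[float, ...] = field(default=DEFAULT_W_GRID)

    def validate(self) -> None:
        if self.min_epochs > self.max_epochs:
            raise ValueError("min_epochs must not exceed max_epochs")
        if self.patience_epochs < 1:
            raise ValueError("patience_epochs must be >= 1")
        if not 0.0 < self.validation_fraction < 1.0:
            raise ValueError("validation_fraction must lie in (0, 1)")

    def make_estimator(self, graph: GeneGraph | None) -> GeneProgramClassifier:
        return GeneProgramClassifier(
            graph=graph,
            n_programs=self.d,
            hidden_units=self.h,
            n_conv_layers=self.n_conv_layers,
            w=self.w,
            learning_rate=self.learning_rate,
            weight_decay=self.weight_decay,
            max_epochs=self.max_epochs,
            min_epochs=self.min_epochs,
            patience=self.patience_epochs,
            dropout=self.dropout_p,
            validation_fraction=self.validation_fraction,
            task=self.task,
            ortho_target=self.ortho_target,
            early_stopping_metric=self.early_stopping_metric,
            random_state=self.seed,
        )


@dataclass
class TrainedModel:
    """Serializable bundle: gene list, loading matrix, head, config, history."""

    gene_list: list[str]
    loading: np.ndarray
    head_weights: list[np.ndarray]
    head_biases: list[np.ndarray]
    config: TrainConfig
    history: pd.DataFrame
    best_epoch: int
    classes: np.ndarray
    validation_score: float = float("nan")

    def __post_init__(self):
        if self.loading.shape[0] != len(self.gene_list):
            raise ValueError("gene list length must equal loading row count")
        rowsum = self.loading.sum(axis=1)
        if np.any(np.abs(rowsum - 1.0) > 1e-6):
            raise ValueError("loading rows must sum to one")

    def loading_frame(self) -> pd.DataFrame:
        cols = [f"program_{k}" for k in range(self.loading.shape[1])]
        return pd.DataFrame(self.loading, index=self.gene_list, columns=cols)

    def head_logits(self, Xr: np.ndarray) -> np.ndarray:
        return head_forward(self.head_weights, self.head_biases, Xr)

    # -- persistence --------------------------------------------------------
    def save(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "genes.txt").write_text("\n".join(self.gene_list) + "\n")
        self.loading_frame().to_csv(outdir / "loading.tsv", sep="\t")
        np.savez(
            outdir / "head.npz",
            **{f"W{i}": W for i, W in enumerate(self.head_weights)},
            **{f"b{i}": b for i, b in enumerate(self.head_biases)},
            classes=self.classes,
        )
        cfg = asdict(self.config)
        cfg["w_grid"] = list(cfg["w_grid"])
        meta = {
            "config": cfg,
            "best_epoch": int(self.best_epoch),
            "validation_score": float(self.validation_score),
        }
        (outdir / "config.json").write_text(json.dumps(meta, indent=2))
        self.history.to_csv(outdir / "history.csv", index=False)

    @staticmethod
    def load(indir: str | Path) -> "TrainedModel":
        indir = Path(indir)
        genes = indir.joinpath("genes.txt").read_text().split()
        loading = pd.read_csv(indir / "loading.tsv", sep="\t", index_col=0).to_numpy()
        blob = np.load(indir / "head.npz", allow_pickle=False)
        n_layers = sum(1 for k in blob.files if k.startswith("W"))
        meta = json.loads(indir.joinpath("config.json").read_text())
        cfg = meta["config"]
        cfg["w_grid"] = tuple(cfg["w_grid"])
        return TrainedModel(
            gene_list=genes,
            loading=loading,
            head_weights=[blob[f"W{i}"] for i in range(n_layers)],
            head_biases=[blob[f"b{i}"] for i in range(n_layers)],
            config=TrainConfig(**cfg),
            history=pd.read_csv(indir / "history.csv"),
            best_epoch=meta["best_epoch"],
            classes=blob["classes"],
            validation_score=meta["validation_score"],
        )


def split_validation(
    data: ExpressionDataset, fraction: float = 0.1, seed: int = 0
) -> ExpressionDataset:
    """Tag a stratified fraction of training cells as 'validation'."""
    train_idx = np.flatnonzero(data.split_mask("train"))
    if len(train_idx) < 10:
        raise ValueError("need at least 10 training cells to split validation")
    y = data.labels()[train_idx]
    _, va = train_test_split(train_idx, test_size=fraction, stratify=y, random_state=seed)
    obs = data.obs.copy()
    obs.iloc[va, obs.columns.get_loc("split")] = "validation"
    out = ExpressionDataset(data.values, list(data.genes), obs)
    if any((y == c).sum() == 0 for c in np.unique(y)):  # pragma: no cover
        import warnings

        warnings.warn("a class has no validation cells")
    return out


def fit(data: ExpressionDataset, graph: GeneGraph, config: TrainConfig) -> TrainedModel:
    """Train on a prepared dataset (normalized values, final gene list).

    ``data.genes`` must match ``graph.genes`` in identical order.  Cells
    tagged 'train' form the encoder's node features; cells tagged
    'validation' drive early stopping (a stratified split is drawn when no
    validation tags are present).  Cells tagged 'test' are ignored here.
    """
    config.validate()
    if list(data.genes) != list(graph.genes):
        raise ValueError("data genes must match graph genes in identical order")
    if "validation" not in set(data.obs["split"]):
        data = split_validation(data, config.validation_fraction, seed=config.seed)
    mask = data.split_mask("train") | data.split_mask("validation")
    subset = data.subset_cells(mask)
    est = config.make_estimator(graph)
    est.fit(
        subset.dense(),
        subset.labels(),
        validation_mask=subset.split_mask("validation"),
    )
    return TrainedModel(
        gene_list=list(data.genes),
        loading=est.loading_,
        head_weights=est.head_weights_,
        head_biases=est.head_biases_,
        config=config,
        history=est.history_,
        best_epoch=est.best_epoch_,
        classes=est.classes_ if hasattr(est, "classes_") else np.array([]),
        validation_score=est.validation_score_,
    )


def sweep_w(
    data: ExpressionDataset,
    graph: GeneGraph,
    config: TrainConfig,
    w_grid: tuple[float, ...] | None = None,
    threshold: float = 0.8,
    n_null: int = 500,
) -> tuple[pd.DataFrame, dict[float, TrainedModel]]:
    """Fit one model per w and tabulate diagnostics.

    Returns the diagnostics table (w, validation metric, non-empty program
    count, mean connectivity quantile of the extracted gene sets) and the
    fitted models keyed by w.
    """
    from dataclasses import replace

    grid = tuple(w_grid if w_grid is not None else config.w_grid)
    if not grid:
        raise ValueError("empty w grid")
    rows, models = [], {}
    for w in grid:
        model = fit(data, graph, replace(config, w=float(w)))
        sets = extract_gene_sets(model.loading, model.gene_list, threshold=threshold)
        quantiles = [
            s.connectivity_quantile(graph, n_null=n_null, seed=config.seed)
            for s in sets.non_empty()
        ]
        rows.append(
            {
                "w": float(w),
                "val_metric": model.validation_score,
                "n_non_empty": sets.non_empty_count,
                "mean_connectivity_quantile": float(np.mean(quantiles)) if quantiles else np.nan,
            }
        )
        models[float(w)] = model
    return pd.DataFrame(rows).sort_values("w", ignore_index=True), models


def select_w(sweep: pd.DataFrame, tolerance: float = 0.02) -> float:
    """Smallest w whose validation metric is within ``tolerance`` of the best.

    The metric is higher-is-better (validation AUC/accuracy).  Diagnostics in
    the sweep table (non-empty counts, connectivity quantiles) are returned
    alongside by :func:`sweep_w` for manual inspection.
    """
    if len(sweep) < 2:
        raise ValueError("need at least two sweep entries to select w")
    best = sweep["val_metric"].max()
    ok = sweep[sweep["val_metric"] >= best - tolerance]
    return float(ok["w"].min())
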