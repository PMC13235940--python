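"""Scikit-learn-style estimator for supervised gene-program learning.

``GeneProgramClassifier`` jointly trains a graph-convolutional pooling
encoder (which produces the gene → program loading matrix ``loading_``)
and an MLP head on the pooled representation, optimizing

    L = Lclf + w (Lc + Lo)

full-batch with Adam.  The first convolution layer's weights are shaped by
the number of training cells (each gene's feature vector is its expression
profile across those cells), which is why fitting is full-batch and why the
loading matrix — not the head — is the transferable artifact.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import train_test_split

from ._autodiff import Adam, Parameter, Tensor, dropout, spmm
from .graph import GeneGraph, identity_graph
from .model import classification_loss, mincut_losses, total_loss

__all__ = ["GeneProgramClassifier"]


def _linear_init(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    bound = 1.0 / np.sqrt(fan_in)
    return rng.uniform(-bound, bound, size=(fan_in, fan_out))


def head_forward(weights: list[np.ndarray], biases: list[np.ndarray], Xr: np.ndarray) -> np.ndarray:
    """Deterministic (no-dropout) MLP head pass; returns raw logits."""
    A = np.asarray(Xr, dtype=np.float64)
    for W, b in zip(weights[:-1], biases[:-1]):
        A = np.maximum(A @ W + b, 0.0)
    return A @ weights[-1] + biases[-1]


class GeneProgramClassifier(ClassifierMixin, BaseEstimator):
    """Supervised gene-program learner with annotation-graph pooling.

    Parameters
    ----------
    graph
        :class:`~geneprog.graph.GeneGraph` whose gene order matches the
        columns of ``X``.  ``None`` uses a self-loop-only identity graph
        (no annotation information).
    n_programs
        Number of gene programs ``d`` (columns of the loading matrix).
    hidden_units, n_conv_layers
        Width and depth of the graph-convolution encoder.
    w
        Weight of the unsupervised graph loss.  ``w=0`` reduces to an
        annotation-free softmax-pooled MLP baseline (the graph terms are
        still recorded but contribute no gradient).
    learning_rate, weight_decay
        Adam settings; defaults follow the reference configuration
        (1e-4 / 1e-4).  Desk-scale runs typically raise the learning rate.
    max_epochs, min_epochs, patience
        Early stopping: training halts once the validation loss has not
        improved for ``patience`` epochs, but never before ``min_epochs``;
        parameters are restored to the best-validation epoch.
    dropout
        Dropout probability after each hidden MLP layer (training only).
    validation_fraction
        Fraction of cells held out (stratified) when ``fit`` is not given an
        explicit validation mask.
    task
        "binary", "multiclass" or "regression".
    ortho_target
        Orthogonality-loss target convention, "scaled" (I_d/sqrt(d)) or
        "identity".
    early_stopping_metric
        "classification" monitors the validation classification loss only
        (the graph terms are cell-independent); "total" adds w·(Lc+Lo).
    center_features
        Center each gene's node-feature vector (its expression across
        training cells) before the encoder.  Projection and scoring always
        use raw values; this only conditions the encoder input.

    Attributes
    ----------
    loading_ : ndarray of shape (n_features, n_programs)
        Row-stochastic gene → program loading matrix S.
    head_weights_, head_biases_ : list of ndarray
        MLP head parameters.
    history_ : DataFrame
        Per-epoch loss decomposition and validation loss.
    best_epoch_ : int
    validation_score_ : float
        Validation AUC (binary/multiclass accuracy; negative MSE for
        regression) at the restored parameters.
    """

    def __init__(
        self,
        graph: GeneGraph | None = None,
        n_programs: int = 40,
        hidden_units: int = 64,
        n_conv_layers: int = 2,
        w: float = 2.0,
        learning_rate: float = 1e-4,
        weight_decay: float = 1e-4,
        max_epochs: int = 50_000,
        min_epochs: int = 10_000,
        patience: int = 3_000,
        dropout: float = 0.5,
        validation_fraction: float = 0.1,
        task: str = "binary",
        ortho_target: str = "scaled",
        early_stopping_metric: str = "classification",
        center_features: bool = True,
        random_state: int | None = None,
    ):
        self.graph = graph
        self.n_programs = n_programs
        self.hidden_units = hidden_units
        self.n_conv_layers = n_conv_layers
        self.w = w
        self.learning_rate = learning_rate
        self.weight_decay = weight_decay
        self.max_epochs = max_epochs
        self.min_epochs = min_epochs
        self.patience = patience
        self.dropout = dropout
        self.validation_fraction = validation_fraction
        self.task = task
        self.ortho_target = ortho_target
        self.early_stopping_metric = early_stopping_metric
        self.center_features = center_features
        self.random_state = random_state

    # -- internal forward pieces ------------------------------------------
    def _encode(self, params: dict, consts: dict) -> Tensor:
        """Node features -> loading matrix S (p × d), on the tape."""
        graph = consts["graph"]
        # layer 1 uses the precomputed Ã·X product; deeper layers convolve H
        H = (Tensor(consts["AX"]) @ params["conv"][0][0]
             + Tensor(consts["Xg"]) @ params["conv"][0][1]).relu()
        for Wl, Ws in params["conv"][1:]:
            H = (spmm(graph.A_norm, H) @ Wl + H @ Ws).relu()
        return (H @ params["pool"]).row_softmax()

    def _head(self, params: dict, Xr: Tensor, rng: np.random.Generator | None) -> Tensor:
        A = Xr
        n_hidden = len(params["head_W"]) - 1
        for i in range(n_hidden):
            A = (A @ params["head_W"][i] + params["head_b"][i]).relu()
            if rng is not None and self.dropout > 0:
                A = dropout(A, self.dropout, rng)
        return A @ params["head_W"][-1] + params["head_b"][-1]

    # -- fit ----------------------------------------------------------------
    def fit(self, X, y, validation_mask: np.ndarray | None = None):
        """Fit on cells × genes matrix ``X`` with per-cell targets ``y``.

        ``validation_mask`` marks cells reserved for early stopping; when
        omitted, a stratified ``validation_fraction`` split is drawn
        internally.  Only non-validation cells form the encoder's node
        features.
        """
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2:
            raise ValueError("X must be 2-dimensional (cells × genes)")
        n_cells, p = X.shape
        if self.min_epochs > self.max_epochs:
            raise ValueError("min_epochs must not exceed max_epochs")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if self.w < 0:
            raise ValueError("w must be nonnegative")
        graph = self.graph if self.graph is not None else identity_graph(
            [f"F{i}" for i in range(p)]
        )
        if graph.n_genes != p:
            raise ValueError(
                f"graph has {graph.n_genes} genes but X has {p} feature columns"
            )

        y = np.asarray(y)
        if self.task in ("binary", "multiclass"):
            self.classes_, y_enc = np.unique(y, return_inverse=True)
            if self.task == "binary" and len(self.classes_) != 2:
                raise ValueError("binary task requires exactly two classes")
            n_out = 1 if self.task == "binary" else len(self.classes_)
        else:
            y_enc = y.astype(np.float64)
            n_out = 1

        ss = np.random.SeedSequence(self.random_state)
        rng_init, rng_split, rng_drop = (np.random.default_rng(s) for s in ss.spawn(3))

        if validation_mask is None:
            idx = np.arange(n_cells)
            strat = y_enc if self.task != "regression" else None
            tr_idx, va_idx = train_test_split(
                idx,
                test_size=self.validation_fraction,
                stratify=strat,
                random_state=int(rng_split.integers(2**31 - 1)),
            )
        else:
            validation_mask = np.asarray(validation_mask, dtype=bool)
            tr_idx = np.flatnonzero(~validation_mask)
            va_idx = np.flatnonzero(validation_mask)
        if len(tr_idx) == 0 or (len(va_idx) == 0 and self.max_epochs > 0):
            raise ValueError("both training and validation cells are required")
        if self.task != "regression":
            present = np.unique(y_enc[va_idx])
            if len(present) < len(np.unique(y_enc)):
                import warnings

                warnings.warn("a class has no validation cells; early stopping may be unreliable")

        X_tr, y_tr = X[tr_idx], y_enc[tr_idx]
        X_va, y_va = X[va_idx], y_enc[va_idx]
        n_tr = len(tr_idx)

        h, d = self.hidden_units, self.n_programs
        params = {
            "conv": [(Parameter(_linear_init(rng_init, n_tr, h)),
                      Parameter(_linear_init(rng_init, n_tr, h)))],
            "pool": Parameter(_linear_init(rng_init, h, d)),
            "head_W": [],
            "head_b": [],
        }
        for _ in range(self.n_conv_layers - 1):
            params["conv"].append(
                (Parameter(_linear_init(rng_init, h, h)),
                 Parameter(_linear_init(rng_init, h, h)))
            )
        dims = [d, 64, 64, 64, n_out]
        for fan_in, fan_out in zip(dims[:-1], dims[1:]):
            params["head_W"].append(Parameter(_linear_init(rng_init, fan_in, fan_out)))
            params["head_b"].append(
                Parameter(rng_init.uniform(-1 / np.sqrt(fan_in), 1 / np.sqrt(fan_in), size=fan_out))
            )

        flat_params: list[Parameter] = [p_ for pair in params["conv"] for p_ in pair]
        flat_params += [params["pool"], *params["head_W"], *params["head_b"]]
        opt = Adam(
            flat_params,
            lr=self.learning_rate,
            weight_decay=self.weight_decay,
        )

        # Node features: each gene's expression profile across training cells.
        # Centering per gene removes the dominant shared-mean direction of
        # nonnegative expression, without which the pooled representations of
        # all genes are nearly collinear and the loadings collapse into a
        # single program.  The projection X·S itself stays on raw values.
        Xg = X_tr.T - (X_tr.mean(axis=0)[:, None] if self.center_features else 0.0)
        consts = {"graph": graph, "Xg": Xg, "AX": np.asarray(graph.A_norm @ Xg)}

        history: list[dict] = []
        best_val = np.inf
        best_epoch = -1
        best_state: list[np.ndarray] | None = None

        for epoch in range(self.max_epochs):
            S = self._encode(params, consts)
            Xr = spmm(X_tr, S)
            logits = self._head(params, Xr, rng_drop)
            l_clf = classification_loss(logits, y_tr, task=self.task)
            l_c, l_o = mincut_losses(S, graph, ortho_target=self.ortho_target)
            loss = l_clf + self.w * (l_c + l_o) if self.w > 0 else l_clf
            loss.backward()
            opt.step()

            # deterministic validation pass through the updated parameters
            S_val = self._encode(params, consts).value
            head_W = [p_.value for p_ in params["head_W"]]
            head_b = [p_.value for p_ in params["head_b"]]
            val_logits = head_forward(head_W, head_b, X_va @ S_val)
            val_clf = float(classification_loss(val_logits, y_va, task=self.task))
            if self.early_stopping_metric == "total":
                vc, vo = mincut_losses(S_val, graph, ortho_target=self.ortho_target)
                val_metric = val_clf + self.w * (float(vc) + float(vo))
            else:
                val_metric = val_clf

            report = total_loss(float(l_clf.value), float(l_c.value), float(l_o.value), self.w)
            history.append(
                {
                    "epoch": epoch,
                    "l_clf": report.l_clf,
                    "l_c": report.l_c,
                    "l_o": report.l_o,
                    "total": report.total,
                    "val_loss": val_metric,
                }
            )
            if val_metric < best_val:
                best_val = val_metric
                best_epoch = epoch
                best_state = [p_.value.copy() for p_ in flat_params]
            if epoch + 1 >= self.min_epochs and epoch - best_epoch >= self.patience:
                break

        if best_state is not None:
            for p_, v in zip(flat_params, best_state):
                p_.value = v

        self.loading_ = self._encode(params, consts).value
        self.head_weights_ = [p_.value.copy() for p_ in params["head_W"]]
        self.head_biases_ = [p_.value.copy() for p_ in params["head_b"]]
        self.history_ = pd.DataFrame(history)
        self.best_epoch_ = best_epoch
        self.best_val_loss_ = best_val
        self.n_features_in_ = p

        val_logits = head_forward(self.head_weights_, self.head_biases_, X_va @ self.loading_)
        if self.task == "binary":
            scores = 1.0 / (1.0 + np.exp(-val_logits[:, 0]))
            self.validation_score_ = (
                float(roc_auc_score(y_va, scores)) if len(np.unique(y_va)) == 2 else np.nan
            )
        elif self.task == "multiclass":
            self.validation_score_ = float(np.mean(val_logits.argmax(axis=1) == y_va))
        else:
            self.validation_score_ = -float(np.mean((val_logits[:, 0] - y_va) ** 2))
        return self

    # -- inference ----------------------------------------------------------
    def _check_fitted(self):
        if not hasattr(self, "loading_"):
            raise RuntimeError("estimator is not fitted")

    def transform(self, X) -> np.ndarray:
        """Project cells into program space: X · S."""
        self._check_fitted()
        X = np.asarray(X, dtype=np.float64)
        if X.shape[1] != self.n_features_in_:
            raise ValueError("feature count does not match the fitted gene list")
        return X @ self.loading_

    def decision_function(self, X) -> np.ndarray:
        self._check_fitted()
        logits = head_forward(self.head_weights_, self.head_biases_, self.transform(X))
        return logits[:, 0] if logits.shape[1] == 1 else logits

    def predict_proba(self, X) -> np.ndarray:
        logits = self.decision_function(X)
        if self.task == "binary":
            p1 = 1.0 / (1.0 + np.exp(-logits))
            return np.column_stack([1 - p1, p1])
        if self.task == "multiclass":
            z = logits - logits.max(axis=1, keepdims=True)
            e = np.exp(z)
            return e / e.sum(axis=1, keepdims=True)
        raise AttributeError("predict_proba is undefined for regression")

    def predict(self, X) -> np.ndarray:
        if self.task == "regression":
            return self.decision_function(X)
        return self.classes_[self.predict_proba(X).argmax(axis=1)]
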