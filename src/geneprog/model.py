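"""Core model operations: graph convolution, softmax pooling, loss terms.

The encoder maps each gene's expression profile across training cells
through graph-convolution layers

    H(1) = ReLU(Ã X W + X W_skip),      H(l) = ReLU(Ã H W(l) + H W_skip(l)),

then pools genes into d programs with a row-wise softmax loading matrix
S = softmax(H W_H).  Two graph penalties shape S: a normalized-cut ratio

    Lc = -Tr(SᵀÃS) / Tr(SᵀD̃S)   in [-1, 0],

which rewards pooling strongly connected genes together (D̃ is the degree
matrix of Ã), and an orthogonality term pushing SᵀS toward a scaled
identity, which favours near-one-hot rows and comparable program sizes.
The supervised head consumes the pooled representation XᵀS and contributes
a cross-entropy (or squared-error) term; the total objective is
Lclf + w (Lc + Lo).

Functions here accept plain arrays or autodiff tensors: passing
:class:`~geneprog._autodiff.Tensor` inputs keeps the computation on the
tape so the training loop can differentiate through it, while array inputs
return arrays — the same code path serves both the tests' oracles and fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._autodiff import (
    Tensor,
    binary_cross_entropy_with_logits,
    softmax_cross_entropy,
    spmm,
)
from .graph import GeneGraph

__all__ = [
    "graph_conv",
    "pool",
    "mincut_losses",
    "classification_loss",
    "total_loss",
    "LossReport",
]


def _as_tensor(x) -> tuple[Tensor, bool]:
    if isinstance(x, Tensor):
        return x, True
    return Tensor(np.asarray(x, dtype=np.float64)), False


def _maybe_value(t: Tensor, keep: bool):
    return t if keep else t.value


def graph_conv(H_in, graph: GeneGraph, W, W_skip):
    """One convolution layer: ReLU(Ã·H_in·W + H_in·W_skip)."""
    H, keep_h = _as_tensor(H_in)
    Wt, keep_w = _as_tensor(W)
    Ws, keep_s = _as_tensor(W_skip)
    if H.value.shape[1] != Wt.value.shape[0] or H.value.shape[1] != Ws.value.shape[0]:
        raise ValueError("feature dimension does not match weight shapes")
    out = (spmm(graph.A_norm, H) @ Wt + H @ Ws).relu()
    return _maybe_value(out, keep_h or keep_w or keep_s)


def pool(H, W_H):
    """Loading matrix S = row-softmax(H·W_H); rows sum to one."""
    Ht, keep_h = _as_tensor(H)
    Wt, keep_w = _as_tensor(W_H)
    logits = Ht @ Wt
    if not np.all(np.isfinite(logits.value)):
        raise FloatingPointError("non-finite pooling logits")
    return _maybe_value(logits.row_softmax(), keep_h or keep_w)


def mincut_losses(S, graph: GeneGraph, ortho_target: str = "scaled"):
    """Cut and orthogonality penalties (l_c, l_o) for a loading matrix.

    ``ortho_target="scaled"`` uses I_d/sqrt(d), whose minimum (zero) is
    attained exactly by balanced one-hot loadings; ``"identity"`` uses the
    plain I_d variant.
    """
    St, keep = _as_tensor(S)
    d = St.value.shape[1]
    if ortho_target not in ("scaled", "identity"):
        raise ValueError("ortho_target must be 'scaled' or 'identity'")
    AS = spmm(graph.A_norm, St)
    num = (St * AS).sum()
    DS = St * Tensor(graph.deg_norm[:, None])
    den = (St * DS).sum()
    if den.value < 1e-12:
        raise FloatingPointError("degenerate pooling: Tr(S^T D~ S) ~ 0")
    l_c = -(num / den)

    G = St.T @ St
    gf = (G * G).sum().sqrt()
    target = np.eye(d) / np.sqrt(d) if ortho_target == "scaled" else np.eye(d)
    diff = G / gf - Tensor(target)
    l_o = (diff * diff).sum().sqrt()
    return _maybe_value(l_c, keep), _maybe_value(l_o, keep)


def classification_loss(logits, labels, task: str = "binary"):
    """Mean supervised loss: BCE, softmax CE, or squared error by task."""
    lt, keep = _as_tensor(logits)
    y = np.asarray(labels)
    if task == "binary":
        if not np.isin(y, (0, 1)).all():
            raise ValueError("binary task requires 0/1 labels")
        out = binary_cross_entropy_with_logits(lt, y)
    elif task == "multiclass":
        n_classes = lt.value.shape[1]
        if y.min() < 0 or y.max() >= n_classes:
            raise ValueError("labels outside the declared class set")
        out = softmax_cross_entropy(lt, y)
    elif task == "regression":
        diff = lt - Tensor(np.asarray(y, dtype=np.float64).reshape(lt.value.shape))
        out = (diff * diff).mean()
    else:
        raise ValueError(f"unknown task '{task}'")
    return _maybe_value(out, keep)


@dataclass
class LossReport:
    """One epoch's loss decomposition; total = l_clf + w·(l_c + l_o)."""

    l_clf: float
    l_c: float
    l_o: float
    w: float

    @property
    def total(self) -> float:
        return self.l_clf + self.w * (self.l_c + self.l_o)


def total_loss(l_clf: float, l_c: float, l_o: float, w: float) -> LossReport:
    if w < 0:
        raise ValueError("graph-loss weight w must be nonnegative")
    for name, v in (("l_clf", l_clf), ("l_c", l_c), ("l_o", l_o)):
        if not np.isfinite(v):
            raise FloatingPointError(f"non-finite loss term {name}")
    return LossReport(float(l_clf), float(l_c), float(l_o), float(w))
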