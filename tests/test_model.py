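"""Model-core operations against brute-force oracles and exact cases."""

import numpy as np
import pytest
import scipy.sparse as sp

from geneprog import (
    GeneGraph,
    classification_loss,
    graph_conv,
    mincut_losses,
    pool,
    total_loss,
)
from geneprog.graph import identity_graph

from .conftest import random_row_stochastic, random_symmetric_graph


# -- independent double-loop oracles ---------------------------------------

def oracle_conv(H, A_norm, W, W_skip):
    p, f = H.shape
    h = W.shape[1]
    out = np.zeros((p, h))
    for i in range(p):
        for k in range(h):
            acc = 0.0
            for j in range(p):
                for c in range(f):
                    acc += A_norm[i, j] * H[j, c] * W[c, k]
            for c in range(f):
                acc += H[i, c] * W_skip[c, k]
            out[i, k] = max(acc, 0.0)
    return out


def oracle_mincut(S, A_norm, deg_norm, scaled=True):
    p, d = S.shape
    num = den = 0.0
    for k in range(d):
        for i in range(p):
            for j in range(p):
                num += S[i, k] * A_norm[i, j] * S[j, k]
            den += S[i, k] * deg_norm[i] * S[i, k]
    l_c = -num / den
    G = np.zeros((d, d))
    for a in range(d):
        for b in range(d):
            for i in range(p):
                G[a, b] += S[i, a] * S[i, b]
    Gn = G / np.sqrt((G**2).sum())
    T = np.eye(d) / np.sqrt(d) if scaled else np.eye(d)
    l_o = np.sqrt(((Gn - T) ** 2).sum())
    return l_c, l_o


class TestGraphConv:
    def test_identity_adjacency_without_skip(self, rng):
        g = identity_graph([f"G{i}" for i in range(4)])
        H = rng.normal(size=(4, 3))
        W = rng.normal(size=(3, 2))
        out = graph_conv(H, g, W, np.zeros((3, 2)))
        assert np.allclose(out, np.maximum(H @ W, 0))

    def test_zero_input_gives_zero_output(self, rng):
        g = random_symmetric_graph(rng, 4)
        out = graph_conv(np.zeros((4, 3)), g, rng.normal(size=(3, 2)), rng.normal(size=(3, 2)))
        assert np.allclose(out, 0)

    def test_matches_triple_loop_oracle(self, rng):
        g = random_symmetric_graph(rng, 5)
        H = rng.normal(size=(5, 3))
        W = rng.normal(size=(3, 4))
        Ws = rng.normal(size=(3, 4))
        expected = oracle_conv(H, g.A_norm.toarray(), W, Ws)
        assert np.allclose(graph_conv(H, g, W, Ws), expected, atol=1e-12)

    def test_dimension_mismatch_rejected(self, rng):
        g = random_symmetric_graph(rng, 4)
        with pytest.raises(ValueError):
            graph_conv(np.zeros((4, 3)), g, np.zeros((2, 2)), np.zeros((2, 2)))


class TestPooling:
    def test_zero_weights_give_uniform_loadings(self, rng):
        S = pool(rng.normal(size=(6, 4)), np.zeros((4, 3)))
        assert np.allclose(S, 1 / 3)

    def test_dominant_logit_saturates(self):
        H = np.array([[25.0, 0.0]])
        S = pool(H, np.eye(2))
        assert S[0, 0] > 0.999

    def test_rows_sum_to_one(self, rng):
        S = pool(rng.normal(size=(7, 5)), rng.normal(size=(5, 6)))
        assert np.allclose(S.sum(axis=1), 1.0, atol=1e-6)
        assert S.min() >= 0

    def test_nonfinite_logits_rejected(self):
        with pytest.raises(FloatingPointError):
            pool(np.array([[np.inf, 0.0]]), np.eye(2))


class TestMincutLosses:
    def test_single_program_all_ones_gives_minus_one(self, rng):
        g = random_symmetric_graph(rng, 6)
        l_c, _ = mincut_losses(np.ones((6, 1)), g)
        assert l_c == pytest.approx(-1.0, abs=1e-12)

    def test_disconnected_components_one_hot_gives_minus_one(self):
        # two 3-cliques with no cross edges; indicator pooling captures all mass
        block = np.ones((3, 3))
        A = np.block([[block, np.zeros((3, 3))], [np.zeros((3, 3)), block]])
        g = GeneGraph([f"G{i}" for i in range(6)], sp.csr_matrix(A))
        S = np.repeat(np.eye(2), 3, axis=0)
        l_c, _ = mincut_losses(S, g)
        expected, _ = oracle_mincut(S, g.A_norm.toarray(), g.deg_norm)
        assert l_c == pytest.approx(-1.0, abs=1e-12)
        assert l_c == pytest.approx(expected, abs=1e-12)

    def test_balanced_one_hot_minimizes_orthogonality(self, rng):
        g = random_symmetric_graph(rng, 8)
        S = np.repeat(np.eye(4), 2, axis=0)  # 4 programs × 2 genes
        _, l_o = mincut_losses(S, g, ortho_target="scaled")
        assert l_o == pytest.approx(0.0, abs=1e-12)
        _, l_o_id = mincut_losses(S, g, ortho_target="identity")
        assert l_o_id > 0.5  # plain identity target is not minimized there

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_double_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        g = random_symmetric_graph(rng, 10)
        S = random_row_stochastic(rng, 10, 4)
        l_c, l_o = mincut_losses(S, g)
        exp_c, exp_o = oracle_mincut(S, g.A_norm.toarray(), g.deg_norm)
        assert l_c == pytest.approx(exp_c, abs=1e-8)
        assert l_o == pytest.approx(exp_o, abs=1e-8)

    @pytest.mark.parametrize("seed", range(10))
    def test_cut_loss_bounded_in_minus_one_zero(self, seed):
        rng = np.random.default_rng(100 + seed)
        g = random_symmetric_graph(rng, 12, density=rng.uniform(0.1, 0.9))
        S = random_row_stochastic(rng, 12, int(rng.integers(2, 6)))
        l_c, l_o = mincut_losses(S, g)
        assert -1.0 - 1e-9 <= l_c <= 0.0
        assert l_o >= 0.0

    def test_permutation_equivariance_of_pooling_pipeline(self, rng):
        # permuting gene order permutes loading rows identically
        g = random_symmetric_graph(rng, 6)
        X = rng.normal(size=(6, 5))
        W, Ws = rng.normal(size=(5, 4)), rng.normal(size=(5, 4))
        WH = rng.normal(size=(4, 3))
        S = pool(graph_conv(X, g, W, Ws), WH)
        perm = rng.permutation(6)
        g_perm = GeneGraph([g.genes[i] for i in perm], g.A[np.ix_(perm, perm)])
        S_perm = pool(graph_conv(X[perm], g_perm, W, Ws), WH)
        assert np.allclose(S_perm, S[perm], atol=1e-12)


class TestClassificationLoss:
    def test_zero_logit_gives_log_two(self):
        assert classification_loss(np.zeros((5, 1)), np.ones(5)) == pytest.approx(np.log(2))

    def test_confident_correct_predictions_vanish(self):
        logits = np.array([[30.0], [-30.0]])
        assert classification_loss(logits, np.array([1, 0])) == pytest.approx(0.0, abs=1e-9)

    def test_binary_matches_hand_computed_formula(self, rng):
        z = rng.normal(size=(8, 1))
        y = rng.integers(0, 2, size=8)
        p = 1 / (1 + np.exp(-z[:, 0]))
        expected = -np.mean(y * np.log(p) + (1 - y) * np.log(1 - p))
        assert classification_loss(z, y) == pytest.approx(expected, abs=1e-8)

    def test_multiclass_matches_hand_computed_formula(self, rng):
        z = rng.normal(size=(6, 3))
        y = rng.integers(0, 3, size=6)
        e = np.exp(z - z.max(axis=1, keepdims=True))
        p = e / e.sum(axis=1, keepdims=True)
        expected = -np.mean(np.log(p[np.arange(6), y]))
        assert classification_loss(z, y, task="multiclass") == pytest.approx(expected, abs=1e-8)

    def test_regression_mean_squared_error(self):
        z = np.array([[1.0], [2.0]])
        assert classification_loss(z, np.array([0.0, 4.0]), task="regression") == pytest.approx(2.5)

    def test_label_outside_class_set_rejected(self):
        with pytest.raises(ValueError):
            classification_loss(np.zeros((2, 1)), np.array([0, 2]))


class TestTotalLoss:
    def test_arithmetic(self):
        report = total_loss(0.5, -0.8, 0.1, w=2.0)
        assert report.total == pytest.approx(0.5 + 2 * (-0.7))

    def test_zero_weight_reduces_to_classification(self):
        report = total_loss(0.37, -0.9, 0.4, w=0.0)
        assert report.total == pytest.approx(0.37)

    def test_negative_weight_rejected(self):
        with pytest.raises(ValueError):
            total_loss(0.1, -0.5, 0.2, w=-1.0)

    def test_default_configuration_weight_is_two(self):
        from geneprog import TrainConfig

        assert TrainConfig().w == 2.0
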