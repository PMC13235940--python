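"""Sparsity, gene-set extraction, connectivity quantiles and AUC metrics."""

import itertools

import numpy as np
import pytest
import scipy.sparse as sp
from hypothesis import given, settings
from hypothesis import strategies as st

from geneprog import (
    GeneGraph,
    auc,
    best_match_auc,
    connectivity,
    connectivity_quantile,
    extract_gene_sets,
    hoyer_sparsity,
    loading_match_auc,
    write_gmt,
)

from .conftest import random_symmetric_graph


def _graph_from_edges(n, edges):
    A = np.eye(n)
    for i, j in edges:
        A[i, j] = A[j, i] = 1.0
    return GeneGraph([f"G{i}" for i in range(n)], sp.csr_matrix(A))


def exhaustive_quantile(gene_set, graph):
    """Mid-rank quantile over all same-size subsets of the universe."""
    k = len(gene_set)
    c_obs = connectivity(gene_set, graph)
    vals = [
        connectivity([graph.genes[i] for i in comb], graph)
        for comb in itertools.combinations(range(graph.n_genes), k)
    ]
    vals = np.array(vals)
    return (np.sum(vals < c_obs) + 0.5 * np.sum(vals == c_obs)) / len(vals)


class TestHoyerSparsity:
    def test_uniform_vector_is_zero(self):
        for d in (2, 5, 40):
            assert hoyer_sparsity(np.full(d, 3.7)) == pytest.approx(0.0, abs=1e-12)

    def test_one_hot_vector_is_one(self):
        v = np.zeros(10)
        v[4] = 2.5
        assert hoyer_sparsity(v) == pytest.approx(1.0, abs=1e-12)

    def test_three_four_example(self):
        expected = (np.sqrt(2) - 7 / 5) / (np.sqrt(2) - 1)
        assert hoyer_sparsity([3.0, 4.0]) == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.0343, abs=5e-4)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        st.lists(st.floats(0.01, 100.0), min_size=2, max_size=20),
        st.floats(0.001, 1000.0),
    )
    def test_scale_invariance(self, entries, alpha):
        v = np.array(entries)
        assert hoyer_sparsity(alpha * v) == pytest.approx(hoyer_sparsity(v), abs=1e-9)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            hoyer_sparsity([1.0])
        with pytest.raises(ValueError):
            hoyer_sparsity([0.0, 0.0])


class TestExtractGeneSets:
    def test_uniform_forty_program_loading_all_empty(self):
        S = np.full((30, 40), 1 / 40)
        sets = extract_gene_sets(S, [f"G{i}" for i in range(30)])
        assert sets.non_empty_count == 0

    def test_one_hot_loading_assigns_every_gene(self, rng):
        assign = rng.integers(0, 4, size=12)
        S = np.eye(4)[assign]
        sets = extract_gene_sets(S, [f"G{i}" for i in range(12)])
        recovered = {g for s in sets.sets for g in s.genes}
        assert len(recovered) == 12
        assert sets.non_empty_count == len(np.unique(assign))

    def test_loading_exactly_at_threshold_unassigned(self):
        S = np.array([[0.8, 0.2]])
        sets = extract_gene_sets(S, ["G0"], threshold=0.8)
        assert sets.non_empty_count == 0

    def test_gene_in_at_most_one_program_above_half(self, rng):
        S = rng.dirichlet(np.ones(3), size=40)
        sets = extract_gene_sets(S, [f"G{i}" for i in range(40)], threshold=0.6)
        members = [g for s in sets.sets for g in s.genes]
        assert len(members) == len(set(members))

    def test_threshold_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            extract_gene_sets(np.eye(2), ["A", "B"], threshold=1.5)


class TestConnectivity:
    def test_triangle(self):
        g = _graph_from_edges(3, [(0, 1), (1, 2), (0, 2)])
        assert connectivity(["G0", "G1", "G2"], g) == pytest.approx(2.0)

    def test_edgeless_pair(self):
        g = _graph_from_edges(3, [])
        assert connectivity(["G0", "G1"], g) == pytest.approx(0.0)

    def test_self_loops_excluded(self):
        g = _graph_from_edges(2, [])
        assert connectivity(["G0"], g) == 0.0

    def test_matches_double_loop_oracle(self, rng):
        g = random_symmetric_graph(rng, 9)
        A = g.A.toarray()
        for _ in range(5):
            size = int(rng.integers(2, 7))
            idx = rng.choice(9, size=size, replace=False)
            manual = sum(
                A[i, j] > 0 for i, j in itertools.combinations(idx, 2)
            )
            got = connectivity([g.genes[i] for i in idx], g)
            assert got == pytest.approx(2 * manual / size)

    def test_weighted_variant_sums_weights(self):
        A = np.array([[1.0, 0.5], [0.5, 1.0]])
        g = GeneGraph(["G0", "G1"], sp.csr_matrix(A))
        assert connectivity(["G0", "G1"], g, weighted=True) == pytest.approx(0.5)
        assert connectivity(["G0", "G1"], g, weighted=False) == pytest.approx(1.0)

    def test_unknown_gene_rejected(self):
        g = _graph_from_edges(2, [])
        with pytest.raises(KeyError):
            connectivity(["H9"], g)


class TestConnectivityQuantile:
    def test_complete_graph_all_ties_give_half(self):
        g = _graph_from_edges(4, list(itertools.combinations(range(4), 2)))
        assert connectivity_quantile(["G0", "G1"], g, n_null=200, seed=0) == pytest.approx(0.5)

    def test_star_graph_center_leaf_pair(self):
        # K1,3: three 2-subsets have C=1, three have C=0 → mid-rank 0.75
        g = _graph_from_edges(4, [(0, 1), (0, 2), (0, 3)])
        assert exhaustive_quantile(["G0", "G1"], g) == pytest.approx(0.75)
        sampled = connectivity_quantile(["G0", "G1"], g, n_null=20000, seed=1)
        assert sampled == pytest.approx(0.75, abs=0.02)

    def test_edgeless_graph_gives_half(self):
        g = _graph_from_edges(5, [])
        assert connectivity_quantile(["G0", "G1"], g, n_null=100, seed=0) == pytest.approx(0.5)

    @pytest.mark.parametrize("seed", range(3))
    def test_sampled_converges_to_exhaustive(self, seed):
        rng = np.random.default_rng(seed)
        g = random_symmetric_graph(rng, 8, density=0.35)
        idx = rng.choice(8, size=3, replace=False)
        genes = [g.genes[i] for i in idx]
        exact = exhaustive_quantile(genes, g)
        sampled = connectivity_quantile(genes, g, n_null=10000, seed=seed)
        assert sampled == pytest.approx(exact, abs=0.02)

    def test_invalid_null_count_rejected(self):
        g = _graph_from_edges(3, [])
        with pytest.raises(ValueError):
            connectivity_quantile(["G0"], g, n_null=0)


class TestAuc:
    def test_perfect_ranking(self):
        assert auc([0.9, 0.8, 0.3, 0.2], [1, 1, 0, 0]) == pytest.approx(1.0)

    def test_three_of_four_concordant_pairs(self):
        assert auc([0.9, 0.4, 0.6, 0.2], [1, 1, 0, 0]) == pytest.approx(0.75)

    def test_random_labels_near_half(self, rng):
        scores = rng.random(4000)
        labels = rng.integers(0, 2, size=4000)
        assert auc(scores, labels) == pytest.approx(0.5, abs=0.05)

    def test_matches_pairwise_enumeration(self, rng):
        scores = rng.random(30)
        labels = rng.integers(0, 2, size=30)
        pos = scores[labels == 1]
        neg = scores[labels == 0]
        pairs = [(0.5 if p == n else float(p > n)) for p in pos for n in neg]
        assert auc(scores, labels) == pytest.approx(np.mean(pairs), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc([0.1, 0.9], [1, 1])


class TestLoadingMatchAuc:
    def test_indicator_weights_are_perfect(self):
        genes = [f"G{i}" for i in range(6)]
        ref = ["G1", "G4"]
        weights = [0, 1, 0, 0, 1, 0]
        assert loading_match_auc(ref, weights, genes) == pytest.approx(1.0)

    def test_constant_weights_are_chance(self):
        genes = [f"G{i}" for i in range(6)]
        assert loading_match_auc(["G0"], np.ones(6), genes) == pytest.approx(0.5)

    def test_best_match_picks_highest_auc_program(self, rng):
        genes = [f"G{i}" for i in range(8)]
        loading = rng.random((8, 3))
        loading[:4, 2] += 5.0  # program 2 ranks the reference set on top
        k, a = best_match_auc(genes[:4], loading, genes)
        assert k == 2
        assert a == pytest.approx(1.0)

    def test_degenerate_reference_rejected(self):
        genes = ["G0", "G1"]
        with pytest.raises(ValueError):
            loading_match_auc(genes, [0.1, 0.2], genes)


def test_gmt_output_lists_non_empty_sets(tmp_path, rng):
    S = np.eye(3)[[0, 0, 1]]
    sets = extract_gene_sets(S, ["A", "B", "C"], threshold=0.7)
    write_gmt(sets, tmp_path / "sets.gmt")
    lines = (tmp_path / "sets.gmt").read_text().strip().split("\n")
    assert len(lines) == 2
    assert lines[0].split("\t")[2:] == ["A", "B"]
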