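"""GCN layers, pair prediction, MCC and the training loop."""

import math

import numpy as np
import pytest
from sklearn.metrics import matthews_corrcoef

from conftest import make_token_nodes
from tokengraph.attention import MockAttentionProvider
from tokengraph.classify import (
    ConfusionCounts,
    GcnParams,
    LabeledPair,
    TrainConfig,
    evaluate,
    gcn_layer,
    graph_embedding,
    load_pairs_tsv,
    mcc,
    pair_to_graphs,
    predict_pair,
    train,
    write_pairs_tsv,
)
from tokengraph.graph_build import GraphConfig, TokenGraph
from tokengraph.synthetic_fixtures import SynthEpiSpec, make_epi_pairs
from tokengraph.tokenization import KmerTokenizer


def graph_of(m: int, edges: dict) -> TokenGraph:
    g = TokenGraph(reference="chr_r")
    for node in make_token_nodes(m):
        g.nodes[node.node_index] = node
    g.edges = dict(edges)
    return g


def params_of(rng, vocab=64, d=8) -> GcnParams:
    return GcnParams.init(vocab, d, rng)


class TestMcc:
    @pytest.mark.parametrize(
        "counts,expected",
        [
            (ConfusionCounts(5, 5, 0, 0), 1.0),
            (ConfusionCounts(0, 0, 5, 5), -1.0),
            (ConfusionCounts(4, 3, 1, 2), 10 / math.sqrt(600)),
            (ConfusionCounts(0, 10, 0, 0), 0.0),  # zero-denominator convention
        ],
    )
    def test_worked_examples(self, counts, expected):
        assert mcc(counts) == pytest.approx(expected, abs=1e-12)

    def test_equals_pearson_correlation_for_all_small_tables(self):
        # oracle: direct correlation of the binary label vectors
        for total in range(1, 13):
            for tp in range(total + 1):
                for tn in range(total - tp + 1):
                    for fp in range(total - tp - tn + 1):
                        fn = total - tp - tn - fp
                        c = ConfusionCounts(tp, tn, fp, fn)
                        y_true = [1] * tp + [0] * tn + [0] * fp + [1] * fn
                        y_pred = [1] * tp + [0] * tn + [1] * fp + [0] * fn
                        with np.errstate(invalid="ignore"):
                            r = np.corrcoef(y_true, y_pred)[0, 1]
                        expected = 0.0 if np.isnan(r) else float(r)
                        assert mcc(c) == pytest.approx(expected, abs=1e-12)
                        assert mcc(c) == pytest.approx(
                            matthews_corrcoef(y_true, y_pred), abs=1e-12
                        )

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(-1, 0, 0, 0)


class TestGcnLayer:
    def test_edgeless_graph_identity_propagation(self):
        g = graph_of(4, {})
        h = np.abs(np.random.default_rng(0).normal(size=(4, 3)))
        out = gcn_layer(h, g, np.eye(3))
        np.testing.assert_allclose(out, h)  # A+I = I, D = I

    def test_single_unit_edge_averages_neighbors(self):
        g = graph_of(2, {(0, 1): 1.0})
        h = np.eye(2)
        out = gcn_layer(h, g, np.eye(2))
        # degrees are 2 each; normalized adjacency is [[.5,.5],[.5,.5]]
        np.testing.assert_allclose(out, [[0.5, 0.5], [0.5, 0.5]])

    def test_zero_weight_matrix_annihilates(self):
        g = graph_of(3, {(0, 1): 0.4})
        h = np.random.default_rng(1).normal(size=(3, 2))
        np.testing.assert_allclose(gcn_layer(h, g, np.zeros((2, 2))), 0.0)

    def test_shape_mismatch_rejected(self):
        g = graph_of(3, {})
        with pytest.raises(ValueError):
            gcn_layer(np.zeros((2, 4)), g, np.eye(4))
        with pytest.raises(ValueError):
            gcn_layer(np.zeros((3, 4)), g, np.eye(5))


class TestGraphEmbedding:
    def test_one_node_graph_embedding_is_node_features(self):
        rng = np.random.default_rng(2)
        params = params_of(rng)
        g = graph_of(1, {})
        emb = graph_embedding(g, params)
        x = params.embedding[g.nodes[0].token_id][None, :]
        expected = np.maximum(
            np.maximum(x @ params.W1, 0.0) @ params.W2, 0.0
        )[0]
        np.testing.assert_allclose(emb, expected)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(3)
        params = params_of(rng)
        g = graph_of(6, {(0, 1): 0.5, (2, 4): 0.2, (1, 5): 0.9})
        emb = graph_embedding(g, params)
        # relabel nodes by a permutation; mean pooling must not care
        perm = [3, 0, 5, 1, 4, 2]
        relabeled = TokenGraph(reference="chr_r")
        for old, node in g.nodes.items():
            new = perm[old]
            relabeled.nodes[new] = type(node)(
                token_id=node.token_id, token_string=node.token_string,
                reference=node.reference, start=node.start, end=node.end,
                node_index=new,
            )
        for (i, j), w in g.edges.items():
            a, b = sorted((perm[i], perm[j]))
            relabeled.edges[(a, b)] = w
        np.testing.assert_allclose(
            graph_embedding(relabeled, params), emb, atol=1e-12
        )

    def test_duplication_invariance(self):
        # doubling every node and edge leaves the mean embedding unchanged
        rng = np.random.default_rng(4)
        params = params_of(rng)
        g = graph_of(3, {(0, 1): 0.7})
        doubled = TokenGraph(reference="chr_r")
        for idx, node in g.nodes.items():
            for copy in (0, 1):
                new = idx + 3 * copy
                doubled.nodes[new] = type(node)(
                    token_id=node.token_id, token_string=node.token_string,
                    reference=node.reference, start=node.start, end=node.end,
                    node_index=new,
                )
        for (i, j), w in g.edges.items():
            doubled.edges[(i, j)] = w
            doubled.edges[(i + 3, j + 3)] = w
        np.testing.assert_allclose(
            graph_embedding(doubled, params), graph_embedding(g, params), atol=1e-12
        )

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError):
            graph_embedding(TokenGraph(reference="x"), params_of(np.random.default_rng(5)))


class TestPredictPair:
    def test_zero_readout_gives_half(self):
        rng = np.random.default_rng(6)
        params = params_of(rng)
        params.w_out = np.zeros_like(params.w_out)
        params.b_out = 0.0
        g = graph_of(3, {(0, 1): 0.5})
        assert predict_pair((g, g), params) == pytest.approx(0.5)

    def test_large_bias_saturates(self):
        rng = np.random.default_rng(7)
        params = params_of(rng)
        params.b_out = 50.0
        g = graph_of(2, {})
        assert predict_pair((g, g), params) > 0.999999

    def test_deterministic_inference(self):
        rng = np.random.default_rng(8)
        params = params_of(rng)
        g = graph_of(4, {(0, 2): 0.3})
        assert predict_pair((g, g), params) == predict_pair((g, g), params)


class TestPairToGraphs:
    def test_token_count_arithmetic(self):
        pair = LabeledPair(seq_a="ACGT" * 15, seq_b="TTCA" * 15, label=1)
        ga, gb = pair_to_graphs(
            pair, KmerTokenizer(3), MockAttentionProvider(seed=0), GraphConfig(theta=0.0)
        )
        assert ga.n_nodes == 20 and gb.n_nodes == 20

    def test_theta_one_gives_edgeless_graphs_classifier_still_runs(self):
        pair = LabeledPair(seq_a="ACGT" * 10, seq_b="GGCC" * 10, label=0)
        ga, gb = pair_to_graphs(
            pair, KmerTokenizer(3), MockAttentionProvider(seed=0), GraphConfig(theta=1.0)
        )
        assert ga.n_edges == 0 and gb.n_edges == 0
        prob = predict_pair((ga, gb), params_of(np.random.default_rng(9)))
        assert 0.0 < prob < 1.0

    def test_identical_sequences_same_seed_identical_graphs(self):
        seq = "ACGTTGCA" * 10
        pair = LabeledPair(seq_a=seq, seq_b=seq, label=1)
        ga, gb = pair_to_graphs(
            pair, KmerTokenizer(3), MockAttentionProvider(seed=5), GraphConfig()
        )
        assert ga.nodes.keys() == gb.nodes.keys()
        assert {k: v for k, v in ga.edges.items()} == gb.edges
        assert all(
            ga.nodes[i].token_id == gb.nodes[i].token_id for i in ga.nodes
        )


@pytest.fixture(scope="module")
def tiny_dataset():
    return make_epi_pairs(SynthEpiSpec(n_pairs=40, seq_length=120, seed=21))


class TestTrain:
    def test_single_class_dataset_rejected(self):
        pairs = [LabeledPair("ACGTAC", "ACGTAC", 1) for _ in range(8)]
        with pytest.raises(ValueError):
            train(pairs, TrainConfig(epochs=1))

    def test_zero_epochs_returns_initialized_params(self, tiny_dataset):
        params0, report0 = train(tiny_dataset, TrainConfig(epochs=0), seed=3)
        params1, _ = train(tiny_dataset, TrainConfig(epochs=0), seed=3)
        np.testing.assert_array_equal(params0.embedding, params1.embedding)
        np.testing.assert_array_equal(params0.W1, params1.W1)
        assert report0["history"] == [report0["best_val_mcc"]]

    def test_same_seed_reproducible(self, tiny_dataset):
        a, ra = train(tiny_dataset, TrainConfig(epochs=3), seed=5)
        b, rb = train(tiny_dataset, TrainConfig(epochs=3), seed=5)
        np.testing.assert_array_equal(a.embedding, b.embedding)
        np.testing.assert_array_equal(a.W1, b.W1)
        np.testing.assert_array_equal(a.w_out, b.w_out)
        assert ra["history"] == rb["history"]

    def test_learns_separable_signal_quickly(self, tiny_dataset):
        _, report = train(tiny_dataset, TrainConfig(epochs=15), seed=1)
        assert report["best_val_mcc"] >= 0.6

    def test_evaluate_counts_sum_to_dataset(self, tiny_dataset):
        params, _ = train(tiny_dataset, TrainConfig(epochs=2), seed=2)
        tok = KmerTokenizer(3)
        prov = MockAttentionProvider(seed=0)
        gp = [pair_to_graphs(p, tok, prov, GraphConfig()) for p in tiny_dataset]
        counts = evaluate(gp, [p.label for p in tiny_dataset], params)
        assert counts.TP + counts.TN + counts.FP + counts.FN == len(tiny_dataset)


def test_pairs_tsv_roundtrip(tmp_path):
    pairs = make_epi_pairs(SynthEpiSpec(n_pairs=6, seq_length=50, seed=1))
    path = tmp_path / "pairs.tsv"
    write_pairs_tsv(pairs, path)
    assert load_pairs_tsv(path) == pairs
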