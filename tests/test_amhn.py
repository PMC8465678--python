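"""Multiplex-embedding forward pass against a straight-line oracle, plus
attention, aggregation and training contracts."""

import numpy as np
import pytest

from mdlinker.amhn import (
    GatneConfig,
    GatneParams,
    _Trainer,
    aggregate_edge_embedding,
    attention_combine,
    attention_weights,
    build_amhn,
    compute_embeddings,
    final_embedding,
    train_gatne,
)
from mdlinker.io_formats import ASSOCIATION_TYPES, AssociationRecord

from conftest import random_features


def small_graph(ne=6, seed=0, records=None):
    mirnas = ["m0", "m1", "m2"]
    diseases = ["d0", "d1", "d2"]
    if records is None:
        records = [
            AssociationRecord("m0", "d0", "genetics"),
            AssociationRecord("m0", "d1", "genetics"),
            AssociationRecord("m1", "d1", "target"),
            AssociationRecord("m2", "d2", "tissue"),
            AssociationRecord("m1", "d0", "circulating"),
        ]
    mf = random_features(mirnas, ne, seed)
    df = random_features(diseases, ne, seed + 1)
    return build_amhn(records, mf, df)


# ---------------------------------------------------------------------------
# oracle: plain-loop recomputation of the whole forward pass


def oracle_final_embedding(graph, params, cfg, i, r):
    n, m = graph.n_nodes, graph.n_layers
    per_layer = []
    for r2 in range(m):
        cur = []
        for j in range(n):
            z = graph.node_type[j]
            cur.append(graph.X[j] @ params.G_w[z, r2] + params.G_b[z, r2])
        for _ in range(cfg.depth):
            nxt = []
            for j in range(n):
                nbrs = [k for k in range(n) if graph.adjacency[r2, j, k]]
                if not nbrs:
                    nxt.append(cur[j])
                else:
                    agg = sum(cur[k] for k in nbrs) / len(nbrs)
                    nxt.append(np.tanh(agg) if cfg.activation == "tanh" else agg)
            cur = nxt
        per_layer.append(cur)
    d_i = np.stack([per_layer[r2][i] for r2 in range(m)])  # (m, DE)
    e = np.array([
        params.w_att[r] @ np.tanh(params.W_att[r] @ d_i[r2]) for r2 in range(m)
    ])
    a = np.exp(e - e.max())
    a = a / a.sum()
    s = sum(a[r2] * d_i[r2] for r2 in range(m))
    u = params.alpha[r] * (params.M[r].T @ s)
    z = graph.node_type[i]
    b = params.H_w[z].T @ graph.X[i] + params.H_b[z]
    attr = params.beta[r] * (params.D_feat[z].T @ graph.X[i])
    return attr + b + u


class TestForwardOracle:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_straight_line_recomputation(self, seed):
        graph = small_graph(seed=seed)
        cfg = GatneConfig(be=4, de=3, att_dim=2, depth=2)
        rng = np.random.default_rng(seed + 10)
        params = GatneParams.init(6, graph.n_nodes, graph.n_layers, cfg, rng)
        for i in range(graph.n_nodes):
            for r in range(graph.n_layers):
                got = final_embedding(graph, params, cfg, i, r)
                want = oracle_final_embedding(graph, params, cfg, i, r)
                np.testing.assert_allclose(got, want, atol=1e-9)

    def test_full_forward_matches_single_node_path(self):
        graph = small_graph()
        cfg = GatneConfig(be=4, de=3, att_dim=2)
        params = GatneParams.init(6, graph.n_nodes, graph.n_layers, cfg,
                                  np.random.default_rng(3))
        emb = compute_embeddings(graph, params, cfg)
        np.testing.assert_allclose(
            emb.V[2, 1], oracle_final_embedding(graph, params, cfg, 1, 2),
            atol=1e-9,
        )


class TestBuildGraph:
    def test_layers_carry_only_their_type(self):
        graph = small_graph(records=[
            AssociationRecord("m0", "d0", "target"),
            AssociationRecord("m0", "d0", "genetics"),
        ])
        per_layer = [graph.layer_edges(r) for r in range(graph.n_layers)]
        assert per_layer == [1, 0, 0, 1, 0]

    def test_empty_records_give_empty_layers(self, caplog):
        with caplog.at_level("WARNING"):
            graph = small_graph(records=[])
        assert not graph.adjacency.any()

    def test_layers_are_bipartite(self):
        graph = small_graph()
        is_m = graph.node_type == 0
        for r in range(graph.n_layers):
            assert not graph.adjacency[r][np.ix_(is_m, is_m)].any()
            assert not graph.adjacency[r][np.ix_(~is_m, ~is_m)].any()

    def test_unknown_endpoint_is_fatal(self):
        mf = random_features(["m0"], 4, 0)
        df = random_features(["d0"], 4, 1)
        with pytest.raises(KeyError):
            build_amhn([AssociationRecord("mX", "d0", "target")], mf, df)


class TestAggregation:
    def test_level_zero_is_the_attribute_transform(self):
        graph = small_graph()
        cfg = GatneConfig(be=4, de=3)
        params = GatneParams.init(6, graph.n_nodes, graph.n_layers, cfg,
                                  np.random.default_rng(0))
        z = graph.node_type[1]
        want = graph.X[1] @ params.G_w[z, 0] + params.G_b[z, 0]
        got = aggregate_edge_embedding(graph, params, cfg, i=1, r=0, k=0)
        np.testing.assert_allclose(got, want, atol=1e-12)

    def test_isolated_node_keeps_level_zero(self):
        graph = small_graph()
        cfg = GatneConfig(be=4, de=3, depth=2)
        params = GatneParams.init(6, graph.n_nodes, graph.n_layers, cfg,
                                  np.random.default_rng(0))
        # layer 1 (epigenetics) is empty: every node is isolated there
        d0 = aggregate_edge_embedding(graph, params, cfg, i=0, r=1, k=0)
        d2 = aggregate_edge_embedding(graph, params, cfg, i=0, r=1, k=2)
        np.testing.assert_allclose(d0, d2, atol=1e-12)

    def test_star_mean_aggregation_with_identity_transforms(self):
        # star in the genetics layer: m0 linked to d0, d1, d2
        records = [AssociationRecord("m0", f"d{j}", "genetics") for j in range(3)]
        graph = small_graph(ne=3, records=records)
        cfg = GatneConfig(be=4, de=3, depth=1, activation="identity")
        params = GatneParams.init(3, graph.n_nodes, graph.n_layers, cfg,
                                  np.random.default_rng(0))
        params.G_w[:] = np.eye(3)  # g_{z,r} = identity
        params.G_b[:] = 0.0
        center = aggregate_edge_embedding(graph, params, cfg, i=0, r=0, k=1)
        leaves = graph.X[3:6]  # d0, d1, d2 level-0 values = their attributes
        np.testing.assert_allclose(center, leaves.mean(axis=0), atol=1e-12)


class TestAttention:
    def test_weights_nonnegative_and_normalized(self):
        graph = small_graph()
        cfg = GatneConfig(be=4, de=3)
        params = GatneParams.init(6, graph.n_nodes, graph.n_layers, cfg,
                                  np.random.default_rng(0))
        d_stack = np.random.default_rng(1).normal(size=(graph.n_nodes, 5, 3))
        for r in range(5):
            a = attention_weights(params, d_stack, r)
            assert (a >= 0).all()
            np.testing.assert_allclose(a.sum(axis=-1), 1.0, atol=1e-12)

    def test_zero_attention_matrix_gives_uniform_weights(self):
        graph = small_graph()
        cfg = GatneConfig(be=4, de=3)
        params = GatneParams.init(6, graph.n_nodes, graph.n_layers, cfg,
                                  np.random.default_rng(0))
        params.W_att[0][:] = 0.0
        a = attention_weights(params, np.ones((2, 5, 3)), 0)
        np.testing.assert_allclose(a, 0.2, atol=1e-12)

    def test_single_layer_collapses_to_projection(self):
        graph = small_graph()
        cfg = GatneConfig(be=4, de=3)
        params = GatneParams.init(6, graph.n_nodes, graph.n_layers, cfg,
                                  np.random.default_rng(0))
        d = np.random.default_rng(2).normal(size=(1, 3))  # m = 1
        u = attention_combine(params, d, r=0)
        np.testing.assert_allclose(
            u, params.alpha[0] * params.M[0].T @ d[0], atol=1e-12
        )


class TestFinalEmbedding:
    def test_zero_coefficients_collapse_to_base(self):
        graph = small_graph()
        cfg = GatneConfig(be=4, de=3, alpha_r=0.0, beta_r=0.0)
        params = GatneParams.init(6, graph.n_nodes, graph.n_layers, cfg,
                                  np.random.default_rng(0))
        emb = compute_embeddings(graph, params, cfg)
        for r in range(1, graph.n_layers):
            np.testing.assert_allclose(emb.V[r], emb.V[0], atol=1e-12)

    def test_identical_layers_and_parameters_give_identical_embeddings(self):
        records = [
            AssociationRecord("m0", "d0", "genetics"),
            AssociationRecord("m1", "d1", "genetics"),
            AssociationRecord("m0", "d0", "epigenetics"),
            AssociationRecord("m1", "d1", "epigenetics"),
        ]
        graph = small_graph(records=records)
        cfg = GatneConfig(be=4, de=3)
        params = GatneParams.init(6, graph.n_nodes, graph.n_layers, cfg,
                                  np.random.default_rng(0))
        for arr in (params.G_w[:, 1], params.G_b[:, 1]):
            arr[:] = arr * 0
        params.G_w[:, 1] = params.G_w[:, 0]
        params.G_b[:, 1] = params.G_b[:, 0]
        params.W_att[1] = params.W_att[0]
        params.w_att[1] = params.w_att[0]
        params.M[1] = params.M[0]
        emb = compute_embeddings(graph, params, cfg)
        np.testing.assert_allclose(emb.V[1], emb.V[0], atol=1e-12)


class TestTraining:
    def test_all_layers_empty_is_an_error(self):
        graph = small_graph(records=[])
        with pytest.raises(ValueError):
            train_gatne(graph, GatneConfig(be=4, de=3))

    def test_batch_loss_finite_and_nonnegative(self):
        graph = small_graph()
        cfg = GatneConfig(be=4, de=3)
        params = GatneParams.init(6, graph.n_nodes, graph.n_layers, cfg,
                                  np.random.default_rng(0))
        trainer = _Trainer(graph, cfg, params)
        loss = trainer.batch_step(
            r=0,
            centers=np.array([0, 3]),
            contexts=np.array([3, 0]),
            negatives=np.array([[4, 5], [1, 2]]),
            lr=0.01,
        )
        assert np.isfinite(loss) and loss >= 0.0

    def test_fixed_seed_reproduces_embeddings(self):
        graph = small_graph()
        cfg = GatneConfig(be=4, de=3, epochs=2, seed=7)
        _, emb1 = train_gatne(graph, cfg)
        _, emb2 = train_gatne(graph, cfg)
        np.testing.assert_array_equal(emb1.V, emb2.V)

    def test_attention_normalized_after_every_epoch(self):
        graph = small_graph()
        cfg = GatneConfig(be=4, de=3, epochs=3, seed=1)
        seen = []

        def check(epoch, params, attention):
            seen.append(epoch)
            assert (attention >= 0).all()
            np.testing.assert_allclose(attention.sum(axis=-1), 1.0, atol=1e-9)

        train_gatne(graph, cfg, on_epoch_end=check)
        assert seen == [0, 1, 2]

    def test_planted_blocks_recovered_within_layer(self):
        # 2x2 block multiplex: block pairs connected in the genetics layer
        rng = np.random.default_rng(0)
        mirnas = [f"m{i}" for i in range(8)]
        diseases = [f"d{i}" for i in range(8)]
        records = []
        for i in range(8):
            for j in range(8):
                if (i < 4) == (j < 4) and rng.random() < 0.8:
                    records.append(AssociationRecord(f"m{i}", f"d{j}", "genetics"))
        mf = random_features(mirnas, 8, 1)
        df = random_features(diseases, 8, 2)
        graph = build_amhn(records, mf, df)
        cfg = GatneConfig(be=8, de=8, epochs=4, seed=3)
        _, emb = train_gatne(graph, cfg)
        V = emb.V[0]  # genetics layer
        Vn = V / np.linalg.norm(V, axis=1, keepdims=True)
        C = Vn @ Vn.T
        block = np.array([i < 4 for i in range(8)] * 2)
        same = block[:, None] == block[None, :]
        off = ~np.eye(16, dtype=bool)
        assert C[same & off].mean() > C[~same].mean()

    def test_cross_layer_information_flow(self):
        # genetics layer empty, target layer dense: genetics-layer embeddings
        # of target-connected nodes must still be closer than random pairs
        wins = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            mirnas = [f"m{i}" for i in range(6)]
            diseases = [f"d{i}" for i in range(6)]
            records = []
            for i in range(6):
                for j in range(6):
                    if (i < 3) == (j < 3):
                        records.append(
                            AssociationRecord(f"m{i}", f"d{j}", "target")
                        )
            mf = random_features(mirnas, 8, seed * 2 + 1)
            df = random_features(diseases, 8, seed * 2 + 2)
            graph = build_amhn(records, mf, df)
            cfg = GatneConfig(be=8, de=8, epochs=10, lr=0.1,
                              walks_per_node=10, seed=seed)
            _, emb = train_gatne(graph, cfg)
            V = emb.V[0]  # the empty genetics layer
            d_conn, d_rand = [], []
            for i in range(6):
                for j in range(6):
                    dist = np.linalg.norm(V[i] - V[6 + j])
                    (d_conn if (i < 3) == (j < 3) else d_rand).append(dist)
            if np.mean(d_conn) < np.mean(d_rand):
                wins += 1
        assert wins >= 8
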