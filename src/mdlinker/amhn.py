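"""Attributed multi-layer heterogeneous network embedding.

The miRNA-disease association network has one layer per evidence type; every
layer is bipartite between the same two node classes (miRNA, disease), and
every node carries an attribute vector learned from its similarity network.
Each node i gets, per layer r, an embedding

    v_{i,r} = beta_r D_z^T x_i  +  b_i  +  u_{i,r}

with three parts: a transformed-attribute term, a layer-shared base embedding
b_i = h_z(x_i), and a layer-specific term u_{i,r} built by (1) initialising a
per-layer edge embedding d_{i,r}^(0) = g_{z,r}(x_i) from the attributes,
(2) aggregating neighbours within layer r for K levels (GraphSAGE-style mean,
max optional), and (3) mixing the edge embeddings of ALL layers with a
per-target-layer self-attention head:

    a_{i,r} = softmax(w_r^T tanh(W_r D_i))^T,   D_i = (d_{i,1}, ..., d_{i,m})
    u_{i,r} = alpha_r M_r^T D_i a_{i,r}

Parameters are trained by skip-gram with negative sampling over within-layer
meta-path walks (miRNA-disease-miRNA alternation, which the bipartite layers
enforce), with gradients derived and applied by hand in numpy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .io_formats import ASSOCIATION_TYPES, AssociationRecord
from .node_features import FeatureTable
from .sgns import _sigmoid, sample_from_cdf, scatter_add, unigram_noise

logger = logging.getLogger(__name__)

MIRNA, DISEASE = 0, 1  # node-type codes z


@dataclass
class GatneConfig:
    """Dimensions and training hyperparameters for the multiplex embedding."""

    be: int = 32            # base-embedding dimension (also final dim)
    de: int = 32            # edge-embedding dimension
    att_dim: int = 16       # attention hidden size
    depth: int = 2          # neighbour-aggregation levels K
    aggregator: str = "mean"        # "mean" or "max"
    activation: str = "tanh"        # "tanh" or "identity"
    alpha_r: float = 1.0    # fixed edge-term coefficient (per layer)
    beta_r: float = 1.0     # fixed attribute-term coefficient (per layer)
    walk_length: int = 10
    walks_per_node: int = 6
    window: int = 3
    negatives: int = 5
    epochs: int = 2
    batch_size: int = 1024
    lr: float = 0.05
    min_lr: float = 1e-4
    seed: int = 0


@dataclass
class AttributedMultiLayerGraph:
    """Shared node set, per-type bipartite edge layers, per-node attributes."""

    labels: tuple[str, ...]           # miRNAs first, then diseases
    node_type: np.ndarray             # (n,) in {MIRNA, DISEASE}
    X: np.ndarray                     # (n, NE) attribute vectors
    layer_names: tuple[str, ...]
    adjacency: np.ndarray             # (R, n, n) boolean, symmetric

    @property
    def n_nodes(self) -> int:
        return len(self.labels)

    @property
    def n_layers(self) -> int:
        return len(self.layer_names)

    def index(self, label: str) -> int:
        return self.labels.index(label)

    def layer_index(self, name: str) -> int:
        return self.layer_names.index(name)

    def layer_edges(self, r: int) -> int:
        return int(self.adjacency[r].sum()) // 2


def build_amhn(
    records: Sequence[AssociationRecord],
    mirna_features: FeatureTable,
    disease_features: FeatureTable,
) -> AttributedMultiLayerGraph:
    """Assemble the multiplex graph: one layer per association type.

    Every record endpoint must have an attribute vector (the io module's
    intersection filter guarantees this for well-formed pipelines).
    """
    labels = tuple(mirna_features.labels) + tuple(disease_features.labels)
    index = {name: i for i, name in enumerate(labels)}
    node_type = np.array(
        [MIRNA] * len(mirna_features.labels) + [DISEASE] * len(disease_features.labels)
    )
    X = np.vstack([mirna_features.X, disease_features.X])
    n = len(labels)
    adjacency = np.zeros((len(ASSOCIATION_TYPES), n, n), dtype=bool)
    for rec in records:
        if rec.mirna_name not in index or rec.disease_name not in index:
            raise KeyError(
                f"record endpoint without attribute vector: "
                f"({rec.mirna_name!r}, {rec.disease_name!r})"
            )
        r = ASSOCIATION_TYPES.index(rec.type_label)
        i, j = index[rec.mirna_name], index[rec.disease_name]
        adjacency[r, i, j] = adjacency[r, j, i] = True
    if not records:
        logger.warning("empty record list: all %d layers empty", len(ASSOCIATION_TYPES))
    return AttributedMultiLayerGraph(labels, node_type, X, ASSOCIATION_TYPES, adjacency)


@dataclass
class GatneParams:
    """All trainable parameters, indexed by node type z and layer r."""

    H_w: np.ndarray   # (2, NE, BE)   base transform h_z
    H_b: np.ndarray   # (2, BE)
    G_w: np.ndarray   # (2, R, NE, DE) edge-embedding transform g_{z,r}
    G_b: np.ndarray   # (2, R, DE)
    W_att: np.ndarray  # (R, att, DE)
    w_att: np.ndarray  # (R, att)
    M: np.ndarray      # (R, DE, BE)
    D_feat: np.ndarray  # (2, NE, BE)  attribute transform D_z
    alpha: np.ndarray   # (R,)
    beta: np.ndarray    # (R,)
    context: np.ndarray  # (n, BE) skip-gram context embeddings

    @classmethod
    def init(cls, ne: int, n_nodes: int, n_layers: int, cfg: GatneConfig,
             rng: np.random.Generator) -> "GatneParams":
        s = 1.0 / np.sqrt(ne)
        r_, be, de, att = n_layers, cfg.be, cfg.de, cfg.att_dim
        return cls(
            H_w=rng.normal(0, s, (2, ne, be)),
            H_b=np.zeros((2, be)),
            G_w=rng.normal(0, s, (2, r_, ne, de)),
            G_b=np.zeros((2, r_, de)),
            W_att=rng.normal(0, 1.0 / np.sqrt(de), (r_, att, de)),
            w_att=rng.normal(0, 1.0 / np.sqrt(att), (r_, att)),
            M=rng.normal(0, 1.0 / np.sqrt(de), (r_, de, be)),
            D_feat=rng.normal(0, s, (2, ne, be)),
            alpha=np.full(r_, cfg.alpha_r),
            beta=np.full(r_, cfg.beta_r),
            context=np.zeros((n_nodes, be)),
        )


@dataclass(frozen=True)
class LayerEmbeddings:
    """Final per-layer, per-node embeddings v_{i,r}."""

    labels: tuple[str, ...]
    layer_names: tuple[str, ...]
    V: np.ndarray  # (R, n, BE)

    def vector(self, label: str, layer: str) -> np.ndarray:
        return self.V[self.layer_names.index(layer), self.labels.index(label)]


def _activate(x: np.ndarray, kind: str) -> np.ndarray:
    if kind == "tanh":
        return np.tanh(x)
    if kind == "identity":
        return x
    raise ValueError(f"unknown activation {kind!r}")


def _edge_level_cache(graph: AttributedMultiLayerGraph, params: GatneParams,
                      cfg: GatneConfig) -> list[list[np.ndarray]]:
    """Per-layer list of level matrices [D^(0), ..., D^(K)], each (n, DE).

    Isolated nodes in a layer pass their previous level through unchanged, so
    every node has an edge embedding in every layer.
    """
    n = graph.n_nodes
    cache: list[list[np.ndarray]] = []
    for r in range(graph.n_layers):
        d0 = np.empty((n, cfg.de))
        for z in (MIRNA, DISEASE):
            rows = graph.node_type == z
            d0[rows] = graph.X[rows] @ params.G_w[z, r] + params.G_b[z, r]
        levels = [d0]
        adj = graph.adjacency[r].astype(float)
        deg = adj.sum(axis=1)
        isolated = deg == 0
        p_mat = np.divide(adj, np.maximum(deg, 1.0)[:, None])
        for _ in range(cfg.depth):
            prev = levels[-1]
            if cfg.aggregator == "mean":
                agg = p_mat @ prev
            elif cfg.aggregator == "max":
                masked = np.where(adj[:, :, None] > 0, prev[None, :, :], -np.inf)
                agg = masked.max(axis=1)
                agg[isolated] = 0.0
            else:
                raise ValueError(f"unknown aggregator {cfg.aggregator!r}")
            nxt = _activate(agg, cfg.activation)
            nxt[isolated] = prev[isolated]
            levels.append(nxt)
        cache.append(levels)
    return cache


def aggregate_edge_embedding(graph: AttributedMultiLayerGraph, params: GatneParams,
                             cfg: GatneConfig, i: int, r: int, k: int) -> np.ndarray:
    """d_{i,r}^(k): node i's level-k edge embedding in layer r."""
    if k < 0 or k > cfg.depth:
        raise ValueError("level k must be in [0, depth]")
    return _edge_level_cache(graph, params, cfg)[r][k][i].copy()


def attention_weights(params: GatneParams, d_stack: np.ndarray, r: int) -> np.ndarray:
    """a_{i,r} for a (..., m, DE) stack of per-layer edge embeddings."""
    pre = np.tanh(np.einsum("ad,...md->...am", params.W_att[r], d_stack))
    e = np.einsum("a,...am->...m", params.w_att[r], pre)
    e = e - e.max(axis=-1, keepdims=True)
    ex = np.exp(e)
    return ex / ex.sum(axis=-1, keepdims=True)


def attention_combine(params: GatneParams, d_stack: np.ndarray, r: int) -> np.ndarray:
    """u_{i,r} = alpha_r M_r^T D_i a_{i,r} for a (m, DE) stack (single node)."""
    a = attention_weights(params, d_stack, r)
    s = a @ d_stack  # (DE,)
    return params.alpha[r] * (s @ params.M[r])


def compute_embeddings(graph: AttributedMultiLayerGraph, params: GatneParams,
                       cfg: GatneConfig) -> LayerEmbeddings:
    """Full forward pass: v_{i,r} for every node and layer."""
    cache = _edge_level_cache(graph, params, cfg)
    top = np.stack([levels[-1] for levels in cache], axis=1)  # (n, m, DE)
    n, m = graph.n_nodes, graph.n_layers
    base = np.empty((n, cfg.be))
    attr = np.empty((m, n, cfg.be))
    for z in (MIRNA, DISEASE):
        rows = graph.node_type == z
        base[rows] = graph.X[rows] @ params.H_w[z] + params.H_b[z]
        for r in range(m):
            attr[r, rows] = params.beta[r] * (graph.X[rows] @ params.D_feat[z])
    V = np.empty((m, n, cfg.be))
    for r in range(m):
        a = attention_weights(params, top, r)            # (n, m)
        s = np.einsum("nmd,nm->nd", top, a)              # (n, DE)
        u = params.alpha[r] * (s @ params.M[r])          # (n, BE)
        V[r] = attr[r] + base + u
    return LayerEmbeddings(graph.labels, graph.layer_names, V)


def final_embedding(graph: AttributedMultiLayerGraph, params: GatneParams,
                    cfg: GatneConfig, i: int, r: int) -> np.ndarray:
    """v_{i,r} for one node (thin wrapper over the full forward pass)."""
    return compute_embeddings(graph, params, cfg).V[r, i].copy()


def _metapath_walks(graph: AttributedMultiLayerGraph, r: int, cfg: GatneConfig,
                    rng: np.random.Generator) -> list[list[int]]:
    """Uniform within-layer walks; bipartite layers alternate node classes."""
    adj = graph.adjacency[r]
    neighbors = [np.flatnonzero(adj[i]) for i in range(graph.n_nodes)]
    starts = [i for i in range(graph.n_nodes) if neighbors[i].size > 0]
    walks = []
    for _ in range(cfg.walks_per_node):
        for s in starts:
            walk = [s]
            cur = s
            for _ in range(cfg.walk_length - 1):
                nbr = neighbors[cur]
                cur = int(nbr[rng.integers(nbr.size)])
                walk.append(cur)
            walks.append(walk)
    return walks


def _layer_pairs(walks: list[list[int]], window: int) -> np.ndarray:
    centers, contexts = [], []
    for walk in walks:
        n = len(walk)
        for pos, c in enumerate(walk):
            for other in range(max(0, pos - window), min(n, pos + window + 1)):
                if other != pos:
                    centers.append(c)
                    contexts.append(walk[other])
    if not centers:
        return np.empty((0, 2), dtype=np.int64)
    return np.column_stack([centers, contexts]).astype(np.int64)


class _Trainer:
    """Hand-derived SGD for the skip-gram objective over the forward pass."""

    def __init__(self, graph: AttributedMultiLayerGraph, cfg: GatneConfig,
                 params: GatneParams):
        self.graph = graph
        self.cfg = cfg
        self.params = params
        self.type_rows = [np.flatnonzero(graph.node_type == z) for z in (MIRNA, DISEASE)]

    def batch_step(self, r: int, centers: np.ndarray, contexts: np.ndarray,
                   negatives: np.ndarray, lr: float) -> float:
        g, cfg, p = self.graph, self.cfg, self.params
        n, m = g.n_nodes, g.n_layers
        b = len(centers)
        cache = _edge_level_cache(g, p, cfg)
        top = np.stack([levels[-1] for levels in cache], axis=1)  # (n, m, DE)

        d_b = top[centers]                                   # (b, m, DE)
        pre = np.einsum("ad,bmd->bam", p.W_att[r], d_b)
        t_act = np.tanh(pre)                                 # (b, att, m)
        e = np.einsum("a,bam->bm", p.w_att[r], t_act)
        e = e - e.max(axis=1, keepdims=True)
        ex = np.exp(e)
        a = ex / ex.sum(axis=1, keepdims=True)               # (b, m)
        s = np.einsum("bmd,bm->bd", d_b, a)                  # (b, DE)
        u = p.alpha[r] * (s @ p.M[r])                        # (b, BE)
        x_b = g.X[centers]
        z_b = g.node_type[centers]
        base = np.empty((b, cfg.be))
        attr = np.empty((b, cfg.be))
        for z in (MIRNA, DISEASE):
            rows = z_b == z
            if rows.any():
                base[rows] = x_b[rows] @ p.H_w[z] + p.H_b[z]
                attr[rows] = p.beta[r] * (x_b[rows] @ p.D_feat[z])
        v = attr + base + u                                  # (b, BE)

        targets = np.concatenate([contexts[:, None], negatives], axis=1)
        c_t = p.context[targets]                             # (b, 1+L, BE)
        score = _sigmoid(np.einsum("bd,btd->bt", v, c_t))
        label = np.zeros_like(score)
        label[:, 0] = 1.0
        gsc_raw = score - label                              # dL/dlogit per pair
        # shared dense parameters see the batch-mean gradient; the sparse
        # per-node context rows keep per-pair SGD magnitude (word2vec style)
        gsc = gsc_raw / b
        loss = float(-(np.log(np.maximum(score[:, 0], 1e-12)).sum()
                       + np.log(np.maximum(1 - score[:, 1:], 1e-12)).sum())) / b

        dv = np.einsum("bt,btd->bd", gsc, c_t)               # (b, BE)
        dc = gsc_raw[..., None] * v[:, None, :]
        scatter_add(p.context, targets.ravel(), -lr * dc.reshape(-1, cfg.be))

        # base + attribute transforms
        for z in (MIRNA, DISEASE):
            rows = z_b == z
            if rows.any():
                xz, dvz = x_b[rows], dv[rows]
                p.H_w[z] -= lr * (xz.T @ dvz)
                p.H_b[z] -= lr * dvz.sum(axis=0)
                p.D_feat[z] -= lr * p.beta[r] * (xz.T @ dvz)

        # attention head
        ds = p.alpha[r] * (dv @ p.M[r].T)                    # (b, DE)
        p.M[r] -= lr * p.alpha[r] * (s.T @ dv)
        dd_b = a[:, :, None] * ds[:, None, :]                # via s = sum_m a_m d_m
        da = np.einsum("bmd,bd->bm", d_b, ds)
        de_ = a * (da - (a * da).sum(axis=1, keepdims=True))
        p.w_att[r] -= lr * np.einsum("bam,bm->a", t_act, de_)
        dt = p.w_att[r][None, :, None] * de_[:, None, :]
        dpre = dt * (1.0 - t_act ** 2)
        p.W_att[r] -= lr * np.einsum("bam,bmd->ad", dpre, d_b)
        dd_b += np.einsum("ad,bam->bmd", p.W_att[r], dpre)

        # push gradients back through the per-layer aggregation chains
        d_top = np.zeros((m, n, cfg.de))
        for r2 in range(m):
            scatter_add(d_top[r2], centers, dd_b[:, r2, :])
        for r2 in range(m):
            self._backprop_layer(r2, cache[r2], d_top[r2], lr)
        return loss

    def _backprop_layer(self, r: int, levels: list[np.ndarray],
                        d_out: np.ndarray, lr: float) -> None:
        g, cfg, p = self.graph, self.cfg, self.params
        adj = g.adjacency[r].astype(float)
        deg = adj.sum(axis=1)
        isolated = deg == 0
        p_mat = np.divide(adj, np.maximum(deg, 1.0)[:, None])
        grad = d_out
        for k in range(cfg.depth, 0, -1):
            post = levels[k]
            if cfg.activation == "tanh":
                dpre = grad * (1.0 - post ** 2)
            else:
                dpre = grad.copy()
            dpre[isolated] = 0.0
            if cfg.aggregator == "mean":
                nxt = p_mat.T @ dpre
            else:  # max: route each feature's gradient to the argmax neighbour
                prev = levels[k - 1]
                masked = np.where(adj[:, :, None] > 0, prev[None, :, :], -np.inf)
                arg = masked.argmax(axis=1)                  # (n, DE)
                nxt = np.zeros_like(grad)
                rows = np.flatnonzero(~isolated)
                for d in range(cfg.de):
                    np.add.at(nxt[:, d], arg[rows, d], dpre[rows, d])
            nxt[isolated] += grad[isolated]                  # pass-through
            grad = nxt
        for z in (MIRNA, DISEASE):
            rows = self.type_rows[z]
            gz = grad[rows]
            if gz.size:
                p.G_w[z, r] -= lr * (g.X[rows].T @ gz)
                p.G_b[z, r] -= lr * gz.sum(axis=0)


def train_gatne(
    graph: AttributedMultiLayerGraph,
    cfg: GatneConfig,
    on_epoch_end: Callable[[int, GatneParams, np.ndarray], None] | None = None,
) -> tuple[GatneParams, LayerEmbeddings]:
    """Fit the multiplex embedding by skip-gram with negative sampling.

    ``on_epoch_end(epoch, params, attention)`` receives, after every epoch,
    the (R, n, m) tensor of attention weights over layers for every node and
    target layer.  All randomness flows from ``cfg.seed``.
    """
    if not graph.adjacency.any():
        raise ValueError("cannot train: all layers are empty")
    rng = np.random.default_rng(cfg.seed)
    ne = graph.X.shape[1]
    params = GatneParams.init(ne, graph.n_nodes, graph.n_layers, cfg, rng)

    layer_pairs: dict[int, np.ndarray] = {}
    counts = np.zeros(graph.n_nodes)
    for r in range(graph.n_layers):
        if not graph.adjacency[r].any():
            continue
        walks = _metapath_walks(graph, r, cfg, rng)
        pairs = _layer_pairs(walks, cfg.window)
        if pairs.size:
            layer_pairs[r] = pairs
            np.add.at(counts, np.concatenate([w for w in walks]), 1)
    noise_cdf = []
    for z in (MIRNA, DISEASE):
        c = np.where(graph.node_type == z, counts, 0.0)
        if c.sum() == 0:
            c = (graph.node_type == z).astype(float)
        cdf = np.cumsum(unigram_noise(c))
        cdf[-1] = 1.0
        noise_cdf.append(cdf)

    n_batches_total = cfg.epochs * sum(
        int(np.ceil(len(p_) / cfg.batch_size)) for p_ in layer_pairs.values()
    )
    trainer = _Trainer(graph, cfg, params)
    step = 0
    for epoch in range(cfg.epochs):
        batches: list[tuple[int, np.ndarray]] = []
        for r, pairs in layer_pairs.items():
            order = rng.permutation(len(pairs))
            for start in range(0, len(pairs), cfg.batch_size):
                batches.append((r, pairs[order[start : start + cfg.batch_size]]))
        rng.shuffle(batches)
        for r, chunk in batches:
            lr = max(cfg.min_lr, cfg.lr * (1.0 - step / max(1, n_batches_total)))
            step += 1
            centers, contexts = chunk[:, 0], chunk[:, 1]
            negatives = np.empty((len(chunk), cfg.negatives), dtype=np.int64)
            for z in (MIRNA, DISEASE):
                rows = np.flatnonzero(graph.node_type[contexts] == z)
                if rows.size:
                    negatives[rows] = sample_from_cdf(
                        noise_cdf[z], rng, (rows.size, cfg.negatives)
                    )
            trainer.batch_step(r, centers, contexts, negatives, lr)
        if on_epoch_end is not None:
            cache = _edge_level_cache(graph, params, cfg)
            top = np.stack([levels[-1] for levels in cache], axis=1)
            att = np.stack([attention_weights(params, top, r)
                            for r in range(graph.n_layers)])
            on_epoch_end(epoch, params, att)
    return params, compute_embeddings(graph, params, cfg)
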