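"""Node attribute vectors from similarity networks via biased random walks.

Each node class (miRNAs, diseases) gets its own weighted similarity graph; a
second-order random walk with return parameter p and in-out parameter q
generates a corpus of node sequences, and skip-gram with negative sampling
turns the corpus into one NE-dimensional vector per node.  The walk bias on a
step t -> v -> x multiplies the edge weight w_vx by

    1/p  if x == t            (return)
    1    if x is adjacent to t
    1/q  otherwise            (exploration)

and renormalises.  p=1, q=2 biases the walk toward the local neighbourhood,
matching the assumption that similar nodes share disease associations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from . import sgns
from .similarity import SimilarityMatrix

logger = logging.getLogger(__name__)


@dataclass
class WalkConfig:
    """Random-walk and skip-gram hyperparameters for node features."""

    p: float = 1.0
    q: float = 2.0
    walk_length: int = 80
    walks_per_node: int = 10
    window: int = 5
    dim: int = 128          # NE, the attribute dimension
    epochs: int = 5
    negatives: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.p <= 0 or self.q <= 0:
            raise ValueError("p and q must be positive")
        if self.dim <= 0:
            raise ValueError("embedding dimension must be positive")


@dataclass(frozen=True)
class FeatureTable:
    """One attribute vector x_i per node of one class."""

    labels: tuple[str, ...]
    X: np.ndarray  # (n, NE)

    def __post_init__(self) -> None:
        if self.X.shape[0] != len(self.labels):
            raise ValueError("feature table rows must match labels")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("feature table must be finite")

    def row(self, label: str) -> np.ndarray:
        return self.X[self.labels.index(label)]


def _weights(sim: SimilarityMatrix) -> np.ndarray:
    w = sim.values.copy()
    np.fill_diagonal(w, 0.0)
    return w


def transition_probs(
    weights: np.ndarray,
    t: int | None,
    v: int,
    p: float = 1.0,
    q: float = 2.0,
) -> np.ndarray:
    """Distribution over next nodes from current node v with previous node t.

    ``weights`` is the symmetric non-negative edge-weight matrix with zero
    diagonal.  With t None (first step of a walk) the distribution is plain
    edge-weight proportional.  An isolated v yields the empty (all-zero)
    distribution and the walk terminates.
    """
    w = weights[v].astype(float).copy()
    if t is not None:
        alpha = np.where(weights[t] > 0, 1.0, 1.0 / q)
        alpha[t] = 1.0 / p
        w = w * alpha
    total = w.sum()
    if total == 0:
        return np.zeros_like(w)
    return w / total


def generate_walks(sim: SimilarityMatrix, config: WalkConfig,
                   rng: np.random.Generator | None = None) -> list[list[int]]:
    """Biased second-order walks, ``walks_per_node`` starts per node.

    All walks advance in lock step, so each step draws one vectorised
    categorical sample per active walk.  Walks from isolated nodes terminate
    immediately (length 1).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    weights = _weights(sim)
    n = weights.shape[0]
    if n == 0:
        return []
    adj = weights > 0
    inv_q = 1.0 / config.q
    inv_p = 1.0 / config.p

    starts = np.tile(np.arange(n), config.walks_per_node)
    walks = [[int(s)] for s in starts]
    cur = starts.copy()
    prev = np.full_like(cur, -1)
    active = np.ones(len(cur), dtype=bool)
    for step in range(config.walk_length - 1):
        if not active.any():
            break
        idx = np.flatnonzero(active)
        w = weights[cur[idx]].copy()              # (a, n)
        has_prev = prev[idx] >= 0
        if has_prev.any():
            sub = idx[has_prev]
            alpha = np.where(adj[prev[sub]], 1.0, inv_q)
            alpha[np.arange(len(sub)), prev[sub]] = inv_p
            w[has_prev] *= alpha
        totals = w.sum(axis=1)
        alive = totals > 0
        # isolated current node: walk ends here
        active[idx[~alive]] = False
        if not alive.any():
            continue
        live = idx[alive]
        probs = w[alive] / totals[alive, None]
        u = rng.random(len(live))
        nxt = (probs.cumsum(axis=1) < u[:, None]).sum(axis=1)
        nxt = np.minimum(nxt, weights.shape[0] - 1)
        for wi, node in zip(live, nxt):
            walks[wi].append(int(node))
        prev[live] = cur[live]
        cur[live] = nxt
    return walks


def train_features(
    sim: SimilarityMatrix,
    config: WalkConfig,
    walks: list[list[int]] | None = None,
) -> FeatureTable:
    """Skip-gram features from a walk corpus over one similarity network.

    A node absent from every walk (isolated in the graph) keeps a zero vector
    and is reported with a warning.
    """
    rng = np.random.default_rng(config.seed)
    if walks is None:
        walks = generate_walks(sim, config, rng)
    n = len(sim.labels)
    pairs = sgns.walk_corpus_pairs(walks, config.window, rng)
    counts = np.zeros(n)
    for walk in walks:
        for node in walk:
            counts[node] += 1
    in_pairs = np.zeros(n, dtype=bool)
    if pairs.size:
        in_pairs[np.unique(pairs)] = True
    missing = np.flatnonzero(~in_pairs)
    if missing.size:
        logger.warning(
            "%d nodes without any walk context get zero feature vectors",
            missing.size,
        )
    counts[missing] = 0.0
    noise = sgns.unigram_noise(counts)
    X = sgns.train_sgns(
        pairs, n, config.dim, rng, noise,
        epochs=config.epochs, negatives=config.negatives,
    )
    X[missing] = 0.0
    return FeatureTable(tuple(sim.labels), X)
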