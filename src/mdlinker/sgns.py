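"""Minibatch skip-gram with negative sampling, in plain numpy.

Shared by the node-feature trainer (second-order random walks over similarity
networks) for learning one vector per node from a walk corpus.  Center ("in")
and context ("out") embeddings are separate tables; negatives are drawn from a
unigram distribution raised to the 3/4 power; optimisation is plain SGD with a
linearly decaying learning rate.  Everything is driven by one Generator, so a
fixed seed gives a bit-identical trajectory within one build environment.
"""

from __future__ import annotations

import numpy as np


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -30.0, 30.0)))


try:  # fast row scatter; plain-numpy fallback keeps numba optional
    from numba import njit

    @njit(cache=False)
    def _scatter_rows(out, idx, rows):  # pragma: no cover - jitted
        for i in range(idx.shape[0]):
            k = idx[i]
            for j in range(rows.shape[1]):
                out[k, j] += rows[i, j]

    def scatter_add(out: np.ndarray, idx: np.ndarray, rows: np.ndarray) -> None:
        """``out[idx] += rows`` with repeated indices summed."""
        _scatter_rows(out, np.ascontiguousarray(idx),
                      np.ascontiguousarray(rows))

except ImportError:  # pragma: no cover

    def scatter_add(out: np.ndarray, idx: np.ndarray, rows: np.ndarray) -> None:
        """``out[idx] += rows`` with repeated indices summed (bincount-backed)."""
        n, dim = out.shape
        flat = np.bincount(
            (idx[:, None] * dim + np.arange(dim)).ravel(),
            weights=rows.ravel(),
            minlength=n * dim,
        )
        out += flat.reshape(n, dim)


def sample_from_cdf(cdf: np.ndarray, rng: np.random.Generator,
                    shape: tuple[int, ...]) -> np.ndarray:
    """Categorical sampling via inverse-CDF lookup (fast path for rng.choice)."""
    return np.searchsorted(cdf, rng.random(shape), side="right")


def walk_corpus_pairs(
    walks: list[list[int]], window: int, rng: np.random.Generator
) -> np.ndarray:
    """(center, context) index pairs from a walk corpus with a fixed window."""
    centers: list[int] = []
    contexts: list[int] = []
    for walk in walks:
        n = len(walk)
        for pos, center in enumerate(walk):
            lo = max(0, pos - window)
            hi = min(n, pos + window + 1)
            for other in range(lo, hi):
                if other != pos:
                    centers.append(center)
                    contexts.append(walk[other])
    if not centers:
        return np.empty((0, 2), dtype=np.int64)
    pairs = np.column_stack([np.asarray(centers), np.asarray(contexts)])
    rng.shuffle(pairs, axis=0)
    return pairs


def unigram_noise(counts: np.ndarray, power: float = 0.75) -> np.ndarray:
    """Noise distribution proportional to counts**power (zeros stay zero)."""
    w = np.asarray(counts, dtype=float) ** power
    total = w.sum()
    if total == 0:
        w = np.ones_like(w)
        total = w.sum()
    return w / total


def train_sgns(
    pairs: np.ndarray,
    n_nodes: int,
    dim: int,
    rng: np.random.Generator,
    noise: np.ndarray,
    epochs: int = 5,
    negatives: int = 5,
    lr: float = 0.025,
    min_lr: float = 0.0001,
    batch_size: int | None = None,
) -> np.ndarray:
    """Return the (n_nodes, dim) center-embedding table.

    Gradients within a minibatch are accumulated so that a node appearing
    several times in one batch receives the summed update.  Because the
    accumulated updates are computed against stale embeddings, the batch is
    sized so each node appears only a handful of times per update (else the
    repeated same-direction pushes overshoot and diverge on small graphs).
    """
    if pairs.size == 0:
        return np.zeros((n_nodes, dim))
    if batch_size is None:
        batch_size = int(min(1024, max(64, 8 * n_nodes)))
    w_in = (rng.random((n_nodes, dim)) - 0.5) / dim
    w_out = np.zeros((n_nodes, dim))
    noise_cdf = np.cumsum(noise)
    noise_cdf[-1] = 1.0
    n_batches_total = epochs * int(np.ceil(len(pairs) / batch_size))
    step = 0
    for epoch in range(epochs):
        order = rng.permutation(len(pairs))
        for start in range(0, len(pairs), batch_size):
            idx = order[start : start + batch_size]
            centers = pairs[idx, 0]
            pos = pairs[idx, 1]
            b = len(idx)
            neg = sample_from_cdf(noise_cdf, rng, (b, negatives))
            cur_lr = max(min_lr, lr * (1.0 - step / max(1, n_batches_total)))
            step += 1

            v = w_in[centers]                      # (b, dim)
            targets = np.concatenate(
                [pos[:, None], neg], axis=1        # (b, 1+neg)
            )
            u = w_out[targets]                     # (b, 1+neg, dim)
            score = _sigmoid(np.einsum("bd,btd->bt", v, u))
            label = np.zeros_like(score)
            label[:, 0] = 1.0
            g = score - label                      # (b, 1+neg)
            grad_v = np.einsum("bt,btd->bd", g, u)
            grad_u = g[..., None] * v[:, None, :]
            scatter_add(w_in, centers, -cur_lr * grad_v)
            scatter_add(w_out, targets.ravel(),
                        -cur_lr * grad_u.reshape(-1, dim))
    return w_in
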