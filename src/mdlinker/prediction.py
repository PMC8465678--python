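"""Triple features, distance-filtered negative sampling and classification.

A candidate (miRNA, disease, type) triple is represented by concatenating the
two endpoints' layer-r embeddings, miRNA first.  Because experimentally
confirmed negatives do not exist, reliable negatives are selected per type r
from the unconfirmed triples: compute the mean positive feature f_avg,r, then
the mean Euclidean distance dis_r from f_avg,r to all unconfirmed triples of
type r, and keep only the triples strictly farther than dis_r.  Training uses
equally many sampled negatives as positives per type; scoring uses one shared
random forest over all five types (the type is encoded by the layer-specific
embedding halves).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .amhn import LayerEmbeddings
from .io_formats import ASSOCIATION_TYPES

logger = logging.getLogger(__name__)

Triple = tuple[str, str, str]  # (mirna, disease, type)


def make_triple_features(
    embeddings: LayerEmbeddings, triples: list[Triple]
) -> np.ndarray:
    """(len(triples), 2*BE) matrix of concatenated endpoint embeddings.

    Concatenation order is deterministic: miRNA half first, disease half
    second, both taken from the triple's own layer.
    """
    if not triples:
        return np.empty((0, 2 * embeddings.V.shape[2]))
    node_idx = {label: i for i, label in enumerate(embeddings.labels)}
    layer_idx = {name: r for r, name in enumerate(embeddings.layer_names)}
    try:
        mi = np.array([node_idx[t[0]] for t in triples])
        di = np.array([node_idx[t[1]] for t in triples])
        ri = np.array([layer_idx[t[2]] for t in triples])
    except KeyError as exc:
        raise KeyError(f"missing embedding for {exc.args[0]!r}") from exc
    return np.concatenate([embeddings.V[ri, mi], embeddings.V[ri, di]], axis=1)


@dataclass
class NegativePool:
    """Distance-filtered reliable-negative candidates for one type r."""

    type_label: str
    f_avg: np.ndarray          # mean positive feature of type r
    threshold: float           # dis_r: mean distance over unconfirmed triples
    triples: list[Triple]      # eligible candidates (distance > threshold)
    distances: np.ndarray      # distance of each eligible candidate


def build_negative_pool(
    positive_features: np.ndarray,
    unconfirmed_triples: list[Triple],
    unconfirmed_features: np.ndarray,
    type_label: str,
) -> NegativePool:
    """Keep unconfirmed triples strictly farther from f_avg,r than the mean.

    ``positive_features`` are the training positives of type r;
    ``unconfirmed_triples``/``features`` are the unconfirmed or non-existent
    triples of type r (never overlapping the positives, by construction of
    the candidate universe).
    """
    if len(positive_features) == 0:
        raise ValueError(f"no training positives of type {type_label!r}")
    f_avg = positive_features.mean(axis=0)
    if len(unconfirmed_triples) == 0:
        logger.warning("no unconfirmed triples of type %r: empty pool", type_label)
        return NegativePool(type_label, f_avg, 0.0, [], np.empty(0))
    d = np.linalg.norm(unconfirmed_features - f_avg, axis=1)
    thr = float(d.mean())
    keep = d > thr
    return NegativePool(
        type_label,
        f_avg,
        thr,
        [t for t, k in zip(unconfirmed_triples, keep) if k],
        d[keep],
    )


def sample_negatives(
    pool: NegativePool, n_pos: int, rng: np.random.Generator
) -> list[Triple]:
    """Uniformly sample ``n_pos`` negatives without replacement (all, if fewer)."""
    if not pool.triples:
        raise ValueError(f"empty negative pool for type {pool.type_label!r}")
    if len(pool.triples) < n_pos:
        logger.warning(
            "negative pool for %r has %d < %d candidates; taking all",
            pool.type_label, len(pool.triples), n_pos,
        )
        return list(pool.triples)
    idx = rng.choice(len(pool.triples), size=n_pos, replace=False)
    return [pool.triples[i] for i in sorted(idx)]


def train_classifier(
    X: np.ndarray,
    y: np.ndarray,
    seed: int,
    n_estimators: int = 200,
) -> RandomForestClassifier:
    """Bagged decision-tree ensemble on the concatenated-embedding features."""
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("training data must contain both classes")
    clf = RandomForestClassifier(
        n_estimators=n_estimators,
        max_features="sqrt",
        random_state=int(seed),
        n_jobs=1,
    )
    clf.fit(X, y)
    return clf


def score_triples(
    clf: RandomForestClassifier,
    embeddings: LayerEmbeddings,
    triples: list[Triple],
) -> np.ndarray:
    """Class-1 probability for each triple."""
    if not triples:
        return np.empty(0)
    X = make_triple_features(embeddings, triples)
    pos_col = int(np.flatnonzero(clf.classes_ == 1)[0])
    return clf.predict_proba(X)[:, pos_col]


def score_all(
    clf: RandomForestClassifier,
    embeddings: LayerEmbeddings,
    pairs: list[tuple[str, str]],
) -> pd.DataFrame:
    """Score every (pair, type) combination: |pairs| x 5 rows."""
    triples = [
        (m, d, t) for (m, d) in pairs for t in ASSOCIATION_TYPES
    ]
    scores = score_triples(clf, embeddings, triples)
    return pd.DataFrame(
        {
            "mirna": [t[0] for t in triples],
            "disease": [t[1] for t in triples],
            "type": [t[2] for t in triples],
            "score": scores,
        }
    )


def candidate_universe(
    mirnas: list[str],
    diseases: list[str],
    confirmed: set[Triple],
    exclude: set[Triple] | None = None,
) -> list[Triple]:
    """All unconfirmed (miRNA, disease, type) triples over the node sets.

    ``exclude`` removes further triples (e.g. every triple of a held-out pair)
    from the universe so they can never be drawn as training negatives.
    """
    exclude = exclude or set()
    return [
        (m, d, t)
        for m in mirnas
        for d in diseases
        for t in ASSOCIATION_TYPES
        if (m, d, t) not in confirmed and (m, d, t) not in exclude
    ]
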