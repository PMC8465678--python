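"""End-to-end glue: similarities -> node features -> multiplex embedding ->
negative sampling -> random forest.

The evaluation protocols and the CLI drive the pipeline through two entry
points: :func:`compute_features` (fold-independent, derived from the
similarity networks only) and :func:`fit_predictor` (per training split,
because the multiplex embedding and the negative pools must be retrained on
training edges only to avoid leakage).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from . import prediction
from .amhn import (
    AttributedMultiLayerGraph,
    GatneConfig,
    LayerEmbeddings,
    build_amhn,
    train_gatne,
)
from .io_formats import ASSOCIATION_TYPES, AssociationRecord, Dataset
from .node_features import FeatureTable, WalkConfig, train_features
from .prediction import NegativePool, Triple
from .similarity import (
    DEFAULT_ALPHA,
    DEFAULT_CGR_RESOLUTION,
    build_dag,
    cgr_profile,
    disease_similarity_matrix,
    mirna_similarity,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything tunable, with the defaults used throughout the study."""

    alpha: float = DEFAULT_ALPHA              # DAG semantic decay
    cgr_resolution: int = DEFAULT_CGR_RESOLUTION
    walk: WalkConfig = field(default_factory=WalkConfig)
    gatne: GatneConfig = field(default_factory=GatneConfig)
    rf_trees: int = 200
    per_type_classifier: bool = False
    n_folds: int = 10


def derive_seeds(master_seed: int, n: int) -> list[int]:
    """Independent child seeds, reproducibly derived from one master seed."""
    rng = np.random.default_rng(master_seed)
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]


def compute_features(
    dataset: Dataset, cfg: PipelineConfig, seed: int
) -> tuple[FeatureTable, FeatureTable]:
    """Similarity networks -> biased-walk skip-gram attribute vectors.

    These depend only on the sequences and the disease hierarchy, never on
    the association labels, so they are computed once per dataset and shared
    across cross-validation folds.
    """
    seeds = derive_seeds(seed, 2)
    dag = build_dag(dataset.mesh, alpha=cfg.alpha)
    d_sim = disease_similarity_matrix(dag, dataset.diseases)
    profiles = [cgr_profile(s, cfg.cgr_resolution) for s in dataset.sequences]
    m_sim = mirna_similarity(profiles)
    mf = train_features(m_sim, replace(cfg.walk, seed=seeds[0]))
    df = train_features(d_sim, replace(cfg.walk, seed=seeds[1]))
    return mf, df


@dataclass
class FittedModel:
    """A trained fold/run: embeddings, classifier(s) and negative bookkeeping."""

    graph: AttributedMultiLayerGraph
    embeddings: LayerEmbeddings
    classifiers: dict[str, object]     # "shared" -> clf, or one per type
    pools: dict[str, NegativePool]
    train_negatives: list[Triple]
    per_type: bool

    def score(self, triples: list[Triple]) -> np.ndarray:
        if not self.per_type:
            return prediction.score_triples(
                self.classifiers["shared"], self.embeddings, triples
            )
        scores = np.zeros(len(triples))
        by_type: dict[str, list[int]] = {}
        for i, t in enumerate(triples):
            by_type.setdefault(t[2], []).append(i)
        for type_label, idx in by_type.items():
            clf = self.classifiers.get(type_label)
            if clf is None:
                continue
            sub = [triples[i] for i in idx]
            scores[np.array(idx)] = prediction.score_triples(
                clf, self.embeddings, sub
            )
        return scores


def fit_predictor(
    train_triples: list[Triple],
    mirnas: list[str],
    diseases: list[str],
    mirna_features: FeatureTable,
    disease_features: FeatureTable,
    cfg: PipelineConfig,
    seed: int,
    universe_exclude: set[Triple] | None = None,
    confirmed: set[Triple] | None = None,
) -> FittedModel:
    """Train the multiplex embedding and classifier on one training split.

    ``confirmed`` is the full set of confirmed triples used to define the
    unconfirmed candidate universe (defaults to the training triples);
    ``universe_exclude`` removes additional triples (e.g. all triples of
    held-out pairs) so they can never become training negatives.
    """
    seeds = derive_seeds(seed, 3)
    records = [AssociationRecord(m, d, t) for m, d, t in train_triples]
    graph = build_amhn(records, mirna_features, disease_features)
    _, embeddings = train_gatne(graph, replace(cfg.gatne, seed=seeds[0]))

    confirmed = set(confirmed) if confirmed is not None else set(train_triples)
    universe = prediction.candidate_universe(
        mirnas, diseases, confirmed, universe_exclude
    )
    rng = np.random.default_rng(seeds[1])
    pools: dict[str, NegativePool] = {}
    pos_by_type: dict[str, list[Triple]] = {}
    for t in train_triples:
        pos_by_type.setdefault(t[2], []).append(t)
    unc_by_type: dict[str, list[Triple]] = {t: [] for t in ASSOCIATION_TYPES}
    for u in universe:
        unc_by_type[u[2]].append(u)

    negatives: list[Triple] = []
    train_x: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for type_label in ASSOCIATION_TYPES:
        pos = pos_by_type.get(type_label)
        if not pos:
            logger.warning("no training positives of type %r", type_label)
            continue
        pos_x = prediction.make_triple_features(embeddings, pos)
        unc = unc_by_type[type_label]
        unc_x = prediction.make_triple_features(embeddings, unc)
        pool = prediction.build_negative_pool(pos_x, unc, unc_x, type_label)
        pools[type_label] = pool
        neg = prediction.sample_negatives(pool, len(pos), rng)
        negatives.extend(neg)
        neg_x = prediction.make_triple_features(embeddings, neg)
        train_x[type_label] = (pos_x, neg_x)

    if not train_x:
        raise ValueError("no association type has training positives")

    classifiers: dict[str, object] = {}
    if cfg.per_type_classifier:
        for k, (type_label, (pos_x, neg_x)) in enumerate(train_x.items()):
            X = np.vstack([pos_x, neg_x])
            y = np.concatenate([np.ones(len(pos_x)), np.zeros(len(neg_x))])
            classifiers[type_label] = prediction.train_classifier(
                X, y, seed=seeds[2] + k, n_estimators=cfg.rf_trees
            )
    else:
        X = np.vstack([x for px, nx in train_x.values() for x in (px, nx)])
        y = np.concatenate(
            [np.concatenate([np.ones(len(px)), np.zeros(len(nx))])
             for px, nx in train_x.values()]
        )
        classifiers["shared"] = prediction.train_classifier(
            X, y, seed=seeds[2], n_estimators=cfg.rf_trees
        )
    return FittedModel(
        graph, embeddings, classifiers, pools, negatives, cfg.per_type_classifier
    )


def run_pipeline(
    dataset: Dataset, cfg: PipelineConfig, seed: int
) -> FittedModel:
    """Fit on the full dataset (no held-out split); used for real prediction."""
    mf, df = compute_features(dataset, cfg, seed)
    triples = [r.triple for r in dataset.associations]
    return fit_predictor(
        triples, dataset.mirnas, dataset.diseases, mf, df, cfg,
        seed=derive_seeds(seed, 3)[2],
    )
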