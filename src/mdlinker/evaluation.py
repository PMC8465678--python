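"""Cross-validation protocols and consensus ranking.

Two 10-fold protocols judge the predictor:

* CV-Type folds over confirmed miRNA-disease *pairs*.  All five type scores
  of each held-out pair are ranked; a hit means the top-ranked type is one of
  the pair's true types.  Top-1 precision is hits per test pair, top-1 recall
  is hits per true test triple (a pair with several true types can contribute
  at most one hit), and F1 is their harmonic mean.
* CV-Triple folds over confirmed *triples*.  Held-out positives are scored
  against equally many held-out negatives drawn from the distance-filtered
  pool, and AUPR, ROC-AUC and F1 (at probability threshold 0.5) are reported.

Embedding features from the similarity networks are fold-independent; the
multiplex embedding and the negative pools are retrained per fold on training
information only, so no test triple ever leaks into training.

Consensus ranking repeats the full stochastic pipeline n_runs times with
distinct seeds and ranks unknown triples by how often they appear among a
run's top predictions (ties broken by mean probability).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, f1_score, roc_auc_score

from .io_formats import ASSOCIATION_TYPES
from .node_features import FeatureTable
from .pipeline import PipelineConfig, derive_seeds, fit_predictor
from .prediction import Triple, candidate_universe

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# metrics

def auc_score(y_true: np.ndarray, scores: np.ndarray) -> float:
    """Tie-aware ROC-AUC (Mann-Whitney rank statistic)."""
    return float(roc_auc_score(y_true, scores))


def aupr_score(y_true: np.ndarray, scores: np.ndarray) -> float:
    """Area under the precision-recall curve by step integration."""
    return float(average_precision_score(y_true, scores))


def f1_at_threshold(y_true: np.ndarray, scores: np.ndarray,
                    threshold: float = 0.5) -> float:
    """F1 of the hard labelling score >= threshold."""
    return float(f1_score(y_true, (scores >= threshold).astype(int),
                          zero_division=0.0))


def top1_metrics(
    pair_scores: dict[tuple[str, str], np.ndarray],
    true_types: dict[tuple[str, str], set[str]],
) -> tuple[float, float, float]:
    """Top-1 precision / recall / F1 over a set of test pairs.

    ``pair_scores[pair]`` holds the five type scores in canonical type order;
    ties are broken by that fixed order (first maximum wins).
    """
    if not pair_scores:
        raise ValueError("no test pairs")
    hits = 0
    n_true = 0
    for pair, scores in pair_scores.items():
        top = ASSOCIATION_TYPES[int(np.argmax(scores))]
        truth = true_types[pair]
        n_true += len(truth)
        if top in truth:
            hits += 1
    precision = hits / len(pair_scores)
    recall = hits / n_true if n_true else 0.0
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall > 0 else 0.0)
    return precision, recall, f1


@dataclass
class MetricsReport:
    """Per-fold metric values plus their means for one protocol."""

    protocol: str
    per_fold: list[dict[str, float]] = field(default_factory=list)

    @property
    def mean(self) -> dict[str, float]:
        if not self.per_fold:
            return {}
        keys = self.per_fold[0].keys()
        return {k: float(np.mean([f[k] for f in self.per_fold])) for k in keys}

    def to_json(self) -> str:
        return json.dumps(
            {"protocol": self.protocol, "per_fold": self.per_fold,
             "mean": self.mean},
            indent=2,
        )


def assign_folds(n_units: int, n_folds: int, rng: np.random.Generator) -> np.ndarray:
    """Random partition into folds whose sizes differ by at most one."""
    if n_units < n_folds:
        raise ValueError(f"need at least {n_folds} units, got {n_units}")
    folds = np.arange(n_units) % n_folds
    rng.shuffle(folds)
    return folds


# ---------------------------------------------------------------------------
# protocols

def cv_type(
    triples: list[Triple],
    mirnas: list[str],
    diseases: list[str],
    mirna_features: FeatureTable,
    disease_features: FeatureTable,
    cfg: PipelineConfig,
    seed: int,
) -> MetricsReport:
    """10-fold cross-validation over confirmed pairs, judged by the top type."""
    pairs = sorted({(m, d) for m, d, _ in triples})
    true_types: dict[tuple[str, str], set[str]] = {}
    for m, d, t in triples:
        true_types.setdefault((m, d), set()).add(t)
    seeds = derive_seeds(seed, cfg.n_folds + 1)
    folds = assign_folds(len(pairs), cfg.n_folds,
                         np.random.default_rng(seeds[-1]))
    report = MetricsReport("cv-type")
    for k in range(cfg.n_folds):
        test_pairs = [p for p, f in zip(pairs, folds) if f == k]
        test_pair_set = set(test_pairs)
        train = [t for t in triples if (t[0], t[1]) not in test_pair_set]
        # no triple of a test pair may be a training positive or negative
        exclude = {
            (m, d, t) for (m, d) in test_pairs for t in ASSOCIATION_TYPES
        }
        model = fit_predictor(
            train, mirnas, diseases, mirna_features, disease_features,
            cfg, seed=seeds[k], universe_exclude=exclude,
        )
        query = [(m, d, t) for (m, d) in test_pairs for t in ASSOCIATION_TYPES]
        scores = model.score(query)
        pair_scores = {
            pair: scores[i * len(ASSOCIATION_TYPES):(i + 1) * len(ASSOCIATION_TYPES)]
            for i, pair in enumerate(test_pairs)
        }
        p, r, f1 = top1_metrics(pair_scores,
                                {p_: true_types[p_] for p_ in test_pairs})
        report.per_fold.append(
            {"top1_precision": p, "top1_recall": r, "top1_f1": f1}
        )
    return report


def cv_triple(
    triples: list[Triple],
    mirnas: list[str],
    diseases: list[str],
    mirna_features: FeatureTable,
    disease_features: FeatureTable,
    cfg: PipelineConfig,
    seed: int,
) -> MetricsReport:
    """10-fold cross-validation over confirmed triples (AUPR / AUC / F1)."""
    triples = sorted(set(triples))
    confirmed = set(triples)
    seeds = derive_seeds(seed, cfg.n_folds + 1)
    folds = assign_folds(len(triples), cfg.n_folds,
                         np.random.default_rng(seeds[-1]))
    report = MetricsReport("cv-triple")
    for k in range(cfg.n_folds):
        test_pos = [t for t, f in zip(triples, folds) if f == k]
        train = [t for t, f in zip(triples, folds) if f != k]
        model = fit_predictor(
            train, mirnas, diseases, mirna_features, disease_features,
            cfg, seed=seeds[k], confirmed=confirmed,
        )
        # held-out negatives: from the pool, never overlapping train negatives
        rng = np.random.default_rng(seeds[k] + 1)
        taken = set(model.train_negatives)
        test_neg: list[Triple] = []
        for type_label in ASSOCIATION_TYPES:
            n_t = sum(1 for t in test_pos if t[2] == type_label)
            if n_t == 0:
                continue
            pool = model.pools.get(type_label)
            if pool is None:
                continue
            avail = [t for t in pool.triples if t not in taken]
            if len(avail) < n_t:
                logger.warning(
                    "pool for %r has only %d held-out candidates (< %d)",
                    type_label, len(avail), n_t,
                )
                test_neg.extend(avail)
            else:
                idx = rng.choice(len(avail), size=n_t, replace=False)
                test_neg.extend(avail[i] for i in sorted(idx))
        query = test_pos + test_neg
        y = np.concatenate([np.ones(len(test_pos)), np.zeros(len(test_neg))])
        scores = model.score(query)
        report.per_fold.append(
            {
                "aupr": aupr_score(y, scores),
                "auc": auc_score(y, scores),
                "f1": f1_at_threshold(y, scores),
            }
        )
    return report


def consensus_rank(
    triples: list[Triple],
    mirnas: list[str],
    diseases: list[str],
    mirna_features: FeatureTable,
    disease_features: FeatureTable,
    cfg: PipelineConfig,
    seed: int,
    n_runs: int = 50,
    k: int = 20,
) -> pd.DataFrame:
    """Frequency-consensus top-k unknown triples over repeated runs.

    Each run retrains the stochastic pipeline with its own seed, scores the
    whole unknown candidate universe and contributes its top 2k triples; the
    final ranking orders triples by appearance frequency across runs, ties by
    mean predicted probability, then lexicographically.
    """
    confirmed = set(triples)
    universe = candidate_universe(mirnas, diseases, confirmed)
    seeds = derive_seeds(seed, n_runs)
    counts: dict[Triple, int] = {}
    score_sums: dict[Triple, float] = {}
    for run_seed in seeds:
        model = fit_predictor(
            triples, mirnas, diseases, mirna_features, disease_features,
            cfg, seed=run_seed,
        )
        scores = model.score(universe)
        top_idx = np.argsort(-scores, kind="stable")[: 2 * k]
        for i in top_idx:
            t = universe[i]
            counts[t] = counts.get(t, 0) + 1
            score_sums[t] = score_sums.get(t, 0.0) + float(scores[i])
    rows = [
        {
            "mirna": t[0], "disease": t[1], "type": t[2],
            "frequency": c, "mean_score": score_sums[t] / c,
        }
        for t, c in counts.items()
    ]
    out = pd.DataFrame(rows).sort_values(
        by=["frequency", "mean_score", "mirna", "disease", "type"],
        ascending=[False, False, True, True, True],
        kind="stable",
    )
    return out.head(k).reset_index(drop=True)
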