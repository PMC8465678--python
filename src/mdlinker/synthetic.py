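"""Seeded synthetic fixtures: toy disease trees, RNA sequences and planted
multi-layer association networks.

The planted model matches miRNA blocks to disease blocks 1:1 and samples
association triples within matched blocks at a high rate and across blocks at
a low rate, independently per evidence type; with probability
``type_correlation`` an associated pair gains one additional type, emulating
the empirical observation that many pairs carry several evidence types.
Disease blocks live in separate subtrees of the generated hierarchy and miRNA
blocks descend from per-block ancestor sequences, so both similarity networks
carry the same planted structure and the full pipeline has a recoverable
signal.  Every generator is a pure function of its seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import (
    ASSOCIATION_TYPES,
    AssociationRecord,
    Dataset,
    MeshEntry,
    SequenceRecord,
    intersect_inputs,
)

_NUCLEOTIDES = np.array(list("ACGU"))


@dataclass
class PlantedConfig:
    """Study conditions for the planted multi-layer benchmark."""

    n_mirna: int = 60
    n_disease: int = 40
    n_types: int = 5
    n_blocks: int = 3
    within_block_edge_prob: float = 0.3
    cross_block_edge_prob: float = 0.02
    #: probability that an associated pair gains one additional evidence type
    type_correlation: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.within_block_edge_prob > self.cross_block_edge_prob:
            raise ValueError(
                "within_block_edge_prob must exceed cross_block_edge_prob"
            )
        if self.n_types < 1 or self.n_types > len(ASSOCIATION_TYPES):
            raise ValueError("n_types must be between 1 and 5")


def _block_of(i: int, n: int, n_blocks: int) -> int:
    """Contiguous block assignment of item i among n items."""
    return min(i * n_blocks // n, n_blocks - 1)


def gen_mesh_tree(
    n_diseases: int, depth: int, branching: int, seed: int
) -> list[MeshEntry]:
    """A random prefix hierarchy with ``n_diseases`` named positions.

    The full ``branching``-ary tree of the given depth is generated under a
    single root code; a seeded random subset of its positions receives disease
    names (one code each).
    """
    codes = ["C01"]
    frontier = ["C01"]
    for _ in range(depth):
        frontier = [f"{c}.{b + 1}" for c in frontier for b in range(branching)]
        codes.extend(frontier)
    if n_diseases > len(codes):
        raise ValueError(
            f"tree has {len(codes)} positions < {n_diseases} diseases"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(codes), size=n_diseases, replace=False)
    return [
        MeshEntry(f"disease-{k:03d}", (codes[int(c)],))
        for k, c in enumerate(sorted(chosen))
    ]


def gen_block_mesh(n_diseases: int, n_blocks: int, seed: int) -> list[MeshEntry]:
    """One subtree per block: diseases of a block share a block-level parent."""
    del seed  # layout is deterministic; kept for interface uniformity
    entries = []
    for i in range(n_diseases):
        b = _block_of(i, n_diseases, n_blocks)
        entries.append(
            MeshEntry(f"disease-{i:03d}", (f"C01.{b + 1}.{i + 1}",))
        )
    return entries


def gen_sequences(
    n: int,
    length_range: tuple[int, int],
    block_assignments: list[int],
    mutation_rate: float,
    seed: int,
) -> list[SequenceRecord]:
    """Per-block ancestor sequences with point-mutated copies.

    Each block gets one uniform-random ancestor whose length is drawn from
    ``length_range``; each member copies its block's ancestor and mutates each
    position, with probability ``mutation_rate``, to a different nucleotide.
    """
    if not 0.0 <= mutation_rate <= 1.0:
        raise ValueError("mutation_rate must be in [0, 1]")
    if len(block_assignments) != n:
        raise ValueError("need one block assignment per sequence")
    rng = np.random.default_rng(seed)
    lo, hi = length_range
    ancestors: dict[int, np.ndarray] = {}
    for b in sorted(set(block_assignments)):
        length = int(rng.integers(lo, hi + 1))
        ancestors[b] = rng.choice(4, size=length)
    records = []
    for i, b in enumerate(block_assignments):
        seq = ancestors[b].copy()
        mutate = rng.random(seq.size) < mutation_rate
        # a mutation always changes the nucleotide (shift by 1..3 mod 4)
        seq[mutate] = (seq[mutate] + rng.integers(1, 4, mutate.sum())) % 4
        records.append(
            SequenceRecord(f"mir-{i:03d}", "".join(_NUCLEOTIDES[seq]))
        )
    return records


def gen_planted_amhn(
    config: PlantedConfig,
) -> tuple[list[AssociationRecord], dict[str, int]]:
    """Sample association triples with planted block structure.

    Returns the records and the ground-truth block label of every node name.
    """
    rng = np.random.default_rng(config.seed)
    types = ASSOCIATION_TYPES[: config.n_types]
    labels: dict[str, int] = {}
    for i in range(config.n_mirna):
        labels[f"mir-{i:03d}"] = _block_of(i, config.n_mirna, config.n_blocks)
    for j in range(config.n_disease):
        labels[f"disease-{j:03d}"] = _block_of(
            j, config.n_disease, config.n_blocks
        )
    records: list[AssociationRecord] = []
    for i in range(config.n_mirna):
        m = f"mir-{i:03d}"
        for j in range(config.n_disease):
            d = f"disease-{j:03d}"
            p = (
                config.within_block_edge_prob
                if labels[m] == labels[d]
                else config.cross_block_edge_prob
            )
            has = rng.random(len(types)) < p
            pair_types = [t for t, h in zip(types, has) if h]
            if (
                pair_types
                and len(pair_types) < len(types)
                and rng.random() < config.type_correlation
            ):
                missing = [t for t in types if t not in pair_types]
                pair_types.append(missing[int(rng.integers(len(missing)))])
            for t in pair_types:
                records.append(AssociationRecord(m, d, t))
    return records, labels


def bayes_optimal_auc(
    config: PlantedConfig,
    within_negative_fraction: float,
    holdout: float = 0.1,
    n_pair_sim: int = 200_000,
    seed: int = 0,
) -> float:
    """Information ceiling of the triple-holdout protocol on this generator.

    Scores every candidate triple by its exact posterior probability of being
    true given everything a leakage-free model may observe — the endpoint
    blocks and the pair's visible (non-held-out) types — and returns the
    ROC-AUC of held-out positives against negatives drawn with the given
    fraction of within-matched-block candidates.  No learned model can exceed
    this in expectation, so it quantifies how much signal the benchmark
    plants.
    """
    rng = np.random.default_rng(seed)
    n_types = config.n_types

    def draw_types(p: float) -> set[int]:
        base = set(np.flatnonzero(rng.random(n_types) < p))
        if 1 <= len(base) < n_types and rng.random() < config.type_correlation:
            missing = [t for t in range(n_types) if t not in base]
            base.add(missing[int(rng.integers(len(missing)))])
        return base

    # posterior P(type true | block match, #visible sibling types) by MC
    num: dict[tuple[int, int], float] = {}
    den: dict[tuple[int, int], float] = {}
    samples: dict[tuple[int, int], list[tuple[float, bool]]] = {}
    for _ in range(n_pair_sim):
        for blk, p in ((1, config.within_block_edge_prob),
                       (0, config.cross_block_edge_prob)):
            types = draw_types(p)
            held = {t for t in types if rng.random() < holdout}
            k = len(types - held)
            for t in range(n_types):
                if t in types - held:
                    continue
                key = (blk, k)
                den[key] = den.get(key, 0.0) + 1
                if t in types:
                    num[key] = num.get(key, 0.0) + 1
                samples.setdefault(key, []).append(
                    (0.0, t in held)  # score filled in below
                )
    post = {key: num.get(key, 0.0) / den[key] for key in den}
    pos_scores, neg_within, neg_cross = [], [], []
    for (blk, k), items in samples.items():
        s = post[(blk, k)]
        for _, held_out_true in items:
            if held_out_true:
                pos_scores.append(s)
            elif blk == 1:
                neg_within.append(s)
            else:
                neg_cross.append(s)
    n = len(pos_scores)
    k_within = int(within_negative_fraction * n)
    neg = list(rng.choice(neg_within, size=k_within)) + list(
        rng.choice(neg_cross, size=n - k_within)
    )
    from sklearn.metrics import roc_auc_score

    y = np.r_[np.ones(n), np.zeros(n)]
    return float(roc_auc_score(y, np.r_[pos_scores, neg]))


def planted_dataset(
    config: PlantedConfig,
    mutation_rate: float = 0.05,
    length_range: tuple[int, int] = (60, 110),
) -> tuple[Dataset, dict[str, int]]:
    """Full synthetic inputs (associations, hierarchy, sequences), intersected."""
    records, labels = gen_planted_amhn(config)
    mesh = gen_block_mesh(config.n_disease, config.n_blocks, config.seed)
    blocks = [
        _block_of(i, config.n_mirna, config.n_blocks)
        for i in range(config.n_mirna)
    ]
    seqs = gen_sequences(
        config.n_mirna, length_range, blocks, mutation_rate, config.seed + 1
    )
    return intersect_inputs(records, mesh, seqs), labels
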