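"""Disease-disease semantic similarity and miRNA-miRNA sequence similarity.

Disease similarity follows the classic DAG-decay scheme of Wang et al.: a
disease hierarchy given as dot-separated tree codes induces a directed acyclic
graph (child -> parent by truncating the last code segment).  Each disease P
contributes semantic value 1 to itself and alpha^depth (through a max over
children, so multiple placements take the best chain) to each ancestor; the
similarity of P and Q is the shared semantic mass normalised by the total:

    sim(P, Q) = sum_{t in N_P ^ N_Q} (D_P(t) + D_Q(t)) / (DV(P) + DV(Q))

miRNA similarity uses a chaos-game representation (CGR) of the precursor
sequence: the sequence is mapped into the unit square by iterated midpoint
jumps toward the corner of each nucleotide, the square is divided into
2^k x 2^k subregions, and the similarity of two miRNAs is the min-max-inverted
Euclidean (Frobenius) region distance between their visit-frequency matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_formats import MeshEntry, SequenceRecord

DEFAULT_ALPHA = 0.5  # ancestor semantic-contribution decay per generation
DEFAULT_CGR_RESOLUTION = 3  # 2^3 x 2^3 = 64 subregions

#: CGR corner assignment on the unit square.
CGR_CORNERS = {
    "A": (0.0, 0.0),
    "C": (0.0, 1.0),
    "G": (1.0, 1.0),
    "U": (1.0, 0.0),
}


def _prefixes(code: str) -> list[str]:
    """All dot-prefixes of a tree code, most specific first."""
    parts = code.split(".")
    return [".".join(parts[: i + 1]) for i in range(len(parts) - 1, -1, -1)]


@dataclass
class DiseaseDAG:
    """Ancestor closure of a disease hierarchy given as tree codes.

    DAG nodes are named diseases where a tree position carries a name in the
    input, and anonymous tree positions otherwise.  Multiple tree codes of the
    same disease collapse onto one named node; the per-ancestor semantic value
    D_P(t) then takes the best (max) chain, which is exactly what the
    max-over-children recursion realises.
    """

    alpha: float = DEFAULT_ALPHA
    #: disease name -> tuple of tree codes
    codes: dict[str, tuple[str, ...]] = field(default_factory=dict)
    #: tree code -> node id (a disease name, or the code itself if anonymous)
    _node_of_code: dict[str, str] = field(default_factory=dict)

    @property
    def diseases(self) -> list[str]:
        return sorted(self.codes)

    def __contains__(self, disease: str) -> bool:
        return disease in self.codes

    def ancestors(self, disease: str) -> set[str]:
        """N_P: the disease itself plus all its ancestors, as node ids."""
        return set(self.semantic_values(disease))

    def semantic_values(self, disease: str) -> dict[str, float]:
        """D_P(t) for every t in N_P.

        The disease's own positions score 1; every other position in the
        prefix closure scores alpha times the max over its child positions.
        Positions are then collapsed to node ids by max.
        """
        if disease not in self.codes:
            raise KeyError(f"disease {disease!r} not in DAG")
        own = set(self.codes[disease])
        # value per tree position, computed from most specific outward
        pos_val: dict[str, float] = {}
        # collect the full prefix closure, then process by decreasing depth
        closure: set[str] = set()
        for code in own:
            closure.update(_prefixes(code))
        for code in sorted(closure, key=lambda c: -c.count(".")):
            if code in own:
                pos_val[code] = 1.0
                continue
            children = [c for c in closure if c.rsplit(".", 1)[0] == code and "." in c]
            assert children, "non-own position in closure must have a child"
            pos_val[code] = self.alpha * max(pos_val[c] for c in children)
        values: dict[str, float] = {}
        for code, v in pos_val.items():
            node = self._node_of_code.get(code, code)
            values[node] = max(values.get(node, 0.0), v)
        # the disease node itself is always exactly 1
        values[disease] = 1.0
        return values

    def semantic_value_sum(self, disease: str) -> float:
        """DV(P): total semantic mass of P's ancestor closure."""
        return float(sum(self.semantic_values(disease).values()))


def build_dag(entries: list[MeshEntry], alpha: float = DEFAULT_ALPHA) -> DiseaseDAG:
    """Build the ancestor-closure DAG from (disease, tree codes) entries."""
    dag = DiseaseDAG(alpha=alpha)
    for e in entries:
        dag.codes[e.disease_name] = tuple(e.tree_codes)
        for code in e.tree_codes:
            dag._node_of_code[code] = e.disease_name
    return dag


def disease_similarity(dag: DiseaseDAG, p: str, q: str) -> float:
    """Semantic similarity of two diseases; 0 when their closures are disjoint."""
    dp = dag.semantic_values(p)
    dq = dag.semantic_values(q)
    shared = set(dp) & set(dq)
    if not shared:
        return 0.0
    num = sum(dp[t] + dq[t] for t in shared)
    return float(num / (sum(dp.values()) + sum(dq.values())))


@dataclass(frozen=True)
class SimilarityMatrix:
    """Symmetric similarity over one node class, unit diagonal, entries in [0,1]."""

    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = self.values
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("similarity matrix shape does not match labels")
        if not np.allclose(v, v.T):
            raise ValueError("similarity matrix must be symmetric")
        if not np.allclose(np.diag(v), 1.0):
            raise ValueError("similarity matrix must have unit diagonal")
        if v.min() < -1e-12 or v.max() > 1 + 1e-12:
            raise ValueError("similarity entries must lie in [0, 1]")

    def loc(self, a: str, b: str) -> float:
        i = self.labels.index(a)
        j = self.labels.index(b)
        return float(self.values[i, j])


def disease_similarity_matrix(dag: DiseaseDAG, diseases: list[str] | None = None) -> SimilarityMatrix:
    names = sorted(diseases) if diseases is not None else dag.diseases
    tables = {d: dag.semantic_values(d) for d in names}
    dv = {d: sum(t.values()) for d, t in tables.items()}
    n = len(names)
    values = np.eye(n)
    for i in range(n):
        ti = tables[names[i]]
        for j in range(i + 1, n):
            tj = tables[names[j]]
            shared = set(ti) & set(tj)
            if shared:
                num = sum(ti[t] + tj[t] for t in shared)
                values[i, j] = values[j, i] = num / (dv[names[i]] + dv[names[j]])
    return SimilarityMatrix(tuple(names), values)


@dataclass(frozen=True)
class CGRProfile:
    """Normalized subregion visit frequencies of one sequence's chaos game."""

    mirna_name: str
    resolution: int
    freq: np.ndarray  # (2^k, 2^k), entries >= 0, summing to 1


def cgr_profile(seq: SequenceRecord, k: int = DEFAULT_CGR_RESOLUTION) -> CGRProfile:
    """Chaos-game representation at resolution k.

    Starting from the square's centre, each nucleotide moves the point halfway
    toward its corner; the frequencies count the L iterated points (the seed
    point is not counted) over the 2^k x 2^k grid.
    """
    if k < 1:
        raise ValueError("resolution k must be >= 1")
    if len(seq.sequence) < k:
        raise ValueError(
            f"sequence {seq.mirna_name!r} shorter than resolution k={k}"
        )
    side = 2 ** k
    freq = np.zeros((side, side))
    x, y = 0.5, 0.5
    for nt in seq.sequence:
        cx, cy = CGR_CORNERS[nt]
        x = (x + cx) / 2.0
        y = (y + cy) / 2.0
        ix = min(int(x * side), side - 1)
        iy = min(int(y * side), side - 1)
        freq[iy, ix] += 1.0
    freq /= len(seq.sequence)
    return CGRProfile(seq.mirna_name, k, freq)


def mirna_similarity(profiles: list[CGRProfile]) -> SimilarityMatrix:
    """Min-max-inverted pairwise region distance between CGR profiles.

    d(u, v) is the Frobenius distance between frequency matrices and
    sim = 1 - d / max d; the diagonal is forced to 1.  When all sequences are
    identical (max distance 0) every similarity is 1.
    """
    if len(profiles) < 2:
        raise ValueError("need at least 2 profiles")
    ks = {p.resolution for p in profiles}
    if len(ks) != 1:
        raise ValueError("all profiles must share one resolution")
    names = [p.mirna_name for p in profiles]
    flat = np.stack([p.freq.ravel() for p in profiles])
    sq = (flat ** 2).sum(axis=1)
    d2 = np.maximum(sq[:, None] + sq[None, :] - 2 * flat @ flat.T, 0.0)
    d = np.sqrt(d2)
    dmax = d.max()
    sim = np.ones_like(d) if dmax == 0 else 1.0 - d / dmax
    np.fill_diagonal(sim, 1.0)
    sim = np.clip((sim + sim.T) / 2.0, 0.0, 1.0)
    np.fill_diagonal(sim, 1.0)
    return SimilarityMatrix(tuple(names), sim)
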