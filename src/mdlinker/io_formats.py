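"""Readers and writers for the three standard inputs.

The pipeline consumes (a) miRNA-disease-type association triples in HMDD-style
tab-separated text, (b) a disease hierarchy given as MeSH-style tree codes and
(c) miRNA precursor sequences in FASTA.  Everything downstream sees only
normalized names and the intersection of entities present in all relevant
inputs; that filtering happens exactly once, in :func:`intersect_inputs`.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

logger = logging.getLogger(__name__)

#: The five heterogeneous evidence categories, in fixed canonical order.
#: This order is also the deterministic tie-break order used when ranking
#: the per-type scores of a pair.
ASSOCIATION_TYPES: tuple[str, ...] = (
    "genetics",
    "epigenetics",
    "circulating",
    "target",
    "tissue",
)

#: Default synonym table mapping category strings found in the wild to the
#: canonical five labels.  HMDD dialects vary across versions; extend via the
#: ``synonyms`` argument of :func:`read_associations`.
CATEGORY_SYNONYMS: dict[str, str] = {
    "genetics": "genetics",
    "genetic": "genetics",
    "epigenetics": "epigenetics",
    "epigenetic": "epigenetics",
    "circulating": "circulating",
    "circulation": "circulating",
    "circulating mirnas": "circulating",
    "target": "target",
    "targets": "target",
    "mirna-target interactions": "target",
    "tissue": "tissue",
    "tissue expression": "tissue",
    "mirna tissue expression": "tissue",
}

_TREE_CODE_RE = re.compile(r"^[A-Za-z0-9]+(\.[A-Za-z0-9]+)*$")


def normalize_name(name: str) -> str:
    """Case-fold, trim and collapse internal whitespace runs."""
    return re.sub(r"\s+", " ", name.strip()).casefold()


@dataclass(frozen=True)
class AssociationRecord:
    """One experimentally supported (miRNA, disease, evidence type) triple."""

    mirna_name: str
    disease_name: str
    type_label: str
    source_id: str | None = None

    def __post_init__(self) -> None:
        if self.type_label not in ASSOCIATION_TYPES:
            raise ValueError(f"unknown association type: {self.type_label!r}")

    @property
    def triple(self) -> tuple[str, str, str]:
        return (self.mirna_name, self.disease_name, self.type_label)


@dataclass(frozen=True)
class MeshEntry:
    """A disease descriptor and its position(s) in the hierarchy tree."""

    disease_name: str
    tree_codes: tuple[str, ...]


@dataclass(frozen=True)
class SequenceRecord:
    """An miRNA precursor sequence over {A, C, G, U}."""

    mirna_name: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"empty sequence for {self.mirna_name!r}")
        bad = set(self.sequence) - set("ACGU")
        if bad:
            raise ValueError(
                f"sequence for {self.mirna_name!r} contains non-ACGU "
                f"residues {sorted(bad)}"
            )


def read_associations(
    path: str | Path,
    mapping: Mapping[str, str] | None = None,
    synonyms: Mapping[str, str] | None = None,
) -> list[AssociationRecord]:
    """Read HMDD-style tab-separated triples.

    Columns: miRNA name, disease name, category, optional source id (PMID).
    Names are normalized; precursor names are collapsed to mature names via
    ``mapping`` when provided; duplicate triples are deduplicated; rows whose
    category does not resolve through the synonym table are skipped with a
    logged count.
    """
    path = Path(path)
    syn = dict(CATEGORY_SYNONYMS)
    if synonyms:
        syn.update({normalize_name(k): v for k, v in synonyms.items()})
    norm_map = (
        {normalize_name(k): normalize_name(v) for k, v in mapping.items()}
        if mapping
        else {}
    )
    seen: set[tuple[str, str, str]] = set()
    records: list[AssociationRecord] = []
    n_bad_category = 0
    with path.open(encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                logger.warning("skipping malformed association row: %r", line)
                continue
            mirna = normalize_name(parts[0])
            mirna = norm_map.get(mirna, mirna)
            disease = normalize_name(parts[1])
            category = syn.get(normalize_name(parts[2]))
            if category is None:
                n_bad_category += 1
                logger.warning("unknown category %r; row skipped", parts[2])
                continue
            source = parts[3].strip() if len(parts) > 3 and parts[3].strip() else None
            key = (mirna, disease, category)
            if key in seen:
                continue
            seen.add(key)
            records.append(AssociationRecord(mirna, disease, category, source))
    if n_bad_category:
        logger.warning("%d rows dropped for unmappable categories", n_bad_category)
    return records


def write_associations(records: Iterable[AssociationRecord], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for r in records:
            fh.write(f"{r.mirna_name}\t{r.disease_name}\t{r.type_label}"
                     f"\t{r.source_id or ''}\n")


def read_mesh(path: str | Path) -> list[MeshEntry]:
    """Read two-column (disease name, tree code) text, grouping codes per disease."""
    path = Path(path)
    codes: dict[str, list[str]] = {}
    n_rows = 0
    with path.open(encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                logger.warning("skipping malformed tree-code row: %r", line)
                continue
            name = normalize_name(parts[0])
            code = parts[1].strip()
            if not _TREE_CODE_RE.match(code):
                logger.warning("malformed tree code %r for %r; row skipped", code, name)
                continue
            n_rows += 1
            codes.setdefault(name, [])
            if code not in codes[name]:
                codes[name].append(code)
    if n_rows == 0:
        logger.warning("no valid tree-code rows in %s", path)
    return [MeshEntry(name, tuple(cs)) for name, cs in codes.items()]


def write_mesh(entries: Iterable[MeshEntry], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for e in entries:
            for code in e.tree_codes:
                fh.write(f"{e.disease_name}\t{code}\n")


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read precursor sequences; the header's first token is the miRNA name.

    T is converted to U on read; any other non-ACGU residue is fatal and the
    error names the offending record.
    """
    records: list[SequenceRecord] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        name = normalize_name(rec.id)
        seq = str(rec.seq).upper().replace("T", "U")
        bad = set(seq) - set("ACGU")
        if bad:
            raise ValueError(
                f"record {rec.id!r}: non-ACGU residues {sorted(bad)} after T->U"
            )
        records.append(SequenceRecord(name, seq))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for r in records:
            fh.write(f">{r.mirna_name}\n{r.sequence}\n")


@dataclass
class Dataset:
    """The intersected inputs every downstream module consumes."""

    associations: list[AssociationRecord]
    mesh: list[MeshEntry]
    sequences: list[SequenceRecord]
    mirnas: list[str] = field(init=False)
    diseases: list[str] = field(init=False)

    def __post_init__(self) -> None:
        self.mirnas = sorted({r.mirna_name for r in self.associations})
        self.diseases = sorted({r.disease_name for r in self.associations})


def intersect_inputs(
    associations: Sequence[AssociationRecord],
    mesh: Sequence[MeshEntry],
    sequences: Sequence[SequenceRecord],
) -> Dataset:
    """Restrict all three inputs to their common entities, once, with logging.

    Downstream modules only ever see miRNAs present in both the associations
    and the FASTA, and diseases present in both the associations and the
    hierarchy table.
    """
    seq_names = {s.mirna_name for s in sequences}
    mesh_names = {e.disease_name for e in mesh}
    assoc_mirnas = {r.mirna_name for r in associations}
    assoc_diseases = {r.disease_name for r in associations}
    keep_mirnas = assoc_mirnas & seq_names
    keep_diseases = assoc_diseases & mesh_names
    dropped_m = len(assoc_mirnas) - len(keep_mirnas)
    dropped_d = len(assoc_diseases) - len(keep_diseases)
    if dropped_m or dropped_d:
        logger.info(
            "intersection filter dropped %d miRNAs without sequences and "
            "%d diseases without tree codes",
            dropped_m, dropped_d,
        )
    kept_assoc = [
        r for r in associations
        if r.mirna_name in keep_mirnas and r.disease_name in keep_diseases
    ]
    # entities whose every association was dropped disappear entirely
    final_mirnas = {r.mirna_name for r in kept_assoc}
    final_diseases = {r.disease_name for r in kept_assoc}
    kept_mesh = [e for e in mesh if e.disease_name in final_diseases]
    kept_seq = [s for s in sequences if s.mirna_name in final_mirnas]
    return Dataset(kept_assoc, kept_mesh, kept_seq)
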