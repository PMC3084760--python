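"""Domain types and file I/O for protein sequence sets.

The unit of data throughout the package is a :class:`ProteinRecord` — one
catalytic-subunit amino-acid sequence with an identifier and optional
taxonomy.  A labelled collection of records (the curated reference set a
query is classified against) is a :class:`ReferenceSet`.

Sequences travel as plain FASTA; labels as a two/three column TSV
(``id<TAB>type[<TAB>taxonomy]``) with a header line.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import ParseError

logger = logging.getLogger("hcoclass")

#: The 20 canonical amino acids plus X for ambiguity.
ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")

#: Non-canonical one-letter codes folded into X on normalization.
AMBIGUOUS_TO_X = str.maketrans({c: "X" for c in "BZJUO"})


class EnzymeType(Enum):
    """Closed label set for the enzyme families handled here.

    A1/A2/B/C are the heme-copper oxygen reductase types; NOR is the
    nitric-oxide reductase family.  UNCLASSIFIED is only ever produced by
    the classifier — it is not a valid reference label.
    """

    A1 = "A1"
    A2 = "A2"
    B = "B"
    C = "C"
    NOR = "NOR"
    UNCLASSIFIED = "UNCLASSIFIED"

    @classmethod
    def parse(cls, token: str) -> "EnzymeType":
        """Case-insensitive parse of a label token (``"a1"`` -> A1)."""
        try:
            return cls(token.strip().upper())
        except ValueError:
            raise ParseError(
                f"unknown enzyme type {token!r}; expected one of "
                f"{[t.value for t in cls if t is not cls.UNCLASSIFIED]}"
            ) from None


#: Types that may appear as reference labels.
REFERENCE_TYPES = tuple(t for t in EnzymeType if t is not EnzymeType.UNCLASSIFIED)


def normalize_residues(raw: str, record_id: str = "?") -> str:
    """Uppercase, strip whitespace and ``*`` stops, fold B/Z/J/U/O to X.

    Raises :class:`ParseError` for characters outside the amino-acid
    alphabet after folding.
    """
    seq = "".join(raw.split()).upper().replace("*", "")
    folded = seq.translate(AMBIGUOUS_TO_X)
    if folded != seq:
        logger.warning("record %s: non-canonical residue letters mapped to X", record_id)
    bad = set(folded) - ALPHABET
    if bad:
        raise ParseError(f"record {record_id}: illegal residue characters {sorted(bad)}")
    return folded


@dataclass
class ProteinRecord:
    """One amino-acid sequence of a catalytic subunit.

    ``residues`` is normalized on construction (uppercased, ``*`` stripped,
    rare ambiguity codes folded to X).  ``description`` holds the FASTA
    header text after the id token; ``taxonomy`` is an opaque organism /
    lineage string used only for strain-redundancy grouping.
    """

    id: str
    residues: str
    description: str = ""
    taxonomy: str | None = None
    accession: str | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ParseError("ProteinRecord id must be nonempty")
        self.residues = normalize_residues(self.residues, self.id)
        if not self.residues:
            raise ParseError(f"record {self.id}: empty sequence")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class ReferenceSet:
    """A labelled ("gold standard") sequence set.

    Invariant: the records and the label map cover exactly the same ids,
    and no label is UNCLASSIFIED.
    """

    records: list[ProteinRecord]
    labels: dict[str, EnzymeType] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate record ids in reference set")
        if set(ids) != set(self.labels):
            missing = set(ids) ^ set(self.labels)
            raise ValueError(f"records and labels do not match: {sorted(missing)[:5]} ...")
        if any(t is EnzymeType.UNCLASSIFIED for t in self.labels.values()):
            raise ValueError("UNCLASSIFIED is not a valid reference label")
        self._by_id = {r.id: r for r in self.records}

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, record_id: str) -> ProteinRecord:
        return self._by_id[record_id]

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def label_of(self, record_id: str) -> EnzymeType:
        return self.labels[record_id]

    def types(self) -> set[EnzymeType]:
        return set(self.labels.values())

    def without(self, record_id: str) -> "ReferenceSet":
        """The reference set minus one record (for leave-one-out)."""
        return ReferenceSet(
            records=[r for r in self.records if r.id != record_id],
            labels={i: t for i, t in self.labels.items() if i != record_id},
        )


# ---------------------------------------------------------------------------
# FASTA I/O


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a FASTA file into normalized records.

    The id is the header token up to the first whitespace; the remainder of
    the header is kept verbatim as the description.  An empty file yields an
    empty list; a file whose first non-blank line is not a ``>`` header is a
    :class:`ParseError` naming that line.
    """
    path = Path(path)
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if line.strip():
                if not line.startswith(">"):
                    raise ParseError(
                        f"{path}: line {lineno}: expected FASTA header starting with '>'"
                    )
                break
        else:
            return []
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for seq_record in SeqIO.parse(str(path), "fasta"):
        if not seq_record.id:
            raise ParseError(f"{path}: FASTA entry with empty header id")
        if seq_record.id in seen:
            raise ParseError(f"{path}: duplicate FASTA id {seq_record.id!r}")
        seen.add(seq_record.id)
        description = seq_record.description
        if description.startswith(seq_record.id):
            description = description[len(seq_record.id):].strip()
        records.append(
            ProteinRecord(id=seq_record.id, residues=str(seq_record.seq), description=description)
        )
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    """Write records as FASTA, wrapped at 60 columns."""
    seq_records = [
        SeqRecord(Seq(r.residues), id=r.id, description=r.description) for r in records
    ]
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=60)
        writer.write_file(seq_records)


# ---------------------------------------------------------------------------
# Label tables


def read_labels(path: str | Path) -> dict[str, EnzymeType]:
    """Read an ``id<TAB>type[<TAB>taxonomy]`` table with a header line.

    Type tokens are parsed case-insensitively against the closed label set;
    unknown tokens and conflicting duplicate ids are errors.
    """
    frame = pd.read_csv(path, sep="\t", dtype=str)
    cols = {c.lower(): c for c in frame.columns}
    if "id" not in cols or "type" not in cols:
        raise ParseError(f"{path}: label table must have 'id' and 'type' columns")
    labels: dict[str, EnzymeType] = {}
    for row_index, row in frame.iterrows():
        record_id = str(row[cols["id"]]).strip()
        try:
            enzyme_type = EnzymeType.parse(str(row[cols["type"]]))
        except ParseError as exc:
            raise ParseError(f"{path}: row {row_index + 2}: {exc}") from None
        if enzyme_type is EnzymeType.UNCLASSIFIED:
            raise ParseError(f"{path}: row {row_index + 2}: UNCLASSIFIED is not a reference label")
        if record_id in labels and labels[record_id] is not enzyme_type:
            raise ParseError(
                f"{path}: duplicate id {record_id!r} with conflicting types "
                f"{labels[record_id].value} / {enzyme_type.value}"
            )
        labels[record_id] = enzyme_type
    return labels


def read_label_taxonomy(path: str | Path) -> dict[str, str]:
    """Optional third column of the label table, as an id -> taxonomy map."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    cols = {c.lower(): c for c in frame.columns}
    if "taxonomy" not in cols:
        return {}
    out = {}
    for _, row in frame.iterrows():
        value = row[cols["taxonomy"]]
        if isinstance(value, str) and value.strip():
            out[str(row[cols["id"]]).strip()] = value.strip()
    return out


def write_labels(labels: Mapping[str, EnzymeType], path: str | Path,
                 taxonomy: Mapping[str, str] | None = None) -> None:
    """Write a label table (TSV with header)."""
    with open(path, "w") as handle:
        if taxonomy:
            handle.write("id\ttype\ttaxonomy\n")
            for record_id, enzyme_type in labels.items():
                handle.write(f"{record_id}\t{enzyme_type.value}\t{taxonomy.get(record_id, '')}\n")
        else:
            handle.write("id\ttype\n")
            for record_id, enzyme_type in labels.items():
                handle.write(f"{record_id}\t{enzyme_type.value}\n")


def build_reference_set(
    records: Iterable[ProteinRecord], labels: Mapping[str, EnzymeType]
) -> tuple[ReferenceSet, list[str]]:
    """Join records with their labels into a :class:`ReferenceSet`.

    Records without a label are dropped and reported in the second return
    value.  A label pointing at a record id that does not exist is an error.
    """
    records = list(records)
    record_ids = {r.id for r in records}
    dangling = sorted(set(labels) - record_ids)
    if dangling:
        raise ValueError(f"labels refer to missing record ids: {dangling[:5]}")
    kept = [r for r in records if r.id in labels]
    dropped = sorted(record_ids - set(labels))
    for record_id in dropped:
        logger.info("build_reference_set: dropping unlabeled record %s", record_id)
    return ReferenceSet(records=kept, labels={r.id: labels[r.id] for r in kept}), dropped
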