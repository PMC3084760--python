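"""Reference-set acceptance filters.

Candidate subunit sequences pass three filters before entering a curated
reference set, applied in a fixed order:

1. length — anything shorter than 400 residues is discarded (fragments
   cannot carry the full channel fingerprints);
2. metal ligands — the six histidines liganding the low- and high-spin
   hemes and Cu_B (or Fe in NOR) must be present at the anchor-mapped
   positions;
3. redundancy — exact duplicate sequences, and multiple same-type
   sequences from strains of one species, are collapsed to one.

Each filter returns a :class:`FilterReport` that conserves the input ids.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .alignment import DEFAULT_SCORING, ScoringScheme
from .errors import ConfigurationError
from .fingerprints import AnchorProfile, build_position_map
from .records import EnzymeType, ProteinRecord

logger = logging.getLogger("hcoclass")

DEFAULT_MIN_LENGTH = 400

#: Valid discard reasons.
REASONS = ("too_short", "missing_ligand", "duplicate", "redundant_strain")


@dataclass
class FilterReport:
    """Outcome of one filter pass: kept ids and (id, reason) discards."""

    kept: list[str]
    discarded: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        kept, dropped = set(self.kept), {i for i, _ in self.discarded}
        if kept & dropped:
            raise ValueError(f"ids both kept and discarded: {sorted(kept & dropped)[:5]}")
        for _, reason in self.discarded:
            if reason not in REASONS:
                raise ValueError(f"unknown discard reason {reason!r}")

    @property
    def all_ids(self) -> set[str]:
        return set(self.kept) | {i for i, _ in self.discarded}


def filter_by_length(records: Sequence[ProteinRecord],
                     min_length: int = DEFAULT_MIN_LENGTH) -> FilterReport:
    """Discard records shorter than ``min_length`` (boundary length kept)."""
    if min_length < 1:
        raise ValueError("min_length must be >= 1")
    kept, discarded = [], []
    for record in records:
        if len(record) < min_length:
            discarded.append((record.id, "too_short"))
            logger.info("discard %s: too_short (%d < %d)", record.id, len(record), min_length)
        else:
            kept.append(record.id)
    return FilterReport(kept=kept, discarded=discarded)


def check_metal_ligand_histidines(record: ProteinRecord, anchor: ProteinRecord,
                                  anchor_his_positions: Sequence[int],
                                  scoring: ScoringScheme = DEFAULT_SCORING) -> bool:
    """True iff the record keeps a histidine at all six anchor ligand sites.

    The record is globally aligned to the anchor; a gap or non-His residue
    at any mapped ligand position fails the check.
    """
    if len(anchor_his_positions) != 6:
        raise ConfigurationError("exactly six histidine ligand positions are required")
    for pos in anchor_his_positions:
        if not (1 <= pos <= len(anchor)) or anchor.residues[pos - 1] != "H":
            raise ConfigurationError(f"anchor position {pos} is not a histidine")
    pmap = build_position_map(record, anchor, scoring)
    return all(pmap.residue(record, pos) == "H" for pos in anchor_his_positions)


def filter_by_ligands(records: Sequence[ProteinRecord],
                      anchors: Iterable[AnchorProfile],
                      scoring: ScoringScheme = DEFAULT_SCORING) -> FilterReport:
    """Keep records passing the six-histidine check against ANY anchor."""
    anchors = list(anchors)
    if not anchors:
        raise ConfigurationError("at least one anchor profile is required")
    kept, discarded = [], []
    for record in records:
        ok = any(
            check_metal_ligand_histidines(record, profile.anchor, profile.his_ligands, scoring)
            for profile in anchors
        )
        if ok:
            kept.append(record.id)
        else:
            discarded.append((record.id, "missing_ligand"))
            logger.info("discard %s: missing_ligand", record.id)
    return FilterReport(kept=kept, discarded=discarded)


def species_key(record: ProteinRecord) -> str | None:
    """Binomial species key: first two whitespace tokens of the taxonomy."""
    if not record.taxonomy:
        return None
    tokens = record.taxonomy.split()
    return " ".join(tokens[:2]) if len(tokens) >= 2 else tokens[0]


def deduplicate(records: Sequence[ProteinRecord],
                labels: Mapping[str, EnzymeType],
                taxonomy_key=species_key) -> FilterReport:
    """Collapse duplicates and same-species same-type strain redundancy.

    Exact duplicate residue strings are collapsed first; then, among
    records sharing a species key and a type label, only the
    lexicographically smallest id survives.  Records without taxonomy are
    never treated as strain-redundant.
    """
    missing = [r.id for r in records if r.id not in labels]
    if missing:
        raise ValueError(f"records without labels: {missing[:5]}")
    ordered = sorted(records, key=lambda r: r.id)
    kept_records: list[ProteinRecord] = []
    discarded: list[tuple[str, str]] = []

    seen_sequences: dict[str, str] = {}
    for record in ordered:
        if record.residues in seen_sequences:
            discarded.append((record.id, "duplicate"))
            logger.info("discard %s: duplicate of %s", record.id, seen_sequences[record.residues])
        else:
            seen_sequences[record.residues] = record.id
            kept_records.append(record)

    seen_strains: dict[tuple[str, EnzymeType], str] = {}
    kept: list[str] = []
    for record in kept_records:
        key = taxonomy_key(record)
        if key is None:
            kept.append(record.id)
            continue
        group = (key, labels[record.id])
        if group in seen_strains:
            discarded.append((record.id, "redundant_strain"))
            logger.info("discard %s: redundant_strain (kept %s)", record.id, seen_strains[group])
        else:
            seen_strains[group] = record.id
            kept.append(record.id)
    return FilterReport(kept=kept, discarded=discarded)


def curate(records: Sequence[ProteinRecord], labels: Mapping[str, EnzymeType],
           anchors: Iterable[AnchorProfile] | None = None,
           min_length: int = DEFAULT_MIN_LENGTH,
           scoring: ScoringScheme = DEFAULT_SCORING,
           ) -> tuple[list[ProteinRecord], FilterReport]:
    """Full curation pass: length -> ligands -> redundancy.

    Returns the surviving records and a combined report over all stages.
    """
    by_id = {r.id: r for r in records}
    report_length = filter_by_length(records, min_length)
    survivors = [by_id[i] for i in report_length.kept]
    discards = list(report_length.discarded)

    if anchors is not None:
        report_ligand = filter_by_ligands(survivors, anchors, scoring)
        survivors = [by_id[i] for i in report_ligand.kept]
        discards += report_ligand.discarded

    report_dedup = deduplicate(survivors, labels)
    survivors = [by_id[i] for i in report_dedup.kept]
    discards += report_dedup.discarded
    return survivors, FilterReport(kept=[r.id for r in survivors], discarded=discards)
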