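"""Best-hit annotation-transfer classification and its benchmark.

A query is locally aligned against every sequence of the labelled
reference set.  Hits are ranked by E-value (ties: higher raw score, then
id); if the best hit's E-value is below the acceptance cutoff (0.01 by
default) the query inherits its label.  In the top-k modes (k = 2, 3, 5)
the first k hits must agree on the label, otherwise the query is reported
as unclassified.

The benchmark is leave-one-out cross-validation over the reference set
itself, summarized as per-type and micro-averaged ("global") precision
and recall.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, NamedTuple

from .alignment import DEFAULT_SCORING, PairAlignment, ScoringScheme, local_align, similarity_percent
from .records import EnzymeType, ProteinRecord, ReferenceSet

logger = logging.getLogger("hcoclass")

MODES = ("top1", "top2", "top3", "top5")
DEFAULT_EVALUE_CUTOFF = 0.01
#: Hits above this E-value are not reported at all (search-time cutoff).
REPORTING_EVALUE = 10.0


class Hit(NamedTuple):
    subject_id: str
    type: EnzymeType
    evalue: float
    similarity: float
    raw_score: int


@dataclass
class ClassificationResult:
    """One query's outcome: a predicted type, or why there is none."""

    query_id: str
    predicted: EnzymeType
    mode: str
    hits: list[Hit]
    status: str  # classified | unclassified | no_hit
    #: True when fewer hits than the mode's k passed the cutoff and
    #: agreement was evaluated over the available ones.
    truncated: bool = False

    def __post_init__(self) -> None:
        if self.status not in ("classified", "unclassified", "no_hit"):
            raise ValueError(f"bad status {self.status!r}")
        if (self.predicted is EnzymeType.UNCLASSIFIED) != (self.status != "classified"):
            raise ValueError("predicted type inconsistent with status")


def _mode_k(mode: str) -> int:
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    return int(mode[3:])


def rank_hits(query: ProteinRecord, refset: ReferenceSet,
              scoring: ScoringScheme = DEFAULT_SCORING,
              reporting_evalue: float = REPORTING_EVALUE,
              alignments: Mapping[tuple[str, str], PairAlignment] | None = None,
              ) -> list[Hit]:
    """Reference hits for a query, best first.

    Sorted by ascending E-value, ties broken by descending raw score then
    ascending subject id.  ``alignments`` may supply precomputed
    (query_id, subject_id) local alignments to avoid re-aligning.
    """
    if len(refset) == 0:
        raise ValueError("empty reference set")
    hits = []
    for subject in refset.records:
        if subject.id == query.id:
            continue
        if alignments is not None and (query.id, subject.id) in alignments:
            aln = alignments[(query.id, subject.id)]
        else:
            aln = local_align(query, subject, scoring)
        if aln.evalue > reporting_evalue:
            continue
        similarity = similarity_percent(aln) if aln.query_span > 0 else 0.0
        hits.append(Hit(subject.id, refset.label_of(subject.id), aln.evalue,
                        similarity, aln.raw_score))
    hits.sort(key=lambda h: (h.evalue, -h.raw_score, h.subject_id))
    return hits


def classify(query: ProteinRecord, refset: ReferenceSet, mode: str = "top1",
             evalue_cutoff: float = DEFAULT_EVALUE_CUTOFF,
             scoring: ScoringScheme = DEFAULT_SCORING,
             alignments: Mapping[tuple[str, str], PairAlignment] | None = None,
             ) -> ClassificationResult:
    """Classify one query by annotation transfer from its best hits.

    No hit below the E-value cutoff -> status ``no_hit``.  In top-k modes
    the first k passing hits must share one label, otherwise the query is
    ``unclassified``; with fewer than k passing hits, agreement is
    evaluated over those available (flagged as truncated).
    """
    k = _mode_k(mode)
    hits = rank_hits(query, refset, scoring, alignments=alignments)
    passing = [h for h in hits if h.evalue < evalue_cutoff]
    if not passing:
        return ClassificationResult(query.id, EnzymeType.UNCLASSIFIED, mode, hits, "no_hit")
    top = passing[:k]
    labels = {h.type for h in top}
    truncated = len(passing) < k
    if len(labels) == 1:
        return ClassificationResult(query.id, top[0].type, mode, hits, "classified",
                                    truncated=truncated)
    return ClassificationResult(query.id, EnzymeType.UNCLASSIFIED, mode, hits,
                                "unclassified", truncated=truncated)


@dataclass
class ConfusionTally:
    """Per-type true/false positive and false negative counts."""

    tp: dict[EnzymeType, int] = field(default_factory=dict)
    fp: dict[EnzymeType, int] = field(default_factory=dict)
    fn: dict[EnzymeType, int] = field(default_factory=dict)
    n_unclassified: int = 0

    def types(self) -> list[EnzymeType]:
        present = set(self.tp) | set(self.fp) | set(self.fn)
        return [t for t in EnzymeType if t in present]

    def add(self, true_type: EnzymeType, result: ClassificationResult) -> None:
        for counter in (self.tp, self.fp, self.fn):
            counter.setdefault(true_type, 0)
        if result.status == "classified":
            self.fp.setdefault(result.predicted, 0)
            if result.predicted is true_type:
                self.tp[true_type] += 1
            else:
                self.fp[result.predicted] += 1
                self.fn[true_type] += 1
        else:
            self.fn[true_type] += 1
            self.n_unclassified += 1

    @property
    def n_queries(self) -> int:
        return sum(self.tp.values()) + sum(self.fn.values())


def leave_one_out(refset: ReferenceSet, mode: str = "top1",
                  scoring: ScoringScheme = DEFAULT_SCORING,
                  evalue_cutoff: float = DEFAULT_EVALUE_CUTOFF,
                  alignments: Mapping[tuple[str, str], PairAlignment] | None = None,
                  ) -> ConfusionTally:
    """Leave-one-out cross-validation of annotation transfer.

    Each reference sequence is classified against the remaining ones and
    the prediction compared to its curated label.
    """
    if len(refset) < 2:
        raise ValueError("leave-one-out needs at least two records")
    counts: dict[EnzymeType, int] = {}
    for enzyme_type in refset.labels.values():
        counts[enzyme_type] = counts.get(enzyme_type, 0) + 1
    for enzyme_type, n in counts.items():
        if n == 1:
            logger.warning("type %s has a single member; its LOO recall is "
                           "structurally limited", enzyme_type.value)
    tally = ConfusionTally()
    for record in refset.records:
        result = classify(record, refset.without(record.id), mode,
                          evalue_cutoff, scoring, alignments=alignments)
        tally.add(refset.label_of(record.id), result)
    return tally


def precision(tally: ConfusionTally, enzyme_type: EnzymeType) -> float:
    """Tp / (Tp + Fp); NaN when nothing was classified as this type."""
    tp = tally.tp.get(enzyme_type, 0)
    fp = tally.fp.get(enzyme_type, 0)
    return tp / (tp + fp) if tp + fp else math.nan


def recall(tally: ConfusionTally, enzyme_type: EnzymeType) -> float:
    """Tp / (Tp + Fn); NaN when the type has no evaluated members."""
    tp = tally.tp.get(enzyme_type, 0)
    fn = tally.fn.get(enzyme_type, 0)
    return tp / (tp + fn) if tp + fn else math.nan


def global_precision_recall(tally: ConfusionTally) -> tuple[float, float]:
    """Micro-averaged precision and recall over all types."""
    tp = sum(tally.tp.values())
    fp = sum(tally.fp.values())
    fn = sum(tally.fn.values())
    return (tp / (tp + fp) if tp + fp else math.nan,
            tp / (tp + fn) if tp + fn else math.nan)
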