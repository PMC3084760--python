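"""Pairwise alignment, percent similarity and the all-vs-all matrix.

Alignments are exact (full dynamic programming, no word-hit heuristics):
Smith–Waterman for local comparisons, Needleman–Wunsch for the global
anchor mapping used by the fingerprint module.  Scoring follows the
classical protein-search defaults — BLOSUM62 with affine gap penalties of
11 to open and 1 to extend.

The similarity between two sequences is the local alignment's positives
(aligned residue pairs with a positive substitution score) divided by the
alignment length over the query, as a percentage.  Directed similarities
for the two orientations of a pair are averaged into a symmetric
:class:`SimilarityMatrix`.

E-values use the Karlin–Altschul formula ``K·m·n·exp(−λS)`` with fixed
gapped-BLOSUM62 constants; they exist to drive the classifier's 0.01
accept/discard rule, not to replicate any particular search engine's
composition adjustments.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .errors import ConfigurationError, UndefinedSimilarityError
from .records import ProteinRecord

#: Gapped BLOSUM62 Karlin–Altschul parameters (natural-log scale).
DEFAULT_LAMBDA = 0.267
DEFAULT_K = 0.041


@dataclass(frozen=True)
class ScoringScheme:
    """Substitution matrix, affine gap penalties and E-value constants."""

    matrix_name: str = "BLOSUM62"
    gap_open: int = 11     # cost of the first residue of a gap, minus extension
    gap_extend: int = 1    # cost of each gapped residue
    karlin_lambda: float = DEFAULT_LAMBDA
    karlin_k: float = DEFAULT_K

    def __post_init__(self) -> None:
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ConfigurationError("gap penalties are nonnegative costs")


DEFAULT_SCORING = ScoringScheme()


@lru_cache(maxsize=8)
def _matrix(name: str):
    return substitution_matrices.load(name)


@lru_cache(maxsize=16)
def _aligner(scoring: ScoringScheme, mode: str) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = _matrix(scoring.matrix_name)
    # Biopython charges open_gap_score for the first gapped residue; the
    # conventional open+extend*L cost therefore maps to -(open+extend), -extend.
    aligner.open_gap_score = -(scoring.gap_open + scoring.gap_extend)
    aligner.extend_gap_score = -scoring.gap_extend
    aligner.mode = mode
    return aligner


@dataclass
class PairAlignment:
    """One local alignment between a query and a subject sequence."""

    query_id: str
    subject_id: str
    raw_score: int
    bit_score: float
    evalue: float
    positives: int
    identities: int
    query_span: int       # alignment columns across the aligned query segment
    query_interval: tuple[int, int]    # 1-based inclusive
    subject_interval: tuple[int, int]  # 1-based inclusive

    def __post_init__(self) -> None:
        if not (self.identities <= self.positives <= max(self.query_span, 0)):
            raise ValueError(
                f"{self.query_id}/{self.subject_id}: inconsistent counts "
                f"id={self.identities} pos={self.positives} span={self.query_span}"
            )


def evalue(raw_score: float, m: int, n: int,
           scoring: ScoringScheme = DEFAULT_SCORING) -> float:
    """Karlin–Altschul expectation ``K·m·n·exp(−λS)`` for a score S."""
    if scoring.karlin_lambda <= 0 or scoring.karlin_k <= 0:
        raise ConfigurationError("Karlin-Altschul lambda and K must be positive")
    if m <= 0 or n <= 0:
        raise ConfigurationError("sequence lengths must be positive")
    return scoring.karlin_k * m * n * math.exp(-scoring.karlin_lambda * raw_score)


def _seq(x: ProteinRecord | str) -> str:
    return x.residues if isinstance(x, ProteinRecord) else x


def _check_alphabet(seq: str, scoring: ScoringScheme) -> None:
    alphabet = set(str(_matrix(scoring.matrix_name).alphabet))
    bad = set(seq) - alphabet
    if bad:
        raise ValueError(f"residues {sorted(bad)} outside the {scoring.matrix_name} alphabet")


def local_align(query: ProteinRecord | str, subject: ProteinRecord | str,
                scoring: ScoringScheme = DEFAULT_SCORING) -> PairAlignment:
    """Optimal Smith–Waterman local alignment of query against subject.

    Counts are taken from the (deterministic) first optimal traceback:
    identities, positives (substitution score > 0) and the query span —
    the number of alignment columns between the first and last aligned
    query residue, gap columns included.
    """
    query_seq, subject_seq = _seq(query), _seq(subject)
    if not query_seq or not subject_seq:
        raise ValueError("cannot align empty sequences")
    _check_alphabet(query_seq, scoring)
    _check_alphabet(subject_seq, scoring)
    matrix = _matrix(scoring.matrix_name)
    result = _aligner(scoring, "local").align(query_seq, subject_seq)
    best = result[0]
    raw = int(round(best.score))

    identities = positives = 0
    columns = best.indices  # (2, ncols); -1 marks a gap
    query_cols = columns[0]
    subject_cols = columns[1]
    for qi, si in zip(query_cols, subject_cols):
        if qi < 0 or si < 0:
            continue
        a, b = query_seq[qi], subject_seq[si]
        if a == b:
            identities += 1
        if matrix[a, b] > 0:
            positives += 1
    span = columns.shape[1]

    aligned_q = query_cols[query_cols >= 0]
    aligned_s = subject_cols[subject_cols >= 0]
    if span == 0 or aligned_q.size == 0 or aligned_s.size == 0:
        # No residue pair scores positive: empty local alignment.
        q_interval = s_interval = (0, 0)
        span = 0
    else:
        q_interval = (int(aligned_q[0]) + 1, int(aligned_q[-1]) + 1)
        s_interval = (int(aligned_s[0]) + 1, int(aligned_s[-1]) + 1)

    lam, k = scoring.karlin_lambda, scoring.karlin_k
    bit = (lam * raw - math.log(k)) / math.log(2)
    expect = evalue(raw, len(query_seq), len(subject_seq), scoring)
    return PairAlignment(
        query_id=query.id if isinstance(query, ProteinRecord) else "query",
        subject_id=subject.id if isinstance(subject, ProteinRecord) else "subject",
        raw_score=raw,
        bit_score=bit,
        evalue=expect,
        positives=positives,
        identities=identities,
        query_span=span,
        query_interval=q_interval,
        subject_interval=s_interval,
    )


def global_alignment_columns(query: ProteinRecord | str, anchor: ProteinRecord | str,
                             scoring: ScoringScheme = DEFAULT_SCORING) -> np.ndarray:
    """End-to-end alignment of query vs anchor as a (2, ncols) index array.

    Row 0 holds query indices, row 1 anchor indices; -1 marks a gap.  Used
    by the fingerprint module to transfer anchor numbering onto a query.
    """
    query_seq, anchor_seq = _seq(query), _seq(anchor)
    if not query_seq or not anchor_seq:
        raise ValueError("cannot align empty sequences")
    _check_alphabet(query_seq, scoring)
    _check_alphabet(anchor_seq, scoring)
    best = _aligner(scoring, "global").align(query_seq, anchor_seq)[0]
    return best.indices


def similarity_percent(aln: PairAlignment) -> float:
    """The similarity score: ``100 × positives / query_span``."""
    if aln.query_span <= 0:
        raise UndefinedSimilarityError(
            f"{aln.query_id}/{aln.subject_id}: zero-length alignment"
        )
    return 100.0 * aln.positives / aln.query_span


@dataclass
class SimilarityMatrix:
    """Symmetric percent-similarity matrix over an ordered id list."""

    ids: list[str]
    sim: np.ndarray

    def __post_init__(self) -> None:
        self.sim = np.asarray(self.sim, dtype=float)
        n = len(self.ids)
        if self.sim.shape != (n, n):
            raise ValueError("similarity matrix shape does not match id list")
        if not np.allclose(self.sim, self.sim.T):
            raise ValueError("similarity matrix is not symmetric")
        if self.sim.min() < 0 or self.sim.max() > 100 + 1e-9:
            raise ValueError("similarities must lie in [0, 100]")
        self._index = {record_id: i for i, record_id in enumerate(self.ids)}

    def value(self, id_a: str, id_b: str) -> float:
        return float(self.sim[self._index[id_a], self._index[id_b]])

    def to_frame(self) -> pd.DataFrame:
        """Long-format (id1, id2, similarity) table over unordered pairs."""
        rows = [
            (self.ids[i], self.ids[j], self.sim[i, j])
            for i, j in itertools.combinations(range(len(self.ids)), 2)
        ]
        return pd.DataFrame(rows, columns=["id1", "id2", "similarity"])

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.4f")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "SimilarityMatrix":
        frame = pd.read_csv(path, sep="\t")
        ids = sorted(set(frame["id1"]) | set(frame["id2"]))
        index = {record_id: i for i, record_id in enumerate(ids)}
        sim = np.full((len(ids), len(ids)), 0.0)
        np.fill_diagonal(sim, 100.0)
        for _, row in frame.iterrows():
            i, j = index[row["id1"]], index[row["id2"]]
            sim[i, j] = sim[j, i] = float(row["similarity"])
        return cls(ids=ids, sim=sim)


def symmetrize(raw_scores: Mapping[tuple[str, str], float],
               ids: Sequence[str] | None = None) -> SimilarityMatrix:
    """Average the two directed similarities of each pair into a matrix.

    ``raw_scores`` maps ordered (query_id, subject_id) pairs to percent
    similarities.  A missing orientation is treated as 0 with a warning;
    self-similarities are forced to 100.
    """
    import logging

    logger = logging.getLogger("hcoclass")
    if ids is None:
        ids = sorted({i for pair in raw_scores for i in pair})
    ids = list(ids)
    index = {record_id: i for i, record_id in enumerate(ids)}
    sim = np.zeros((len(ids), len(ids)))
    for (id_a, id_b) in itertools.combinations(ids, 2):
        forward = raw_scores.get((id_a, id_b))
        backward = raw_scores.get((id_b, id_a))
        if forward is None or backward is None:
            logger.warning("symmetrize: missing direction for pair (%s, %s)", id_a, id_b)
        mean = ((forward or 0.0) + (backward or 0.0)) / 2.0
        sim[index[id_a], index[id_b]] = sim[index[id_b], index[id_a]] = mean
    np.fill_diagonal(sim, 100.0)
    return SimilarityMatrix(ids=ids, sim=sim)


def align_all_pairs(records: Sequence[ProteinRecord],
                    scoring: ScoringScheme = DEFAULT_SCORING,
                    ) -> dict[tuple[str, str], PairAlignment]:
    """Local alignments for every ordered pair of distinct records."""
    table: dict[tuple[str, str], PairAlignment] = {}
    for query, subject in itertools.permutations(records, 2):
        table[(query.id, subject.id)] = local_align(query, subject, scoring)
    return table


def similarity_from_alignments(ids: Sequence[str],
                               alignments: Mapping[tuple[str, str], PairAlignment],
                               ) -> SimilarityMatrix:
    """Symmetrized similarity matrix from a directed alignment table."""
    raw = {
        pair: (similarity_percent(aln) if aln.query_span > 0 else 0.0)
        for pair, aln in alignments.items()
    }
    return symmetrize(raw, ids=ids)


def all_vs_all(records: Sequence[ProteinRecord],
               scoring: ScoringScheme = DEFAULT_SCORING) -> SimilarityMatrix:
    """Align every ordered pair and symmetrize, as in a reference-set
    self-comparison."""
    if len(records) < 2:
        raise ValueError("all_vs_all needs at least two records")
    alignments = align_all_pairs(records, scoring)
    return similarity_from_alignments([r.id for r in records], alignments)
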