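import math

import numpy as np
import pytest

from hcoclass.alignment import align_all_pairs, evalue, local_align
from hcoclass.classifier import (
    ConfusionTally,
    classify,
    global_precision_recall,
    leave_one_out,
    precision,
    rank_hits,
    recall,
)
from hcoclass.records import EnzymeType, ProteinRecord, ReferenceSet

AA = "ACDEFGHIKLMNPQRSTVWY"


def _random_seq(rng, length=120):
    return "".join(AA[i] for i in rng.integers(len(AA), size=length))


def _mutate(seq, positions, rng):
    out = list(seq)
    for pos in positions:
        out[pos] = AA[(AA.index(out[pos]) + 1 + int(rng.integers(18))) % len(AA)]
    return "".join(out)


@pytest.fixture()
def toy_refset():
    """Ten 120-mers in two families plus one engineered near-tie cluster."""
    rng = np.random.default_rng(30)
    base_b = _random_seq(rng)
    base_c = _random_seq(rng)
    records, labels = [], {}
    for k in range(3):
        seq = _mutate(base_b, rng.choice(120, size=3 * k, replace=False), rng)
        records.append(ProteinRecord(id=f"b{k}", residues=seq))
        labels[f"b{k}"] = EnzymeType.B
    for k in range(3):
        seq = _mutate(base_c, rng.choice(120, size=3 * k, replace=False), rng)
        records.append(ProteinRecord(id=f"c{k}", residues=seq))
        labels[f"c{k}"] = EnzymeType.C
    return ReferenceSet(records=records, labels=labels)


class TestRankHits:
    def test_identical_reference_ranks_first(self, toy_refset):
        query = ProteinRecord(id="q", residues=toy_refset["b0"].residues)
        hits = rank_hits(query, toy_refset)
        assert hits[0].subject_id == "b0"

    def test_equal_scores_tie_broken_by_id(self):
        seq = "MKWVTFISLLFLFSSAYSRGV" * 6
        refset = ReferenceSet(
            records=[ProteinRecord(id="z", residues=seq),
                     ProteinRecord(id="a", residues=seq)],
            labels={"z": EnzymeType.A1, "a": EnzymeType.A1},
        )
        query = ProteinRecord(id="q", residues=seq)
        hits = rank_hits(query, refset)
        assert [h.subject_id for h in hits] == ["a", "z"]

    def test_ranking_matches_independent_sort(self, toy_refset):
        rng = np.random.default_rng(31)
        query = ProteinRecord(id="q", residues=_mutate(toy_refset["c1"].residues,
                                                       rng.choice(120, 5), rng))
        hits = rank_hits(query, toy_refset)
        expected = []
        for subject in toy_refset.records:
            aln = local_align(query, subject)
            expected.append((aln.evalue, -aln.raw_score, subject.id))
        expected.sort()
        assert [h.subject_id for h in hits] == [e[2] for e in expected]


class TestClassify:
    def test_high_evalue_best_hit_is_no_hit(self):
        """Best hit above the 0.01 cutoff -> discarded, unclassified."""
        rng = np.random.default_rng(32)
        refset = ReferenceSet(
            records=[ProteinRecord(id=f"r{i}", residues=_random_seq(rng, 500))
                     for i in range(3)],
            labels={f"r{i}": EnzymeType.A1 for i in range(3)},
        )
        query = ProteinRecord(id="q", residues=_random_seq(rng, 25))
        result = classify(query, refset)
        best = min(local_align(query, s).evalue for s in refset.records)
        assert best >= 0.01  # engineered: short random query
        assert result.status == "no_hit"
        assert result.predicted is EnzymeType.UNCLASSIFIED

    def test_identity_transfer_top1(self, toy_refset):
        query = ProteinRecord(id="q", residues=toy_refset["c0"].residues)
        result = classify(query, toy_refset, "top1")
        assert result.status == "classified"
        assert result.predicted is EnzymeType.C

    def test_top3_label_disagreement_is_unclassified(self):
        """First three hits typed B, B, C -> unclassified."""
        rng = np.random.default_rng(33)
        base = _random_seq(rng, 150)
        records = [
            ProteinRecord(id="hit1", residues=base),
            ProteinRecord(id="hit2", residues=_mutate(base, [5], rng)),
            ProteinRecord(id="hit3", residues=_mutate(base, [10, 20], rng)),
            ProteinRecord(id="far", residues=_random_seq(rng, 150)),
        ]
        labels = {"hit1": EnzymeType.B, "hit2": EnzymeType.B,
                  "hit3": EnzymeType.C, "far": EnzymeType.A1}
        refset = ReferenceSet(records=records, labels=labels)
        query = ProteinRecord(id="q", residues=base)
        top3 = classify(query, refset, "top3")
        assert [h.type for h in top3.hits[:3]] == [EnzymeType.B, EnzymeType.B, EnzymeType.C]
        assert top3.status == "unclassified"
        assert classify(query, refset, "top2").predicted is EnzymeType.B

    def test_top1_never_unclassified(self, toy_refset):
        rng = np.random.default_rng(34)
        for record in toy_refset.records:
            query = ProteinRecord(id="q", residues=_mutate(record.residues,
                                                           rng.choice(120, 10), rng))
            result = classify(query, toy_refset, "top1")
            assert result.status in ("classified", "no_hit")

    def test_prefix_disagreement_persists_for_larger_k(self, toy_refset):
        """A query unclassified under top-k by disagreement within the first
        k hits stays unclassified for any larger k."""
        rng = np.random.default_rng(35)
        for record in toy_refset.records:
            query = ProteinRecord(id="q", residues=_mutate(record.residues,
                                                           rng.choice(120, 20), rng))
            previous_disagree = False
            for mode in ("top2", "top3", "top5"):
                result = classify(query, toy_refset, mode)
                if previous_disagree:
                    assert result.status == "unclassified"
                previous_disagree = previous_disagree or result.status == "unclassified"

    def test_empty_refset_is_error(self):
        query = ProteinRecord(id="q", residues="MKWVTF")
        with pytest.raises(ValueError):
            classify(query, ReferenceSet(records=[], labels={}))


class TestLeaveOneOut:
    def test_perfect_neighbors(self):
        seq_a = "MKWVTFISLLFLFSSAYSRGV" * 8
        seq_n = "GDVEKGKKIFIMKCSQCHTVE" * 8
        records = [ProteinRecord(id=f"a{i}", residues=seq_a) for i in range(2)]
        records += [ProteinRecord(id=f"n{i}", residues=seq_n) for i in range(2)]
        labels = {"a0": EnzymeType.A1, "a1": EnzymeType.A1,
                  "n0": EnzymeType.NOR, "n1": EnzymeType.NOR}
        tally = leave_one_out(ReferenceSet(records=records, labels=labels), "top1")
        assert tally.tp[EnzymeType.A1] == 2 and tally.tp[EnzymeType.NOR] == 2
        assert sum(tally.fp.values()) == 0 and sum(tally.fn.values()) == 0
        assert global_precision_recall(tally) == (1.0, 1.0)

    def test_mislabeled_member_matches_hand_enumeration(self):
        """Two identical A1s with one relabeled NOR: every same-sequence
        neighbor transfer goes wrong exactly as enumerable by hand."""
        seq_a = "MKWVTFISLLFLFSSAYSRGV" * 8
        seq_n = "GDVEKGKKIFIMKCSQCHTVE" * 8
        records = [ProteinRecord(id="a0", residues=seq_a),
                   ProteinRecord(id="a1", residues=seq_a),
                   ProteinRecord(id="n0", residues=seq_n),
                   ProteinRecord(id="n1", residues=seq_n)]
        labels = {"a0": EnzymeType.A1, "a1": EnzymeType.NOR,
                  "n0": EnzymeType.NOR, "n1": EnzymeType.NOR}
        tally = leave_one_out(ReferenceSet(records=records, labels=labels), "top1")
        assert tally.tp == {EnzymeType.A1: 0, EnzymeType.NOR: 2}
        assert tally.fp[EnzymeType.A1] == 1 and tally.fp[EnzymeType.NOR] == 1
        assert tally.fn[EnzymeType.A1] == 1 and tally.fn[EnzymeType.NOR] == 1
        assert precision(tally, EnzymeType.NOR) == pytest.approx(2 / 3)
        assert recall(tally, EnzymeType.A1) == 0.0

    def test_matches_independent_classify_loop(self, toy_refset):
        alignments = align_all_pairs(toy_refset.records)
        tally = leave_one_out(toy_refset, "top1", alignments=alignments)
        expected = ConfusionTally()
        for record in toy_refset.records:
            result = classify(record, toy_refset.without(record.id), "top1")
            expected.add(toy_refset.label_of(record.id), result)
        assert tally.tp == expected.tp
        assert tally.fp == expected.fp
        assert tally.fn == expected.fn

    def test_tally_conservation(self, toy_refset):
        tally = leave_one_out(toy_refset, "top3")
        assert tally.n_queries == len(toy_refset)


class TestPrecisionRecall:
    def _tally(self, tp, fp, fn):
        return ConfusionTally(tp={EnzymeType.B: tp}, fp={EnzymeType.B: fp},
                              fn={EnzymeType.B: fn})

    @pytest.mark.parametrize("tp,fp,expected", [(5, 0, 1.0), (3, 1, 0.75)])
    def test_precision_formula(self, tp, fp, expected):
        assert precision(self._tally(tp, fp, 0), EnzymeType.B) == expected

    @pytest.mark.parametrize("tp,fn,expected", [(5, 0, 1.0), (3, 2, 0.6)])
    def test_recall_formula(self, tp, fn, expected):
        assert recall(self._tally(tp, 0, fn), EnzymeType.B) == expected

    def test_empty_denominators_are_nan_not_zero_or_one(self):
        tally = self._tally(0, 0, 0)
        assert math.isnan(precision(tally, EnzymeType.B))
        assert math.isnan(recall(tally, EnzymeType.B))

    def test_global_micro_average(self):
        tally = ConfusionTally(
            tp={EnzymeType.A1: 8, EnzymeType.C: 2},
            fp={EnzymeType.A1: 1, EnzymeType.C: 0},
            fn={EnzymeType.A1: 0, EnzymeType.C: 1},
        )
        global_p, global_r = global_precision_recall(tally)
        assert global_p == pytest.approx(10 / 11)
        assert global_r == pytest.approx(10 / 11)
        assert 0.0 <= global_p <= 1.0 and 0.0 <= global_r <= 1.0
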