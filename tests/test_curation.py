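import numpy as np
import pytest

from hcoclass.curation import (
    check_metal_ligand_histidines,
    curate,
    deduplicate,
    filter_by_length,
    filter_by_ligands,
)
from hcoclass.errors import ConfigurationError
from hcoclass.records import EnzymeType, ProteinRecord
from hcoclass.simulate import FamilySpec, HIS_LIGANDS, generate_family

AA = "ACDEFGIKLMNPQRSTVWY"


def _random_record(record_id, length, rng, taxonomy=None):
    seq = "".join(AA[i] for i in rng.integers(len(AA), size=length))
    return ProteinRecord(id=record_id, residues=seq, taxonomy=taxonomy)


class TestLengthFilter:
    def test_boundary_length_is_kept(self):
        rng = np.random.default_rng(0)
        records = [_random_record(f"r{n}", n, rng) for n in (399, 400, 401)]
        report = filter_by_length(records, 400)
        assert sorted(report.kept) == ["r400", "r401"]
        assert report.discarded == [("r399", "too_short")]

    def test_empty_input(self):
        report = filter_by_length([], 400)
        assert report.kept == [] and report.discarded == []

    def test_matches_brute_force_on_random_lengths(self):
        rng = np.random.default_rng(1)
        lengths = rng.integers(300, 701, size=50)
        records = [_random_record(f"r{i:02d}", int(n), rng) for i, n in enumerate(lengths)]
        report = filter_by_length(records, 400)
        assert len(report.kept) == sum(1 for r in records if len(r) >= 400)
        assert report.all_ids == {r.id for r in records}

    def test_idempotent(self):
        rng = np.random.default_rng(2)
        records = [_random_record(f"r{i}", int(n), rng)
                   for i, n in enumerate(rng.integers(350, 450, size=20))]
        once = filter_by_length(records, 400)
        kept_records = [r for r in records if r.id in set(once.kept)]
        twice = filter_by_length(kept_records, 400)
        assert sorted(twice.kept) == sorted(once.kept)
        assert twice.discarded == []


class TestLigandCheck:
    def test_identity_passes(self, templates, profiles):
        anchor = profiles.hco.anchor
        record = ProteinRecord(id="copy", residues=anchor.residues)
        assert check_metal_ligand_histidines(record, anchor, HIS_LIGANDS)

    def test_single_mutated_ligand_fails(self, profiles):
        anchor = profiles.hco.anchor
        seq = list(anchor.residues)
        seq[HIS_LIGANDS[2] - 1] = "A"
        record = ProteinRecord(id="mut", residues="".join(seq))
        assert not check_metal_ligand_histidines(record, anchor, HIS_LIGANDS)

    def test_bad_configuration_rejected(self, profiles):
        anchor = profiles.hco.anchor
        record = ProteinRecord(id="q", residues=anchor.residues)
        with pytest.raises(ConfigurationError):
            check_metal_ligand_histidines(record, anchor, HIS_LIGANDS[:5])
        with pytest.raises(ConfigurationError):
            # position 1 is not a histidine in the anchor
            check_metal_ligand_histidines(record, anchor, (1,) + HIS_LIGANDS[:5])

    def test_acceptance_matches_planted_ground_truth(self, templates, profiles):
        """Records with 0..6 intact ligands are accepted iff all 6 remain."""
        rng = np.random.default_rng(3)
        template = templates[EnzymeType.A1]
        records, expected = [], []
        for k in range(20):
            n_broken = int(rng.integers(0, 7))
            broken = rng.choice(len(HIS_LIGANDS), size=n_broken, replace=False)
            seq = list(template.residues)
            for b in broken:
                seq[HIS_LIGANDS[b] - 1] = "L"
            records.append(ProteinRecord(id=f"q{k:02d}", residues="".join(seq)))
            expected.append(n_broken == 0)
        report = filter_by_ligands(records, [profiles.hco])
        kept = set(report.kept)
        assert [r.id in kept for r in records] == expected

    def test_any_anchor_suffices(self, templates, profiles):
        nor_like = ProteinRecord(id="n", residues=templates[EnzymeType.NOR].residues)
        report = filter_by_ligands([nor_like], profiles.anchors)
        assert report.kept == ["n"]


class TestDeduplicate:
    def test_exact_duplicates_collapse(self):
        rng = np.random.default_rng(4)
        a = _random_record("a", 450, rng)
        b = ProteinRecord(id="b", residues=a.residues)
        labels = {"a": EnzymeType.A1, "b": EnzymeType.A1}
        report = deduplicate([a, b], labels)
        assert report.kept == ["a"]
        assert report.discarded == [("b", "duplicate")]

    def test_same_species_same_type_collapses(self):
        rng = np.random.default_rng(5)
        a = _random_record("a", 450, rng, taxonomy="Paracoccus denitrificans PD1222")
        b = _random_record("b", 450, rng, taxonomy="Paracoccus denitrificans DSM413")
        labels = {"a": EnzymeType.A1, "b": EnzymeType.A1}
        report = deduplicate([a, b], labels)
        assert report.kept == ["a"]
        assert report.discarded == [("b", "redundant_strain")]

    def test_same_species_different_type_both_kept(self):
        rng = np.random.default_rng(6)
        a = _random_record("a", 450, rng, taxonomy="Vibrio cholerae O395")
        b = _random_record("b", 450, rng, taxonomy="Vibrio cholerae N16961")
        labels = {"a": EnzymeType.C, "b": EnzymeType.NOR}
        assert sorted(deduplicate([a, b], labels).kept) == ["a", "b"]

    def test_matches_brute_force_grouping(self):
        rng = np.random.default_rng(7)
        records, labels = [], {}
        for i in range(30):
            species = f"Genus species{int(rng.integers(5))}"
            enzyme_type = [EnzymeType.A1, EnzymeType.B][int(rng.integers(2))]
            if i % 7 == 0 and records:  # plant exact duplicates
                record = ProteinRecord(id=f"r{i:02d}", residues=records[0].residues,
                                       taxonomy=species)
            else:
                record = _random_record(f"r{i:02d}", 420, rng, taxonomy=f"{species} strain{i}")
            records.append(record)
            labels[record.id] = enzyme_type

        # oracle: first by id wins within residue groups, then strain groups
        kept_expected = []
        seen_seq, seen_group = set(), set()
        for record in sorted(records, key=lambda r: r.id):
            if record.residues in seen_seq:
                continue
            seen_seq.add(record.residues)
            group = (" ".join(record.taxonomy.split()[:2]), labels[record.id])
            if group in seen_group:
                continue
            seen_group.add(group)
            kept_expected.append(record.id)

        report = deduplicate(records, labels)
        assert sorted(report.kept) == sorted(kept_expected)
        assert report.all_ids == {r.id for r in records}


class TestComposition:
    def test_pipeline_conserves_ids_and_is_idempotent(self, templates, profiles):
        spec = FamilySpec(type=EnzymeType.B, template=templates[EnzymeType.B],
                          n=6, substitution_rate=0.1, seed=9)
        records = generate_family(spec)
        # plant one short fragment and one broken-ligand record
        records.append(ProteinRecord(id="short", residues=records[0].residues[:200]))
        broken = list(records[1].residues)
        for pos in HIS_LIGANDS:
            broken[pos - 1] = "A"
        records.append(ProteinRecord(id="noligs", residues="".join(broken)))
        labels = {r.id: EnzymeType.B for r in records}

        kept, report = curate(records, labels, profiles.anchors)
        assert {i for i, _ in report.discarded} >= {"short", "noligs"}
        assert report.all_ids == {r.id for r in records}
        kept_again, report_again = curate(kept, labels, profiles.anchors)
        assert [r.id for r in kept_again] == [r.id for r in kept]
        assert report_again.discarded == []
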