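"""Synthetic sequence families with planted fingerprints.

Real curated reference sets for this enzyme superfamily live behind
database accessions; everything here is generated so the whole pipeline is
testable offline.  Five ~520-residue type templates descend from one
random ancestor scaffold (so they are genuinely homologous and globally
alignable, like the real families) with ~50% divergence between types.
Each template carries its type's full fingerprint at the canonical
reference positions: D- and K-channel residues, Tyr-I/Tyr-II, the six
metal-liganding histidines, and — for the NOR template — both NOR motifs.

A family is the template plus independent per-site substitutions.  With
``protect_fingerprint`` the fingerprint role positions, the helix-VII
interval and a 24-residue window downstream of every histidine are left
untouched, and histidine is excluded from the substitution alphabet —
both NOR motifs are His-anchored, so this guarantees mutation neither
destroys a planted fingerprint nor creates a spurious one.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np

from .fingerprints import (
    AROMATIC,
    AnchorProfile,
    FingerprintProfiles,
    assign_type_by_fingerprint,
)
from .records import EnzymeType, ProteinRecord, ReferenceSet, read_fasta, write_fasta, write_labels

TEMPLATE_LENGTH = 520
#: Per-site divergence applied to the ancestor scaffold to derive each
#: type template (between-family divergence).
TEMPLATE_DIVERGENCE = 0.5
#: Seed that generated the packaged templates.
DESIGN_SEED = 7

D_CHANNEL_POSITIONS = {
    "Tyr35": 35, "Asn113": 113, "Asp124": 124, "Asn131": 131,
    "Ser134": 134, "Ser193": 193, "Asn199": 199, "Glu278": 278,
}
K_CHANNEL_POSITIONS = {"Tyr280": 280, "Ser291": 291, "Thr351": 351, "Lys354": 354}
HIS_LIGANDS = (94, 276, 325, 326, 411, 413)
TYRII_REGION = (430, 460)
_TYRII_PLANT = 445
_NOR_MOTIF1_START = 160   # H-x-Y-x-E at 160..164
_NOR_MOTIF2_START = 470   # H-H-x-F-W-x17-E at 470..492

_AA = "ACDEFGHIKLMNPQRSTVWY"
_AA_NO_H = _AA.replace("H", "")

_ROLE_RESIDUE = {
    "Tyr35": "Y", "Asn113": "N", "Asp124": "D", "Asn131": "N",
    "Ser134": "S", "Ser193": "S", "Asn199": "N", "Glu278": "E",
    "Tyr280": "Y", "Ser291": "S", "Thr351": "T", "Lys354": "K",
}

_MOTIF_1 = re.compile(rf"H.[{AROMATIC}].E")
_MOTIF_2 = re.compile(rf"HH.[{AROMATIC}][{AROMATIC}].{{17}}E")

#: Residues either side of each anchored feature kept identical across the
#: type templates.  Functional channel residues sit in conserved sequence
#: context in the real families; the conserved flanks are also what keeps
#: the anchor-numbering transfer (global alignment) exact at those sites.
_CONTEXT = 3


def _conserved_design_positions() -> frozenset[int]:
    """0-based positions excluded from between-template divergence."""
    anchored = (
        list(D_CHANNEL_POSITIONS.values())
        + list(K_CHANNEL_POSITIONS.values())
        + list(HIS_LIGANDS)
        + [_TYRII_PLANT]
    )
    conserved: set[int] = set()
    for pos in anchored:
        conserved.update(range(max(pos - 1 - _CONTEXT, 0),
                               min(pos + _CONTEXT, TEMPLATE_LENGTH)))
    return frozenset(conserved)


# ---------------------------------------------------------------------------
# Template design


def _force_mismatch(seq: list[str], pos_1based: int, wanted: str) -> None:
    if seq[pos_1based - 1] == wanted:
        seq[pos_1based - 1] = "A" if wanted != "A" else "G"


def _break_spurious_motifs(seq: list[str], frozen: set[int]) -> None:
    """Edit a non-NOR template until neither NOR motif matches.

    Every motif match is anchored at a histidine; the match is broken at
    its glutamate (-> Q) or, failing that, an aromatic position (-> L),
    never at a frozen (planted) position.
    """
    for _ in range(100):
        text = "".join(seq)
        match = _MOTIF_1.search(text) or _MOTIF_2.search(text)
        if match is None:
            return
        start = match.start()
        if match.re is _MOTIF_1:
            glu, aromatics = start + 4, [start + 2]
        else:
            glu, aromatics = start + 22, [start + 3, start + 4]
        if glu not in frozen:
            seq[glu] = "Q"
            continue
        for pos in aromatics:
            if pos not in frozen:
                seq[pos] = "L"
                break
        else:
            raise RuntimeError("cannot break spurious NOR motif without touching plants")
    raise RuntimeError("motif cleanup did not converge")


def design_templates(seed: int = DESIGN_SEED) -> dict[EnzymeType, ProteinRecord]:
    """Design the five type templates (the source of the packaged data).

    Deterministic in ``seed``.  The A1 template doubles as the HCO anchor
    and the NOR template as the NOR anchor of the default profiles.
    """
    rng = np.random.default_rng(seed)
    ancestor = [_AA_NO_H[i] for i in rng.integers(len(_AA_NO_H), size=TEMPLATE_LENGTH)]
    conserved = _conserved_design_positions()

    templates: dict[EnzymeType, ProteinRecord] = {}
    for enzyme_type in (EnzymeType.A1, EnzymeType.A2, EnzymeType.B,
                        EnzymeType.C, EnzymeType.NOR):
        seq = list(ancestor)
        mutate = rng.random(TEMPLATE_LENGTH) < TEMPLATE_DIVERGENCE
        draws = rng.integers(len(_AA_NO_H) - 1, size=TEMPLATE_LENGTH)
        for i in range(TEMPLATE_LENGTH):
            if mutate[i] and i not in conserved:
                options = _AA_NO_H.replace(seq[i], "")
                seq[i] = options[draws[i]]

        # No tyrosine in the helix-VII interval unless planted (Tyr-II is
        # the C-type discriminator).
        for pos in range(TYRII_REGION[0], TYRII_REGION[1] + 1):
            if seq[pos - 1] == "Y":
                seq[pos - 1] = "F"

        frozen: set[int] = set()  # 0-based positions that must not be edited
        for pos in HIS_LIGANDS:
            seq[pos - 1] = "H"
            frozen.add(pos - 1)

        if enzyme_type in (EnzymeType.A1, EnzymeType.A2):
            for role, pos in D_CHANNEL_POSITIONS.items():
                seq[pos - 1] = _ROLE_RESIDUE[role]
                frozen.add(pos - 1)
            if enzyme_type is EnzymeType.A2:
                seq[D_CHANNEL_POSITIONS["Glu278"] - 1] = "Y"
            for role, pos in K_CHANNEL_POSITIONS.items():
                seq[pos - 1] = _ROLE_RESIDUE[role]
                frozen.add(pos - 1)
        else:
            for role, pos in D_CHANNEL_POSITIONS.items():
                _force_mismatch(seq, pos, _ROLE_RESIDUE[role])
            if enzyme_type is EnzymeType.B:
                plants = {"Tyr280": "Y", "Ser291": "Y", "Thr351": "S", "Lys354": "T"}
            elif enzyme_type is EnzymeType.C:
                plants = {"Ser291": "Y", "Thr351": "S"}
                _force_mismatch(seq, K_CHANNEL_POSITIONS["Tyr280"], "Y")
                _force_mismatch(seq, K_CHANNEL_POSITIONS["Lys354"], "K")
                seq[_TYRII_PLANT - 1] = "Y"
                frozen.add(_TYRII_PLANT - 1)
            else:  # NOR
                plants = {}
                for role, pos in K_CHANNEL_POSITIONS.items():
                    _force_mismatch(seq, pos, _ROLE_RESIDUE[role])
            for role, residue in plants.items():
                pos = K_CHANNEL_POSITIONS[role]
                seq[pos - 1] = residue
                frozen.add(pos - 1)

        if enzyme_type is EnzymeType.NOR:
            s1 = _NOR_MOTIF1_START
            seq[s1 - 1], seq[s1 + 1], seq[s1 + 3] = "H", "Y", "E"
            frozen.update({s1 - 1, s1 + 1, s1 + 3})
            s2 = _NOR_MOTIF2_START
            seq[s2 - 1], seq[s2] = "H", "H"
            seq[s2 + 2], seq[s2 + 3] = "F", "W"
            seq[s2 + 21] = "E"
            frozen.update({s2 - 1, s2, s2 + 2, s2 + 3, s2 + 21})
        else:
            _break_spurious_motifs(seq, frozen)

        templates[enzyme_type] = ProteinRecord(
            id=f"TEMPLATE_{enzyme_type.value}",
            residues="".join(seq),
            description=f"synthetic {enzyme_type.value} type template",
        )

    _validate_templates(templates)
    return templates


def profiles_from_templates(templates: dict[EnzymeType, ProteinRecord]) -> FingerprintProfiles:
    """Anchor profiles anchored on the A1 and NOR templates."""
    hco = AnchorProfile(
        anchor=ProteinRecord(id="HCO_anchor", residues=templates[EnzymeType.A1].residues,
                             description="synthetic HCO anchor (A1-type fingerprint)"),
        his_ligands=HIS_LIGANDS,
        d_channel=dict(D_CHANNEL_POSITIONS),
        k_channel=dict(K_CHANNEL_POSITIONS),
        tyrII_region=TYRII_REGION,
    )
    nor = AnchorProfile(
        anchor=ProteinRecord(id="NOR_anchor", residues=templates[EnzymeType.NOR].residues,
                             description="synthetic NOR anchor"),
        his_ligands=HIS_LIGANDS,
    )
    return FingerprintProfiles(hco=hco, nor=nor)


def _validate_templates(templates: dict[EnzymeType, ProteinRecord]) -> None:
    profiles = profiles_from_templates(templates)
    for enzyme_type, template in templates.items():
        call = assign_type_by_fingerprint(template, profiles)
        if call.enzyme_type is not enzyme_type:
            raise RuntimeError(
                f"template design failure: {enzyme_type.value} template typed as "
                f"{call.enzyme_type} with evidence {call.evidence}"
            )


# ---------------------------------------------------------------------------
# Packaged templates


def load_templates() -> dict[EnzymeType, ProteinRecord]:
    """The packaged synthetic type templates."""
    with resources.as_file(
        resources.files("hcoclass.data").joinpath("synthetic_templates.fasta")
    ) as path:
        records = read_fasta(path)
    out: dict[EnzymeType, ProteinRecord] = {}
    for record in records:
        out[EnzymeType(record.id.removeprefix("TEMPLATE_"))] = record
    return out


# ---------------------------------------------------------------------------
# Family generation


@dataclass
class FamilySpec:
    """Recipe for one synthetic family."""

    type: EnzymeType
    template: ProteinRecord
    n: int
    substitution_rate: float
    protect_fingerprint: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.substitution_rate < 1):
            raise ValueError("substitution_rate must lie in [0, 1)")
        if self.n < 0:
            raise ValueError("n must be nonnegative")


def protected_positions(template: ProteinRecord) -> frozenset[int]:
    """0-based positions never mutated when the fingerprint is protected.

    Covers all channel-role positions, the helix-VII Tyr-II interval and a
    24-residue window starting at every histidine (both NOR motifs fit in
    such a window, so His-anchored motifs can be neither broken nor — as
    long as no new histidine is introduced — created).
    """
    protected: set[int] = set()
    for pos in list(D_CHANNEL_POSITIONS.values()) + list(K_CHANNEL_POSITIONS.values()):
        protected.add(pos - 1)
    protected.update(range(TYRII_REGION[0] - 1, TYRII_REGION[1]))
    length = len(template.residues)
    for i, residue in enumerate(template.residues):
        if residue == "H":
            protected.update(range(i, min(i + 24, length)))
    return frozenset(protected)


def generate_family(spec: FamilySpec) -> list[ProteinRecord]:
    """Mutated copies of the template, deterministic under the seed."""
    rng = np.random.default_rng(spec.seed)
    length = len(spec.template.residues)
    protected = protected_positions(spec.template) if spec.protect_fingerprint else frozenset()
    alphabet = _AA_NO_H if spec.protect_fingerprint else _AA
    template = spec.template.residues
    records = []
    for k in range(spec.n):
        hit = rng.random(length) < spec.substitution_rate
        draws = rng.integers(len(alphabet) - 1, size=length)
        seq = list(template)
        for i in range(length):
            if hit[i] and i not in protected:
                options = alphabet.replace(seq[i], "") if seq[i] in alphabet else alphabet
                seq[i] = options[draws[i] % len(options)]
        records.append(
            ProteinRecord(
                id=f"{spec.type.value}_{k:03d}",
                residues="".join(seq),
                description=f"synthetic {spec.type.value} family member",
            )
        )
    return records


def generate_gold_standard(per_type_n: int, rate: float, seed: int,
                           protect_fingerprint: bool = True) -> ReferenceSet:
    """A labelled five-family reference set (scaled-down gold standard)."""
    if per_type_n < 2:
        raise ValueError("per_type_n must be at least 2")
    templates = load_templates()
    rng = np.random.default_rng(seed)
    family_seeds = rng.integers(0, 2**31 - 1, size=len(templates))
    records: list[ProteinRecord] = []
    labels: dict[str, EnzymeType] = {}
    for family_seed, (enzyme_type, template) in zip(family_seeds, templates.items()):
        spec = FamilySpec(
            type=enzyme_type, template=template, n=per_type_n,
            substitution_rate=rate, protect_fingerprint=protect_fingerprint,
            seed=int(family_seed),
        )
        for record in generate_family(spec):
            records.append(record)
            labels[record.id] = enzyme_type
    return ReferenceSet(records=records, labels=labels)


def write_gold_standard(refset: ReferenceSet, out_dir: str | Path) -> tuple[Path, Path]:
    """Write a reference set as FASTA + labels TSV; returns the two paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    fasta = out_dir / "gold_standard.fasta"
    labels = out_dir / "gold_standard_labels.tsv"
    write_fasta(refset.records, fasta)
    write_labels(refset.labels, labels)
    return fasta, labels


# ---------------------------------------------------------------------------
# Random additive trees (test/benchmark input for neighbor joining)


def random_additive_tree(n_leaves: int, rng: np.random.Generator):
    """A random binary tree and its (additive) leaf distance matrix.

    Returns ``(skbio.TreeNode, skbio.DistanceMatrix)``; branch lengths are
    uniform on [0.1, 1.0], so the matrix is additive by construction.
    """
    from skbio import DistanceMatrix, TreeNode

    if n_leaves < 3:
        raise ValueError("need at least 3 leaves")
    nodes = [TreeNode(name=f"t{i}") for i in range(n_leaves)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        right = nodes.pop(j)
        left = nodes.pop(i)
        left.length = float(rng.uniform(0.1, 1.0))
        right.length = float(rng.uniform(0.1, 1.0))
        parent = TreeNode(children=[left, right])
        nodes.append(parent)
    tree = nodes[0]
    ids = sorted(tip.name for tip in tree.tips())
    dm = tree.tip_tip_distances(endpoints=ids)
    return tree, DistanceMatrix(dm.data, ids)
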