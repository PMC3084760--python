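"""Residue-fingerprint typing of oxygen- and NO-reductase subunits.

The four HCO types and the NORs are told apart by conserved residues of
the proton-conducting channels and by two NOR sequence motifs:

* A types carry the full D-channel (Asp124, Asn199, Asn113, Asn131, Tyr35,
  Ser134, Ser193 in the reference numbering); A1 additionally has Glu278
  where A2 has a tyrosine.
* A types carry the canonical K-channel (Lys354, Thr351, Ser291, Tyr280 —
  the cross-linked Tyr-I).
* B types lack the D-channel; their alternative K-channel keeps Tyr-I but
  replaces Lys354/Thr351/Ser291 with Thr/Ser/Tyr.
* C types lack the D-channel and Tyr-I; their alternative K-channel is
  built from Tyr-II (a tyrosine in helix VII) plus Ser and Tyr at the
  Thr351/Ser291 positions.
* NORs are recognized by two motifs, H-X-(Arom)-X-E and
  H-H-X-(Arom)-(Arom)-X17-E, with (Arom) = F/Y/W.

Channel residues are located on a query by transferring anchor numbering
through an end-to-end global alignment against a packaged anchor sequence.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import pandas as pd

from .alignment import DEFAULT_SCORING, ScoringScheme, global_alignment_columns
from .errors import ConfigurationError
from .records import EnzymeType, ProteinRecord, read_fasta

#: Aromatic residues for the (Arom) motif positions; His is not included.
AROMATIC = "FYW"

_MOTIF_1 = re.compile(rf"H.[{AROMATIC}].E")
_MOTIF_2 = re.compile(rf"HH.[{AROMATIC}][{AROMATIC}].{{17}}E")

#: Fixed evidence vocabulary of a fingerprint call.
FEATURES = (
    "d_channel",
    "d_channel_glu278",
    "d_channel_tyr_at_278",
    "k_channel_A",
    "alt_k_channel_B",
    "alt_k_channel_C",
    "tyrI",
    "tyrII",
    "nor_motif_1",
    "nor_motif_2",
)

#: D-channel roles that must all match for the channel to count as present
#: (position 278 is reported separately as the A1/A2 discriminator).
D_CHANNEL_CORE = ("Tyr35", "Asn113", "Asp124", "Asn131", "Ser134", "Ser193", "Asn199")
D_CHANNEL_ROLES = D_CHANNEL_CORE + ("Glu278",)
K_CHANNEL_ROLES = ("Tyr280", "Ser291", "Thr351", "Lys354")

_THREE_TO_ONE = {
    "Ala": "A", "Arg": "R", "Asn": "N", "Asp": "D", "Cys": "C", "Gln": "Q",
    "Glu": "E", "Gly": "G", "His": "H", "Ile": "I", "Leu": "L", "Lys": "K",
    "Met": "M", "Phe": "F", "Pro": "P", "Ser": "S", "Thr": "T", "Trp": "W",
    "Tyr": "Y", "Val": "V",
}


def role_residue(role: str) -> str:
    """Expected one-letter residue of a role like ``"Asp124"``."""
    try:
        return _THREE_TO_ONE[role[:3]]
    except KeyError:
        raise ConfigurationError(f"cannot parse role name {role!r}") from None


@dataclass
class AnchorProfile:
    """An annotated anchor sequence carrying the reference numbering.

    Positions are 1-based in anchor coordinates.  ``d_channel`` and
    ``k_channel`` map role names (e.g. ``"Asp124"``) to anchor positions;
    ``tyrII_region`` is the inclusive helix-VII interval searched for
    Tyr-II; ``his_ligands`` are the six histidines liganding the metal
    centers, used by the curation filter.
    """

    anchor: ProteinRecord
    his_ligands: tuple[int, ...] = ()
    d_channel: dict[str, int] = field(default_factory=dict)
    k_channel: dict[str, int] = field(default_factory=dict)
    tyrII_region: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        seq = self.anchor.residues
        for role_map in (self.d_channel, self.k_channel):
            for role, pos in role_map.items():
                if not (1 <= pos <= len(seq)):
                    raise ConfigurationError(f"{role}: position {pos} outside anchor")
                if seq[pos - 1] != role_residue(role):
                    raise ConfigurationError(
                        f"{role}: anchor has {seq[pos - 1]} at position {pos}, "
                        f"expected {role_residue(role)}"
                    )
        for pos in self.his_ligands:
            if not (1 <= pos <= len(seq)) or seq[pos - 1] != "H":
                raise ConfigurationError(f"histidine ligand position {pos} is not H in anchor")
        if self.tyrII_region is not None:
            lo, hi = self.tyrII_region
            if not (1 <= lo <= hi <= len(seq)):
                raise ConfigurationError("tyrII_region outside anchor bounds")

    @property
    def tyrI_position(self) -> int | None:
        return self.k_channel.get("Tyr280")


@dataclass
class PositionMap:
    """Anchor position (1-based) -> query position (1-based) or None (gap)."""

    pairs: dict[int, int | None]

    def __getitem__(self, anchor_pos: int) -> int | None:
        return self.pairs[anchor_pos]

    def residue(self, query: ProteinRecord | str, anchor_pos: int) -> str | None:
        """Query residue aligned to an anchor position, or None over a gap."""
        qpos = self.pairs.get(anchor_pos)
        if qpos is None:
            return None
        seq = query.residues if isinstance(query, ProteinRecord) else query
        return seq[qpos - 1]


def build_position_map(query: ProteinRecord | str, anchor: ProteinRecord | str,
                       scoring: ScoringScheme = DEFAULT_SCORING) -> PositionMap:
    """Transfer anchor numbering onto a query by global alignment."""
    columns = global_alignment_columns(query, anchor, scoring)
    pairs: dict[int, int | None] = {}
    for qi, ai in zip(columns[0], columns[1]):
        if ai >= 0:
            pairs[int(ai) + 1] = int(qi) + 1 if qi >= 0 else None
    return PositionMap(pairs=pairs)


# ---------------------------------------------------------------------------
# Evidence extraction


def _status(matched: bool, any_gap: bool) -> str:
    if matched:
        return "present"
    return "gap" if any_gap else "absent"


def _roles_match(query: ProteinRecord | str, profile: AnchorProfile,
                 pmap: PositionMap, roles: Mapping[str, str]) -> tuple[bool, bool]:
    """Whether each role position carries the wanted residue.

    ``roles`` maps role name -> wanted one-letter residue (which may differ
    from the role's own residue, as in the B/C alternative K-channels).
    Returns (all_matched, any_gap).
    """
    any_gap = False
    matched = True
    for role, wanted in roles.items():
        pos = profile.d_channel.get(role) or profile.k_channel.get(role)
        if pos is None:
            raise ConfigurationError(f"profile has no position for role {role!r}")
        residue = pmap.residue(query, pos)
        if residue is None:
            any_gap = True
            matched = False
        elif residue != wanted:
            matched = False
    return matched, any_gap


def detect_d_channel(query: ProteinRecord | str, profile: AnchorProfile,
                     pmap: PositionMap) -> dict[str, str]:
    """D-channel evidence: the seven core roles, plus what sits at 278."""
    wanted = {role: role_residue(role) for role in D_CHANNEL_CORE}
    matched, any_gap = _roles_match(query, profile, pmap, wanted)
    residue_278 = pmap.residue(query, profile.d_channel["Glu278"])
    return {
        "d_channel": _status(matched, any_gap),
        "d_channel_glu278": _status(residue_278 == "E", residue_278 is None),
        "d_channel_tyr_at_278": _status(residue_278 == "Y", residue_278 is None),
    }


def detect_k_channels(query: ProteinRecord | str, profile: AnchorProfile,
                      pmap: PositionMap) -> dict[str, str]:
    """K-channel evidence for the A, B and C variants plus Tyr-I/Tyr-II."""
    tyrI_res = pmap.residue(query, profile.k_channel["Tyr280"])
    tyrI = _status(tyrI_res == "Y", tyrI_res is None)

    # Tyr-II: any query residue aligned within the helix-VII interval is Y.
    lo, hi = profile.tyrII_region if profile.tyrII_region else (0, -1)
    tyrII_found = False
    tyrII_all_gap = True
    for anchor_pos in range(lo, hi + 1):
        residue = pmap.residue(query, anchor_pos) if anchor_pos in pmap.pairs else None
        if residue is not None:
            tyrII_all_gap = False
            if residue == "Y":
                tyrII_found = True
    tyrII = _status(tyrII_found, tyrII_all_gap)

    a_matched, a_gap = _roles_match(
        query, profile, pmap,
        {"Lys354": "K", "Thr351": "T", "Ser291": "S", "Tyr280": "Y"},
    )
    # B: Tyr-I retained; Lys354/Thr351/Ser291 replaced by Thr/Ser/Tyr.
    b_matched, b_gap = _roles_match(
        query, profile, pmap, {"Lys354": "T", "Thr351": "S", "Ser291": "Y"},
    )
    # C: Tyr-II plus Ser and Tyr at the Thr351/Ser291 positions.
    c_matched, c_gap = _roles_match(
        query, profile, pmap, {"Thr351": "S", "Ser291": "Y"},
    )
    return {
        "tyrI": tyrI,
        "tyrII": tyrII,
        "k_channel_A": _status(a_matched, a_gap),
        "alt_k_channel_B": _status(b_matched and tyrI == "present", b_gap),
        "alt_k_channel_C": _status(c_matched and tyrII == "present", c_gap),
    }


def match_nor_motifs(residues: str) -> tuple[bool, bool]:
    """Presence of the two NOR motifs.

    Motif 1: H, any, aromatic, any, E (contiguous).
    Motif 2: H, H, any, aromatic, aromatic, exactly 17 arbitrary residues, E.
    """
    if not residues:
        raise ValueError("empty residue string")
    return bool(_MOTIF_1.search(residues)), bool(_MOTIF_2.search(residues))


# ---------------------------------------------------------------------------
# Decision rule


@dataclass
class FingerprintCall:
    """Outcome of fingerprint typing: a type, or None when undetermined."""

    enzyme_type: EnzymeType | None
    evidence: dict[str, str]

    def __post_init__(self) -> None:
        unknown = set(self.evidence) - set(FEATURES)
        if unknown:
            raise ValueError(f"unknown evidence features: {sorted(unknown)}")

    @property
    def is_determined(self) -> bool:
        return self.enzyme_type is not None


def decide_type(evidence: Mapping[str, str]) -> EnzymeType | None:
    """Pure decision table over the evidence vector.

    Order: both NOR motifs -> NOR; D-channel with Glu278 -> A1; D-channel
    with Tyr at 278 -> A2; no D-channel but C-type alternative K-channel
    (with Tyr-II) -> C; no D-channel but B-type alternative K-channel
    (with Tyr-I) -> B; anything else is undetermined.
    """
    present = lambda key: evidence.get(key) == "present"
    if present("nor_motif_1") and present("nor_motif_2"):
        return EnzymeType.NOR
    if present("d_channel"):
        if present("d_channel_glu278"):
            return EnzymeType.A1
        if present("d_channel_tyr_at_278"):
            return EnzymeType.A2
        return None
    if present("alt_k_channel_C"):
        return EnzymeType.C
    if present("alt_k_channel_B"):
        return EnzymeType.B
    return None


@dataclass
class FingerprintProfiles:
    """The anchor profiles a fingerprint run is configured with.

    ``hco`` anchors the channel-residue numbering; ``nor`` carries the six
    His ligands of the NOR metal centers (used by curation's ligand check).
    """

    hco: AnchorProfile
    nor: AnchorProfile

    @property
    def anchors(self) -> list[AnchorProfile]:
        return [self.hco, self.nor]


def assign_type_by_fingerprint(query: ProteinRecord, profiles: FingerprintProfiles,
                               scoring: ScoringScheme = DEFAULT_SCORING) -> FingerprintCall:
    """Type a query from its channel residues and NOR motifs."""
    pmap = build_position_map(query, profiles.hco.anchor, scoring)
    evidence: dict[str, str] = {}
    evidence.update(detect_d_channel(query, profiles.hco, pmap))
    evidence.update(detect_k_channels(query, profiles.hco, pmap))
    motif_1, motif_2 = match_nor_motifs(query.residues)
    evidence["nor_motif_1"] = "present" if motif_1 else "absent"
    evidence["nor_motif_2"] = "present" if motif_2 else "absent"
    return FingerprintCall(enzyme_type=decide_type(evidence), evidence=evidence)


# ---------------------------------------------------------------------------
# Packaged default profiles


def _load_roles_table() -> pd.DataFrame:
    with resources.files("hcoclass.data").joinpath("synthetic_anchor_roles.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t", dtype=str)


def default_profiles() -> FingerprintProfiles:
    """Load the packaged synthetic anchor profiles.

    The anchors are designed sequences (not database entries) whose role
    positions reuse the canonical reference numbering, so e.g. Asp124 sits
    at anchor position 124.
    """
    data_dir = resources.files("hcoclass.data")
    with resources.as_file(data_dir.joinpath("synthetic_anchors.fasta")) as path:
        anchors = {r.id: r for r in read_fasta(path)}
    table = _load_roles_table()

    def build(anchor_id: str) -> AnchorProfile:
        rows = table[table["anchor_id"] == anchor_id]
        d_channel: dict[str, int] = {}
        k_channel: dict[str, int] = {}
        his: list[int] = []
        tyrII: tuple[int, int] | None = None
        for _, row in rows.iterrows():
            feature, role, position = row["feature"], row["role"], row["position"]
            if feature == "d_channel":
                d_channel[role] = int(position)
            elif feature == "k_channel":
                k_channel[role] = int(position)
            elif feature == "his_ligand":
                his.append(int(position))
            elif feature == "tyrII_region":
                lo, hi = position.split("-")
                tyrII = (int(lo), int(hi))
        return AnchorProfile(
            anchor=anchors[anchor_id],
            his_ligands=tuple(his),
            d_channel=d_channel,
            k_channel=k_channel,
            tyrII_region=tyrII,
        )

    return FingerprintProfiles(hco=build("HCO_anchor"), nor=build("NOR_anchor"))
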