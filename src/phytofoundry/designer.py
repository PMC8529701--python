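"""Combinatorial construct design, fusion-ORF translation and tag removal.

A design names sets of acceptors, optional N-terminal tags, coding sequences
and C-terminal tags; expansion yields every grammar-chainable combination
(e.g. 11 CDSs under 8 tag/acceptor configurations → 88 constructs).  The
fusion open reading frame of an assembled construct is located from the ATG
embedded in the AATG junction — extended upstream in frame when the acceptor
backbone itself contributes coding sequence (the MEKKI expression tag) — and
translated with the standard genetic code.  Known tag peptides are annotated
by exact motif search and the four supported proteases (TEV, thrombin,
Factor Xa, HRV 3C) are scanned so that tag-removal reactions can be planned
at a prescribed protease:target mass ratio.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import yaml
from Bio.SeqUtils import molecular_weight

from ._seq import translate_codon
from .errors import (
    DomainError,
    FrameError,
    PrematureStopError,
    UnknownProteaseError,
    UnresolvedPartError,
)
from .goldengate import AssembledConstruct, BSAI, EnzymeSpec, assemble
from .registry import Part, Registry

NONE_SENTINEL = "none"

#: Named peptide motifs annotated on fusion proteins.  The HiBiT 11-mer is
#: the vendor-published canonical peptide; MEKKI is the N-terminal
#: expression tag; the S-tag is the pancreatic ribonuclease A peptide; the
#: strep motif is the Strep-tag II core.
TAG_MOTIFS: dict[str, str] = {
    "NET": "MEKKI",
    "S-tag": "KETAAAKFERQHMDS",
    "HiBiT": "VSGWRLFKKIS",
    "strep": "WSHPQFEK",
}

#: protease -> (recognition motif regex, cut offset from match start).
#: The returned positions index the residue FOLLOWING the scissile bond.
PROTEASE_MOTIFS: dict[str, tuple[str, int]] = {
    "tev": (r"ENLYFQ(?=[GS])", 6),
    "thrombin": (r"LVPR(?=GS)", 4),
    "factor_xa": (r"I[ED]GR", 4),
    "hrv_3c": (r"LEVLFQ(?=GP)", 6),
}


@dataclass
class DesignSpec:
    """Combinatorial design: acceptors × N-tags × CDSs × C-tags.

    ``n_tags`` may contain the sentinel ``"none"`` for tagless constructs;
    those pair only with acceptors whose insert slot starts AATG.
    """

    acceptors: list[str]
    n_tags: list[str]
    cds_list: list[str]
    c_tags: list[str]

    @classmethod
    def from_dict(cls, data: dict) -> "DesignSpec":
        try:
            return cls(
                acceptors=list(data["acceptors"]),
                n_tags=list(data["n_tags"]),
                cds_list=list(data["cds_list"]),
                c_tags=list(data["c_tags"]),
            )
        except KeyError as exc:
            raise UnresolvedPartError(f"design spec missing key {exc}") from None

    @classmethod
    def from_file(cls, path) -> "DesignSpec":
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() == ".json":
            return cls.from_dict(json.loads(text))
        return cls.from_dict(yaml.safe_load(text))


@dataclass(frozen=True)
class ConstructOrder:
    """One expanded combination, ready for assembly."""

    construct_id: str
    acceptor: str
    n_tag: Optional[str]  # None for tagless
    cds: str
    c_tag: str

    @property
    def insert_ids(self) -> tuple[str, ...]:
        parts = [] if self.n_tag is None else [self.n_tag]
        return tuple(parts + [self.cds, self.c_tag])


def _resolve_part(registry: Registry, part_id: str) -> Part:
    try:
        return registry.get(part_id)
    except KeyError:
        raise UnresolvedPartError(f"design references unknown part {part_id!r}") from None


def _chainable(acceptor: Part, n_tag: Optional[Part], cds: Part, c_tag: Part) -> bool:
    head = acceptor.fusion_5
    if n_tag is not None:
        if n_tag.fusion_5 != head:
            return False
        head = n_tag.fusion_3
    return (
        cds.fusion_5 == head
        and c_tag.fusion_5 == cds.fusion_3
        and c_tag.fusion_3 == acceptor.fusion_3
    )


def expand_design(spec: DesignSpec, registry: Registry) -> list[ConstructOrder]:
    """Cross product of all grammar-chainable combinations.

    Deterministic order: lexicographic by (acceptor, n_tag, cds, c_tag)
    part_id, the tagless sentinel sorting first.  Returns an empty list
    (with a warning) when nothing chains.
    """
    acceptors = sorted(spec.acceptors)
    n_tags = sorted(set(spec.n_tags), key=lambda t: ("" if t == NONE_SENTINEL else t))
    cds_list = sorted(spec.cds_list)
    c_tags = sorted(spec.c_tags)

    orders: list[ConstructOrder] = []
    for acc_id in acceptors:
        acceptor = _resolve_part(registry, acc_id)
        for tag_id in n_tags:
            n_tag = None if tag_id == NONE_SENTINEL else _resolve_part(registry, tag_id)
            for cds_id in cds_list:
                cds = _resolve_part(registry, cds_id)
                for ct_id in c_tags:
                    c_tag = _resolve_part(registry, ct_id)
                    if _chainable(acceptor, n_tag, cds, c_tag):
                        orders.append(
                            ConstructOrder(
                                construct_id=f"c{len(orders) + 1:03d}",
                                acceptor=acc_id,
                                n_tag=None if n_tag is None else tag_id,
                                cds=cds_id,
                                c_tag=ct_id,
                            )
                        )
    if not orders:
        warnings.warn("design expands to zero grammar-compatible combinations", stacklevel=2)
    return orders


def assemble_order(
    order: ConstructOrder, registry: Registry, enzyme: EnzymeSpec = BSAI
) -> AssembledConstruct:
    """Assemble one expanded combination via the Golden Gate simulator."""
    acceptor = _resolve_part(registry, order.acceptor)
    inserts = [_resolve_part(registry, pid) for pid in order.insert_ids]
    return assemble(acceptor, inserts, enzyme)


# --- fusion ORF extraction ------------------------------------------------

@dataclass
class FusionProtein:
    """Translated fusion ORF with tag and protease-site annotations."""

    amino_acid_sequence: str
    length_aa: int
    mw_kda: float
    tags_present: list[tuple[str, int, int]] = field(default_factory=list)
    cleavage_sites: list[tuple[str, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.length_aa != len(self.amino_acid_sequence):
            raise ValueError("length_aa inconsistent with sequence")
        if not self.amino_acid_sequence.startswith("M"):
            raise FrameError("fusion protein must start with methionine")
        if self.mw_kda <= 0:
            raise ValueError("mw_kda must be positive")


def protein_mw_kda(sequence: str, monoisotopic: bool = False) -> float:
    """Chain molecular weight in kDa (average masses by default).

    Residue masses follow the standard amino-acid table with one water mass
    (18.0153 Da average) added per chain.
    """
    return molecular_weight(sequence, seq_type="protein", monoisotopic=monoisotopic) / 1000.0


_UPSTREAM_SCAN_LIMIT = 400  # codons; fixture backbones carry an in-frame stop


def extract_fusion_orf(construct: AssembledConstruct) -> FusionProtein:
    """Translate the fusion ORF of an assembled expression construct.

    The start anchor is the ATG embedded in the AATG junction.  When the
    acceptor backbone contributes an upstream in-frame coding stretch (the
    MEKKI expression tag), the start is moved to the 5'-most in-frame ATG
    reachable before an in-frame stop codon.  Translation then proceeds to
    the first stop; a stop falling before the C-tag span raises
    :class:`PrematureStopError`.
    """
    seq = construct.sequence
    n = len(seq)
    junctions = construct.junction_positions()
    aatg = [pos for overhang, pos in junctions if overhang == "AATG"]
    if len(aatg) != 1:
        raise FrameError(
            f"expected exactly one AATG junction, found {len(aatg)}"
        )
    anchor = (aatg[0] + 1) % n  # the ATG within AATG

    def codon_at(i: int) -> str:
        return seq[i % n] + seq[(i + 1) % n] + seq[(i + 2) % n]

    # Extend upstream in frame to the earliest ATG before a stop.
    start = anchor
    i = anchor - 3
    for _ in range(_UPSTREAM_SCAN_LIMIT):
        codon = codon_at(i)
        if translate_codon(codon) == "*":
            break
        if codon == "ATG":
            start = i % n
        i -= 3
    else:
        raise FrameError("no in-frame stop found upstream of the AATG junction")

    # C-tag span (for premature-stop detection).
    ctag_spans = [e.span for e in construct.parts_in_order if e.role == "c_tag"]

    residues: list[str] = []
    stop_dna_pos: Optional[int] = None
    i = start
    for _ in range(n // 3 + 1):
        aa = translate_codon(codon_at(i))
        if aa == "*":
            stop_dna_pos = i % n
            break
        residues.append(aa)
        i += 3
    if stop_dna_pos is None:
        raise FrameError("fusion ORF never reaches a stop codon")
    if ctag_spans:
        lo, hi = ctag_spans[0]
        inside = lo <= stop_dna_pos < hi or (hi > n and stop_dna_pos < hi - n)
        if not inside:
            raise PrematureStopError(
                f"in-frame stop at nt {stop_dna_pos}, upstream of the C-tag "
                f"span {ctag_spans[0]}",
                position=stop_dna_pos,
            )

    protein = "".join(residues)
    tags = [
        (name, m.start(), m.start() + len(motif))
        for name, motif in TAG_MOTIFS.items()
        for m in re.finditer(re.escape(motif), protein)
    ]
    sites = [
        (protease, pos)
        for protease in PROTEASE_MOTIFS
        for pos in find_protease_sites(protein, protease)
    ]
    fusion = FusionProtein(
        amino_acid_sequence=protein,
        length_aa=len(protein),
        mw_kda=protein_mw_kda(protein),
        tags_present=sorted(tags, key=lambda t: t[1]),
        cleavage_sites=sorted(sites, key=lambda s: (s[1], s[0])),
    )
    construct.orf_span = (start, (stop_dna_pos + 3) % n)
    return fusion


# --- protease planning ----------------------------------------------------

def find_protease_sites(protein, protease: str) -> list[int]:
    """0-based positions of the residue following each scissile bond.

    Motifs: TEV ``E-N-L-Y-F-Q↓(G|S)``, thrombin ``L-V-P-R↓G-S``,
    Factor Xa ``I-(E|D)-G-R↓``, HRV 3C ``L-E-V-L-F-Q↓G-P``.
    """
    seq = protein.amino_acid_sequence if isinstance(protein, FusionProtein) else str(protein)
    if not seq:
        raise DomainError("protein sequence is empty")
    try:
        pattern, offset = PROTEASE_MOTIFS[protease.lower()]
    except KeyError:
        raise UnknownProteaseError(
            f"unknown protease {protease!r}; supported: {sorted(PROTEASE_MOTIFS)}"
        ) from None
    return [m.start() + offset for m in re.finditer(pattern, seq)]


def cleave(protein, protease: str) -> list[str]:
    """Peptide products of cleaving at every site of ``protease``."""
    seq = protein.amino_acid_sequence if isinstance(protein, FusionProtein) else str(protein)
    cuts = find_protease_sites(seq, protease)
    edges = [0, *cuts, len(seq)]
    return [seq[a:b] for a, b in zip(edges[:-1], edges[1:]) if b > a]


@dataclass
class CleavagePlan:
    """Mass/volume bookkeeping for a protease tag-removal reaction."""

    target_mass_ug: float
    ratio_w_w: float  # protease:target
    protease_mass_ug: float
    protease_conc_ug_per_ul: float
    volumes: dict[str, float] = field(default_factory=dict)


def plan_cleavage_mix(
    target_mass_ug: float,
    ratio: float,
    protease_conc_ug_per_ul: float,
) -> CleavagePlan:
    """Plan a tag-removal mix at a protease:target w/w ratio.

    ``ratio`` is the protease:target mass ratio (1/130 for the toolkit's
    standard TEV reaction).
    """
    for name, value in (
        ("target_mass_ug", target_mass_ug),
        ("ratio", ratio),
        ("protease_conc_ug_per_ul", protease_conc_ug_per_ul),
    ):
        if not value > 0:
            raise DomainError(f"{name} must be > 0, got {value}")
    protease_mass = target_mass_ug * ratio
    return CleavagePlan(
        target_mass_ug=target_mass_ug,
        ratio_w_w=ratio,
        protease_mass_ug=protease_mass,
        protease_conc_ug_per_ul=protease_conc_ug_per_ul,
        volumes={"protease_ul": protease_mass / protease_conc_ug_per_ul},
    )


def expansion_table(orders: Sequence[ConstructOrder]):
    """Expansion result as a pandas DataFrame (CSV-ready)."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "construct_id": o.construct_id,
                "acceptor": o.acceptor,
                "n_tag": o.n_tag or NONE_SENTINEL,
                "cds": o.cds,
                "c_tag": o.c_tag,
            }
            for o in orders
        ]
    )
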