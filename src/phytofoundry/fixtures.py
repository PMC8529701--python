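"""Seeded synthetic-data generation for the whole toolkit.

The real toolkit plasmids are deposited in a public repository but their
nucleotide sequences are not bundled here; this module generates
grammar-correct SYNTHETIC stand-ins so every other module is testable
offline.  For each of the 37 toolkit records it emits a full circular
plasmid:

* tag/CDS parts as level-0 storage plasmids — the insert (fusion_5 + body +
  fusion_3) flanked by two inward-facing BsaI-class sites in the backbone,
  so digestion excises the insert with its fusion-site overhangs;
* acceptors as expression plasmids — a dropout cassette carrying two
  outward-cutting BsaI-class sites between the fusion sites, so digestion
  retains a site-free backbone;
* reporter/protease plasmids as simple closed ORFs.

Tag parts reverse-translate the printed tag peptides (MEKKI expression tag,
S-tag, the canonical 11-residue HiBiT, the strep motif, protease cleavage
sites); large folding tags (GST, MBP, TrxA, SUMO) and fluorescent proteins
are represented by short synthetic placeholder peptides.  All bodies are
free of BsaI-class and BpiI-class recognition sites on both strands and all
CDS bodies are stop-free in frame.  Every output is a deterministic
function of the seed.
"""

from __future__ import annotations

import itertools
import random
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from ._seq import CODON_TO_AA, revcomp
from .designer import TAG_MOTIFS, DesignSpec, NONE_SENTINEL, PROTEASE_MOTIFS
from .errors import DomainError, FixtureGenerationError
from .registry import Part, Registry, load_bundled_registry

# --- configuration --------------------------------------------------------

@dataclass
class FixtureConfig:
    """Knobs of the synthetic generator; the seed fixes all outputs."""

    seed: int = 42
    backbone_length: int = 2500
    cds_length_range: tuple[int, int] = (300, 900)
    noise_cv: float = 0.02

    def __post_init__(self) -> None:
        if self.backbone_length <= 0:
            raise DomainError("backbone_length must be positive")
        lo, hi = self.cds_length_range
        if not (0 < lo <= hi):
            raise DomainError("cds_length_range must be positive and ordered")
        if self.noise_cv < 0:
            raise DomainError("noise_cv must be >= 0")


# --- codon machinery ------------------------------------------------------

CODONS_BY_AA: dict[str, list[str]] = {}
for codon, aa in sorted(CODON_TO_AA.items()):
    CODONS_BY_AA.setdefault(aa, []).append(codon)
SENSE_CODONS: list[str] = sorted(CODON_TO_AA)

#: Recognition sites that must never occur inside generated bodies
#: (both toolkit enzymes, both strands).
FORBIDDEN_SITES = ("GGTCTC", "GAGACC", "GAAGAC", "GTCTTC")

_MAX_TRIES = 300


def _has_forbidden(seq: str) -> bool:
    return any(site in seq for site in FORBIDDEN_SITES)


def _random_clean_dna(rng: random.Random, n: int) -> str:
    """Random DNA of length n with no Type IIS recognition site, via repair."""
    s = "".join(rng.choices("ACGT", k=n))
    for _ in range(_MAX_TRIES * 5):
        idx = -1
        for motif in FORBIDDEN_SITES:
            j = s.find(motif)
            if j != -1 and (idx == -1 or j < idx):
                idx = j
        if idx == -1:
            return s
        s = s[:idx] + "".join(rng.choices("ACGT", k=6)) + s[idx + 6:]
    raise FixtureGenerationError("could not domesticate random sequence")


def _codons_for(peptide: str, rng: random.Random) -> list[str]:
    return [rng.choice(CODONS_BY_AA[aa]) for aa in peptide]


def _a_ending_codon(aa: str, rng: random.Random) -> str:
    options = [c for c in CODONS_BY_AA[aa] if c.endswith("A")]
    if not options:
        raise FixtureGenerationError(f"residue {aa} has no A-ending codon")
    return rng.choice(options)


def _g_starting_codon(aa: str, rng: random.Random) -> str:
    options = [c for c in CODONS_BY_AA[aa] if c.startswith("G")]
    if not options:
        raise FixtureGenerationError(f"residue {aa} has no G-starting codon")
    return rng.choice(options)


def _retry(builder, check, what: str):
    for _ in range(_MAX_TRIES):
        candidate = builder()
        if check(candidate):
            return candidate
    raise FixtureGenerationError(f"bounded retries exhausted building {what}")


# --- tag peptide catalogue ------------------------------------------------

HIBIT = TAG_MOTIFS["HiBiT"]  # VSGWRLFKKIS (11 residues)
S_TAG = TAG_MOTIFS["S-tag"]  # KETAAAKFERQHMDS
STREP = TAG_MOTIFS["strep"]  # WSHPQFEK

TEV_SITE = "ENLYFQG"
THROMBIN_SITE = "LVPRGS"
FACTOR_XA_SITE = "IEGR"
HRV_3C_SITE = "LEVLFQGP"

# Short synthetic placeholders for large folding/solubility tags (the first
# residues of the natural proteins; NOT the full-length tags).
GST_SYN = "SPILGYWKIKGL"
MBP_SYN = "KIEEGKLVIWIN"
TRXA_SYN = "SDKIIHLTDDSF"
SUMO_SYN = "SDSEVNQEAKPE"

#: N-terminal tag part -> encoded peptide (after the part's own initial Met).
NTAG_PEPTIDES: dict[str, str] = {
    "pEPYC0CM0258": HIBIT,
    "pEPQD0CM0541": GST_SYN + THROMBIN_SITE,
    "pEPQD0CM0542": HIBIT + "GG" + GST_SYN + THROMBIN_SITE,
    "pEPQD0CM0543": GST_SYN + TEV_SITE,
    "pEPQD0CM0544": MBP_SYN + FACTOR_XA_SITE,
    "pEPQD0CM0545": HIBIT + "GG" + MBP_SYN + FACTOR_XA_SITE,
    "pEPQD0CM0546": MBP_SYN + TEV_SITE,
    "pEPQD0CM0547": TRXA_SYN + TEV_SITE,
    "pEPQD0CM0548": HIBIT + "GG" + TRXA_SYN + TEV_SITE,
    "pEPQD0CM0549": SUMO_SYN + TEV_SITE,
    "pEPQD0CM0550": HIBIT + "GG" + SUMO_SYN + TEV_SITE,
    "pEPQD0CM0281": S_TAG + TEV_SITE,
    "pEPQD0CM0551": HIBIT + "GG" + S_TAG + TEV_SITE,
    "pEPMY0SP0002": "HHHHHH" + HRV_3C_SITE,
}

_ALL_MOTIFS = list(TAG_MOTIFS.values()) + [TEV_SITE, THROMBIN_SITE, FACTOR_XA_SITE, HRV_3C_SITE]


def _random_peptide(rng: random.Random, n: int) -> str:
    """Random peptide free of any named tag or protease motif."""
    residues = sorted(set(CODON_TO_AA.values()))

    def build() -> str:
        return "".join(rng.choice(residues) for _ in range(n))

    return _retry(build, lambda p: not any(m in p for m in _ALL_MOTIFS), "random peptide")


# --- frame conventions ----------------------------------------------------
#
# The reading-frame layout adopted by the generator (one consistent
# convention; see the package methods note):
#
#   CCAT junction: the start codon is CC[AT]|G — the last two bases of CCAT
#     plus the first base of the N-tag body, so N-tag bodies start with G and
#     close their final codon on the first A of the downstream AATG junction.
#   AATG junction: ATG is bases 2-4 of the overhang; tagless acceptors place
#     an in-frame stop (TAA) immediately upstream, NET acceptors place the
#     MEKKI coding stretch there instead.
#   TTCG junction: CDS bodies keep 3 | len(body), so the junction reads
#     TTC-G ("frame2"); the frame1 HiBiT C-tag instead expects the register
#     NNT-TCG and only pairs with frame1 CDSs.


def _ntag_body(peptide: str, rng: random.Random) -> str:
    """Body between CCAT and AATG encoding M + peptide (+ junction-closed codon)."""

    def build() -> str:
        codons = _codons_for(peptide[:-1], rng)
        last = _a_ending_codon(peptide[-1], rng)
        return "G" + "".join(codons) + last[:2]

    return _retry(build, lambda b: not _has_forbidden("CCAT" + b + "AATG"), "n_tag body")


def _cds_body_from_peptide(peptide: str, rng: random.Random) -> str:
    def build() -> str:
        return "".join(_codons_for(peptide, rng))

    return _retry(build, lambda b: not _has_forbidden("AATG" + b + "TTCG"), "cds body")


def _cds_body_random(rng: random.Random, length_nt: int) -> str:
    if length_nt % 3 != 0 or length_nt < 3:
        raise DomainError(f"CDS body length must be a positive codon multiple, got {length_nt}")

    def build() -> str:
        return "".join(rng.choice(SENSE_CODONS) for _ in range(length_nt // 3))

    return _retry(build, lambda b: not _has_forbidden("AATG" + b + "TTCG"), "random cds body")


def _ctag_body_frame2(peptide: str, rng: random.Random) -> str:
    """Body between TTCG and GCTT for the TTC-G register; ends with a stop."""

    def build() -> str:
        first = _g_starting_codon(peptide[0], rng)
        rest = _codons_for(peptide[1:], rng)
        return first[1:] + "".join(rest) + "TAA"

    return _retry(build, lambda b: not _has_forbidden("TTCG" + b + "GCTT"), "c_tag body")


def _ctag_body_frame1(peptide: str, rng: random.Random) -> str:
    """Body for the NNT-TCG register; the junction itself reads as Ser."""

    def build() -> str:
        return "".join(_codons_for(peptide, rng)) + "TAA"

    return _retry(build, lambda b: not _has_forbidden("TTCG" + b + "GCTT"), "c_tag body")


# --- plasmid assembly helpers ---------------------------------------------

_REC = "GGTCTC"  # BsaI-class recognition; spacer 1 nt, 4-nt overhang


def _count_sites(seq: str) -> tuple[int, int]:
    from .goldengate import BPII, BSAI, find_type2s_sites

    return (
        len(find_type2s_sites(seq, "circular", BSAI)),
        len(find_type2s_sites(seq, "circular", BPII)),
    )


def _level0_plasmid(insert: str, rng: random.Random, backbone_length: int) -> str:
    """Storage plasmid: insert flanked by inward-facing BsaI-class sites."""

    def build() -> str:
        backbone = _random_clean_dna(rng, backbone_length)
        return _REC + "A" + insert + "A" + revcomp(_REC) + backbone

    return _retry(build, lambda s: _count_sites(s) == (2, 0), "level-0 plasmid")


def _acceptor_plasmid(
    fusion_5: str,
    fusion_3: str,
    net: bool,
    rng: random.Random,
    backbone_length: int,
) -> str:
    """Expression plasmid: dropout with outward-cutting sites between fusion sites.

    The backbone tail immediately upstream of the fusion_5 junction fixes
    the reading frame: an in-frame TAA stop, preceded (for NET acceptors)
    by the MEKKI coding stretch so the expression tag fuses through the
    junction.
    """
    if net:
        tail = "TAA" + ("ATGGAAAAGAAAAT" if fusion_5 == "AATG" else "ATGGAAAAGAAAATAG")
    else:
        tail = "TA" if fusion_5 == "AATG" else "TAAT"

    def build() -> str:
        dropout = _random_clean_dna(rng, 300)
        backbone = _random_clean_dna(rng, backbone_length)
        return (
            fusion_5
            + "A"
            + revcomp(_REC)
            + dropout
            + _REC
            + "A"
            + fusion_3
            + backbone
            + tail
        )

    return _retry(build, lambda s: _count_sites(s) == (2, 0), "acceptor plasmid")


def _orf_plasmid(peptide: str, rng: random.Random, backbone_length: int) -> str:
    """Non-cloneable control plasmid: a closed ORF in a clean backbone."""

    def build() -> str:
        orf = "ATG" + "".join(_codons_for(peptide, rng)) + "TAA"
        return orf + _random_clean_dna(rng, backbone_length)

    return _retry(build, lambda s: _count_sites(s) == (0, 0), "control plasmid")


# --- public generators ----------------------------------------------------

def generate_registry_fixture(config: Optional[FixtureConfig] = None) -> Registry:
    """The 37-record toolkit registry with synthetic plasmid sequences.

    Metadata (ids, categories, fusion sites) comes from the bundled toolkit
    table; sequences are generated deterministically from ``config.seed``.
    """
    config = config or FixtureConfig()
    rng = random.Random(config.seed)
    registry = load_bundled_registry()
    registry.provenance["fixture_seed"] = config.seed

    gfp_placeholder = _random_peptide(rng, 60)
    tevp_placeholder = _random_peptide(rng, 60)

    ctag_peptides = {
        "pEPYC0CM0257": "GS" + HIBIT,
        "pEPQD0CM0027": "GSSGSSGSS" + _random_peptide(rng, 24) + STREP,
        "pEPQD0CM0028": "GSSGSSGSS" + STREP,
        "pEPQD0CM0029": "G" + STREP,
        "pEPQD0CM0030": "G",
    }

    for part in registry:
        if part.category == "n_tag":
            body = _ntag_body(NTAG_PEPTIDES[part.part_id], rng)
            insert = part.fusion_5 + body + part.fusion_3
            part.sequence = _level0_plasmid(insert, rng, config.backbone_length)
        elif part.category == "cds":
            peptide = gfp_placeholder if "GFP" in part.description else tevp_placeholder
            body = _cds_body_from_peptide(peptide, rng)
            insert = part.fusion_5 + body + part.fusion_3
            part.sequence = _level0_plasmid(insert, rng, config.backbone_length)
        elif part.category == "c_tag":
            if part.part_id == "pEPYC0CM0134":  # frame1 HiBiT variant
                body = _ctag_body_frame1(HIBIT, rng)
            else:
                body = _ctag_body_frame2(ctag_peptides[part.part_id], rng)
            insert = part.fusion_5 + body + part.fusion_3
            part.sequence = _level0_plasmid(insert, rng, config.backbone_length)
        elif part.is_acceptor:
            net = "N-term exp. tag" in part.description
            part.sequence = _acceptor_plasmid(
                part.fusion_5, part.fusion_3, net, rng, config.backbone_length
            )
        else:  # reporter / protease_reaction controls
            if part.part_id == "pEPQDKN0329":
                peptide = "EKKI" + tevp_placeholder + "GS" + HIBIT
            elif part.part_id == "pEPQDKN0729":
                peptide = "EKKI" + tevp_placeholder
            else:  # sfGFP-HiBiT reporters
                peptide = gfp_placeholder + "GS" + HIBIT
            part.sequence = _orf_plasmid(peptide, rng, config.backbone_length)
    return registry


def generate_random_cds(
    seed: int, length_nt: int, part_id: Optional[str] = None, backbone_length: int = 1500
) -> Part:
    """A random stop-free, domesticated CDS part of the given body length."""
    rng = random.Random(seed)
    body = _cds_body_random(rng, length_nt)
    insert = "AATG" + body + "TTCG"
    return Part(
        part_id=part_id or f"pSYNCDS{seed:04d}",
        category="cds",
        fusion_5="AATG",
        fusion_3="TTCG",
        description=f"synthetic random CDS ({length_nt} nt body), no stop codon",
        sequence=_level0_plasmid(insert, rng, backbone_length),
    )


#: The 8 tag/acceptor configurations of the expression screen: the MEKKI
#: expression-tag acceptor used tagless plus 7 N-terminal fusion tags in the
#: plain CCAT acceptor, all quantified through the frame2 C-terminal HiBiT.
SCREEN_ACCEPTORS = ["pEPQD0KN0024", "pEPQD0KN0245"]
SCREEN_N_TAGS = [
    NONE_SENTINEL,
    "pEPQD0CM0541",
    "pEPQD0CM0543",
    "pEPQD0CM0544",
    "pEPQD0CM0546",
    "pEPQD0CM0547",
    "pEPQD0CM0549",
    "pEPQD0CM0281",
]
SCREEN_C_TAGS = ["pEPYC0CM0257"]


def generate_ugt_panel(
    config: Optional[FixtureConfig] = None, n: int = 11
) -> list[Part]:
    """Synthetic stand-ins for the panel of plant glycosyltransferase CDSs."""
    config = config or FixtureConfig()
    rng = random.Random(config.seed + 1)
    lo, hi = config.cds_length_range
    parts = []
    for i in range(n):
        length = rng.randrange(lo // 3, hi // 3 + 1) * 3
        body = _cds_body_random(rng, length)
        insert = "AATG" + body + "TTCG"
        parts.append(
            Part(
                part_id=f"pSYNUGT{i + 1:02d}",
                category="cds",
                fusion_5="AATG",
                fusion_3="TTCG",
                description="synthetic glycosyltransferase CDS stand-in, no stop codon",
                sequence=_level0_plasmid(insert, rng, 1500),
            )
        )
    return parts


def design_fixture(
    config: Optional[FixtureConfig] = None, n_cds: int = 11
) -> tuple[Registry, DesignSpec]:
    """Registry + design spec for the tag-configuration expression screen.

    With the defaults this is the 11 CDS × 8 configuration screen (88
    constructs).
    """
    config = config or FixtureConfig()
    registry = generate_registry_fixture(config)
    ugts = generate_ugt_panel(config, n=n_cds)
    for part in ugts:
        registry.add(part)
    spec = DesignSpec(
        acceptors=list(SCREEN_ACCEPTORS),
        n_tags=list(SCREEN_N_TAGS),
        cds_list=[p.part_id for p in ugts],
        c_tags=list(SCREEN_C_TAGS),
    )
    return registry, spec


# --- level-0 part creation fixtures ---------------------------------------

_BPII_REC = "GAAGAC"  # BpiI/BbsI recognition; spacer 2 nt, 4-nt overhang


def level0_precursor(insert: str, seed: int, pad: int = 12):
    """A synthesized linear fragment: insert flanked by convergent BpiI sites.

    Digestion with the BpiI-class enzyme releases the insert with its
    fusion-site overhangs, ready for capture in a storage acceptor.
    """
    from .registry import SequenceRecord

    rng = random.Random(seed)

    def build() -> str:
        left = _random_clean_dna(rng, pad)
        right = _random_clean_dna(rng, pad)
        return left + _BPII_REC + "TT" + insert + "AA" + revcomp(_BPII_REC) + right

    seq = _retry(
        build,
        lambda s: s.count(_BPII_REC) == 1 and s.count(revcomp(_BPII_REC)) == 1,
        "level-0 precursor",
    )
    return SequenceRecord(id="synthesized_insert", sequence=seq, topology="linear")


def storage_acceptor_record(fusion_5: str, fusion_3: str, seed: int, backbone_length: int = 1500):
    """A universal storage plasmid with a BpiI dropout for level-0 capture."""
    from .goldengate import BPII, find_type2s_sites
    from .registry import SequenceRecord

    rng = random.Random(seed)

    def build() -> str:
        dropout = _random_clean_dna(rng, 200)
        backbone = _random_clean_dna(rng, backbone_length)
        return (
            fusion_5 + "TT" + revcomp(_BPII_REC) + dropout
            + _BPII_REC + "TT" + fusion_3 + backbone
        )

    seq = _retry(
        build,
        lambda s: len(find_type2s_sites(s, "circular", BPII)) == 2
        and _count_sites(s)[0] == 0,
        "storage acceptor",
    )
    return SequenceRecord(id="storage_acceptor", sequence=seq, topology="circular")


# --- plate-reader simulation ----------------------------------------------

#: Two-fold serial dilution of the control protein across the calibrated
#: range (2 nM down to ~0.016 nM), read in triplicate.
STANDARD_CONCS_NM = [2.0 / 2**i for i in range(8)]


def simulate_plate_reader(
    curve_params: tuple[float, float],
    sample_concs_um: Sequence[float],
    dilution: float,
    noise_cv: float = 0.02,
    seed: int = 0,
    standard_concs_nm: Sequence[float] = tuple(STANDARD_CONCS_NM),
    replicates: int = 3,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a luminescence read of standards plus diluted CFPS samples.

    Signal model: RLU = slope × [nM] + intercept, times multiplicative
    lognormal noise with the stated coefficient of variation.  Returns
    (standards, samples) frames; the samples frame carries the true diluted
    concentration for recovery checks.
    """
    slope, intercept = curve_params
    if dilution < 1:
        raise DomainError("dilution must be >= 1")
    if any(c <= 0 for c in sample_concs_um):
        raise DomainError("sample concentrations must be positive")
    rng = np.random.default_rng(seed)
    if noise_cv > 0:
        sigma = float(np.sqrt(np.log1p(noise_cv**2)))

        def noise() -> float:
            return float(rng.lognormal(mean=-sigma**2 / 2, sigma=sigma))
    else:
        def noise() -> float:
            return 1.0

    wells = (f"{r}{c}" for r, c in itertools.product("ABCDEFGH", range(1, 13)))
    std_rows = [
        {
            "well": next(wells),
            "conc_nM": conc,
            "signal": (slope * conc + intercept) * noise(),
        }
        for conc in standard_concs_nm
        for _ in range(replicates)
    ]
    sample_rows = []
    for i, conc_um in enumerate(sample_concs_um):
        diluted_nm = conc_um * 1000.0 / dilution
        sample_rows.append(
            {
                "well": next(wells),
                "sample": f"s{i + 1}",
                "true_conc_nM_diluted": diluted_nm,
                "signal": (slope * diluted_nm + intercept) * noise(),
            }
        )
    return pd.DataFrame(std_rows), pd.DataFrame(sample_rows)
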