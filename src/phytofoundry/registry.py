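"""Parts registry: loading, persistence and phytobrick fusion-site grammar.

A registry holds the toolkit's plasmids — expression acceptors, N-/C-terminal
tag parts, coding sequences and a few non-cloneable reporter/protease control
plasmids.  Cloneable parts carry two 4-nt fusion sites (Type IIS overhangs,
recorded as the top-strand 5'→3' 4-mer); the category grammar fixes which
pairs are legal so that any N-tag → CDS → C-tag chain ligates in order:

    n_tag  : CCAT → AATG
    cds    : AATG → TTCG
    c_tag  : TTCG → GCTT
    acceptor: (AATG | CCAT) → GCTT   (reading across the insert slot)

Reporter and protease-reaction plasmids have no fusion sites ("n/a") and are
excluded from assembly candidate sets.

The bundled toolkit table (37 records) ships as package data without
sequences; grammar-correct synthetic plasmid sequences are produced at run
time by :mod:`phytofoundry.fixtures`.
"""

from __future__ import annotations

import csv
import datetime
import json
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterator, Optional, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

from ._seq import is_dna, revcomp, translate
from .errors import (
    DomesticationError,
    DuplicatePartError,
    FusionSiteGrammarError,
    RegistrySchemaError,
    SequenceContentError,
    SequenceFormatError,
    SequenceUnavailableError,
    UnknownCategoryError,
)

# Controlled category vocabulary.
ACCEPTOR_CATEGORIES = frozenset(
    {"acceptor_ecoli_cfps", "acceptor_wheatgerm", "acceptor_ecoli_cell"}
)
CLONEABLE_CATEGORIES = ACCEPTOR_CATEGORIES | {"n_tag", "cds", "c_tag"}
NONCLONEABLE_CATEGORIES = frozenset({"reporter", "protease_reaction"})
CATEGORIES = CLONEABLE_CATEGORIES | NONCLONEABLE_CATEGORIES

#: category -> (allowed fusion_5 set, allowed fusion_3 set)
GRAMMAR: dict[str, tuple[frozenset[str], frozenset[str]]] = {
    "n_tag": (frozenset({"CCAT"}), frozenset({"AATG"})),
    "cds": (frozenset({"AATG"}), frozenset({"TTCG"})),
    "c_tag": (frozenset({"TTCG"}), frozenset({"GCTT"})),
    "acceptor_ecoli_cfps": (frozenset({"AATG", "CCAT"}), frozenset({"GCTT"})),
    "acceptor_wheatgerm": (frozenset({"AATG", "CCAT"}), frozenset({"GCTT"})),
    "acceptor_ecoli_cell": (frozenset({"AATG", "CCAT"}), frozenset({"GCTT"})),
}

NA_SENTINEL = "n/a"
_FUSION_RE = re.compile(r"^[ACGT]{4}$")

CSV_COLUMNS = [
    "part_id",
    "addgene_id",
    "category",
    "description",
    "fusion_5",
    "fusion_3",
    "resistance",
    "sequence",
]
_REQUIRED_COLUMNS = ["part_id", "category", "fusion_5", "fusion_3"]


@dataclass
class Part:
    """One phytobrick toolkit plasmid.

    ``sequence``, when present, is the full circular plasmid top strand: for
    tag/CDS parts the level-0 storage plasmid, for acceptors the expression
    plasmid itself.
    """

    part_id: str
    category: str
    fusion_5: str
    fusion_3: str
    description: str = ""
    sequence: Optional[str] = None
    addgene_id: Optional[int] = None
    resistance: Optional[str] = None

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise UnknownCategoryError(
                f"{self.part_id}: unknown category {self.category!r}"
            )
        self.fusion_5 = self.fusion_5.strip()
        self.fusion_3 = self.fusion_3.strip()
        for name, site in (("fusion_5", self.fusion_5), ("fusion_3", self.fusion_3)):
            if self.category in NONCLONEABLE_CATEGORIES:
                continue
            if not _FUSION_RE.match(site.upper()):
                raise FusionSiteGrammarError(
                    f"{self.part_id}: {name}={site!r} is not a DNA 4-mer"
                )
        if self.category in CLONEABLE_CATEGORIES:
            self.fusion_5 = self.fusion_5.upper()
            self.fusion_3 = self.fusion_3.upper()
        if self.sequence is not None:
            self.sequence = self.sequence.upper()

    @property
    def cloneable(self) -> bool:
        return self.category in CLONEABLE_CATEGORIES

    @property
    def is_acceptor(self) -> bool:
        return self.category in ACCEPTOR_CATEGORIES

    def require_sequence(self) -> str:
        if not self.sequence:
            raise SequenceUnavailableError(
                f"{self.part_id}: no sequence available in this registry"
            )
        return self.sequence


@dataclass
class Registry:
    """Ordered, id-unique collection of :class:`Part`."""

    parts: list[Part] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for part in self.parts:
            if part.part_id in seen:
                raise DuplicatePartError(f"duplicate part_id {part.part_id!r}")
            seen.add(part.part_id)
        self._index = {p.part_id: p for p in self.parts}

    def __len__(self) -> int:
        return len(self.parts)

    def __iter__(self) -> Iterator[Part]:
        return iter(self.parts)

    def __contains__(self, part_id: str) -> bool:
        return part_id in self._index

    def get(self, part_id: str) -> Part:
        try:
            return self._index[part_id]
        except KeyError:
            raise KeyError(f"part_id {part_id!r} not in registry") from None

    def add(self, part: Part) -> None:
        if part.part_id in self._index:
            raise DuplicatePartError(f"duplicate part_id {part.part_id!r}")
        self.parts.append(part)
        self._index[part.part_id] = part

    def by_category(self, category: str) -> list[Part]:
        if category not in CATEGORIES:
            raise UnknownCategoryError(f"unknown category {category!r}")
        return [p for p in self.parts if p.category == category]

    @property
    def cloneable_parts(self) -> list[Part]:
        """Assembly candidate set: reporter/protease rows are excluded."""
        return [p for p in self.parts if p.cloneable]


def _part_from_record(rec: dict, origin: str) -> Part:
    missing = [c for c in _REQUIRED_COLUMNS if not str(rec.get(c, "")).strip()]
    if missing:
        raise RegistrySchemaError(
            f"{origin}: record {rec.get('part_id') or rec!r} missing required "
            f"field(s): {', '.join(missing)}"
        )
    addgene = str(rec.get("addgene_id", "") or "").strip()
    sequence = str(rec.get("sequence", "") or "").strip() or None
    try:
        return Part(
            part_id=str(rec["part_id"]).strip(),
            category=str(rec["category"]).strip(),
            fusion_5=str(rec["fusion_5"]),
            fusion_3=str(rec["fusion_3"]),
            description=str(rec.get("description", "") or "").strip(),
            sequence=sequence,
            addgene_id=int(addgene) if addgene else None,
            resistance=str(rec.get("resistance", "") or "").strip() or None,
        )
    except FusionSiteGrammarError as exc:
        raise FusionSiteGrammarError(f"{origin}: {exc}") from None


def load_registry(path, format: Optional[str] = None) -> Registry:
    """Load a registry from CSV or JSON.

    ``format`` defaults to the file extension.  The load is order-preserving;
    duplicate ids, missing columns and malformed fusion sites all raise.
    """
    path = Path(path)
    if format is None:
        format = path.suffix.lstrip(".").lower() or "csv"
    if format not in {"csv", "json"}:
        raise RegistrySchemaError(f"unsupported registry format {format!r}")
    text = path.read_text()
    if not text.strip():
        raise RegistrySchemaError(f"{path}: empty registry file")
    if format == "csv":
        rows = list(csv.DictReader(text.splitlines()))
        if not rows:
            raise RegistrySchemaError(f"{path}: no records in CSV")
        header = rows[0].keys()
        missing = [c for c in _REQUIRED_COLUMNS if c not in header]
        if missing:
            raise RegistrySchemaError(
                f"{path}: missing column(s): {', '.join(missing)}"
            )
    else:
        try:
            rows = json.loads(text)
        except json.JSONDecodeError as exc:
            raise RegistrySchemaError(f"{path}: invalid JSON: {exc}") from None
        if not isinstance(rows, list) or not rows:
            raise RegistrySchemaError(f"{path}: JSON registry must be a nonempty list")
    parts = [_part_from_record(r, str(path)) for r in rows]
    return Registry(
        parts=parts,
        provenance={
            "source": str(path),
            "format": format,
            "loaded_at": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        },
    )


def write_registry(registry: Registry, path, format: Optional[str] = None) -> Path:
    """Persist a registry as CSV (Table-layout columns) or a JSON mirror."""
    path = Path(path)
    if format is None:
        format = path.suffix.lstrip(".").lower() or "csv"
    records = [
        {
            "part_id": p.part_id,
            "addgene_id": "" if p.addgene_id is None else p.addgene_id,
            "category": p.category,
            "description": p.description,
            "fusion_5": p.fusion_5,
            "fusion_3": p.fusion_3,
            "resistance": p.resistance or "",
            "sequence": p.sequence or "",
        }
        for p in registry
    ]
    if format == "csv":
        with path.open("w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=CSV_COLUMNS)
            writer.writeheader()
            writer.writerows(records)
    elif format == "json":
        path.write_text(json.dumps(records, indent=1) + "\n")
    else:
        raise RegistrySchemaError(f"unsupported registry format {format!r}")
    return path


def bundled_registry_path() -> Path:
    """Path of the packaged 37-record toolkit table (metadata only)."""
    return Path(resources.files("phytofoundry") / "data" / "toolkit_registry.csv")


def load_bundled_registry() -> Registry:
    return load_registry(bundled_registry_path(), format="csv")


# --- sequence record I/O --------------------------------------------------

@dataclass
class SequenceRecord:
    """A single DNA record with explicit topology (linear or circular)."""

    id: str
    sequence: str
    topology: str = "linear"
    annotations: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if self.topology not in {"linear", "circular"}:
            raise SequenceFormatError(f"invalid topology {self.topology!r}")

    def __len__(self) -> int:
        return len(self.sequence)


def parse_sequence_record(
    path, format: str, topology: Optional[str] = None, index: int = 0
) -> SequenceRecord:
    """Read one record from a GenBank or FASTA file.

    Topology comes from the GenBank LOCUS line when present; an explicit
    ``topology`` argument overrides it (FASTA carries no topology and
    defaults to linear).  Multi-record files are addressed by ``index``.
    """
    if format not in {"genbank", "fasta"}:
        raise SequenceFormatError(f"unsupported sequence format {format!r}")
    try:
        records = list(SeqIO.parse(str(path), format))
    except Exception as exc:
        raise SequenceFormatError(f"{path}: cannot parse as {format}: {exc}") from None
    if not records:
        raise SequenceContentError(f"{path}: no records found")
    try:
        rec = records[index]
    except IndexError:
        raise SequenceContentError(
            f"{path}: record index {index} out of range ({len(records)} records)"
        ) from None
    seq = str(rec.seq).upper()
    if not seq:
        raise SequenceContentError(f"{path}: record {rec.id!r} has an empty sequence")
    resolved = topology or rec.annotations.get("topology") or "linear"
    annotations = dict(rec.annotations)
    annotations.setdefault("description", rec.description)
    return SequenceRecord(id=rec.id, sequence=seq, topology=resolved, annotations=annotations)


def write_sequence_record(record: SequenceRecord, path, format: str) -> Path:
    """Write a :class:`SequenceRecord`; round-trips the sequence payload."""
    if format not in {"genbank", "fasta"}:
        raise SequenceFormatError(f"unsupported sequence format {format!r}")
    bio = _BioSeqRecord(Seq(record.sequence), id=record.id, description=record.annotations.get("description", ""))
    if format == "genbank":
        bio.annotations["topology"] = record.topology
        bio.annotations["molecule_type"] = record.annotations.get("molecule_type", "DNA")
    SeqIO.write([bio], str(path), format)
    return Path(path)


# --- part validation ------------------------------------------------------

@dataclass
class Violation:
    code: str  # grammar | domestication | frame | structure | alphabet
    message: str


@dataclass
class ValidationReport:
    part_id: str
    violations: list[Violation] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def add(self, code: str, message: str) -> None:
        self.violations.append(Violation(code, message))


def validate_part(part: Part, enzymes: Sequence = (), assembly_enzyme=None) -> ValidationReport:
    """Check a part against the fusion-site grammar and domestication rules.

    Violations reported:

    * ``grammar`` — fusion sites inconsistent with the category grammar;
    * ``structure`` — sequence present but no unique excisable fragment with
      the declared fusion sites (digestion with ``assembly_enzyme``);
    * ``domestication`` — internal recognition site of any enzyme in
      ``enzymes`` inside the part body, on either strand;
    * ``frame`` — CDS body with an in-frame stop codon before the 3' fusion
      site (toolkit CDS parts are stop-free by design).
    """
    from . import goldengate  # local import: goldengate imports Part

    if assembly_enzyme is None:
        assembly_enzyme = goldengate.BSAI
    if not enzymes:
        enzymes = (goldengate.BSAI, goldengate.BPII)

    report = ValidationReport(part_id=part.part_id)
    if part.category not in CATEGORIES:  # defensive; Part() already rejects
        raise UnknownCategoryError(f"unknown category {part.category!r}")

    if part.category in NONCLONEABLE_CATEGORIES:
        # Retained in the registry, excluded from assembly; only sanity-check
        # the n/a sentinels.
        for name, site in (("fusion_5", part.fusion_5), ("fusion_3", part.fusion_3)):
            if site.lower() != NA_SENTINEL and not _FUSION_RE.match(site.upper()):
                report.add("grammar", f"{name}={site!r} is neither a 4-mer nor 'n/a'")
        return report

    allowed_5, allowed_3 = GRAMMAR[part.category]
    if part.fusion_5 not in allowed_5:
        report.add(
            "grammar",
            f"fusion_5={part.fusion_5} not allowed for {part.category} "
            f"(expected one of {sorted(allowed_5)})",
        )
    if part.fusion_3 not in allowed_3:
        report.add(
            "grammar",
            f"fusion_3={part.fusion_3} not allowed for {part.category} "
            f"(expected one of {sorted(allowed_3)})",
        )

    if part.sequence is None:
        return report
    if not is_dna(part.sequence):
        report.add("alphabet", "sequence contains characters outside A/C/G/T")
        return report

    if part.is_acceptor:
        expected = (part.fusion_3, part.fusion_5)  # retained backbone, around the circle
    else:
        expected = (part.fusion_5, part.fusion_3)
    try:
        fragment = goldengate.excise(part, assembly_enzyme, expected=expected)
    except DomesticationError as exc:
        report.add("domestication", str(exc))
        return report
    except Exception as exc:
        report.add("structure", f"cannot excise with {assembly_enzyme.name}: {exc}")
        return report

    body = fragment.body
    for enzyme in enzymes:
        for probe in (enzyme.recognition, revcomp(enzyme.recognition)):
            if probe in body:
                report.add(
                    "domestication",
                    f"internal {enzyme.name} recognition site in part body",
                )
                break

    if part.category == "cds":
        insert = fragment.top_strand  # AATG + body + TTCG
        if insert[1:4] != "ATG":
            report.add("frame", "CDS does not begin at the AATG-embedded ATG")
        else:
            # Scan codons from the embedded ATG up to the 3' fusion site.
            coding = insert[1:len(insert) - 4]
            aa = translate(coding)
            if "*" in aa:
                pos = aa.index("*")
                report.add(
                    "frame",
                    f"in-frame stop codon at codon {pos} before the 3' fusion site",
                )
    return report
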