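"""Assay-planning calculators: glucoside formulas, MRM adduct m/z, probes.

Glycosyltransferase activity screens monitor the glucosylated product of a
small-molecule substrate by targeted mass spectrometry.  Glucosylation is a
condensation adding a glucosyl moiety (C6H10O5 — glucose minus water) to the
substrate; the MRM precursor m/z of a product is its monoisotopic neutral
mass plus the adduct mass shift (+H, +Na or +NH4, all singly charged),
rounded half-up to one decimal as entered on the instrument.

The probe-annealing check validates gel-shift (EMSA) probe designs: a
labeled primer must be the exact reverse complement of the 3' end of the
probe oligo so that polymerase fill-in yields a full-length double-stranded
probe.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Optional

from ._seq import is_dna, revcomp
from .errors import AlphabetError, ChemistryError, UnknownAdductError

#: Monoisotopic element masses (Da).
MONOISOTOPIC_MASS: dict[str, float] = {
    "C": 12.000000,
    "H": 1.0078250319,
    "N": 14.0030740052,
    "O": 15.9949146221,
    "S": 31.97207069,
    "P": 30.97376151,
    "Na": 22.98976928,
    "K": 38.9637064864,
}

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class MolecularFormula:
    """Element-count map with non-negative arithmetic."""

    counts: tuple[tuple[str, int], ...]

    @classmethod
    def from_counts(cls, counts: Mapping[str, int]) -> "MolecularFormula":
        clean = {el: int(n) for el, n in counts.items() if n}
        if not clean:
            raise ChemistryError("formula must have at least one nonzero count")
        if any(n < 0 for n in clean.values()):
            raise ChemistryError("element counts must be non-negative")
        unknown = set(clean) - set(MONOISOTOPIC_MASS)
        if unknown:
            raise ChemistryError(f"unsupported element(s): {sorted(unknown)}")
        return cls(counts=tuple(sorted(clean.items())))

    @classmethod
    def parse(cls, hill: str) -> "MolecularFormula":
        """Parse Hill notation, e.g. ``C16H28O6``."""
        if not hill or not re.fullmatch(r"(?:[A-Z][a-z]?\d*)+", hill):
            raise ChemistryError(f"cannot parse formula {hill!r}")
        counts: dict[str, int] = {}
        for element, digits in _FORMULA_TOKEN.findall(hill):
            if element:
                counts[element] = counts.get(element, 0) + (int(digits) if digits else 1)
        return cls.from_counts(counts)

    def as_dict(self) -> dict[str, int]:
        return dict(self.counts)

    def __getitem__(self, element: str) -> int:
        return self.as_dict().get(element, 0)

    def __add__(self, other: "MolecularFormula") -> "MolecularFormula":
        counts = self.as_dict()
        for el, n in other.counts:
            counts[el] = counts.get(el, 0) + n
        return MolecularFormula.from_counts(counts)

    def __sub__(self, other: "MolecularFormula") -> "MolecularFormula":
        counts = self.as_dict()
        for el, n in other.counts:
            counts[el] = counts.get(el, 0) - n
            if counts[el] < 0:
                raise ChemistryError(
                    f"subtraction yields negative {el} count"
                )
        return MolecularFormula.from_counts(counts)

    def __str__(self) -> str:  # Hill order: C, H, then alphabetical
        counts = self.as_dict()
        ordered = [el for el in ("C", "H") if el in counts]
        ordered += sorted(el for el in counts if el not in ("C", "H"))
        return "".join(
            f"{el}{counts[el] if counts[el] != 1 else ''}" for el in ordered
        )

    def monoisotopic_mass(self) -> float:
        return sum(MONOISOTOPIC_MASS[el] * n for el, n in self.counts)


#: Glucose minus water: the moiety added by glycosidic condensation.
GLUCOSYL = MolecularFormula.parse("C6H10O5")

# Substrates of the toolkit's glycosyltransferase activity screen.
GERANIOL = MolecularFormula.parse("C10H18O")
NEPETALACTOL = MolecularFormula.parse("C10H16O2")


@dataclass(frozen=True)
class AdductSpec:
    """A singly charged ESI adduct and its monoisotopic mass shift."""

    name: str
    mass_delta: float
    charge: int = 1


ADDUCTS: dict[str, AdductSpec] = {
    "M+H": AdductSpec("M+H", 1.007276),
    "M+Na": AdductSpec("M+Na", 22.989218),
    "M+NH4": AdductSpec("M+NH4", 18.033823),
}


def glucoside_formula(substrate: MolecularFormula) -> MolecularFormula:
    """Formula of the glucoside product: substrate + C6H10O5.

    The substrate must carry at least one O and one H (the condensation
    partner hydroxyl).
    """
    if substrate["O"] < 1 or substrate["H"] < 1:
        raise ChemistryError(
            f"{substrate}: glucosylation needs a hydroxyl (>=1 O and >=1 H)"
        )
    return substrate + GLUCOSYL


def adduct_mz(formula: MolecularFormula, adduct) -> float:
    """MRM precursor m/z: (monoisotopic mass + adduct shift) / charge.

    Rounded half-up to one decimal, the resolution at which MRM transitions
    are entered on a triple-quadrupole instrument.
    """
    if isinstance(adduct, str):
        try:
            adduct = ADDUCTS[adduct]
        except KeyError:
            raise UnknownAdductError(
                f"unknown adduct {adduct!r}; supported: {sorted(ADDUCTS)}"
            ) from None
    mz = (formula.monoisotopic_mass() + adduct.mass_delta) / adduct.charge
    return float(Decimal(repr(mz)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def check_probe_annealing(probe: str, primer: str) -> tuple[bool, Optional[int]]:
    """Does the primer anneal to the 3' end of the probe oligo?

    True iff the reverse complement of the primer equals the 3'-terminal
    substring of the probe of the primer's length; the position returned is
    the 0-based offset of the annealing site on the probe.
    """
    for name, seq in (("probe", probe), ("primer", primer)):
        if not seq or not is_dna(seq):
            raise AlphabetError(f"{name} must be a nonempty unambiguous DNA string")
    probe = probe.upper()
    primer = primer.upper()
    if len(primer) > len(probe):
        return False, None
    site = probe[len(probe) - len(primer):]
    if revcomp(primer) == site:
        return True, len(probe) - len(primer)
    return False, None
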