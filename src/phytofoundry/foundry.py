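"""Acoustic-dispenser picklist compilation for miniaturized CFPS reactions.

The reaction layout follows a two-step strategy on a 384-well source /
384-well destination pair: a bulk master-mix transfer (default 1735 nl) to
every destination well, then a cherry-pick step delivering the plasmid
template (default 26.6 ng) topped up with water to the sample volume
(default 265 nl), for a 2000-nl reaction at a final DNA concentration of
13.3 ng/µl.  Volumes are quantized to the instrument droplet (2.5 nl,
rounded half-up to the nearest quantum) and master-mix source wells are
drawn down against an explicit dead-volume budget, spilling to the next
source well when exhausted.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

from .errors import (
    DomainError,
    PicklistError,
    PlateCapacityError,
    SourceTooDiluteError,
)

PLATE_ROWS = "ABCDEFGHIJKLMNOP"  # 384-well geometry: rows A-P, columns 1-24
PLATE_COLS = 24
PLATE_WELLS = len(PLATE_ROWS) * PLATE_COLS

PICKLIST_HEADER = [
    "Source Plate Name",
    "Source Well",
    "Destination Plate Name",
    "Destination Well",
    "Transfer Volume",
]

#: Vendor software plate-type settings, recorded as free-text metadata only.
PLATE_TYPE_SETTINGS = {"master_mix": "384PP_AQ_SP2", "cherry_pick": "384PP_AQ_BP2"}


def well_name(row: int, col: int) -> str:
    return f"{PLATE_ROWS[row]}{col + 1}"


def parse_well(name: str) -> tuple[int, int]:
    row = PLATE_ROWS.index(name[0].upper())
    col = int(name[1:]) - 1
    if not 0 <= col < PLATE_COLS:
        raise DomainError(f"column out of range in well {name!r}")
    return row, col


def dest_wells_column_major(count: int) -> list[str]:
    """A1, B1, ..., P1, A2, ... — the deterministic destination fill order."""
    if count > PLATE_WELLS:
        raise PlateCapacityError(f"{count} destinations exceed {PLATE_WELLS} wells")
    return [well_name(i % 16, i // 16) for i in range(count)]


@dataclass
class ReactionLayoutConfig:
    """Volumes and masses governing one CFPS reaction layout (all nl / ng)."""

    reaction_volume_nl: float = 2000.0
    master_mix_volume_nl: float = 1735.0
    sample_volume_nl: float = 265.0
    dna_mass_ng: float = 26.6
    source_fill_nl: float = 65000.0
    droplet_quantum_nl: float = 2.5
    dead_volume_nl: float = 30000.0

    def __post_init__(self) -> None:
        values = {
            "reaction_volume_nl": self.reaction_volume_nl,
            "master_mix_volume_nl": self.master_mix_volume_nl,
            "sample_volume_nl": self.sample_volume_nl,
            "dna_mass_ng": self.dna_mass_ng,
            "source_fill_nl": self.source_fill_nl,
            "droplet_quantum_nl": self.droplet_quantum_nl,
        }
        for name, value in values.items():
            if not value > 0:
                raise DomainError(f"{name} must be > 0, got {value}")
        if self.dead_volume_nl < 0:
            raise DomainError("dead_volume_nl must be >= 0")
        if self.master_mix_volume_nl + self.sample_volume_nl != self.reaction_volume_nl:
            raise DomainError(
                "master_mix_volume_nl + sample_volume_nl must equal reaction_volume_nl"
            )

    @property
    def final_dna_conc_ng_per_ul(self) -> float:
        """Nominal final template concentration per reaction (ng/µl)."""
        return self.dna_mass_ng / (self.reaction_volume_nl / 1000.0)

    def quantize(self, volume_nl: float) -> float:
        """Round a volume half-up to the droplet quantum."""
        q = self.droplet_quantum_nl
        return math.floor(volume_nl / q + 0.5) * q


@dataclass
class SourceBudget:
    """How many transfers one source well supports above its dead volume."""

    fill_nl: float
    dead_volume_nl: float
    per_transfer_nl: float
    capacity: int


def source_capacity(
    fill_nl: float, dead_volume_nl: float, per_transfer_nl: float
) -> SourceBudget:
    """Transfers per source well: floor((fill − dead) / per_transfer)."""
    if fill_nl < 0 or dead_volume_nl < 0:
        raise DomainError("fill and dead volume must be >= 0")
    if not per_transfer_nl > 0:
        raise DomainError("per_transfer_nl must be > 0")
    usable = fill_nl - dead_volume_nl
    capacity = int(usable // per_transfer_nl) if usable > 0 else 0
    return SourceBudget(
        fill_nl=fill_nl,
        dead_volume_nl=dead_volume_nl,
        per_transfer_nl=per_transfer_nl,
        capacity=capacity,
    )


@dataclass(frozen=True)
class TransferEvent:
    """One acoustic transfer from a source well to a destination well."""

    source_plate: str
    source_well: str
    dest_plate: str
    dest_well: str
    volume_nl: float
    reagent: str  # master_mix | plasmid:<id> | water
    dna_mass_ng: float = 0.0


@dataclass
class PickList:
    """Ordered transfer events plus the layout they were compiled against."""

    transfers: list[TransferEvent] = field(default_factory=list)
    layout: ReactionLayoutConfig = field(default_factory=ReactionLayoutConfig)
    metadata: dict = field(default_factory=lambda: dict(PLATE_TYPE_SETTINGS))

    def __len__(self) -> int:
        return len(self.transfers)

    def dest_totals(self) -> dict[str, float]:
        totals: dict[str, float] = {}
        for t in self.transfers:
            totals[t.dest_well] = totals.get(t.dest_well, 0.0) + t.volume_nl
        return totals

    def source_withdrawals(self) -> dict[str, float]:
        totals: dict[str, float] = {}
        for t in self.transfers:
            totals[t.source_well] = totals.get(t.source_well, 0.0) + t.volume_nl
        return totals

    def total_dna_mass_ng(self) -> float:
        return sum(t.dna_mass_ng for t in self.transfers)

    @property
    def final_dna_conc_ng_per_ul(self) -> float:
        return self.layout.final_dna_conc_ng_per_ul


@dataclass(frozen=True)
class ConstructSource:
    """A plasmid stock available in a source well."""

    construct_id: str
    source_conc_ng_per_ul: float
    source_well: str


def _master_mix_wells(occupied: set[str]) -> Iterable[str]:
    """Master-mix wells allocated from column 24 leftwards, skipping stocks."""
    for col in range(PLATE_COLS - 1, -1, -1):
        for row in range(len(PLATE_ROWS)):
            name = well_name(row, col)
            if name not in occupied:
                yield name


def compile_cfps_picklist(
    constructs: Sequence[ConstructSource | tuple],
    layout: Optional[ReactionLayoutConfig] = None,
    replicates: int = 1,
    source_plate: str = "source",
    dest_plate: str = "destination",
) -> PickList:
    """Compile the two-step CFPS picklist for a set of plasmid templates.

    Per destination well: one master-mix transfer, one plasmid transfer of
    ``dna_mass_ng / source_conc`` (quantized) and a water top-up to the
    sample volume.  Destinations fill column-major from A1 with replicates
    adjacent; master-mix withdrawals respect the per-well source budget and
    spill to the next allocated well.
    """
    layout = layout or ReactionLayoutConfig()
    if replicates < 1:
        raise DomainError("replicates must be >= 1")
    constructs = [
        c if isinstance(c, ConstructSource) else ConstructSource(*c) for c in constructs
    ]
    if not constructs:
        raise PicklistError("no constructs to dispense")
    for c in constructs:
        if not c.source_conc_ng_per_ul > 0:
            raise DomainError(f"{c.construct_id}: source concentration must be > 0")
        parse_well(c.source_well)  # validates geometry

    n_dest = len(constructs) * replicates
    wells = dest_wells_column_major(n_dest)  # raises on overflow

    budget = source_capacity(
        layout.source_fill_nl, layout.dead_volume_nl, layout.master_mix_volume_nl
    )
    if budget.capacity < 1:
        raise DomainError(
            "master-mix source budget supports zero transfers "
            f"(fill {layout.source_fill_nl} nl, dead {layout.dead_volume_nl} nl)"
        )
    mm_wells = _master_mix_wells({c.source_well for c in constructs})
    mm_iter = iter(mm_wells)
    mm_current = next(mm_iter)
    mm_used = 0

    transfers: list[TransferEvent] = []
    dest_index = 0
    for construct in constructs:
        needed_nl = layout.dna_mass_ng / construct.source_conc_ng_per_ul * 1000.0
        plasmid_nl = layout.quantize(needed_nl)
        if plasmid_nl > layout.sample_volume_nl:
            raise SourceTooDiluteError(
                f"{construct.construct_id}: {construct.source_conc_ng_per_ul} ng/µl "
                f"needs {needed_nl:.0f} nl > sample volume "
                f"{layout.sample_volume_nl:.0f} nl"
            )
        water_nl = layout.sample_volume_nl - plasmid_nl
        for _ in range(replicates):
            dest = wells[dest_index]
            dest_index += 1
            if mm_used >= budget.capacity:
                mm_current = next(mm_iter)
                mm_used = 0
            transfers.append(
                TransferEvent(
                    source_plate=source_plate,
                    source_well=mm_current,
                    dest_plate=dest_plate,
                    dest_well=dest,
                    volume_nl=layout.master_mix_volume_nl,
                    reagent="master_mix",
                )
            )
            mm_used += 1
            transfers.append(
                TransferEvent(
                    source_plate=source_plate,
                    source_well=construct.source_well,
                    dest_plate=dest_plate,
                    dest_well=dest,
                    volume_nl=plasmid_nl,
                    reagent=f"plasmid:{construct.construct_id}",
                    dna_mass_ng=plasmid_nl / 1000.0 * construct.source_conc_ng_per_ul,
                )
            )
            if water_nl > 0:
                transfers.append(
                    TransferEvent(
                        source_plate=source_plate,
                        source_well="water",
                        dest_plate=dest_plate,
                        dest_well=dest,
                        volume_nl=water_nl,
                        reagent="water",
                    )
                )
    return PickList(transfers=transfers, layout=layout)


def _format_volume(volume_nl: float) -> str:
    """Integers print bare; half-quantum volumes print as x.5."""
    if float(volume_nl).is_integer():
        return str(int(volume_nl))
    return f"{volume_nl:.1f}"


def write_picklist_csv(picklist: PickList, path) -> Path:
    """Write the vendor cherry-pick CSV dialect (bit-exact header)."""
    if not picklist.transfers:
        raise PicklistError("refusing to write an empty picklist")
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(PICKLIST_HEADER)
        for t in picklist.transfers:
            writer.writerow(
                [t.source_plate, t.source_well, t.dest_plate, t.dest_well, _format_volume(t.volume_nl)]
            )
    return path


def read_picklist_csv(path) -> list[dict]:
    """Round-trip reader for the picklist CSV dialect."""
    with Path(path).open() as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames != PICKLIST_HEADER:
            raise PicklistError(f"unexpected header {reader.fieldnames}")
        return [dict(row) for row in reader]
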