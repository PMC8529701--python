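"""Type IIS digestion–ligation (Golden Gate) simulation.

Model
-----
A Type IIS enzyme binds a non-palindromic recognition sequence and cuts at a
fixed offset outside it, leaving 4-nt 5' single-stranded overhangs.  For a
sense-strand site whose recognition occupies ``[i, i + len(rec))``:

    top-strand cut   t = i + len(rec) + spacer_len
    bottom-strand cut    t + overhang_len

so the overhang, written as the top-strand 4-mer, is ``seq[t:t+4]``.  An
antisense site (reverse complement of the recognition at ``[q, q+len(rec))``)
cuts upstream: ``t = q - spacer_len - overhang_len``.

Fragments between cuts carry their boundary 4-mers as ``left_overhang`` /
``right_overhang``; ligation joins fragments wherever one fragment's right
overhang equals the next one's left overhang (exact top-strand identity), and
a chain closing on itself yields a circular product.  Because the recognition
sites of a correctly designed part face away from the retained fragment, a
successful assembly eliminates every site of the assembly enzyme — the
product cannot be re-cut, which is what makes one-pot digestion–ligation
reactions converge.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

from ._seq import circular_slice, min_rotation, require_dna, revcomp
from .errors import (
    AmbiguousAssemblyError,
    CutGeometryError,
    DomesticationError,
    IncompleteCycleError,
    UndigestibleError,
)
from .registry import Part, SequenceRecord


@dataclass(frozen=True)
class EnzymeSpec:
    """Geometry of a Type IIS restriction endonuclease.

    ``spacer_len`` is the number of nucleotides between the end of the
    recognition sequence and the top-strand cut; ``overhang_len`` is the
    length of the 5' overhang left behind.
    """

    name: str
    recognition: str
    spacer_len: int
    overhang_len: int = 4

    def __post_init__(self) -> None:
        object.__setattr__(self, "recognition", require_dna(self.recognition, "recognition"))
        if self.spacer_len < 0:
            raise ValueError("spacer_len must be >= 0")
        if self.overhang_len < 1:
            raise ValueError("overhang_len must be >= 1")
        if revcomp(self.recognition) == self.recognition:
            raise ValueError(
                f"{self.name}: palindromic recognition site has no defined cut direction"
            )


#: BsaI-class enzyme: GGTCTC(N1) — assembles level-0 parts into acceptors.
BSAI = EnzymeSpec(name="BsaI", recognition="GGTCTC", spacer_len=1, overhang_len=4)
#: BpiI (BbsI): GAAGAC(N2) — creates level-0 parts in the storage acceptor.
BPII = EnzymeSpec(name="BpiI", recognition="GAAGAC", spacer_len=2, overhang_len=4)

ENZYMES = {"bsai": BSAI, "bpii": BPII, "bbsi": BPII}


@dataclass(frozen=True)
class CutSite:
    """A double-strand break; ``position`` is the 0-based top-strand cut index."""

    position: int
    strand: str  # '+' if the recognition is on the top strand
    enzyme: EnzymeSpec


@dataclass
class Fragment:
    """A digestion product with its boundary overhangs as top-strand 4-mers.

    Blunt ends of linear molecules carry empty-string overhangs.
    """

    body: str
    left_overhang: str
    right_overhang: str
    source: str = ""

    @property
    def top_strand(self) -> str:
        return self.left_overhang + self.body + self.right_overhang

    def __len__(self) -> int:
        return len(self.top_strand)


@dataclass
class ProvenanceEntry:
    part_id: str
    span: tuple[int, int]  # half-open top-strand coordinates in the product
    role: str = "insert"  # backbone | n_tag | cds | c_tag | insert


@dataclass
class AssembledConstruct:
    """Circular product of a digestion–ligation cycle.

    ``sequence`` starts at the first fragment's left overhang; each
    provenance span covers that fragment's left overhang plus body, so the
    spans tile the circle and each junction 4-mer is counted once.
    """

    sequence: str
    parts_in_order: list[ProvenanceEntry] = field(default_factory=list)
    junctions: list[str] = field(default_factory=list)
    orf_span: Optional[tuple[int, int]] = None

    def __len__(self) -> int:
        return len(self.sequence)

    def canonical(self) -> str:
        """Lexicographically minimal rotation — the identity used in tests."""
        return min_rotation(self.sequence)

    def junction_positions(self) -> list[tuple[str, int]]:
        """(overhang, start index in ``sequence``) for every junction."""
        return [
            (overhang, entry.span[0])
            for overhang, entry in zip(self.junctions, self.parts_in_order)
        ]


def _resolve(record: Union[SequenceRecord, Part, str], topology: Optional[str]) -> tuple[str, str, str]:
    """Normalize input to (id, sequence, topology)."""
    if isinstance(record, SequenceRecord):
        return record.id, record.sequence, topology or record.topology
    if isinstance(record, Part):
        # Part sequences are full circular plasmids.
        return record.part_id, record.require_sequence(), topology or "circular"
    return "seq", require_dna(record), topology or "linear"


def find_type2s_sites(
    seq: str, topology: str, enzyme: EnzymeSpec
) -> list[CutSite]:
    """All cut sites of ``enzyme`` on both strands, sorted by cut position.

    For circular molecules, recognition sites spanning the origin are found
    and cut positions are reduced modulo the sequence length.  For linear
    molecules, sites whose cut or overhang would run off an end are dropped.
    """
    seq = require_dna(seq)
    if topology not in {"linear", "circular"}:
        raise ValueError(f"invalid topology {topology!r}")
    n = len(seq)
    rec = enzyme.recognition
    rc = revcomp(rec)
    reach = len(rec) + enzyme.spacer_len + enzyme.overhang_len
    if topology == "circular":
        window = seq + seq[: min(n, reach)]
    else:
        window = seq

    sites: set[tuple[int, str]] = set()
    for probe, strand in ((rec, "+"), (rc, "-")):
        start = window.find(probe)
        while start != -1:
            if start < n:  # circular duplicates start beyond n
                if strand == "+":
                    t = start + len(rec) + enzyme.spacer_len
                else:
                    t = start - enzyme.spacer_len - enzyme.overhang_len
                if topology == "circular":
                    sites.add((t % n, strand))
                elif 0 <= t and t + enzyme.overhang_len <= n:
                    sites.add((t, strand))
            start = window.find(probe, start + 1)
    return [
        CutSite(position=pos, strand=strand, enzyme=enzyme)
        for pos, strand in sorted(sites)
    ]


def digest(
    record: Union[SequenceRecord, Part, str],
    enzyme: EnzymeSpec,
    topology: Optional[str] = None,
) -> list[Fragment]:
    """Cut a molecule at every site of ``enzyme`` and return its fragments.

    Fragment order follows top-strand position (circular digests start at the
    first cut).  Joining consecutive fragments through their shared overhangs
    reconstructs the input (up to rotation for circular molecules).
    """
    source, seq, topo = _resolve(record, topology)
    sites = find_type2s_sites(seq, topo, enzyme)
    if not sites:
        raise UndigestibleError(f"{source}: no {enzyme.name} site on either strand")
    cuts = [s.position for s in sites]
    k = enzyme.overhang_len
    for a, b in zip(cuts, cuts[1:]):
        if b < a + k:
            raise CutGeometryError(f"{source}: overlapping cuts at {a} and {b}")
    n = len(seq)
    fragments: list[Fragment] = []
    if topo == "circular":
        if (cuts[0] + n) < cuts[-1] + k:
            raise CutGeometryError(
                f"{source}: overlapping cuts at {cuts[-1]} and {cuts[0]} (across origin)"
            )
        for a, b in zip(cuts, cuts[1:] + [cuts[0]]):
            body_len = (b - a - k) % n  # single cut -> n-k, adjacent cuts -> 0
            fragments.append(
                Fragment(
                    body="" if body_len == 0 else circular_slice(seq, a + k, a + k + body_len),
                    left_overhang=circular_slice(seq, a, a + k),
                    right_overhang=circular_slice(seq, b, b + k),
                    source=source,
                )
            )
    else:
        edges: list[Optional[int]] = [None, *cuts, None]
        for a, b in zip(edges[:-1], edges[1:]):
            left = "" if a is None else seq[a:a + k]
            right = "" if b is None else seq[b:b + k]
            body = seq[(0 if a is None else a + k):(len(seq) if b is None else b)]
            if left or right or body:  # drop empty terminal scraps
                fragments.append(
                    Fragment(body=body, left_overhang=left, right_overhang=right, source=source)
                )
    return fragments


def is_site_free(fragment: Fragment, enzyme: EnzymeSpec) -> bool:
    """True when the fragment carries no recognition site on either strand."""
    top = fragment.top_strand
    return enzyme.recognition not in top and revcomp(enzyme.recognition) not in top


def excise(part: Part, enzyme: EnzymeSpec, expected: Optional[tuple[str, str]] = None) -> Fragment:
    """Digest a part plasmid and return its retained (site-free) fragment.

    ``expected`` is the (left, right) overhang pair of the retained fragment:
    ``(fusion_5, fusion_3)`` for insert parts, ``(fusion_3, fusion_5)`` for
    acceptor backbones (reading around the circle).  A part whose body holds
    an internal recognition site has no fragment with the expected overhangs
    and raises :class:`DomesticationError`.
    """
    fragments = digest(part, enzyme)
    candidates = [f for f in fragments if is_site_free(f, enzyme)]
    if expected is not None:
        matching = [
            f for f in candidates
            if (f.left_overhang, f.right_overhang) == expected
        ]
        if not matching:
            if candidates:
                raise DomesticationError(
                    f"{part.part_id}: no site-free fragment with overhangs "
                    f"{expected[0]}→{expected[1]} (internal {enzyme.name} site "
                    f"or fusion-site mismatch)"
                )
            raise DomesticationError(
                f"{part.part_id}: every fragment retains a {enzyme.name} site"
            )
        if len(matching) > 1:
            raise AmbiguousAssemblyError(
                f"{part.part_id}: {len(matching)} fragments share overhangs "
                f"{expected[0]}→{expected[1]}"
            )
        return matching[0]
    if len(candidates) != 1:
        raise AmbiguousAssemblyError(
            f"{part.part_id}: expected exactly one site-free fragment, "
            f"found {len(candidates)}"
        )
    return candidates[0]


def _warn_palindromic(fragments: Sequence[Fragment]) -> set[int]:
    """Indices of fragments with self-complementary overhangs (excluded)."""
    bad: set[int] = set()
    for i, frag in enumerate(fragments):
        for ov in (frag.left_overhang, frag.right_overhang):
            if ov and revcomp(ov) == ov:
                warnings.warn(
                    f"fragment {i} ({frag.source or 'anonymous'}): palindromic "
                    f"overhang {ov} permits inverted ligation not modeled here; "
                    f"fragment excluded from ligation",
                    stacklevel=3,
                )
                bad.add(i)
    return bad


def _construct_from_cycle(
    fragments: Sequence[Fragment], cycle: Sequence[int], roles: Optional[dict[int, str]] = None
) -> AssembledConstruct:
    sequence_parts: list[str] = []
    provenance: list[ProvenanceEntry] = []
    junctions: list[str] = []
    pos = 0
    for idx in cycle:
        frag = fragments[idx]
        chunk = frag.left_overhang + frag.body
        sequence_parts.append(chunk)
        provenance.append(
            ProvenanceEntry(
                part_id=frag.source,
                span=(pos, pos + len(chunk)),
                role=(roles or {}).get(idx, "insert"),
            )
        )
        junctions.append(frag.left_overhang)
        pos += len(chunk)
    return AssembledConstruct(
        sequence="".join(sequence_parts),
        parts_in_order=provenance,
        junctions=junctions,
    )


def ligate_cyclic(fragments: Sequence[Fragment]) -> list[AssembledConstruct]:
    """Enumerate every distinct circular ligation product.

    Fragments chain wherever ``right_overhang`` equals the next fragment's
    ``left_overhang`` (top-strand identity); each fragment is used at most
    once per product; subsets may close on their own.  Products are reported
    up to rotation.  Fragments with palindromic overhangs are excluded with a
    warning.  An empty result means no closable cycle.
    """
    if len(fragments) < 2:
        raise ValueError("ligation requires at least 2 fragments")
    excluded = _warn_palindromic(fragments)
    usable = [i for i in range(len(fragments)) if i not in excluded]
    products: dict[str, AssembledConstruct] = {}

    def extend(start: int, chain: list[int], used: set[int]) -> None:
        tail = fragments[chain[-1]]
        if tail.right_overhang and tail.right_overhang == fragments[start].left_overhang:
            construct = _construct_from_cycle(fragments, chain)
            products.setdefault(construct.canonical(), construct)
            # A cycle may also extend further; keep searching.
        for j in usable:
            # Rotation dedupe: only fragments with index > start may extend.
            if j <= start or j in used:
                continue
            if tail.right_overhang and fragments[j].left_overhang == tail.right_overhang:
                extend(start, chain + [j], used | {j})

    for start in usable:
        frag = fragments[start]
        if not frag.left_overhang or not frag.right_overhang:
            continue  # blunt ends cannot take part in overhang ligation
        extend(start, [start], {start})
    return list(products.values())


def assemble(
    acceptor: Part,
    inserts: Sequence[Part],
    enzyme: EnzymeSpec = BSAI,
) -> AssembledConstruct:
    """One-pot digestion–ligation of level-0 insert parts into an acceptor.

    Digests every input plasmid with ``enzyme``, excises the retained
    fragment of each (acceptor backbone plus one fragment per insert) and
    requires a unique circular product that uses all of them exactly once.
    Raises :class:`IncompleteCycleError` (naming the missing junction) when
    the overhang chain cannot close, :class:`AmbiguousAssemblyError` when
    more than one product closes, and :class:`DomesticationError` when an
    insert carries an internal recognition site.
    """
    backbone = excise(acceptor, enzyme, expected=(acceptor.fusion_3, acceptor.fusion_5))
    fragments: list[Fragment] = [backbone]
    roles = {0: "backbone"}
    for insert in inserts:
        frag = excise(insert, enzyme, expected=(insert.fusion_5, insert.fusion_3))
        roles[len(fragments)] = insert.category if insert.category in {"n_tag", "cds", "c_tag"} else "insert"
        fragments.append(frag)

    excluded = _warn_palindromic(fragments)
    if excluded:
        raise AmbiguousAssemblyError(
            "palindromic overhang(s) would permit inverted ligation; aborting"
        )

    n = len(fragments)
    cycles: list[list[int]] = []

    def extend(chain: list[int], used: set[int]) -> None:
        if len(cycles) > 1:
            return
        tail = fragments[chain[-1]]
        if len(used) == n:
            if tail.right_overhang == fragments[0].left_overhang:
                cycles.append(chain)
            return
        for j in range(1, n):
            if j in used:
                continue
            if fragments[j].left_overhang == tail.right_overhang:
                extend(chain + [j], used | {j})

    extend([0], {0})

    if not cycles:
        # Walk the greedy chain to name the first junction nobody supplies.
        current = backbone.right_overhang
        available = {i: fragments[i] for i in range(1, n)}
        while True:
            nxt = [i for i, f in available.items() if f.left_overhang == current]
            if not nxt:
                break
            current = available.pop(nxt[0]).right_overhang
        raise IncompleteCycleError(
            f"no part supplies junction {current}→{backbone.left_overhang}",
            missing_junction=(current, backbone.left_overhang),
        )
    if len(cycles) > 1:
        raise AmbiguousAssemblyError(
            f"{len(cycles)}+ distinct circular products close the overhang chain"
        )

    construct = _construct_from_cycle(fragments, cycles[0], roles)
    leftover = find_type2s_sites(construct.sequence, "circular", enzyme)
    if leftover:
        raise DomesticationError(
            f"assembled product retains {len(leftover)} {enzyme.name} site(s)"
        )
    return construct
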