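"""Type IIS cut geometry, digestion, ligation enumeration and assembly."""

import random
from itertools import permutations

import pytest

from phytofoundry import fixtures, goldengate as gg
from phytofoundry._seq import min_rotation, revcomp, rotations_equal
from phytofoundry.errors import (
    AmbiguousAssemblyError,
    CutGeometryError,
    DomesticationError,
    IncompleteCycleError,
    UndigestibleError,
)
from phytofoundry.registry import Part, SequenceRecord


def brute_force_sites(seq, topology, enzyme):
    """Independent oracle: scan every substring on both strands and apply
    the enzyme geometry by hand."""
    n = len(seq)
    doubled = seq + seq if topology == "circular" else seq
    rec, rc = enzyme.recognition, revcomp(enzyme.recognition)
    found = set()
    for i in range(n if topology == "circular" else n - len(rec) + 1):
        window = doubled[i:i + len(rec)]
        if window == rec:
            t = i + len(rec) + enzyme.spacer_len
            if topology == "circular":
                found.add((t % n, "+"))
            elif t + enzyme.overhang_len <= n:
                found.add((t, "+"))
        if window == rc:
            t = i - enzyme.spacer_len - enzyme.overhang_len
            if topology == "circular":
                found.add((t % n, "-"))
            elif t >= 0:
                found.add((t, "-"))
    return sorted(found)


def brute_force_ligation_products(fragments):
    """Independent oracle: permutation search over every fragment subset."""
    seqs = set()
    n = len(fragments)
    for r in range(1, n + 1):
        for perm in permutations(range(n), r):
            frs = [fragments[i] for i in perm]
            if any(not f.left_overhang or not f.right_overhang for f in frs):
                continue
            if all(
                frs[i].right_overhang == frs[(i + 1) % r].left_overhang
                for i in range(r)
            ):
                seqs.add(min_rotation("".join(f.left_overhang + f.body for f in frs)))
    return seqs


class TestFindSites:
    def test_sequence_without_sites_yields_empty(self):
        seq = "ATATATACCCCGGGGAAAATTTT"
        assert gg.find_type2s_sites(seq, "linear", gg.BSAI) == []
        assert gg.find_type2s_sites(seq, "linear", gg.BPII) == []

    def test_single_bpii_site_cut_position_by_hand(self):
        # GAAGAC ends at index 16; spacer 2 -> top cut at 18, overhang CATG.
        seq = "ACGTACGTAC" + "GAAGAC" + "TT" + "CATG" + "AAATTTGGGCCCAAATTTG"
        sites = gg.find_type2s_sites(seq, "linear", gg.BPII)
        assert [(s.position, s.strand) for s in sites] == [(18, "+")]
        assert seq[18:22] == "CATG"

    def test_antisense_site_cut_position_by_hand(self):
        # GTCTTC (revcomp of GAAGAC) at index 14: cut = 14 - 2 - 4 = 8.
        seq = "ACGTACGTACGTAC" + "GTCTTC" + "ACGTACGTACGT"
        sites = gg.find_type2s_sites(seq, "linear", gg.BPII)
        assert [(s.position, s.strand) for s in sites] == [(8, "-")]

    def test_circular_site_spanning_origin(self):
        # GGTCTC split: GG at the end, TCTC at the start.
        seq = "TCTCAAATTTCCCGGGAAATTTCCCAAAGG"
        sites = gg.find_type2s_sites(seq, "circular", gg.BSAI)
        assert len(sites) == 1
        # Rotating the molecule must shift the cut position accordingly.
        shift = 10
        rotated = seq[shift:] + seq[:shift]
        rotated_sites = gg.find_type2s_sites(rotated, "circular", gg.BSAI)
        assert rotated_sites[0].position == (sites[0].position - shift) % len(seq)

    @pytest.mark.parametrize("seed", range(10))
    @pytest.mark.parametrize("topology", ["linear", "circular"])
    def test_matches_bruteforce_enumeration(self, seed, topology):
        rng = random.Random(seed)
        seq = "".join(rng.choices("ACGT", k=200))
        # salt with deliberate sites to make hits likely
        for motif in ("GGTCTC", "GAGACC", "GAAGAC"):
            pos = rng.randrange(0, 180)
            seq = seq[:pos] + motif + seq[pos + 6:]
        for enzyme in (gg.BSAI, gg.BPII):
            got = [(s.position, s.strand) for s in gg.find_type2s_sites(seq, topology, enzyme)]
            assert got == brute_force_sites(seq, topology, enzyme)


class TestDigest:
    def test_level0_part_yields_insert_and_backbone(self, fixture_registry):
        part = fixture_registry.get("pEPQD0CM0296")
        fragments = gg.digest(part, gg.BSAI)
        assert len(fragments) == 2
        overhangs = {(f.left_overhang, f.right_overhang) for f in fragments}
        assert (part.fusion_5, part.fusion_3) in overhangs  # insert
        assert (part.fusion_3, part.fusion_5) in overhangs  # backbone

    def test_reassembling_fragments_reproduces_input(self, fixture_registry):
        for part_id in ("pEPQD0CM0296", "pEPQD0KN0245", "pEPYC0CM0257"):
            part = fixture_registry.get(part_id)
            fragments = gg.digest(part, gg.BSAI)
            rebuilt = "".join(f.left_overhang + f.body for f in fragments)
            assert rotations_equal(rebuilt, part.sequence)

    def test_plasmid_without_sites_is_undigestible(self):
        record = SequenceRecord(id="p", sequence="ATATACGCGC" * 30, topology="circular")
        with pytest.raises(UndigestibleError):
            gg.digest(record, gg.BSAI)

    def test_single_cut_linearizes_circle(self):
        seq = "AAACCC" + "GGTCTC" + "A" + "TTTT" + "GGGAAACCCTTT"
        record = SequenceRecord(id="p", sequence=seq, topology="circular")
        fragments = gg.digest(record, gg.BSAI)
        assert len(fragments) == 1
        frag = fragments[0]
        assert frag.left_overhang == frag.right_overhang == "TTTT"
        assert len(frag.body) == len(seq) - 4

    def test_overlapping_cuts_are_geometry_error(self):
        # sense cut at 7 and antisense cut at 5 overlap (< overhang length)
        seq = "GGTCTC" + "ACGT" + "GAGACC" + "ACGTACGTACGTACGTACGT"
        record = SequenceRecord(id="p", sequence=seq, topology="linear")
        with pytest.raises(CutGeometryError):
            gg.digest(record, gg.BSAI)

    def test_linear_digest_keeps_blunt_end_fragments(self):
        seq = "ACGTACGTAC" + "GAAGAC" + "TT" + "CATG" + "AAATTTGGGCCCAAATTTG"
        fragments = gg.digest(seq, gg.BPII, topology="linear")
        assert len(fragments) == 2
        assert fragments[0].left_overhang == "" and fragments[0].right_overhang == "CATG"
        assert fragments[1].left_overhang == "CATG" and fragments[1].right_overhang == ""


class TestLigateCyclic:
    def _frag(self, body, left, right, source=""):
        return gg.Fragment(body=body, left_overhang=left, right_overhang=right, source=source)

    def test_three_fragment_chain_closes_uniquely(self):
        frags = [
            self._frag("A" * 40, "GCTT", "AATG", "backbone"),
            self._frag("C" * 20, "AATG", "TTCG", "cds"),
            self._frag("G" * 10, "TTCG", "GCTT", "ctag"),
        ]
        products = gg.ligate_cyclic(frags)
        assert len(products) == 1
        assert len(products[0]) == 40 + 20 + 10 + 3 * 4

    def test_identical_insert_overhangs_report_two_products(self):
        frags = [
            self._frag("A" * 40, "TTCG", "AATG", "backbone"),
            self._frag("C" * 20, "AATG", "TTCG", "insert1"),
            self._frag("G" * 20, "AATG", "TTCG", "insert2"),
        ]
        assert len(gg.ligate_cyclic(frags)) == 2

    def test_no_matching_overhangs_yields_empty(self):
        frags = [
            self._frag("A" * 10, "AATG", "TTCG"),
            self._frag("C" * 10, "GCTT", "CCAT"),
        ]
        assert gg.ligate_cyclic(frags) == []

    def test_palindromic_overhang_warns_and_excludes(self):
        frags = [
            self._frag("A" * 10, "AATT", "GCTT"),
            self._frag("C" * 10, "GCTT", "AATT"),
        ]
        with pytest.warns(UserWarning, match="palindromic"):
            products = gg.ligate_cyclic(frags)
        assert products == []

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_bruteforce_permutation_search(self, seed):
        """Product enumeration equals exhaustive permutation search (<=6 frags)."""
        rng = random.Random(seed)
        pool = ["AATG", "TTCG", "GCTT", "CCAT", "TGCC"]
        frags = [
            self._frag(
                "".join(rng.choices("ACGT", k=rng.randrange(8, 20))),
                rng.choice(pool),
                rng.choice(pool),
                f"f{i}",
            )
            for i in range(rng.randrange(2, 7))
        ]
        got = {p.canonical() for p in gg.ligate_cyclic(frags)}
        assert got == brute_force_ligation_products(frags)


class TestAssemble:
    def test_four_part_assembly_consumes_four_junctions(self, fixture_registry):
        construct = gg.assemble(
            fixture_registry.get("pEPQD0KN0245"),
            [
                fixture_registry.get("pEPQD0CM0543"),
                fixture_registry.get("pEPQD0CM0296"),
                fixture_registry.get("pEPYC0CM0257"),
            ],
        )
        assert sorted(construct.junctions) == ["AATG", "CCAT", "GCTT", "TTCG"]
        roles = [e.role for e in construct.parts_in_order]
        assert roles == ["backbone", "n_tag", "cds", "c_tag"]

    def test_insert_order_does_not_matter(self, fixture_registry):
        parts = [
            fixture_registry.get("pEPQD0CM0543"),
            fixture_registry.get("pEPQD0CM0296"),
            fixture_registry.get("pEPYC0CM0257"),
        ]
        a = gg.assemble(fixture_registry.get("pEPQD0KN0245"), parts)
        b = gg.assemble(fixture_registry.get("pEPQD0KN0245"), parts[::-1])
        assert a.canonical() == b.canonical()

    def test_missing_c_tag_names_the_junction(self, fixture_registry):
        with pytest.raises(IncompleteCycleError) as exc:
            gg.assemble(
                fixture_registry.get("pEPQD0KN0025"),
                [fixture_registry.get("pEPQD0CM0296")],
            )
        assert exc.value.missing_junction == ("TTCG", "GCTT")

    def test_product_carries_no_assembly_enzyme_site(self, fixture_registry):
        construct = gg.assemble(
            fixture_registry.get("pEPQD0KN0025"),
            [fixture_registry.get("pEPQD0CM0296"), fixture_registry.get("pEPQD0CM0030")],
        )
        assert gg.find_type2s_sites(construct.sequence, "circular", gg.BSAI) == []

    def test_round_trip_recovers_insert_bodies(self, fixture_registry):
        """Provenance spans slice the product back into the input fragments."""
        inserts = [
            fixture_registry.get("pEPQD0CM0281"),
            fixture_registry.get("pEPQD0CM0296"),
            fixture_registry.get("pEPYC0CM0257"),
        ]
        construct = gg.assemble(fixture_registry.get("pEPQD0KN0245"), inserts)
        excised = {
            p.part_id: gg.excise(p, gg.BSAI, expected=(p.fusion_5, p.fusion_3))
            for p in inserts
        }
        for entry in construct.parts_in_order:
            if entry.role == "backbone":
                continue
            lo, hi = entry.span
            chunk = construct.sequence[lo:hi]  # left overhang + body
            frag = excised[entry.part_id]
            assert chunk == frag.left_overhang + frag.body
            assert construct.sequence.count(frag.body) == 1

    def test_insert_with_internal_site_is_domestication_error(self, fixture_registry):
        clean = fixture_registry.get("pEPQD0CM0296")
        frag = gg.excise(clean, gg.BSAI, expected=("AATG", "TTCG"))
        mutated = clean.sequence.replace(frag.body, frag.body[:50] + "GGTCTC" + frag.body[56:])
        bad = Part(part_id="bad_cds", category="cds", fusion_5="AATG",
                   fusion_3="TTCG", sequence=mutated)
        with pytest.raises(DomesticationError):
            gg.assemble(
                fixture_registry.get("pEPQD0KN0025"),
                [bad, fixture_registry.get("pEPYC0CM0257")],
            )

    def test_level0_creation_with_bpii(self, fixture_registry):
        """A synthesized fragment is captured into a storage acceptor."""
        part = fixture_registry.get("pEPQD0CM0296")
        insert = gg.excise(part, gg.BSAI, expected=("AATG", "TTCG"))
        precursor = fixtures.level0_precursor(insert.top_strand, seed=7)
        storage = fixtures.storage_acceptor_record("AATG", "TTCG", seed=8)
        frags = [
            f
            for f in gg.digest(precursor, gg.BPII) + gg.digest(storage, gg.BPII)
            if gg.is_site_free(f, gg.BPII) and f.left_overhang and f.right_overhang
        ]
        products = gg.ligate_cyclic(frags)
        assert len(products) == 1
        assert insert.body in products[0].sequence


class TestEnzymeSpec:
    def test_palindromic_recognition_rejected(self):
        with pytest.raises(ValueError, match="palindromic"):
            gg.EnzymeSpec(name="EcoRV-like", recognition="GATATC", spacer_len=0)

    def test_default_geometries(self):
        assert (gg.BSAI.recognition, gg.BSAI.spacer_len, gg.BSAI.overhang_len) == ("GGTCTC", 1, 4)
        assert (gg.BPII.recognition, gg.BPII.spacer_len, gg.BPII.overhang_len) == ("GAAGAC", 2, 4)
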