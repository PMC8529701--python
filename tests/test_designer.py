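"""Design expansion, fusion-ORF translation and protease planning."""

import random

import pytest
from hypothesis import given, settings, strategies as st

from phytofoundry import designer, fixtures, goldengate as gg
from phytofoundry.designer import (
    DesignSpec,
    FusionProtein,
    cleave,
    expand_design,
    extract_fusion_orf,
    find_protease_sites,
    plan_cleavage_mix,
    protein_mw_kda,
)
from phytofoundry.errors import (
    DomainError,
    FrameError,
    PrematureStopError,
    UnknownProteaseError,
    UnresolvedPartError,
)
from phytofoundry.registry import load_bundled_registry

# Independent average residue masses (Expasy table) for the MW oracle.
AVERAGE_RESIDUE_MASS = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886, "C": 103.1388,
    "E": 129.1155, "Q": 128.1307, "G": 57.0519, "H": 137.1411, "I": 113.1594,
    "L": 113.1594, "K": 128.1741, "M": 131.1926, "F": 147.1766, "P": 97.1167,
    "S": 87.0782, "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}
WATER = 18.0153


def oracle_mw_kda(seq: str) -> float:
    return (sum(AVERAGE_RESIDUE_MASS[aa] for aa in seq) + WATER) / 1000.0


class TestExpandDesign:
    def test_screen_expands_to_88(self, screen):
        registry, spec = screen
        assert len(expand_design(spec, registry)) == 88

    def test_single_combination(self, screen):
        registry, _ = screen
        spec = DesignSpec(
            acceptors=["pEPQD0KN0245"], n_tags=["pEPQD0CM0543"],
            cds_list=["pSYNUGT01"], c_tags=["pEPYC0CM0257"],
        )
        assert len(expand_design(spec, registry)) == 1

    def test_five_by_five_cross_product(self, screen):
        registry, _ = screen
        spec = DesignSpec(
            acceptors=["pEPQD0KN0245"],
            n_tags=["pEPQD0CM0541", "pEPQD0CM0543", "pEPQD0CM0544",
                    "pEPQD0CM0546", "pEPQD0CM0281"],
            cds_list=[f"pSYNUGT{i:02d}" for i in range(1, 6)],
            c_tags=["pEPYC0CM0257"],
        )
        assert len(expand_design(spec, registry)) == 25

    def test_tagless_requires_aatg_acceptor(self, screen):
        registry, _ = screen
        spec = DesignSpec(
            acceptors=["pEPQD0KN0245"],  # CCAT slot: tagless cannot chain
            n_tags=["none"], cds_list=["pSYNUGT01"], c_tags=["pEPYC0CM0257"],
        )
        with pytest.warns(UserWarning, match="zero"):
            assert expand_design(spec, registry) == []

    def test_deterministic_lexicographic_order(self, screen_orders):
        keys = [(o.acceptor, o.n_tag or "", o.cds, o.c_tag) for o in screen_orders]
        assert keys == sorted(keys)

    def test_unresolved_id_is_reference_error(self, screen):
        registry, _ = screen
        spec = DesignSpec(acceptors=["pMISSING"], n_tags=["none"],
                          cds_list=["pSYNUGT01"], c_tags=["pEPYC0CM0257"])
        with pytest.raises(UnresolvedPartError, match="pMISSING"):
            expand_design(spec, registry)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        n_aatg=st.integers(0, 3), n_ccat=st.integers(0, 3),
        tags=st.integers(0, 5), include_none=st.booleans(),
        n_cds=st.integers(0, 2), n_ctags=st.integers(0, 4),
    )
    def test_count_matches_closed_form(self, n_aatg, n_ccat, tags, include_none, n_cds, n_ctags):
        """Expansion size = compatible configurations x CDS count."""
        registry = load_bundled_registry()
        aatg_acceptors = [p.part_id for p in registry.by_category("acceptor_ecoli_cfps")
                          if p.fusion_5 == "AATG"][:n_aatg]
        ccat_acceptors = [p.part_id for p in registry.by_category("acceptor_ecoli_cfps")
                          if p.fusion_5 == "CCAT"][:n_ccat]
        tag_ids = [p.part_id for p in registry.by_category("n_tag")][:tags]
        cds_ids = [p.part_id for p in registry.by_category("cds")][:n_cds]
        ctag_ids = [p.part_id for p in registry.by_category("c_tag")][:n_ctags]
        spec = DesignSpec(
            acceptors=aatg_acceptors + ccat_acceptors,
            n_tags=(["none"] if include_none else []) + tag_ids,
            cds_list=cds_ids,
            c_tags=ctag_ids,
        )
        expected = (
            len(aatg_acceptors) * (1 if include_none else 0)
            + len(ccat_acceptors) * len(tag_ids)
        ) * len(cds_ids) * len(ctag_ids)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            assert len(expand_design(spec, registry)) == expected


class TestFusionOrf:
    def test_net_acceptor_protein_starts_mekki(self, fixture_registry):
        construct = gg.assemble(
            fixture_registry.get("pEPQD0KN0024"),
            [fixture_registry.get("pEPQD0CM0296"), fixture_registry.get("pEPYC0CM0257")],
        )
        protein = extract_fusion_orf(construct)
        assert protein.amino_acid_sequence.startswith("MEKKI")
        assert ("NET", 0, 5) in protein.tags_present

    def test_s_tag_fusion_contains_printed_peptide(self, fixture_registry):
        construct = gg.assemble(
            fixture_registry.get("pEPQD0KN0245"),
            [
                fixture_registry.get("pEPQD0CM0281"),
                fixture_registry.get("pEPQD0CM0296"),
                fixture_registry.get("pEPYC0CM0257"),
            ],
        )
        protein = extract_fusion_orf(construct)
        assert "KETAAAKFERQHMDS" in protein.amino_acid_sequence

    def test_c_terminal_hibit_is_11_residues_at_the_end(self, fixture_registry):
        construct = gg.assemble(
            fixture_registry.get("pEPQD0KN0025"),
            [fixture_registry.get("pEPQD0CM0296"), fixture_registry.get("pEPYC0CM0257")],
        )
        protein = extract_fusion_orf(construct)
        hibit = [t for t in protein.tags_present if t[0] == "HiBiT"]
        assert len(hibit) == 1
        name, start, end = hibit[0]
        assert end - start == 11
        assert end == protein.length_aa  # flush with the C-terminus

    def test_no_stop_free_translation_in_screen(self, screen_constructs):
        """Every fixture construct translates without premature stops."""
        for construct in screen_constructs:
            protein = extract_fusion_orf(construct)
            assert protein.length_aa > 20
            assert "*" not in protein.amino_acid_sequence

    def test_premature_stop_is_reported_with_position(self, fixture_registry):
        construct = gg.assemble(
            fixture_registry.get("pEPQD0KN0025"),
            [fixture_registry.get("pEPQD0CM0296"), fixture_registry.get("pEPYC0CM0257")],
        )
        (aatg_pos,) = [pos for ov, pos in construct.junction_positions() if ov == "AATG"]
        anchor = aatg_pos + 1
        mutate_at = anchor + 30  # in frame, inside the CDS span
        seq = construct.sequence
        construct.sequence = seq[:mutate_at] + "TAA" + seq[mutate_at + 3:]
        with pytest.raises(PrematureStopError) as exc:
            extract_fusion_orf(construct)
        assert exc.value.position == mutate_at

    def test_construct_without_aatg_junction_is_frame_error(self, fixture_registry):
        construct = gg.assemble(
            fixture_registry.get("pEPQD0KN0025"),
            [fixture_registry.get("pEPQD0CM0296"), fixture_registry.get("pEPYC0CM0257")],
        )
        construct.junctions = ["GCTT", "TTCG", "GCTT"]
        with pytest.raises(FrameError):
            extract_fusion_orf(construct)

    def test_mw_matches_independent_residue_summation(self, screen_constructs):
        protein = extract_fusion_orf(screen_constructs[0])
        assert protein.mw_kda == pytest.approx(
            oracle_mw_kda(protein.amino_acid_sequence), rel=1e-4
        )

    def test_fusion_mw_is_additive_minus_water(self):
        a, b = "MEKKIGST", "VSGWRLFKKIS"
        assert protein_mw_kda(a + b) * 1000 == pytest.approx(
            protein_mw_kda(a) * 1000 + protein_mw_kda(b) * 1000 - WATER, abs=0.01
        )


class TestProteaseSites:
    def _protein(self, seq):
        return FusionProtein(
            amino_acid_sequence=seq, length_aa=len(seq), mw_kda=protein_mw_kda(seq)
        )

    def test_gst_tev_fusion_cleaves_into_two_products(self, fixture_registry):
        construct = gg.assemble(
            fixture_registry.get("pEPQD0KN0245"),
            [
                fixture_registry.get("pEPQD0CM0543"),  # GST-[TEV site]
                fixture_registry.get("pEPQD0CM0296"),  # sfGFP stand-in
                fixture_registry.get("pEPQD0CM0030"),  # stop
            ],
        )
        protein = extract_fusion_orf(construct)
        sites = find_protease_sites(protein, "tev")
        assert len(sites) == 1
        products = cleave(protein, "tev")
        assert len(products) == 2
        assert "".join(products) == protein.amino_acid_sequence

    def test_two_tev_motifs_hand_indexed(self):
        #          0123456789...
        protein = self._protein("M" + "ENLYFQG" + "AAAA" + "ENLYFQS" + "WWWWWWWWWWWWWWWWWWWWW")
        # motif 1 at 1 -> cut position 7; motif 2 at 12 -> cut position 18
        assert find_protease_sites(protein, "tev") == [7, 18]

    def test_absent_motif_yields_empty(self):
        assert find_protease_sites(self._protein("MAAAAAAAAAA"), "tev") == []

    @pytest.mark.parametrize(
        "protease,seq,expected",
        [
            ("thrombin", "MAALVPRGSWW", [7]),
            ("factor_xa", "MIEGRWWWW", [5]),
            ("factor_xa", "MIDGRWWWW", [5]),
            ("hrv_3c", "MLEVLFQGPWW", [7]),
        ],
    )
    def test_motif_cut_offsets(self, protease, seq, expected):
        assert find_protease_sites(self._protein(seq), protease) == expected

    def test_unknown_protease_rejected(self):
        with pytest.raises(UnknownProteaseError):
            find_protease_sites(self._protein("MAAA"), "enterokinase")

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=60))
    def test_cleavage_products_concatenate_to_original(self, seq):
        seq = "M" + seq
        assert "".join(cleave(seq, "tev")) == seq


class TestCleavagePlan:
    def test_toolkit_ratio_for_2p5_ug(self):
        plan = plan_cleavage_mix(2.5, 1 / 130, protease_conc_ug_per_ul=1.0)
        assert plan.protease_mass_ug == pytest.approx(0.019231, abs=1e-5)

    def test_unit_ratio(self):
        plan = plan_cleavage_mix(1.0, 1.0, protease_conc_ug_per_ul=2.0)
        assert plan.protease_mass_ug == 1.0
        assert plan.volumes["protease_ul"] == 0.5

    @pytest.mark.parametrize("kwargs", [
        {"target_mass_ug": 0}, {"ratio": 0}, {"protease_conc_ug_per_ul": 0},
    ])
    def test_nonpositive_inputs_rejected(self, kwargs):
        defaults = {"target_mass_ug": 1.0, "ratio": 1 / 130, "protease_conc_ug_per_ul": 1.0}
        defaults.update(kwargs)
        with pytest.raises(DomainError):
            plan_cleavage_mix(**defaults)
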