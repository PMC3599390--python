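"""Domain calling, letter codes, kinase-2 rule, core extraction."""

import itertools

import numpy as np
import pytest

from nbslrr.architecture import (
    DomainArchitecture,
    FrameError,
    classify_protein,
    coiled_coil_score,
    detect_coiled_coil,
    extract_nbs_core,
    kinase2_diagnostic_index,
    letter_code,
    predict_family_kinase2,
    screen_pseudogenes,
    summarize_categories,
)
from nbslrr.motifs import scan_sequence
from nbslrr.synthetic import generate_gene


IDEAL_HEPTAD = "LEELEEK" * 5  # L at heptad positions a/d, E/K elsewhere


class TestCoiledCoil:
    def test_ideal_heptad_repeat_detected_as_one_segment(self):
        segments = detect_coiled_coil(IDEAL_HEPTAD)
        assert len(segments) == 1
        start, end, score = segments[0]
        assert start == 0 and end == len(IDEAL_HEPTAD)
        assert score > 0.9

    def test_poly_glycine_is_negative(self):
        assert detect_coiled_coil("G" * 60) == []

    def test_short_protein_gives_empty(self):
        assert detect_coiled_coil("LAELKEL") == []

    def test_shuffles_score_below_the_periodic_original(self):
        original = coiled_coil_score(IDEAL_HEPTAD)
        rng = np.random.default_rng(5)
        arr = list(IDEAL_HEPTAD)
        for _ in range(100):
            rng.shuffle(arr)
            assert coiled_coil_score("".join(arr)) < original


class TestLetterCode:
    MAPPING = {
        frozenset(): "unclassified",
        frozenset({"TIR", "NBS", "LRR"}): "TNL",
        frozenset({"CC", "NBS", "LRR"}): "CNL",
        frozenset({"TIR", "NBS"}): "TN",
        frozenset({"CC", "NBS"}): "CN",
        frozenset({"NBS"}): "N",
        frozenset({"NBS", "LRR"}): "NL",
        frozenset({"RPW8", "NBS", "LRR"}): "RPW8-NL",
        frozenset({"RPW8", "CC", "NBS", "LRR"}): "RPW8-NL",  # RPW8 precedence
    }

    @pytest.mark.parametrize("domains,expected", sorted(MAPPING.items(), key=str))
    def test_known_combinations(self, domains, expected):
        arch = DomainArchitecture("g", domains=[(d, 0, 1) for d in sorted(domains)])
        assert letter_code(arch) == expected

    def test_mapping_is_total_over_the_powerset(self):
        for r in range(6):
            for combo in itertools.combinations(("TIR", "CC", "NBS", "LRR", "RPW8"), r):
                arch = DomainArchitecture("g", domains=[(d, 0, 1) for d in combo])
                code = letter_code(arch)
                assert code in (
                    "TNL", "CNL", "TN", "CN", "N", "NL", "RPW8-NL", "unclassified"
                )
                if "NBS" not in combo:
                    assert code == "unclassified"


class TestPlantedClassification:
    @pytest.mark.parametrize("code", ["TNL", "CNL", "TN", "CN", "N", "NL", "RPW8-NL"])
    def test_every_letter_code_recovered_at_zero_divergence(
        self, code, motif_library, rpw8_profile
    ):
        gene, truth, _ = generate_gene(code, 2, 0.0, seed=3)
        arch = classify_protein(
            gene.gene_id, gene.protein, motif_library, rpw8_profile=rpw8_profile
        )
        assert arch.letter_code == code

    def test_nbs_only_gene_has_no_nterminal_or_lrr_calls(
        self, motif_library, rpw8_profile
    ):
        gene, _, _ = generate_gene("N", 0, 0.0, seed=2)
        arch = classify_protein(
            gene.gene_id, gene.protein, motif_library, rpw8_profile=rpw8_profile
        )
        assert arch.domain_names == {"NBS"}
        assert len(gene.exons) == 1


class TestKinase2:
    def test_diagnostic_index_follows_the_ddv_run(self, motif_library):
        for motif in motif_library:
            if motif.name != "Kinase-2":
                continue
            idx = kinase2_diagnostic_index(motif)
            consensus_res = motif.positions[idx].residues
            expected = {"CC": frozenset("W"), "TIR": frozenset("D")}
            assert consensus_res == expected[motif.family_context]

    @pytest.mark.parametrize(
        "residue,call", [("D", "TIR"), ("W", "CC"), ("S", "undetermined"),
                          ("N", "undetermined"), ("G", "undetermined")]
    )
    def test_terminal_residue_rule(self, residue, call, motif_library):
        gene, truth, _ = generate_gene("TNL", 0, 0.0, seed=9)
        k2 = truth.planted_motif_positions["Kinase-2"]
        motif = next(
            m for m in motif_library
            if m.name == "Kinase-2" and m.family_context == "TIR"
        )
        pos = k2 + kinase2_diagnostic_index(motif)
        protein = gene.protein[:pos] + residue + gene.protein[pos + 1 :]
        hits = scan_sequence(protein, motif_library)
        got_call, got_residue = predict_family_kinase2(protein, hits, motif_library)
        assert got_call == call
        assert got_residue == residue

    def test_no_kinase2_hit_is_undetermined_none(self, motif_library):
        call, residue = predict_family_kinase2("A" * 50, [], motif_library)
        assert (call, residue) == ("undetermined", None)


class TestNbsCore:
    def test_planted_core_equals_ploop_to_glpl_span(self, motif_library):
        gene, truth, _ = generate_gene("TNL", 1, 0.0, seed=4)
        hits = scan_sequence(gene.protein, motif_library)
        core = extract_nbs_core(gene.protein, hits)
        glpl = next(
            m for m in motif_library
            if m.name == "GLPL" and m.family_context == "TIR"
        )
        start = truth.planted_motif_positions["P-loop"]
        end = truth.planted_motif_positions["GLPL"] + glpl.length
        assert core == gene.protein[start:end]

    def test_missing_glpl_gives_none(self, motif_library):
        gene, truth, _ = generate_gene("TNL", 0, 0.0, seed=4)
        truncated = gene.protein[: truth.planted_motif_positions["GLPL"] - 5]
        hits = scan_sequence(truncated, motif_library)
        assert extract_nbs_core(truncated, hits) is None

    def test_misordered_anchors_give_none(self, motif_library):
        gene, truth, _ = generate_gene("N", 0, 0.0, seed=6)
        hits = scan_sequence(gene.protein, motif_library)
        core = extract_nbs_core(gene.protein, hits)
        # rotate so the full GLPL region precedes the full P-loop region
        k = truth.planted_motif_positions["GLPL"] - 10
        shuffled = gene.protein[k:] + gene.protein[:k]
        shuffled_hits = scan_sequence(shuffled, motif_library)
        by_name = {h.motif_name: h for h in shuffled_hits}
        assert core is not None
        assert by_name["GLPL"].start < by_name["P-loop"].start
        assert extract_nbs_core(shuffled, shuffled_hits) is None


class TestSummary:
    def test_counts_match_planted_composition(self, motif_library, rpw8_profile):
        archs = []
        for i, code in enumerate(["TNL"] * 4 + ["CNL"] * 6):
            gene, _, _ = generate_gene(code, 1, 0.0, seed=100 + i)
            archs.append(
                classify_protein(f"g{i}", gene.protein, motif_library,
                                 rpw8_profile=rpw8_profile)
            )
        summary = summarize_categories(archs)
        assert summary["TNL"] == 4
        assert summary["CNL"] == 6
        assert summary["total"] == 10

    def test_motif_free_proteins_are_unclassified(self):
        archs = [
            classify_protein(f"g{i}", "ACDEFGHIKLMNPQRSTVWY" * 5, [])
            for i in range(3)
        ]
        summary = summarize_categories(archs)
        assert summary == {"unclassified": 3, "total": 3}

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            summarize_categories([])


class TestPseudogeneScreen:
    @pytest.mark.parametrize(
        "seq,expected",
        [
            ("ATGAAATAA", "clean"),  # terminal stop only
            ("ATGTAAAAATAA", "pseudogene"),  # internal stop
            ("ATGAAACCC", "clean"),  # no stop at all
        ],
    )
    def test_examples(self, seq, expected):
        assert screen_pseudogenes(seq) == expected

    def test_out_of_frame_length_raises(self):
        with pytest.raises(FrameError):
            screen_pseudogenes("ATGAA")

    def test_planted_internal_tga_detected(self):
        rng = np.random.default_rng(8)
        codons = ["".join(rng.choice(list("ACGT"), 3)) for _ in range(60)]
        codons = [c for c in codons if c not in ("TAA", "TAG", "TGA")]
        codons[len(codons) // 2] = "TGA"
        assert screen_pseudogenes("".join(codons)) == "pseudogene"
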