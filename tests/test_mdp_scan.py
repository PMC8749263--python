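from itertools import product

import numpy as np
import pytest

from mitoring.mdp_scan import (
    EXTENDED_STARTS,
    STANDARD_CODE,
    VERTEBRATE_MITO_CODE,
    LocusSpec,
    build_conservation_matrix,
    classify_mdp,
    conserved_core,
    gau_extended_scan,
    genetic_code,
    locate_locus,
    predict_mdp,
    scan_sorfs,
    translate,
)
from mitoring.mito_model import CircularSequence, reverse_complement, rotate
from mitoring.synthetic_data import SimPlan, generate_mitogenome, plant_pseudogenization

from _oracles import brute_force_sorfs, standard_table, vertebrate_mito_table

ALL_CODONS = ["".join(c) for c in product("TCAG", repeat=3)]


class TestGeneticCodes:
    @pytest.mark.parametrize(
        "code,oracle",
        [(STANDARD_CODE, standard_table()), (VERTEBRATE_MITO_CODE, vertebrate_mito_table())],
        ids=["standard", "vertebrate_mito"],
    )
    def test_all_64_codons_match_independent_transcription(self, code, oracle):
        assert len(ALL_CODONS) == 64
        for codon in ALL_CODONS:
            assert code.aa(codon) == oracle[codon], codon

    def test_start_sets(self):
        assert STANDARD_CODE.start_set == frozenset({"ATG"})
        assert EXTENDED_STARTS == frozenset({"ATG", "ATA", "ATT", "ATC", "GTG"})

    def test_unknown_code_name(self):
        with pytest.raises(ValueError, match="unknown genetic code"):
            genetic_code("plastid")


class TestTranslate:
    def test_simple_orf(self):
        res = translate("ATGAAATAA", STANDARD_CODE)
        assert res.peptide == "MK" and res.stop_found

    def test_ata_start_rejected_under_standard_code(self):
        res = translate("ATAAAATAA", STANDARD_CODE)
        assert res.status == "absent_no_start" and res.peptide == ""

    def test_ata_start_accepted_with_extended_set(self):
        res = translate("ATAAAATAA", STANDARD_CODE, start_set=EXTENDED_STARTS)
        assert res.peptide == "MK"  # initial residue reported as M

    def test_ambiguous_codon_is_x(self):
        res = translate("ATGANATAA", STANDARD_CODE)
        assert res.peptide == "MX"

    def test_no_start_required_policy(self):
        res = translate("AAAAAATAG", STANDARD_CODE, start_policy="no_start_required")
        assert res.peptide == "KK" and res.stop_found

    def test_short_input_is_error(self):
        with pytest.raises(ValueError):
            translate("AT", STANDARD_CODE)


class TestLocateLocus:
    def test_verbatim_plant_found_at_exact_coordinates(self, catalog, base_sim):
        g, _, truth = base_sim
        for spec in catalog:
            hit = locate_locus(g, spec)
            t = truth["loci"][spec.mdp_name]
            assert hit.locatable and hit.identity == 100.0
            assert (hit.start % g.length, hit.strand) == (t["start"], t["strand"])

    def test_mutated_plant_found_near_planting(self, catalog, base_sim):
        from mitoring.synthetic_data import mutate_haplotype

        g, _, truth = base_sim
        g2 = mutate_haplotype(g, 5, seed=42)
        spec = next(s for s in catalog if s.mdp_name == "SHLP3")
        hit = locate_locus(g2, spec)
        assert hit.locatable
        assert abs(hit.start - truth["loci"]["SHLP3"]["start"]) <= 10

    def test_unrelated_reference_not_locatable(self, base_genome):
        spec = LocusSpec(
            mdp_name="decoy", host_gene="MT-RNR2",
            nt="ATG" + "CAGTCA" * 20 + "TAA",
        )
        hit = locate_locus(base_genome, spec, min_identity=90.0)
        assert not hit.locatable

    def test_shlp6_window_overlaps_primer_footprint(self, catalog, base_sim):
        """SHLP6 sits next to the conserved primer motif, so its padded
        locus window overlaps the primer footprint."""
        g, _, truth = base_sim
        spec = next(s for s in catalog if s.mdp_name == "SHLP6")
        hit = locate_locus(g, spec)
        w0, w1 = hit.window_start, hit.window_start + len(hit.window_nt)
        m0, m1 = truth["motif_span"]
        assert w0 < m1 and m0 < w1


class TestScanSorfs:
    @pytest.mark.parametrize("seed", range(10))
    def test_equals_brute_force_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        window = "".join(rng.choice(list("ACGT"), 400))
        got = [
            (r.frame, r.start, r.end, r.peptide, r.status, r.truncated)
            for r in scan_sorfs(window, STANDARD_CODE)
        ]
        expect = brute_force_sorfs(window, standard_table(), {"ATG"})
        assert got == expect

    def test_planted_twelve_codon_orf(self):
        rng = np.random.default_rng(3)
        orf = "ATG" + "GCC" * 11 + "TAA"
        # embed in a stop-rich background so no other ORF appears in-frame
        window = "TAATAATAA" + orf + "TAATAATAA"
        recs = [r for r in scan_sorfs(window, STANDARD_CODE) if r.status == "intact"]
        assert len(recs) == 1
        assert recs[0].peptide == "M" + "A" * 11 and recs[0].length == 12

    def test_seven_residue_orf_is_below_min_length(self):
        window = "CCTCCTCC" + "ATG" + "GCC" * 6 + "TAA" + "CCTCC"
        recs = scan_sorfs(window, STANDARD_CODE)
        assert [r.status for r in recs] == ["below_min_length"]
        assert recs[0].length == 7

    def test_no_start_codon_gives_no_records(self):
        window = "CCTCCTCCTCCTCCTCCTCCGCCGCA"
        assert scan_sorfs(window, STANDARD_CODE) == []


class TestClassify:
    @pytest.mark.parametrize("mode", ["intact", "absent_no_start", "premature_stop", "frameshift"])
    def test_planted_modes_recovered(self, catalog, mode):
        g, _, _ = generate_mitogenome(
            SimPlan(seed=99, mdp_plan={"SHLP4": mode}), catalog
        )
        spec = next(s for s in catalog if s.mdp_name == "SHLP4")
        rec = predict_mdp(g, spec)
        assert rec.status == mode
        if mode == "intact":
            assert rec.peptide == spec.peptide

    def test_premature_stop_before_reference_length(self, catalog, base_genome):
        spec = next(s for s in catalog if s.mdp_name == "humanin")
        lesioned = plant_pseudogenization(spec.nt, "premature_stop", seed=5)
        stop_codon = next(
            i for i in range(1, len(lesioned) // 3 - 1) if lesioned[3 * i : 3 * i + 3] == "TAA"
        )
        assert stop_codon < len(spec.peptide) // 2

    def test_downstream_start_counted_for_motsc(self, catalog):
        # MOTS-c carries an internal M; killing the first start must not
        # rescue the locus, but the downstream start is reported
        g, _, _ = generate_mitogenome(
            SimPlan(seed=55, mdp_plan={"MOTS-c": "absent_no_start"}), catalog
        )
        spec = next(s for s in catalog if s.mdp_name == "MOTS-c")
        rec = predict_mdp(g, spec)
        assert rec.status == "absent_no_start"
        assert rec.downstream_starts >= 1

    def test_empty_records_not_locatable_hit(self, catalog):
        spec = catalog[0]
        from mitoring.mdp_scan import LocusHit

        hit = LocusHit(spec.mdp_name, "+", 0, 0, 0.0, "", 0, 30, 0, "", locatable=False)
        rec = classify_mdp([], spec, hit, 16000)
        assert rec.status == "not_locatable"


class TestGau:
    def test_standard_policy_finds_no_start(self, catalog, base_genome):
        spec = next(s for s in catalog if s.mdp_name == "gau")
        rec = predict_mdp(base_genome, spec, start_set=frozenset({"ATG"}))
        assert rec.status == "absent_no_start"

    def test_extended_starts_yield_dwarf_peptide(self, catalog, base_genome):
        spec = next(s for s in catalog if s.mdp_name == "gau")
        rec = gau_extended_scan(base_genome, spec)
        assert rec.status == "intact" and rec.length == 14
        assert rec.strand == "-"  # antisense within MT-CO1

    def test_atg_start_identical_under_both_policies(self, catalog, base_genome):
        spec = next(s for s in catalog if s.mdp_name == "SHLP5")  # ATG-led locus
        std = predict_mdp(base_genome, spec, start_set=frozenset({"ATG"}))
        ext = predict_mdp(base_genome, spec, start_set=EXTENDED_STARTS)
        assert (std.status, std.peptide) == (ext.status, ext.peptide)


class TestMatrix:
    def test_all_intact_plan(self, catalog):
        genomes = [generate_mitogenome(SimPlan(seed=s, genome_id=f"g{s}"), catalog)[0] for s in range(3)]
        m = build_conservation_matrix(genomes, catalog)
        assert m.statuses.shape == (3, 9)
        assert m.statuses.map(lambda c: c.startswith("intact")).to_numpy().all()

    def test_planted_statuses_match_plan_exactly(self, catalog):
        rng = np.random.default_rng(17)
        modes = ["intact", "absent_no_start", "premature_stop", "frameshift"]
        genomes, plans = [], []
        for s in range(4):
            plan = {spec.mdp_name: modes[rng.integers(4)] for spec in catalog}
            g, _, _ = generate_mitogenome(SimPlan(seed=400 + s, genome_id=f"g{s}", mdp_plan=plan), catalog)
            genomes.append(g)
            plans.append(plan)
        m = build_conservation_matrix(genomes, catalog)
        for g, plan in zip(genomes, plans):
            for spec in catalog:
                cell = m.statuses.loc[g.id, spec.mdp_name]
                assert cell.split("(")[0] == plan[spec.mdp_name]

    def test_rotation_and_strand_invariance(self, catalog):
        g, _, _ = generate_mitogenome(
            SimPlan(seed=21, mdp_plan={"SHLP3": "frameshift", "humanin": "premature_stop"}),
            catalog,
        )
        m0 = build_conservation_matrix([g], catalog).statuses
        mr = build_conservation_matrix([rotate(g, 7777)], catalog).statuses
        mc = build_conservation_matrix(
            [CircularSequence(g.id, reverse_complement(g.seq))], catalog
        ).statuses
        assert (m0.values == mr.values).all()
        assert (m0.values == mc.values).all()

    def test_empty_genome_list_is_error(self, catalog):
        with pytest.raises(ValueError, match="at least one genome"):
            build_conservation_matrix([], catalog)


class TestConservedCore:
    def test_identical_peptides_full_core(self):
        lng, core = conserved_core(["MRWQEMGYIFYPRKLR"] * 3)
        assert lng == 16 and core == "MRWQEMGYIFYPRKLR"

    def test_constructed_four_residue_core(self):
        peps = ["MKLVWQRS", "MALVWQTT", "PKLVWQAC"]
        assert conserved_core(peps) == (4, "LVWQ")

    def test_core_with_length_variants(self):
        peps = ["MLDFVESRTKWH", "MLDFVESRTKWHANGIPYQSCVLRIA"]
        lng, core = conserved_core(peps)
        assert lng == 12 and core == "MLDFVESRTKWH"

    def test_empty_peptide_is_error(self):
        with pytest.raises(ValueError, match="empty"):
            conserved_core(["MKLV", ""])
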