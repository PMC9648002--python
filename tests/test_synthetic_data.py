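"""Simulator invariants: determinism, length bookkeeping, lift-map
invertibility, callset error models, and joint genotyping."""

import numpy as np
import pytest

from persoma.core_model import SvRecord
from persoma.synthetic_data import (NOISE_FREE, CallerProfile,
                                    SimulationConfig, EditScript,
                                    derive_personal_genome,
                                    generate_reference_genome,
                                    plant_somatic_variants,
                                    simulate_caller_callset,
                                    simulate_joint_genotyped_sv_vcf,
                                    simulate_snv_crossmap_study,
                                    simulate_truth)

SMALL = SimulationConfig(seed=11, n_scaffolds=2, scaffold_length_bp=150_000,
                         somatic_snv_count=30)


@pytest.fixture(scope="module")
def small_truth():
    return simulate_truth(SMALL)


class TestReferenceGenome:
    def test_seeded_generation_is_byte_identical(self):
        g1, p1, _ = generate_reference_genome(SMALL)
        g2, p2, _ = generate_reference_genome(SMALL)
        assert g1 == g2
        assert p1 == p2

    def test_repeat_placements_are_recorded_and_present(self):
        genome, placements, consensus = generate_reference_genome(SMALL)
        expected = sum(v["reference_copies"]
                       for v in SMALL.repeat_library.values())
        assert len(placements) == expected
        for p in placements:
            planted = genome.fetch(p.scaffold, p.start, p.start + p.length - 1)
            # each copy diverges from consensus by at most 2%
            mismatches = sum(a != b for a, b in zip(planted,
                                                    consensus[p.family]))
            assert mismatches <= 0.02 * p.length + 1

    def test_zero_repeats_gives_pure_background(self):
        config = SimulationConfig(seed=1, scaffold_length_bp=50_000,
                                  repeat_library={})
        genome, placements, _ = generate_reference_genome(config)
        assert placements == []

    def test_includes_circular_chrm(self):
        genome, _, _ = generate_reference_genome(SMALL)
        assert "chrM" in genome
        assert genome.is_circular("chrM")
        assert len(genome["chrM"]) == SMALL.chrm_length_bp

    def test_overcrowded_scaffold_raises(self):
        config = SimulationConfig(
            seed=1, n_scaffolds=1, scaffold_length_bp=2_000,
            repeat_library={"Big": {"length": 1500, "reference_copies": 2,
                                    "personal_only_copies": 0}})
        with pytest.raises(ValueError, match="too small"):
            generate_reference_genome(config)


class TestPersonalGenome:
    def test_length_bookkeeping(self, small_truth):
        reference, personal, truth = small_truth
        for chrom in reference.names():
            delta = sum(alt - ref for _, ref, alt
                        in truth.edit_script.edits(chrom))
            assert len(personal[chrom]) == len(reference[chrom]) + delta

    def test_zero_rates_give_identity(self):
        config = SimulationConfig(
            seed=2, scaffold_length_bp=30_000, germline_snv_rate=0,
            germline_indel_rate=0, germline_sv_counts={},
            homopolymer_diff_count=0,
            repeat_library={}, somatic_snv_count=5, somatic_sv_counts={},
            somatic_sv_in_personal_repeat=0)
        reference, _, _ = generate_reference_genome(config)
        personal, truth = derive_personal_genome(reference, config)
        assert personal == reference
        assert truth.edit_script.ref_to_personal("scaffold_1", 12345) == 12345

    def test_lift_map_is_invertible_on_planted_positions(self, small_truth):
        _, _, truth = small_truth
        script = truth.edit_script
        checked = 0
        for v in truth.germline_variants + truth.somatic_variants:
            if v.ref_pos is None or v.personal_pos is None:
                continue
            assert script.ref_to_personal(v.chrom, v.ref_pos) == v.personal_pos
            assert script.personal_to_ref(v.chrom, v.personal_pos) == v.ref_pos
            checked += 1
        assert checked > 50

    def test_insertion_shifts_downstream_positions_by_inserted_length(self):
        script = EditScript()
        script.add("c", 100, 1, 301)   # 300 bp insertion anchored at 100
        assert script.ref_to_personal("c", 99) == 99
        assert script.ref_to_personal("c", 100) == 100
        assert script.ref_to_personal("c", 101) == 401
        assert script.personal_to_ref("c", 401) == 101
        assert script.personal_to_ref("c", 250) is None   # inside insertion

    def test_somatic_ref_allele_matches_personal_genome(self, small_truth):
        _, personal, truth = small_truth
        for v in truth.somatic_variants:
            if v.kind == "snv":
                assert personal[v.chrom][v.personal_pos - 1] == v.ref_allele


class TestSomaticTruth:
    def test_requested_counts_and_maf_domain(self, small_truth):
        _, _, truth = small_truth
        snvs = [v for v in truth.somatic_variants if v.kind == "snv"]
        assert len(snvs) == SMALL.somatic_snv_count
        assert all(0 < v.maf <= 1 for v in snvs)
        assert set(v.maf for v in snvs) <= {0.5, 1.0}

    def test_personal_only_deletion_flagged(self, small_truth):
        _, _, truth = small_truth
        flagged = [v for v in truth.somatic_variants
                   if v.personal_only_context and v.sv_type == "DEL"]
        assert len(flagged) >= SMALL.somatic_sv_in_personal_repeat
        assert all(v.ref_pos is None for v in flagged)

    def test_fixed_seed_reproduces_truth(self):
        t1 = simulate_truth(SMALL)[2]
        t2 = simulate_truth(SMALL)[2]
        assert t1.somatic_variants == t2.somatic_variants
        assert t1.germline_variants == t2.germline_variants


class TestCallerCallsets:
    def test_noise_free_callset_equals_truth(self, small_truth):
        _, _, truth = small_truth
        svs = [v for v in truth.somatic_variants if v.kind == "sv"
               and not v.personal_only_context]
        records = simulate_caller_callset(svs, "reference", NOISE_FREE, seed=0)
        assert len(records) == len(svs)
        for v, r in zip(svs, records):
            assert (r.chrom, r.start) == (v.chrom, v.ref_pos)

    def test_personal_only_records_absent_from_reference_callset(self,
                                                                 small_truth):
        _, _, truth = small_truth
        flagged = [v for v in truth.somatic_variants if v.personal_only_context]
        assert flagged
        ref_records = simulate_caller_callset(flagged, "reference",
                                              NOISE_FREE, seed=0)
        personal_records = simulate_caller_callset(flagged, "personal",
                                                   NOISE_FREE, seed=0)
        assert ref_records == []
        assert len(personal_records) == len(flagged)

    def test_false_negative_rate_is_binomial(self, small_truth):
        """Across 100 seeds, dropped counts behave like Binomial(n, 0.1)."""
        _, _, truth = small_truth
        snvs = [v for v in truth.somatic_variants if v.kind == "snv"]
        profile = CallerProfile("lossy", fn_rate=0.1)
        n = len(snvs)
        dropped = [n - len(simulate_caller_callset(snvs, "personal", profile,
                                                   seed=s))
                   for s in range(100)]
        mean = np.mean(dropped)
        se = np.sqrt(n * 0.1 * 0.9 / 100)
        assert abs(mean - 0.1 * n) < 5 * se
        assert dropped[0] == (n - len(simulate_caller_callset(
            snvs, "personal", profile, seed=0)))   # reproducible

    def test_breakpoint_jitter_moves_sv_starts(self, small_truth):
        _, _, truth = small_truth
        svs = [v for v in truth.somatic_variants
               if v.kind == "sv" and not v.personal_only_context]
        jittery = CallerProfile("jit", jitter_sd_bp=30.0)
        records = simulate_caller_callset(svs, "personal", jittery, seed=1)
        shifts = [abs(r.start - v.personal_pos)
                  for v, r in zip(svs, records)]
        assert any(s > 0 for s in shifts)
        assert all(s < 300 for s in shifts)


class TestJointGenotyping:
    def test_somatic_and_germline_genotype_structure(self, small_truth):
        _, _, truth = small_truth
        joint = simulate_joint_genotyped_sv_vcf(
            truth.germline_variants + truth.somatic_variants, seed=0)
        assert joint, "no SV records produced"
        for rec in joint:
            tumor, normal = rec.sample("tumor"), rec.sample("normal")
            assert tumor is not None and normal is not None
            if normal.genotype == "0/0":       # somatic
                assert tumor.genotype in ("0/1", "1/1")
                assert normal.alt_depth == 0
                expected = 0.5 if tumor.genotype == "0/1" else 1.0
                assert tumor.allele_fraction == pytest.approx(expected)
            else:                              # germline
                assert normal.genotype == tumor.genotype

    def test_fixed_seed_identical_records(self, small_truth):
        _, _, truth = small_truth
        args = truth.germline_variants + truth.somatic_variants
        assert simulate_joint_genotyped_sv_vcf(args, seed=3) \
            == simulate_joint_genotyped_sv_vcf(args, seed=3)


class TestCrossmapStudyGenerator:
    def test_classes_and_consensus_structure(self):
        study = simulate_snv_crossmap_study(seed=7, genome_length_bp=200_000,
                                            n_clean=10, n_flank_germline=5,
                                            n_destroyed=5)
        assert len(study.source_snvs) == 20
        from collections import Counter
        counts = Counter(study.expected_category.values())
        assert counts == {"identical": 10, "equivalent": 5, "unmapped": 5}
        # every target-consensus record carries the personal-genome REF base
        for v in study.target_consensus:
            assert study.personal[v.chrom][v.pos - 1] == v.ref_allele
            assert v.ref_allele != v.alt_allele

    def test_deterministic(self):
        a = simulate_snv_crossmap_study(seed=7, genome_length_bp=100_000,
                                        n_clean=5, n_flank_germline=3,
                                        n_destroyed=2)
        b = simulate_snv_crossmap_study(seed=7, genome_length_bp=100_000,
                                        n_clean=5, n_flank_germline=3,
                                        n_destroyed=2)
        assert a.source_snvs == b.source_snvs
        assert a.personal == b.personal
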