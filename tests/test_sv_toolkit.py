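"""SV filtering, somatic selection, merging, and cross-assembly mapping."""

import numpy as np
import pytest

from persoma.core_model import GenotypeEntry, ScaffoldSet, SvRecord
from persoma.flank_mapper import SeedIndex
from persoma.sv_toolkit import (DEFAULT_MERGE_CRITERIA, NOVOBREAK_PROFILE,
                                MergeCriteria, SomaticSelectionCriteria,
                                SvFilterProfile, SvFlankEdgeError,
                                build_sv_flank_queries, filter_sv_callset,
                                harmonize_sv_types, harmonized_type,
                                map_sv_flanks, match_mapped_sv,
                                merge_sv_callsets, require_replicate_support,
                                select_somatic_sv_joint,
                                subtract_germline_svs)

from _oracles import brute_force_single_linkage
from conftest import random_seq


def _sv(start=10_000, end=10_500, sv_type="DEL", chrom="chr1", **kw):
    length = kw.pop("sv_len", -(end - start + 1) if sv_type == "DEL"
                    else end - start + 1)
    return SvRecord(sv_type, chrom, start, end, length, **kw)


def _gt(label, gt, alt, af):
    return GenotypeEntry(label, gt, alt_depth=alt, allele_fraction=af)


class TestFiltering:
    def test_svlen_boundary_at_50bp(self):
        profile = SvFilterProfile()
        short = _sv(1000, 1048, sv_len=-49)
        exact = _sv(2000, 2049, sv_len=-50)
        assert filter_sv_callset([short, exact], profile) == [exact]

    def test_novobreak_quality_boundary_at_20(self):
        low = _sv(quality=19.0)
        ok = _sv(start=20_000, end=20_400, quality=20.0)
        assert filter_sv_callset([low, ok], NOVOBREAK_PROFILE) == [ok]

    def test_intra_chromosomal_bnd_dropped(self):
        intra = SvRecord("BND", "chr1", 100, 100, 1,
                         mate_chrom="chr1", mate_pos=90_000)
        inter = SvRecord("BND", "chr1", 100, 100, 1,
                         mate_chrom="chr2", mate_pos=90_000)
        out = filter_sv_callset([intra, inter], SvFilterProfile())
        assert out == [inter]

    def test_imprecise_and_non_pass_dropped(self):
        imprecise = _sv(precise_flag=False)
        lowqual = _sv(start=30_000, end=30_400, filter_status="LowQual")
        ok = _sv(start=40_000, end=40_400)
        assert filter_sv_callset([imprecise, lowqual, ok],
                                 SvFilterProfile()) == [ok]

    def test_translocations_exempt_from_svlen(self):
        tra = SvRecord("TRA", "chr1", 100, 100, 1,
                       mate_chrom="chr2", mate_pos=500)
        assert filter_sv_callset([tra], SvFilterProfile()) == [tra]

    def test_filtering_is_idempotent_and_subset(self):
        records = [_sv(1000, 1048, sv_len=-49), _sv(2000, 2400),
                   _sv(3000, 3400, precise_flag=False)]
        once = filter_sv_callset(records, SvFilterProfile())
        assert set(id(r) for r in once) <= set(id(r) for r in records)
        assert filter_sv_callset(once, SvFilterProfile()) == once


class TestHarmonization:
    @pytest.mark.parametrize("raw,expected", [
        ("repeat_contraction", "DEL"),
        ("tandem_contraction", "DEL"),
        ("repeat_expansion", "INS"),
        ("tandem_expansion", "INS"),
        ("DEL", "DEL"), ("INS", "INS"), ("INV", "INV"), ("DUP", "DUP"),
    ])
    def test_type_mapping(self, raw, expected):
        rec = _sv(sv_type=raw, sv_len=668)
        assert harmonize_sv_types(rec).sv_type == expected

    def test_repeat_contraction_length_preserved(self):
        # the same 668 bp event notated as Deletion vs Repeat_contraction
        rec = _sv(159_539_232, 159_543_981, sv_type="repeat_contraction",
                  sv_len=668, chrom="chr3")
        out = harmonize_sv_types(rec)
        assert out.sv_type == "DEL"
        assert out.sv_len == 668

    def test_dup_ins_pooling_is_opt_in(self):
        dup = _sv(sv_type="DUP", sv_len=300)
        assert harmonize_sv_types(dup).sv_type == "DUP"
        assert harmonize_sv_types(dup, pool_dup_ins=True).sv_type == "INS"


class TestSomaticSelection:
    def _record(self, normal_gt, tumor_gt, t_alt, t_af, n_alt=0, n_af=0.0):
        return _sv(samples=(_gt("tumor", tumor_gt, t_alt, t_af),
                            _gt("normal", normal_gt, n_alt, n_af)))

    @pytest.mark.parametrize("tumor_gt,alt,af,kept", [
        ("0/1", 6, 0.25, True),    # rule 1 satisfied
        ("1/1", 5, 0.20, True),    # rule 1 boundary
        ("0/1", 4, 0.25, False),   # alt below 5
        ("0/1", 6, 0.19, False),   # AF below 0.2
    ])
    def test_rule1_normal_reference_genotype(self, tumor_gt, alt, af, kept):
        rec = self._record("0/0", tumor_gt, alt, af)
        assert (select_somatic_sv_joint([rec]) == [rec]) is kept

    @pytest.mark.parametrize("t_alt,t_af,n_af,kept", [
        (12, 0.90, 0.40, True),    # diff 0.50 >= 0.45
        (10, 0.85, 0.40, True),    # all boundaries met
        (12, 0.80, 0.40, False),   # AF below 0.85
        (12, 0.90, 0.50, False),   # diff 0.40 < 0.45
        (9, 0.90, 0.40, False),    # alt below 10
    ])
    def test_rule2_normal_het_genotype(self, t_alt, t_af, n_af, kept):
        rec = self._record("0/1", "1/1", t_alt, t_af, n_alt=15, n_af=n_af)
        assert (select_somatic_sv_joint([rec]) == [rec]) is kept

    def test_het_to_het_never_selected(self):
        rec = self._record("0/1", "0/1", 20, 0.5, n_alt=15, n_af=0.5)
        assert select_somatic_sv_joint([rec]) == []

    def test_missing_genotype_dropped_with_warning(self, caplog):
        rec = _sv(samples=(_gt("tumor", "0/1", 20, 0.5),))
        with caplog.at_level("WARNING"):
            assert select_somatic_sv_joint([rec]) == []
        assert "missing" in caplog.text


class TestGermlineSubtraction:
    def test_supported_germline_neighbor_removes_tumor_call(self):
        tumor = _sv(50_000, 50_900)
        germ = _sv(50_100, 50_850,
                   samples=(_gt("normal", "0/1", 20, 0.5),))
        assert subtract_germline_svs([tumor], [germ]) == []

    def test_low_af_germline_does_not_subtract(self):
        tumor = _sv(50_000, 50_900)
        weak = _sv(50_100, 50_850,
                   samples=(_gt("normal", "0/1", 20, 0.05),))
        low_alt = _sv(50_100, 50_850,
                      samples=(_gt("normal", "0/1", 4, 0.5),))
        assert subtract_germline_svs([tumor], [weak]) == [tumor]
        assert subtract_germline_svs([tumor], [low_alt]) == [tumor]

    def test_distance_and_type_compatibility(self):
        tumor = _sv(50_000, 50_900)
        far = _sv(80_000, 80_900, samples=(_gt("normal", "0/1", 20, 0.5),))
        inv = _sv(50_000, 50_900, sv_type="INV", sv_len=901,
                  samples=(_gt("normal", "0/1", 20, 0.5),))
        assert subtract_germline_svs([tumor], [far]) == [tumor]
        assert subtract_germline_svs([tumor], [inv]) == [tumor]

    def test_empty_normal_set_keeps_everything(self):
        tumor = [_sv(), _sv(start=30_000, end=30_400)]
        assert subtract_germline_svs(tumor, []) == tumor


class TestMerging:
    def test_identical_record_from_two_callers_merges(self):
        a = _sv()
        b = _sv()
        (cons,) = merge_sv_callsets({"callerA": [a], "callerB": [b]})
        assert cons.support == 2
        assert cons.representative is a   # first-label member

    def test_breakpoint_distance_boundary(self):
        base = _sv(10_000, 20_000)
        near = _sv(10_900, 20_900)     # both breakpoints within 1000
        far = _sv(11_100, 21_100)      # both beyond 1000
        assert len(merge_sv_callsets({"a": [base], "b": [near]})) == 1
        assert merge_sv_callsets({"a": [base], "b": [far]}) == []

    def test_min_support_excludes_single_caller_clusters(self):
        assert merge_sv_callsets({"only": [_sv()]}) == []
        criteria = MergeCriteria(min_support=1)
        assert len(merge_sv_callsets({"only": [_sv()]}, criteria)) == 1

    def test_type_aware_clustering_separates_types(self):
        del_rec = _sv()
        inv_rec = _sv(sv_type="INV", sv_len=501)
        assert merge_sv_callsets({"a": [del_rec], "b": [inv_rec]}) == []

    def test_harmonized_types_cluster_together(self):
        del_rec = _sv()
        contraction = _sv(sv_type="repeat_contraction", sv_len=501)
        (cons,) = merge_sv_callsets({"a": [del_rec], "b": [contraction]})
        assert cons.support == 2

    def test_records_below_min_size_ignored(self):
        tiny_a = _sv(10_000, 10_040, sv_len=-41)
        tiny_b = _sv(10_010, 10_050, sv_len=-41)
        assert merge_sv_callsets({"a": [tiny_a], "b": [tiny_b]}) == []

    def test_clustering_equals_brute_force_single_linkage(self, rng):
        """Union-find clustering matches the full pairwise-graph components
        on random instances up to 200 records."""
        for _ in range(25):
            n = int(rng.integers(2, 200))
            records = []
            for i in range(n):
                start = int(rng.integers(1, 200_000))
                length = int(rng.integers(50, 2000))
                sv_type = ["DEL", "INS", "DUP", "INV"][rng.integers(4)]
                chrom = ["chr1", "chr2"][rng.integers(2)]
                records.append(_sv(start, start + length - 1, sv_type=sv_type,
                                   chrom=chrom,
                                   sv_len=length if sv_type != "DEL"
                                   else -length))
            labeled = {f"c{i}": [r] for i, r in enumerate(records)}
            criteria = MergeCriteria(min_support=1)
            mine = merge_sv_callsets(labeled, criteria)
            mine_sets = {frozenset(id(m[1]) for m in c.members)
                         for c in mine}
            oracle = brute_force_single_linkage(
                records, criteria.max_breakpoint_dist_bp, True,
                harmonized_type)
            oracle_sets = {frozenset(id(records[i]) for i in comp)
                           for comp in oracle}
            assert mine_sets == oracle_sets

    def test_replicate_support(self):
        rng = np.random.default_rng(3)
        truth_start, truth_end = 40_000, 41_000
        reps = {}
        for r in range(3):
            jit = int(rng.normal(0, 30))
            reps[f"rep{r}"] = [_sv(truth_start + jit, truth_end + jit)]
        out = require_replicate_support(reps, min_reps=2)
        assert len(out) == 1
        assert out[0].support == 3
        # an SV present in only one replicate is dropped
        reps["rep0"].append(_sv(90_000, 91_000))
        out = require_replicate_support(reps, min_reps=2)
        assert len(out) == 1


class TestFlankMapping:
    @pytest.fixture(scope="class")
    @staticmethod
    def assemblies():
        rng = np.random.default_rng(808)
        seq = random_seq(rng, 40_000)
        source = ScaffoldSet({"chr1": seq})
        target = ScaffoldSet({"chr1": seq})
        return source, target, SeedIndex(target)

    def test_flank_queries_abut_breakpoints(self, assemblies):
        source, _, _ = assemblies
        sv = _sv(20_000, 20_310)
        q = build_sv_flank_queries(sv, source)
        assert q.upstream == source.fetch("chr1", 19_900, 19_999)
        assert q.downstream == source.fetch("chr1", 20_311, 20_410)

    def test_insertion_flanks_abut_insertion_point(self, assemblies):
        source, _, _ = assemblies
        ins = _sv(20_000, 20_000, sv_type="INS", sv_len=300)
        q = build_sv_flank_queries(ins, source)
        assert q.upstream == source.fetch("chr1", 19_900, 19_999)
        assert q.downstream == source.fetch("chr1", 20_000, 20_099)

    def test_translocation_is_out_of_scope(self, assemblies):
        source, _, _ = assemblies
        tra = SvRecord("TRA", "chr1", 100, 100, 1, mate_chrom="chr2",
                       mate_pos=5)
        with pytest.raises(ValueError, match="DEL/DUP/INS/INV"):
            build_sv_flank_queries(tra, source)

    def test_edge_truncation_raises(self, assemblies):
        source, _, _ = assemblies
        with pytest.raises(SvFlankEdgeError):
            build_sv_flank_queries(_sv(50, 400), source)

    def test_verbatim_flanks_map(self, assemblies):
        source, target, index = assemblies
        sv = _sv(20_000, 20_310)
        result = map_sv_flanks(build_sv_flank_queries(sv, source), index,
                               target)
        assert result.status == "mapped"
        assert result.target_scaffold == "chr1"
        left, right = result.target_interval
        assert (left, right) == (19_999, 20_311)

    def test_destroyed_flank_is_unmapped(self, assemblies):
        source, _, _ = assemblies
        rng = np.random.default_rng(11)
        seq = source["chr1"]
        # target lacks the upstream flank sequence entirely
        broken = seq[:19_880] + random_seq(rng, 140) + seq[20_020:]
        target = ScaffoldSet({"chr1": broken})
        sv = _sv(20_000, 20_310)
        result = map_sv_flanks(build_sv_flank_queries(sv, source),
                               SeedIndex(target), target)
        assert result.status == "unmapped"

    def test_flanks_on_two_scaffolds_unmapped(self, assemblies):
        source, _, _ = assemblies
        seq = source["chr1"]
        split = ScaffoldSet({"left": seq[:20_000], "right": seq[20_000:]})
        sv = _sv(20_000, 20_310)
        result = map_sv_flanks(build_sv_flank_queries(sv, source),
                               SeedIndex(split), split)
        assert result.status == "unmapped"

    def test_match_within_radius_and_type(self, assemblies):
        source, target, index = assemblies
        sv = _sv(20_000, 20_310)
        result = map_sv_flanks(build_sv_flank_queries(sv, source), index,
                               target)
        near = _sv(19_800, 20_500)
        inv = _sv(19_800, 20_500, sv_type="INV", sv_len=701)
        far = _sv(25_000, 25_310)
        assert match_mapped_sv(result, [near]).final_status == "matched"
        assert match_mapped_sv(result, [inv]).final_status \
            == "mapped_without_match"
        assert match_mapped_sv(result, [far]).final_status \
            == "mapped_without_match"
        assert match_mapped_sv(result, []).final_status \
            == "mapped_without_match"
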