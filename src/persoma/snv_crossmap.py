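"""Two-step SNV cross-assembly mapping and four-way classification.

Each source-assembly somatic SNV is turned into a reference-allele query and
an alternate-allele query (the allele base plus 50 bp of flanking sequence on
each side).  Step 1 maps both queries under stringent criteria (identity
>= 99%, alignment length >= 101 bp); SNVs not selected in step 1 are retried
in step 2 with lower thresholds (95% identity, 95 bp alignment).  In both
steps the two queries must map to the same target location — same scaffold,
start, end, and strand — and the alternate allele must sit at the query
center.  Mapped SNVs are then classified against the target assembly's
two-caller consensus callset:

* ``identical``  — flanks align with zero non-center mismatches and no gaps,
  and a matching consensus call exists at the mapped center;
* ``equivalent`` — a matching consensus call exists but the flanks carry
  differences (germline variation between the assemblies);
* ``mapped_no_call`` — the site maps cleanly but no consensus call is there;
* ``unmapped``  — both steps fail.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

from .core_model import ScaffoldSet, SmallVariant, normalize_small_variant
from .flank_mapper import (AlignmentHit, MappingCriteria, SeedIndex,
                           local_align_query, select_best_hit)

STEP1_CRITERIA = MappingCriteria(min_identity_pct=99.0, min_alignment_len_bp=101)
STEP2_CRITERIA = MappingCriteria(min_identity_pct=95.0, min_alignment_len_bp=95)
DEFAULT_FLANK = 50

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

CATEGORIES = ("identical", "equivalent", "mapped_no_call", "unmapped")


class FlankEdgeError(ValueError):
    """The flank window is truncated by a scaffold edge; record excluded."""


@dataclass(frozen=True)
class SnvQueryPair:
    """Reference- and alternate-allele flank queries for one SNV."""

    snv: SmallVariant
    ref_query: str
    alt_query: str
    center_offset: int   # 1-based position of the allele base within the query

    @property
    def query_len(self) -> int:
        return len(self.ref_query)


@dataclass(frozen=True)
class SnvMappingResult:
    snv: SmallVariant
    step: int | None                    # 1 | 2 | None
    ref_hit: AlignmentHit | None = None
    alt_hit: AlignmentHit | None = None
    mapped_center: tuple[str, int] | None = None
    category: str | None = None
    flank_mismatch_count: int = 0

    @property
    def strand(self) -> str | None:
        return self.ref_hit.strand if self.ref_hit else None


def build_snv_queries(snv: SmallVariant, source_genome: ScaffoldSet,
                      flank: int = DEFAULT_FLANK) -> SnvQueryPair:
    """Extract both alleles of a SNV with their flanking sequences.

    Raises :class:`FlankEdgeError` when the window would run off the
    scaffold, and ``ValueError`` for non-SNV input or a REF/genome mismatch.
    """
    if not snv.is_snv:
        raise ValueError("flank queries are built for single-base substitutions only")
    scaffold_len = len(source_genome[snv.chrom])
    start, end = snv.pos - flank, snv.pos + flank
    if start < 1 or end > scaffold_len:
        raise FlankEdgeError(
            f"{snv.chrom}:{snv.pos}: flank window {start}-{end} outside scaffold")
    ref_query = source_genome.fetch(snv.chrom, start, end)
    center = flank  # 0-based index of the allele base
    if ref_query[center] != snv.ref_allele:
        raise ValueError(
            f"{snv.chrom}:{snv.pos}: REF {snv.ref_allele!r} != genome "
            f"{ref_query[center]!r}")
    alt_query = ref_query[:center] + snv.alt_allele + ref_query[center + 1:]
    return SnvQueryPair(snv=snv, ref_query=ref_query, alt_query=alt_query,
                        center_offset=flank + 1)


def _paired_best_hits(pair: SnvQueryPair, index: SeedIndex,
                      genome: ScaffoldSet, criteria: MappingCriteria
                      ) -> tuple[AlignmentHit, AlignmentHit] | None:
    ref_hit = select_best_hit(local_align_query(
        pair.ref_query, index, genome, criteria, query_id="ref"))
    alt_hit = select_best_hit(local_align_query(
        pair.alt_query, index, genome, criteria, query_id="alt"))
    if ref_hit is None or alt_hit is None:
        return None
    same_locus = (ref_hit.target_scaffold == alt_hit.target_scaffold
                  and ref_hit.target_start == alt_hit.target_start
                  and ref_hit.target_end == alt_hit.target_end
                  and ref_hit.strand == alt_hit.strand)
    if not same_locus:
        return None
    return ref_hit, alt_hit


def map_snv_two_step(pair: SnvQueryPair, target_index: SeedIndex,
                     target_genome: ScaffoldSet,
                     step1: MappingCriteria = STEP1_CRITERIA,
                     step2: MappingCriteria = STEP2_CRITERIA
                     ) -> SnvMappingResult:
    """Map one SNV query pair with the stringent-then-relaxed two-step rule.

    Both queries' best hits must share scaffold, start, end, and strand, and
    the query center must project onto a target base (not a gap).  The
    returned result has ``category`` unset; see :func:`classify_snv_mapping`.
    """
    for step, criteria in ((1, step1), (2, step2)):
        hits = _paired_best_hits(pair, target_index, target_genome, criteria)
        if hits is None:
            continue
        ref_hit, alt_hit = hits
        # the ref query matches the (normal) target at the center, so its
        # alignment places the center base unambiguously; the alt query can
        # legally explain its center mismatch as an indel pair instead
        center_t = (ref_hit.project_query_pos(pair.center_offset)
                    or alt_hit.project_query_pos(pair.center_offset))
        if center_t is None:
            continue
        flank_mm = sum(1 for p in ref_hit.mismatch_query_positions()
                       if p != pair.center_offset)
        return SnvMappingResult(
            snv=pair.snv, step=step, ref_hit=ref_hit, alt_hit=alt_hit,
            mapped_center=(alt_hit.target_scaffold, center_t),
            flank_mismatch_count=flank_mm)
    return SnvMappingResult(snv=pair.snv, step=None, category="unmapped")


def _flanks_perfect(result: SnvMappingResult, center_offset: int) -> bool:
    """Zero non-center mismatches, no gaps, full-length alignment in both hits."""
    for hit in (result.ref_hit, result.alt_hit):
        if hit.n_gap_columns > 0:
            return False
        if hit.alignment_len != hit.query_len:
            return False
        non_center = [p for p in hit.mismatch_query_positions() if p != center_offset]
        if non_center:
            return False
    return True


def classify_snv_mapping(result: SnvMappingResult,
                         target_consensus_snvs: Iterable[SmallVariant],
                         center_offset: int = DEFAULT_FLANK + 1
                         ) -> SnvMappingResult:
    """Assign the four-way category to a mapping result.

    ``target_consensus_snvs`` is the two-caller overlap set on the target
    assembly.  Allele matching complements the source alleles when the
    mapping is on the minus strand.
    """
    if result.step is None:
        return replace(result, category="unmapped")
    by_site = _index_by_site(target_consensus_snvs)
    scaffold, pos = result.mapped_center
    ref, alt = result.snv.ref_allele, result.snv.alt_allele
    if result.strand == "-":
        ref, alt = _COMP[ref], _COMP[alt]
    call = by_site.get((scaffold, pos))
    if call is None or call.alt_allele != alt:
        return replace(result, category="mapped_no_call")
    category = ("identical" if _flanks_perfect(result, center_offset)
                else "equivalent")
    return replace(result, category=category)


def _index_by_site(snvs: Iterable[SmallVariant]) -> dict[tuple[str, int], SmallVariant]:
    if isinstance(snvs, dict):
        return snvs
    return {(v.chrom, v.pos): v for v in snvs if v.is_snv}


def intersect_caller_callsets(callset_a: Sequence[SmallVariant],
                              callset_b: Sequence[SmallVariant],
                              genome: ScaffoldSet) -> list[SmallVariant]:
    """Allele-aware consensus of two caller callsets on one assembly.

    Both callsets are normalized (indels left-aligned and trimmed) against
    ``genome``; records present in both under (chrom, pos, ref, alt) equality
    survive.  SNVs and indels are intersected separately, which under keyed
    equality is the same partition-wise operation.
    """
    norm_a = [normalize_small_variant(v, genome) for v in callset_a]
    keys_b = {normalize_small_variant(v, genome).key() for v in callset_b}
    seen: set[tuple] = set()
    out = []
    for v in norm_a:
        k = v.key()
        if k in keys_b and k not in seen:
            seen.add(k)
            out.append(v)
    return out


@dataclass(frozen=True)
class SnvCrossmapSummary:
    category_counts: dict[str, int]
    step1_selected: int
    step2_selected: int
    total: int


def crossmap_snvs(source_snvs: Sequence[SmallVariant],
                  source_genome: ScaffoldSet,
                  target_genome: ScaffoldSet,
                  target_consensus_snvs: Sequence[SmallVariant],
                  target_index: SeedIndex | None = None,
                  flank: int = DEFAULT_FLANK
                  ) -> tuple[list[SnvMappingResult], SnvCrossmapSummary]:
    """Run build -> two-step map -> classify over a whole SNV callset.

    SNVs whose flank window is truncated by a scaffold edge are excluded up
    front (counted in no category).  Every remaining SNV receives exactly one
    category.  ``step1_selected`` is reported alongside the flank-based
    ``identical`` count so either reading of "identical" can be checked.
    """
    if target_index is None:
        target_index = SeedIndex(target_genome)
    by_site = _index_by_site(target_consensus_snvs)
    results = []
    for snv in source_snvs:
        try:
            pair = build_snv_queries(snv, source_genome, flank=flank)
        except FlankEdgeError:
            continue
        result = map_snv_two_step(pair, target_index, target_genome)
        result = classify_snv_mapping(result, by_site,
                                      center_offset=pair.center_offset)
        results.append(result)
    counts = {c: 0 for c in CATEGORIES}
    for r in results:
        counts[r.category] += 1
    summary = SnvCrossmapSummary(
        category_counts=counts,
        step1_selected=sum(1 for r in results if r.step == 1),
        step2_selected=sum(1 for r in results if r.step == 2),
        total=len(results))
    return results, summary
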