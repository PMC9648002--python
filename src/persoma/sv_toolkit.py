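"""Structural-variant callset filtering, somatic selection, germline
subtraction, type harmonization, consensus merging, replicate-support
filtering, and cross-assembly SV mapping/matching.

Thresholds mirror the analysis defaults: SVLEN >= 50 bp (translocations
exempt), novoBreak quality >= 20, IMPRECISE/SHADOWED calls dropped,
intra-chromosomal breakends removed, and SURVIVOR-style consensus merging
with a 1000 bp breakpoint radius and a minimum caller support of 2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

from .core_model import (RegionExclusionRules, ScaffoldSet, SvRecord,
                         apply_region_exclusions)
from .flank_mapper import (AlignmentHit, MappingCriteria, SeedIndex,
                           local_align_query, select_best_hit)

logger = logging.getLogger(__name__)

SV_FLANK_CRITERIA = MappingCriteria(min_identity_pct=98.0, min_alignment_len_bp=90)
DEFAULT_SV_FLANK = 100
MAPPABLE_SV_TYPES = frozenset({"DEL", "DUP", "INS", "INV"})

_DEL_LIKE = frozenset({"DEL", "repeat_contraction", "tandem_contraction"})
_INS_LIKE = frozenset({"INS", "repeat_expansion", "tandem_expansion"})


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SvFilterProfile:
    """Pre-filters applied to one caller's SV callset, in a fixed order:
    PASS, quality, IMPRECISE/SHADOWED, SVLEN, intra-chromosomal BND,
    region exclusion."""

    min_sv_len_bp: int = 50
    drop_intra_chrom_bnd: bool = True
    min_quality: float | None = None       # novoBreak uses 20
    require_pass: bool = True
    drop_imprecise: bool = True
    drop_shadowed: bool = True
    region_rules: RegionExclusionRules | None = None

    def __post_init__(self):
        if self.min_sv_len_bp < 1:
            raise ValueError("min_sv_len_bp must be >= 1")


NOVOBREAK_PROFILE = SvFilterProfile(min_quality=20.0)


def filter_sv_callset(records: Sequence[SvRecord],
                      profile: SvFilterProfile) -> list[SvRecord]:
    """Apply the ordered pre-filter stack; the output is a subset of the
    input and the operation is idempotent."""
    kept = list(records)
    stages: list[tuple[str, int]] = []

    def _stage(name, pred):
        nonlocal kept
        before = len(kept)
        kept = [r for r in kept if pred(r)]
        stages.append((name, before - len(kept)))

    if profile.require_pass:
        _stage("PASS", lambda r: r.filter_status == "PASS")
    if profile.min_quality is not None:
        _stage("quality", lambda r: r.quality is None
               or r.quality >= profile.min_quality)
    if profile.drop_imprecise:
        _stage("IMPRECISE", lambda r: r.precise_flag)
    if profile.drop_shadowed:
        _stage("SHADOWED", lambda r: "SHADOWED" not in r.filter_status)
    _stage("SVLEN", lambda r: r.is_translocation
           or abs(r.sv_len) >= profile.min_sv_len_bp)
    if profile.drop_intra_chrom_bnd:
        _stage("intra-chrom BND", lambda r: not r.is_intra_chrom_bnd)
    if profile.region_rules is not None:
        before = len(kept)
        kept = apply_region_exclusions(kept, profile.region_rules)
        stages.append(("region", before - len(kept)))
    logger.info("SV filter stages: %s",
                ", ".join(f"{n}={d}" for n, d in stages))
    return kept


def harmonize_sv_types(record: SvRecord, pool_dup_ins: bool = False) -> SvRecord:
    """Collapse caller-specific SV notations onto canonical types.

    Deletions pool with repeat/tandem contractions (DEL); insertions pool
    with repeat/tandem expansions (INS).  With ``pool_dup_ins`` DUP and INS
    both report as INS, the pooled "DUP/INS" accounting unit.
    """
    t = record.sv_type
    if t in _DEL_LIKE:
        new = "DEL"
    elif t in _INS_LIKE:
        new = "INS"
    elif t in ("DUP", "INV", "TRA", "BND"):
        new = t
    else:  # pragma: no cover - SvRecord already validates sv_type
        raise ValueError(f"unknown sv_type {t!r}")
    if pool_dup_ins and new == "DUP":
        new = "INS"
    return record if new == t else replace(record, sv_type=new)


def harmonized_type(record: SvRecord, pool_dup_ins: bool = False) -> str:
    return harmonize_sv_types(record, pool_dup_ins=pool_dup_ins).sv_type


# ---------------------------------------------------------------------------
# Somatic selection on joint tumor-normal genotyped calls
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SomaticSelectionCriteria:
    """Two-rule somatic selection on jointly genotyped tumor/normal calls.

    Rule 1: normal 0/0 and tumor 0/1 or 1/1 with alternate allele count >= 5
    and allele fraction >= 0.2.  Rule 2: normal 0/1 and tumor 1/1 with
    alternate allele count >= 10, allele fraction >= 0.85, and tumor-normal
    allele-fraction difference >= 0.45.
    """

    rule1_min_tumor_alt: int = 5
    rule1_min_tumor_af: float = 0.2
    rule2_min_tumor_alt: int = 10
    rule2_min_tumor_af: float = 0.85
    rule2_min_af_diff: float = 0.45
    germline_min_af: float = 0.1
    germline_min_alt: int = 5


DEFAULT_SOMATIC_CRITERIA = SomaticSelectionCriteria()
_EPS = 1e-9


def _passes_somatic_rules(record: SvRecord,
                          c: SomaticSelectionCriteria) -> bool:
    tumor = record.sample("tumor")
    normal = record.sample("normal")
    if tumor is None or normal is None:
        logger.warning("record %s missing tumor/normal genotype; dropped",
                       record.record_id or f"{record.chrom}:{record.start}")
        return False
    t_alt = tumor.alt_depth if tumor.alt_depth is not None else 0
    t_af = tumor.allele_fraction if tumor.allele_fraction is not None else 0.0
    if normal.genotype == "0/0":
        return (tumor.genotype in ("0/1", "1/1")
                and t_alt >= c.rule1_min_tumor_alt
                and t_af >= c.rule1_min_tumor_af - _EPS)
    if normal.genotype == "0/1":
        n_af = normal.allele_fraction if normal.allele_fraction is not None else 0.0
        return (tumor.genotype == "1/1"
                and t_alt >= c.rule2_min_tumor_alt
                and t_af >= c.rule2_min_tumor_af - _EPS
                and (t_af - n_af) >= c.rule2_min_af_diff - _EPS)
    return False


def select_somatic_sv_joint(joint_records: Sequence[SvRecord],
                            criteria: SomaticSelectionCriteria = DEFAULT_SOMATIC_CRITERIA
                            ) -> list[SvRecord]:
    """Retain records satisfying either somatic selection rule."""
    return [r for r in joint_records if _passes_somatic_rules(r, criteria)]


# ---------------------------------------------------------------------------
# Breakpoint-distance clustering (consensus merging)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MergeCriteria:
    """SURVIVOR-style merge parameters: breakpoint radius, minimum caller
    support, minimum SV size."""

    max_breakpoint_dist_bp: int = 1000
    min_support: int = 2
    min_size_bp: int = 50
    type_aware: bool = True

    def __post_init__(self):
        if min(self.max_breakpoint_dist_bp, self.min_support, self.min_size_bp) < 1:
            raise ValueError("merge criteria must be positive")


DEFAULT_MERGE_CRITERIA = MergeCriteria()


@dataclass(frozen=True)
class ConsensusSv:
    """One merged SV cluster: a representative record plus its supporters."""

    representative: SvRecord
    support_labels: tuple[str, ...]
    members: tuple[tuple[str, SvRecord], ...]

    @property
    def support(self) -> int:
        return len(set(self.support_labels))


def _breakpoints_close(a: SvRecord, b: SvRecord, dist: int,
                       type_aware: bool) -> bool:
    if type_aware and harmonized_type(a) != harmonized_type(b):
        return False
    if a.chrom != b.chrom:
        return False
    if a.is_translocation or b.is_translocation:
        if not (a.is_translocation and b.is_translocation):
            return False
        return (a.mate_chrom == b.mate_chrom
                and abs(a.start - b.start) <= dist
                and abs(a.mate_pos - b.mate_pos) <= dist)
    return abs(a.start - b.start) <= dist and abs(a.end - b.end) <= dist


def _single_linkage_clusters(labeled: list[tuple[str, SvRecord]],
                             criteria: MergeCriteria) -> list[list[int]]:
    """Union-find single linkage under the breakpoint-distance relation."""
    n = len(labeled)
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x, y):
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[max(rx, ry)] = min(rx, ry)

    order = sorted(range(n), key=lambda i: (labeled[i][1].chrom,
                                            labeled[i][1].start))
    for oi in range(n):
        i = order[oi]
        for oj in range(oi + 1, n):
            j = order[oj]
            if labeled[j][1].chrom != labeled[i][1].chrom:
                break
            if (labeled[j][1].start - labeled[i][1].start
                    > criteria.max_breakpoint_dist_bp):
                break
            if _breakpoints_close(labeled[i][1], labeled[j][1],
                                  criteria.max_breakpoint_dist_bp,
                                  criteria.type_aware):
                union(i, j)
        # translocations may pair beyond the start-sorted horizon via mates;
        # fall back to full scan for them
        if labeled[i][1].is_translocation:
            for j in range(n):
                if j != i and _breakpoints_close(
                        labeled[i][1], labeled[j][1],
                        criteria.max_breakpoint_dist_bp, criteria.type_aware):
                    union(i, j)
    clusters: dict[int, list[int]] = {}
    for i in range(n):
        clusters.setdefault(find(i), []).append(i)
    return [sorted(v) for _, v in sorted(clusters.items())]


def merge_sv_callsets(labeled_callsets: Mapping[str, Sequence[SvRecord]],
                      criteria: MergeCriteria = DEFAULT_MERGE_CRITERIA
                      ) -> list[ConsensusSv]:
    """Single-linkage consensus merge of per-caller callsets.

    Same-(harmonized-)type records whose start and end breakpoints each
    differ by at most the radius link into one cluster; clusters supported
    by at least ``min_support`` distinct labels survive.  Records below
    ``min_size_bp`` are ignored (translocations exempt).  The representative
    is the first-label member (insertion-order label priority, then
    coordinate order).
    """
    label_priority = {lab: i for i, lab in enumerate(labeled_callsets)}
    labeled: list[tuple[str, SvRecord]] = []
    for label, records in labeled_callsets.items():
        for rec in records:
            if rec.is_translocation or abs(rec.sv_len) >= criteria.min_size_bp:
                labeled.append((label, rec))
    out = []
    for cluster in _single_linkage_clusters(labeled, criteria):
        members = [labeled[i] for i in cluster]
        labels = tuple(lab for lab, _ in members)
        if len(set(labels)) < criteria.min_support:
            continue
        rep = min(members, key=lambda m: (label_priority[m[0]], m[1].chrom,
                                          m[1].start, m[1].end))[1]
        out.append(ConsensusSv(representative=rep, support_labels=labels,
                               members=tuple(members)))
    out.sort(key=lambda c: (c.representative.chrom, c.representative.start))
    return out


def require_replicate_support(replicate_callsets: Mapping[str, Sequence[SvRecord]],
                              min_reps: int = 2,
                              criteria: MergeCriteria = DEFAULT_MERGE_CRITERIA
                              ) -> list[ConsensusSv]:
    """Keep SVs called in at least ``min_reps`` replicates of one caller
    (same clustering as consensus merging, support counted over replicates)."""
    return merge_sv_callsets(replicate_callsets,
                             replace(criteria, min_support=min_reps))


def subtract_germline_svs(tumor_svs: Sequence[SvRecord],
                          normal_svs: Sequence[SvRecord],
                          criteria: SomaticSelectionCriteria = DEFAULT_SOMATIC_CRITERIA,
                          merge_criteria: MergeCriteria = DEFAULT_MERGE_CRITERIA
                          ) -> list[SvRecord]:
    """Remove tumor calls overlapping sufficiently supported germline calls.

    The germline set is first reduced to records with allele fraction >= 0.1
    and alternate allele count >= 5 (in any genotyped sample); a tumor record
    is dropped iff a reduced germline record of compatible harmonized type
    lies within the breakpoint radius.
    """
    def _supported(rec: SvRecord) -> bool:
        entries = rec.samples or ()
        if not entries:
            return True   # assembly-derived germline calls carry no depths
        for e in entries:
            af = e.allele_fraction if e.allele_fraction is not None else 0.0
            alt = e.alt_depth if e.alt_depth is not None else 0
            if af >= criteria.germline_min_af - _EPS and alt >= criteria.germline_min_alt:
                return True
        return False

    germline = [r for r in normal_svs if _supported(r)]
    kept = []
    for rec in tumor_svs:
        if any(_breakpoints_close(rec, g, merge_criteria.max_breakpoint_dist_bp,
                                  merge_criteria.type_aware) for g in germline):
            continue
        kept.append(rec)
    return kept


# ---------------------------------------------------------------------------
# Cross-assembly SV flank mapping
# ---------------------------------------------------------------------------

class SvFlankEdgeError(ValueError):
    """A flank window runs off the scaffold; record excluded and logged."""


@dataclass(frozen=True)
class SvFlankQueries:
    sv: SvRecord
    upstream: str     # ends at start-1 on the source assembly
    downstream: str   # begins at end+1


@dataclass(frozen=True)
class SvMappingResult:
    sv: SvRecord
    status: str                                   # mapped | unmapped
    target_scaffold: str | None = None
    target_interval: tuple[int, int] | None = None
    strand: str | None = None
    match_status: str | None = None               # matched | mapped_without_match

    @property
    def final_status(self) -> str:
        """One of matched / mapped_without_match / unmapped."""
        if self.status == "unmapped":
            return "unmapped"
        return self.match_status or "mapped_without_match"


def build_sv_flank_queries(sv: SvRecord, source_genome: ScaffoldSet,
                           flank: int = DEFAULT_SV_FLANK) -> SvFlankQueries:
    """Extract the two flanking sequences of a DEL/DUP/INS/INV.

    For insertions (start == end insertion point) the flanks abut the
    insertion point.  Translocations are out of mapping scope.
    """
    if sv.sv_type not in MAPPABLE_SV_TYPES:
        raise ValueError(f"flank mapping covers DEL/DUP/INS/INV only, "
                         f"not {sv.sv_type}")
    scaffold_len = len(source_genome[sv.chrom])
    up_start, up_end = sv.start - flank, sv.start - 1
    down_start = sv.end + 1 if sv.sv_type != "INS" else sv.start
    down_end = down_start + flank - 1
    if up_start < 1 or down_end > scaffold_len:
        raise SvFlankEdgeError(
            f"{sv.chrom}:{sv.start}-{sv.end}: flank window outside scaffold")
    return SvFlankQueries(
        sv=sv,
        upstream=source_genome.fetch(sv.chrom, up_start, up_end),
        downstream=source_genome.fetch(sv.chrom, down_start, down_end))


def map_sv_flanks(queries: SvFlankQueries, target_index: SeedIndex,
                  target_genome: ScaffoldSet,
                  criteria: MappingCriteria = SV_FLANK_CRITERIA
                  ) -> SvMappingResult:
    """Map both flanks; "mapped" requires both best hits to meet the
    identity/length gate on one scaffold, same strand, in consistent order.
    The target interval spans between the inner hit ends."""
    up_hit = select_best_hit(local_align_query(
        queries.upstream, target_index, target_genome, criteria, query_id="up"))
    down_hit = select_best_hit(local_align_query(
        queries.downstream, target_index, target_genome, criteria, query_id="down"))
    if up_hit is None or down_hit is None:
        return SvMappingResult(sv=queries.sv, status="unmapped")
    if (up_hit.target_scaffold != down_hit.target_scaffold
            or up_hit.strand != down_hit.strand):
        return SvMappingResult(sv=queries.sv, status="unmapped")
    if up_hit.strand == "+":
        inner_left, inner_right = up_hit.target_end, down_hit.target_start
    else:
        inner_left, inner_right = down_hit.target_end, up_hit.target_start
    if inner_right < inner_left:
        return SvMappingResult(sv=queries.sv, status="unmapped")
    return SvMappingResult(
        sv=queries.sv, status="mapped",
        target_scaffold=up_hit.target_scaffold,
        target_interval=(inner_left, inner_right),
        strand=up_hit.strand)


def match_mapped_sv(result: SvMappingResult,
                    target_consensus_svs: Sequence[SvRecord | ConsensusSv],
                    merge_criteria: MergeCriteria = DEFAULT_MERGE_CRITERIA
                    ) -> SvMappingResult:
    """Matched iff a target SV of compatible harmonized type has both
    breakpoints within the radius of the mapped interval."""
    if result.status != "mapped":
        return result
    left, right = result.target_interval
    probe_type = harmonized_type(result.sv)
    dist = merge_criteria.max_breakpoint_dist_bp
    for target in target_consensus_svs:
        rec = target.representative if isinstance(target, ConsensusSv) else target
        if rec.is_translocation:
            continue
        if merge_criteria.type_aware and harmonized_type(rec) != probe_type:
            continue
        if (rec.chrom == result.target_scaffold
                and abs(rec.start - left) <= dist
                and abs(rec.end - right) <= dist):
            return replace(result, match_status="matched")
    return replace(result, match_status="mapped_without_match")


def crossmap_svs(svs: Sequence[SvRecord], source_genome: ScaffoldSet,
                 target_genome: ScaffoldSet,
                 target_consensus_svs: Sequence[SvRecord | ConsensusSv],
                 target_index: SeedIndex | None = None,
                 flank: int = DEFAULT_SV_FLANK,
                 criteria: MappingCriteria = SV_FLANK_CRITERIA,
                 merge_criteria: MergeCriteria = DEFAULT_MERGE_CRITERIA
                 ) -> list[SvMappingResult]:
    """Flank-map and match a whole SV callset (TRA excluded up front).

    Every mappable input SV ends up exactly one of matched /
    mapped_without_match / unmapped.
    """
    if target_index is None:
        target_index = SeedIndex(target_genome)
    out = []
    for sv in svs:
        if sv.sv_type not in MAPPABLE_SV_TYPES:
            continue
        try:
            queries = build_sv_flank_queries(sv, source_genome, flank=flank)
        except SvFlankEdgeError as exc:
            logger.info("excluded: %s", exc)
            continue
        result = map_sv_flanks(queries, target_index, target_genome, criteria)
        result = match_mapped_sv(result, target_consensus_svs, merge_criteria)
        out.append(result)
    return out
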