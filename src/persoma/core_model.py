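"""Domain types, FASTA/VCF readers and writers, coordinate conventions, and
the shared callset pre-filters.

All coordinates are 1-based inclusive (VCF convention).  Any half-open
arithmetic is confined to private helpers.  Sequences are uppercase strings
over the alphabet ``{A, C, G, T, N}``; N bases never count as matches
anywhere downstream.
"""

from __future__ import annotations

import fnmatch
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_BASES = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of an A/C/G/T/N sequence."""
    return seq.translate(_COMPLEMENT)[::-1]


class ParseError(ValueError):
    """Raised when an input file violates its format contract."""


class RefMismatchError(ValueError):
    """Raised when a variant's REF allele disagrees with the attached genome."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

class ScaffoldSet:
    """An ordered collection of named linear sequences.

    The unit both real assemblies and synthetic genomes share.  Scaffold
    names are unique, sequences non-empty and restricted to A/C/G/T/N.
    A per-scaffold ``circular`` flag marks the mitochondrion.
    """

    def __init__(self, scaffolds: dict[str, str] | None = None,
                 circular_flags: dict[str, bool] | None = None):
        self._scaffolds: dict[str, str] = {}
        self._circular: dict[str, bool] = {}
        if scaffolds:
            for name, seq in scaffolds.items():
                self.add(name, seq, circular=bool(circular_flags.get(name, False))
                         if circular_flags else False)

    def add(self, name: str, seq: str, circular: bool = False) -> None:
        if name in self._scaffolds:
            raise ValueError(f"duplicate scaffold name: {name!r}")
        seq = seq.upper()
        if not seq:
            raise ValueError(f"scaffold {name!r} has an empty sequence")
        bad = set(seq) - VALID_BASES
        if bad:
            raise ValueError(f"scaffold {name!r} contains invalid bases: {sorted(bad)}")
        self._scaffolds[name] = seq
        self._circular[name] = circular

    def __contains__(self, name: str) -> bool:
        return name in self._scaffolds

    def __getitem__(self, name: str) -> str:
        return self._scaffolds[name]

    def __len__(self) -> int:
        return len(self._scaffolds)

    def __iter__(self) -> Iterator[str]:
        return iter(self._scaffolds)

    def names(self) -> list[str]:
        return list(self._scaffolds)

    def items(self) -> Iterable[tuple[str, str]]:
        return self._scaffolds.items()

    def lengths(self) -> dict[str, int]:
        return {n: len(s) for n, s in self._scaffolds.items()}

    def total_bp(self) -> int:
        return sum(len(s) for s in self._scaffolds.values())

    def is_circular(self, name: str) -> bool:
        return self._circular[name]

    def fetch(self, name: str, start: int, end: int) -> str:
        """1-based inclusive slice of scaffold ``name``; bounds checked."""
        seq = self._scaffolds[name]
        if start < 1 or end > len(seq) or end < start:
            raise IndexError(
                f"window {name}:{start}-{end} outside scaffold of length {len(seq)}")
        return seq[start - 1:end]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ScaffoldSet):
            return NotImplemented
        return (self._scaffolds == other._scaffolds
                and self._circular == other._circular
                and list(self._scaffolds) == list(other._scaffolds))


@dataclass(frozen=True)
class GenotypeEntry:
    """Per-sample genotype payload: GT, alternate allele count, allele fraction."""

    sample_label: str                      # "tumor" | "normal"
    genotype: str                          # "0/0" | "0/1" | "1/1" | "./."
    alt_depth: int | None = None
    allele_fraction: float | None = None

    def __post_init__(self):
        if self.genotype not in {"0/0", "0/1", "1/1", "./."}:
            raise ValueError(f"unsupported genotype {self.genotype!r}")
        if self.alt_depth is not None and self.alt_depth < 0:
            raise ValueError("alt_depth must be non-negative")
        if self.allele_fraction is not None and not 0.0 <= self.allele_fraction <= 1.0:
            raise ValueError("allele_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class SmallVariant:
    """A SNV or small indel: chrom, 1-based pos of the first REF base, alleles."""

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    filter_status: str = "PASS"
    samples: tuple[GenotypeEntry, ...] = ()

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError("pos must be >= 1")
        if not self.ref_allele or not self.alt_allele:
            raise ValueError("alleles must be non-empty")

    @property
    def is_snv(self) -> bool:
        return len(self.ref_allele) == 1 == len(self.alt_allele)

    def sample(self, label: str) -> GenotypeEntry | None:
        for entry in self.samples:
            if entry.sample_label == label:
                return entry
        return None

    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref_allele, self.alt_allele)


SV_TYPES = ("DEL", "DUP", "INS", "INV", "TRA", "BND",
            "repeat_contraction", "repeat_expansion",
            "tandem_contraction", "tandem_expansion")


@dataclass(frozen=True)
class SvRecord:
    """A typed structural variant with 1-based inclusive breakpoint span."""

    sv_type: str
    chrom: str
    start: int
    end: int
    sv_len: int
    mate_chrom: str | None = None
    mate_pos: int | None = None
    quality: float | None = None
    precise_flag: bool = True
    filter_status: str = "PASS"
    samples: tuple[GenotypeEntry, ...] = ()
    record_id: str | None = None
    caller: str | None = None

    def __post_init__(self):
        if self.sv_type not in SV_TYPES:
            raise ValueError(f"unknown sv_type {self.sv_type!r}")
        if self.sv_type in ("TRA", "BND"):
            if self.mate_chrom is None or self.mate_pos is None:
                raise ValueError("TRA/BND records require mate coordinates")
        else:
            if self.end < self.start:
                raise ValueError("end must be >= start for non-TRA records")
            if abs(self.sv_len) < 1:
                raise ValueError("|sv_len| must be >= 1")

    @property
    def is_translocation(self) -> bool:
        return self.sv_type in ("TRA", "BND")

    @property
    def is_intra_chrom_bnd(self) -> bool:
        return self.is_translocation and self.mate_chrom == self.chrom

    def sample(self, label: str) -> GenotypeEntry | None:
        for entry in self.samples:
            if entry.sample_label == label:
                return entry
        return None


@dataclass(frozen=True)
class PartialExclude:
    """Sub-scaffold rule expressed the way the analysis states it:
    drop positions ``below``/``above`` a coordinate on one scaffold."""

    scaffold: str
    comparator: str          # "below" | "above"
    coordinate: int

    def matches(self, chrom: str, pos: int) -> bool:
        if chrom != self.scaffold:
            return False
        if self.comparator == "below":
            return pos < self.coordinate
        if self.comparator == "above":
            return pos > self.coordinate
        raise ValueError(f"unknown comparator {self.comparator!r}")


@dataclass(frozen=True)
class RegionExclusionRules:
    """Whole-scaffold name patterns plus comparator-style partial excludes."""

    whole_scaffold_excludes: tuple[str, ...] = ()
    partial_excludes: tuple[PartialExclude, ...] = ()

    def matches(self, chrom: str, pos: int) -> bool:
        for pattern in self.whole_scaffold_excludes:
            if fnmatch.fnmatchcase(chrom, pattern):
                return True
        return any(rule.matches(chrom, pos) for rule in self.partial_excludes)

    def to_bed(self, scaffold_lengths: dict[str, int]) -> list[tuple[str, int, int]]:
        """Export as half-open BED intervals over known scaffolds."""
        out: list[tuple[str, int, int]] = []
        for name, length in scaffold_lengths.items():
            if any(fnmatch.fnmatchcase(name, p) for p in self.whole_scaffold_excludes):
                out.append((name, 0, length))
                continue
            for rule in self.partial_excludes:
                if rule.scaffold != name:
                    continue
                if rule.comparator == "below":
                    out.append((name, 0, min(rule.coordinate - 1, length)))
                else:
                    out.append((name, min(rule.coordinate, length), length))
        return out


def grch38_exclusion_rules() -> RegionExclusionRules:
    """The study's exclusion set: chrX, chrY, unplaced/unlocalized/decoy
    scaffolds, chr6p below 58,500,000 and chr16q above 38,400,000."""
    return RegionExclusionRules(
        whole_scaffold_excludes=("chrX", "chrY", "chrUn_*", "*_random", "*_decoy", "*_alt"),
        partial_excludes=(
            PartialExclude("chr6", "below", 58_500_000),
            PartialExclude("chr16", "above", 38_400_000),
        ),
    )


# ---------------------------------------------------------------------------
# FASTA io
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> ScaffoldSet:
    """Read a (possibly wrapped) multi-record FASTA into a ScaffoldSet.

    Lowercase bases are uppercased.  Empty or duplicate records raise
    :class:`ParseError` naming the offending header line.
    """
    path = Path(path)
    sset = ScaffoldSet()
    for rec in SeqIO.parse(str(path), "fasta"):
        circular = "circular" in rec.description.lower()
        try:
            sset.add(rec.id, str(rec.seq), circular=circular)
        except ValueError as exc:
            line_no = _find_header_line(path, rec.id)
            raise ParseError(f"{path}:{line_no}: {exc}") from exc
    if len(sset) == 0:
        raise ParseError(f"{path}:1: no FASTA records found")
    return sset


def _find_header_line(path: Path, name: str) -> int:
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            if line.startswith(">") and line[1:].split()[0:1] == [name]:
                return i
    return 1


def write_fasta(sset: ScaffoldSet, path: str | Path, width: int = 60) -> None:
    """Write a ScaffoldSet as wrapped FASTA, preserving record order."""
    records = []
    for name, seq in sset.items():
        desc = "circular" if sset.is_circular(name) else ""
        records.append(SeqRecord(Seq(seq), id=name, description=desc))
    writer_path = str(Path(path))
    with open(writer_path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# VCF io
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VcfDialect:
    """Names which INFO/FORMAT keys carry the modeled fields for one caller.

    ``require_pass`` keeps only FILTER == PASS (or '.') records on read,
    the default throughout the analysis.
    """

    name: str = "generic"
    svtype_key: str = "SVTYPE"
    svlen_key: str = "SVLEN"
    end_key: str = "END"
    imprecise_key: str = "IMPRECISE"
    gt_key: str = "GT"
    ad_key: str = "AD"
    af_key: str = "AF"
    require_pass: bool = True
    sample_labels: tuple[str, ...] = ("tumor", "normal")


GENERIC_DIALECT = VcfDialect()


def _genotype_entries(rec, dialect: VcfDialect) -> tuple[GenotypeEntry, ...]:
    entries = []
    for i, sample_name in enumerate(rec.samples):
        label = (dialect.sample_labels[i]
                 if i < len(dialect.sample_labels) else sample_name)
        sample = rec.samples[sample_name]
        gt = sample.get(dialect.gt_key)
        if gt is None or all(a is None for a in gt):
            gt_str = "./."
        else:
            gt_str = "/".join("." if a is None else str(min(a, 1)) for a in gt)
            if gt_str == "1/0":
                gt_str = "0/1"
        alt_depth = None
        af = None
        ad = sample.get(dialect.ad_key)
        if ad is not None and len(ad) >= 2 and ad[1] is not None:
            alt_depth = int(ad[1])
            total = sum(int(x) for x in ad if x is not None)
            if total > 0:
                af = alt_depth / total
        af_val = sample.get(dialect.af_key)
        if af_val is not None:
            af = float(af_val[0] if isinstance(af_val, tuple) else af_val)
        try:
            entries.append(GenotypeEntry(label, gt_str, alt_depth, af))
        except ValueError:
            entries.append(GenotypeEntry(label, "./.", alt_depth, af))
    return tuple(entries)


def read_vcf(path: str | Path,
             dialect: VcfDialect = GENERIC_DIALECT) -> list[SmallVariant | SvRecord]:
    """Read a VCF into SmallVariant / SvRecord objects.

    Records with an SVTYPE INFO key become :class:`SvRecord`; everything else
    becomes :class:`SmallVariant`.  Multi-allelic small-variant records are
    split into bi-allelic records.  Unknown keys are ignored.
    """
    path = Path(path)
    out: list[SmallVariant | SvRecord] = []
    try:
        vf = pysam.VariantFile(str(path))
    except (OSError, ValueError) as exc:
        raise ParseError(f"{path}: not a parseable VCF: {exc}") from exc
    with vf:
        for rec in vf:
            filt = ",".join(rec.filter.keys()) if list(rec.filter.keys()) else "PASS"
            if filt == ".":
                filt = "PASS"
            if dialect.require_pass and filt != "PASS":
                continue
            info = dict(rec.info)
            if dialect.svtype_key in info:
                out.append(_sv_from_pysam(rec, info, filt, dialect))
            else:
                out.extend(_small_from_pysam(rec, filt, dialect))
    return out


def _sv_from_pysam(rec, info, filt, dialect: VcfDialect) -> SvRecord:
    svtype = info[dialect.svtype_key]
    if isinstance(svtype, tuple):
        svtype = svtype[0]
    svlen = info.get(dialect.svlen_key)
    if isinstance(svlen, tuple):
        svlen = svlen[0]
    end = info.get(dialect.end_key, rec.stop)
    mate_chrom = info.get("CHR2")
    mate_pos = info.get("MATEPOS") or (end if mate_chrom else None)
    if svtype in ("TRA", "BND") and mate_chrom is None:
        # parse a breakend ALT like N[chr2:321682[
        m = re.search(r"[\[\]]([^\[\]:]+):(\d+)[\[\]]", rec.alts[0] if rec.alts else "")
        if m:
            mate_chrom, mate_pos = m.group(1), int(m.group(2))
        else:
            raise ParseError(f"{rec.chrom}:{rec.pos}: TRA/BND without mate coordinate")
    if svlen is None:
        svlen = int(end) - rec.pos + 1 if svtype != "INS" else 0
    return SvRecord(
        sv_type=str(svtype), chrom=rec.chrom, start=rec.pos,
        end=int(end) if end is not None else rec.pos,
        sv_len=int(svlen),
        mate_chrom=mate_chrom, mate_pos=int(mate_pos) if mate_pos else None,
        quality=rec.qual, precise_flag=not info.get(dialect.imprecise_key, False),
        filter_status=filt, samples=_genotype_entries(rec, dialect),
        record_id=rec.id, caller=dialect.name if dialect.name != "generic" else None)


def _small_from_pysam(rec, filt, dialect: VcfDialect) -> list[SmallVariant]:
    if rec.pos is None or rec.ref is None:
        raise ParseError(f"{rec.chrom}: record with unparseable coordinate")
    out = []
    for alt in rec.alts or ():
        if alt is None or set(alt.upper()) - VALID_BASES:
            continue   # symbolic or spanning-deletion allele
        out.append(SmallVariant(
            chrom=rec.chrom, pos=rec.pos, ref_allele=rec.ref.upper(),
            alt_allele=alt.upper(), filter_status=filt,
            samples=_genotype_entries(rec, dialect)))
    return out


def write_vcf(records: Sequence[SmallVariant | SvRecord],
              path: str | Path,
              scaffold_lengths: dict[str, int] | None = None,
              dialect: VcfDialect = GENERIC_DIALECT) -> None:
    """Write records to a plain-text VCF; lossless for the modeled fields."""
    header = pysam.VariantHeader()
    header.add_line('##source=persoma')
    contigs: dict[str, int] = dict(scaffold_lengths or {})
    for rec in records:
        for name in filter(None, (getattr(rec, "chrom", None),
                                  getattr(rec, "mate_chrom", None))):
            contigs.setdefault(name, 2_000_000_000)
    for name, length in contigs.items():
        header.add_line(f'##contig=<ID={name},length={length}>')
    header.add_line('##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">')
    header.add_line('##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="SV length">')
    header.add_line('##INFO=<ID=END,Number=1,Type=Integer,Description="End position">')
    header.add_line('##INFO=<ID=IMPRECISE,Number=0,Type=Flag,Description="Imprecise breakpoints">')
    header.add_line('##INFO=<ID=CHR2,Number=1,Type=String,Description="Mate chromosome">')
    header.add_line('##INFO=<ID=MATEPOS,Number=1,Type=Integer,Description="Mate position">')
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header.add_line('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">')
    header.add_line('##FORMAT=<ID=AF,Number=1,Type=Float,Description="Allele fraction">')
    header.add_line('##FILTER=<ID=LowQual,Description="Non-PASS">')
    sample_names = []
    for rec in records:
        for entry in rec.samples:
            if entry.sample_label not in sample_names:
                sample_names.append(entry.sample_label)
    for name in sample_names:
        header.add_sample(name)
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for i, rec in enumerate(records):
            out = vf.new_record()
            out.chrom = rec.chrom
            out.id = getattr(rec, "record_id", None) or f"rec{i+1}"
            if isinstance(rec, SvRecord):
                out.pos = rec.start
                out.ref = "N"
                out.alts = (f"<{rec.sv_type}>",)
                out.info["SVTYPE"] = rec.sv_type
                out.info["SVLEN"] = rec.sv_len
                out.stop = max(rec.end, rec.start)
                if rec.mate_chrom is not None:
                    out.info["CHR2"] = rec.mate_chrom
                    out.info["MATEPOS"] = rec.mate_pos
                if not rec.precise_flag:
                    out.info["IMPRECISE"] = True
                if rec.quality is not None:
                    out.qual = rec.quality
            else:
                out.pos = rec.pos
                out.ref = rec.ref_allele
                out.alts = (rec.alt_allele,)
            if rec.filter_status == "PASS":
                out.filter.add("PASS")
            else:
                out.filter.add("LowQual")
            for entry in rec.samples:
                sample = out.samples[entry.sample_label]
                if entry.genotype == "./.":
                    sample["GT"] = (None, None)
                else:
                    sample["GT"] = tuple(int(a) for a in entry.genotype.split("/"))
                if entry.allele_fraction is not None:
                    sample["AF"] = entry.allele_fraction
                if entry.alt_depth is not None:
                    af = entry.allele_fraction
                    if af and af > 0:
                        total = round(entry.alt_depth / af)
                    else:
                        total = entry.alt_depth
                    sample["AD"] = (max(total - entry.alt_depth, 0), entry.alt_depth)
            vf.write(out)


# ---------------------------------------------------------------------------
# Region exclusion and small-variant normalization
# ---------------------------------------------------------------------------

def apply_region_exclusions(records: Sequence[SmallVariant | SvRecord],
                            rules: RegionExclusionRules
                            ) -> list[SmallVariant | SvRecord]:
    """Drop records falling in excluded regions.

    A record is dropped iff any rule matches its position; a translocation is
    dropped if either endpoint matches.  Unknown scaffold names pass through
    unless a name pattern matches them.
    """
    kept = []
    for rec in records:
        if isinstance(rec, SvRecord):
            hit = rules.matches(rec.chrom, rec.start)
            if not hit and not rec.is_translocation:
                hit = rules.matches(rec.chrom, rec.end)
            if not hit and rec.is_translocation:
                hit = rules.matches(rec.mate_chrom, rec.mate_pos)
        else:
            hit = rules.matches(rec.chrom, rec.pos)
        if not hit:
            kept.append(rec)
    return kept


def normalize_small_variant(variant: SmallVariant, genome: ScaffoldSet) -> SmallVariant:
    """Left-align and parsimony-trim a small variant against ``genome``.

    SNVs are returned unchanged.  The operation is idempotent and preserves
    the reconstructed haplotype.  Raises :class:`RefMismatchError` when the
    REF allele disagrees with the genome.
    """
    seq = genome[variant.chrom]
    pos, ref, alt = variant.pos, variant.ref_allele, variant.alt_allele
    if seq[pos - 1:pos - 1 + len(ref)] != ref:
        raise RefMismatchError(
            f"{variant.chrom}:{pos} REF {ref!r} != genome "
            f"{seq[pos - 1:pos - 1 + len(ref)]!r}")
    if len(ref) == 1 == len(alt):
        return variant
    # vt-style normalization: shrink from the right (extending left through
    # the genome when an allele empties), then trim the shared prefix.
    while True:
        if ref and alt and ref[-1] == alt[-1] and (len(ref) > 1 or len(alt) > 1):
            ref, alt = ref[:-1], alt[:-1]
            if not ref or not alt:
                pos -= 1
                if pos < 1:
                    raise RefMismatchError("cannot left-extend past scaffold start")
                base = seq[pos - 1]
                ref, alt = base + ref, base + alt
            continue
        break
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return replace(variant, pos=pos, ref_allele=ref, alt_allele=alt)


def apply_variant_to_sequence(seq: str, variant: SmallVariant) -> str:
    """Reconstruct the mutated haplotype (used by normalization tests)."""
    p = variant.pos - 1
    assert seq[p:p + len(variant.ref_allele)] == variant.ref_allele
    return seq[:p] + variant.alt_allele + seq[p + len(variant.ref_allele):]
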