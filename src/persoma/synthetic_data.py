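"""Synthetic dual-assembly data: a reference genome, a personal genome
differing by germline variation (SNVs, indels, repeat-element SVs), tumor
somatic truth with allele fractions, and simulated caller callsets against
either assembly.

The generator emulates the structure of a tumor/normal personal-genome
study: the personal genome carries repeat insertions (Alu-like ~300 bp,
LTR-like ~500 bp, SVA-like ~1.6 kb) absent from the reference, homopolymer
run-length differences, and germline SNVs in the flanks of somatic sites;
somatic variants carry mutant allele fractions from a clonal-het/hom
mixture (0.5 and 1.0).  A single seeded RNG stream makes every product
byte-reproducible.

Coordinates of every planted variant are recorded on BOTH assemblies via an
explicit edit script, so recovery tests can score cross-assembly mapping
exactly.
"""

from __future__ import annotations

import bisect
import logging
import zlib
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np

from .core_model import (GenotypeEntry, ScaffoldSet, SmallVariant, SvRecord,
                         revcomp)

logger = logging.getLogger(__name__)

_BASES = np.array(list("ACGT"))

DEFAULT_REPEAT_LIBRARY = {
    "AluLike": {"length": 300, "reference_copies": 5, "personal_only_copies": 2},
    "LtrLike": {"length": 500, "reference_copies": 3, "personal_only_copies": 1},
    "SvaLike": {"length": 1600, "reference_copies": 2, "personal_only_copies": 1},
}


@dataclass(frozen=True)
class CallerProfile:
    """Error model for one simulated caller."""

    name: str
    fn_rate: float = 0.0
    fp_rate: float = 0.0          # expected false positives per truth record
    jitter_sd_bp: float = 0.0     # sd of Gaussian breakpoint jitter
    base_quality: float = 60.0

    def __post_init__(self):
        if not 0 <= self.fn_rate <= 1 or not 0 <= self.fp_rate <= 1:
            raise ValueError("rates must lie in [0, 1]")
        if self.jitter_sd_bp < 0:
            raise ValueError("jitter sd must be >= 0")


NOISE_FREE = CallerProfile(name="noise_free")


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    n_scaffolds: int = 2
    scaffold_length_bp: int = 500_000
    gc_content: float = 0.41
    chrm_length_bp: int = 16_500
    germline_snv_rate: float = 1e-3
    germline_indel_rate: float = 1e-4
    germline_sv_counts: dict[str, int] = field(
        default_factory=lambda: {"DEL": 4, "INS": 4, "tandem_expansion": 2})
    repeat_library: dict[str, dict[str, int]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_REPEAT_LIBRARY.items()})
    repeat_divergence_range: tuple[float, float] = (0.005, 0.02)
    homopolymer_diff_count: int = 2
    somatic_snv_count: int = 100
    somatic_maf_clonal_fraction: float = 0.7    # P(MAF=0.5); else MAF=1.0
    somatic_sv_counts: dict[str, int] = field(
        default_factory=lambda: {"DEL": 6, "INS": 3, "DUP": 2, "INV": 2})
    somatic_sv_in_personal_repeat: int = 1
    min_sv_separation_bp: int = 2000
    sequencing_depth: int = 30

    def __post_init__(self):
        for rate in (self.germline_snv_rate, self.germline_indel_rate,
                     self.somatic_maf_clonal_fraction, self.gc_content):
            if not 0 <= rate <= 1:
                raise ValueError("rates must lie in [0, 1]")
        if any(c < 0 for c in self.germline_sv_counts.values()):
            raise ValueError("counts must be >= 0")


@dataclass(frozen=True)
class RepeatPlacement:
    repeat_id: str      # e.g. "AluLike.3"
    family: str
    scaffold: str
    start: int          # 1-based, on the genome the copy lives in
    length: int
    personal_only: bool = False


@dataclass(frozen=True)
class TruthVariant:
    """A planted variant with coordinates on both assemblies.

    ``ref_pos`` is ``None`` for variants whose context exists only on the
    personal genome (``personal_only_context=True``).
    """

    kind: Literal["snv", "indel", "sv"]
    is_somatic: bool
    chrom: str
    personal_pos: int | None
    ref_pos: int | None
    ref_allele: str = ""
    alt_allele: str = ""
    sv_type: str | None = None
    sv_len: int = 0
    personal_end: int | None = None
    ref_end: int | None = None
    maf: float | None = None
    zygosity: str = "het"             # germline zygosity
    personal_only_context: bool = False
    provenance: str | None = None


class EditScript:
    """The exact reference -> personal coordinate lift.

    Edits are VCF-style replacements (pos, ref_len, alt_len) anchored at a
    shared base; they never overlap.  The lift is invertible on every
    position outside replaced spans.
    """

    def __init__(self):
        self._edits: dict[str, list[tuple[int, int, int]]] = {}
        self._finalized: dict[str, tuple[list[int], list[int]]] = {}

    def add(self, chrom: str, pos: int, ref_len: int, alt_len: int) -> None:
        self._edits.setdefault(chrom, []).append((pos, ref_len, alt_len))
        self._finalized.pop(chrom, None)

    def edits(self, chrom: str) -> list[tuple[int, int, int]]:
        return sorted(self._edits.get(chrom, []))

    def _tables(self, chrom: str) -> tuple[list[int], list[int]]:
        if chrom not in self._finalized:
            ends, deltas = [], []
            delta = 0
            for pos, ref_len, alt_len in self.edits(chrom):
                delta += alt_len - ref_len
                ends.append(pos + ref_len - 1)
                deltas.append(delta)
            self._finalized[chrom] = (ends, deltas)
        return self._finalized[chrom]

    def ref_to_personal(self, chrom: str, pos: int) -> int | None:
        """Personal-genome position of reference position ``pos``; ``None``
        when the base was removed by an edit."""
        for e_pos, ref_len, alt_len in self.edits(chrom):
            if e_pos < pos <= e_pos + ref_len - 1:
                return None   # inside a replaced span (anchor base excluded)
        ends, deltas = self._tables(chrom)
        i = bisect.bisect_left(ends, pos)
        delta = deltas[i - 1] if i > 0 else 0
        return pos + delta

    def personal_to_ref(self, chrom: str, pos: int) -> int | None:
        """Inverse lift; ``None`` for positions inside personal-only spans."""
        delta = 0
        for e_pos, ref_len, alt_len in self.edits(chrom):
            p_start = e_pos + delta
            if pos <= p_start:
                break
            if p_start < pos <= p_start + alt_len - 1:
                return None
            delta += alt_len - ref_len
        return pos - delta

    def apply(self, chrom: str, seq: str,
              alt_seqs: dict[tuple[int, int, int], str]) -> str:
        """Splice the personal sequence from the reference in one pass."""
        pieces = []
        cursor = 0   # 0-based position in seq
        for edit in self.edits(chrom):
            pos, ref_len, _ = edit
            pieces.append(seq[cursor:pos - 1])
            pieces.append(alt_seqs[edit])
            cursor = pos - 1 + ref_len
        pieces.append(seq[cursor:])
        return "".join(pieces)


@dataclass
class TruthSet:
    germline_variants: list[TruthVariant]
    somatic_variants: list[TruthVariant]
    edit_script: EditScript
    repeat_placements: list[RepeatPlacement] = field(default_factory=list)

    def to_table(self) -> "object":
        """Truth records as a pandas DataFrame (TSV-ready)."""
        import pandas as pd
        rows = []
        for v in self.germline_variants + self.somatic_variants:
            rows.append({
                "kind": v.kind, "somatic": v.is_somatic, "chrom": v.chrom,
                "ref_pos": v.ref_pos, "ref_end": v.ref_end,
                "personal_pos": v.personal_pos, "personal_end": v.personal_end,
                "ref_allele": v.ref_allele, "alt_allele": v.alt_allele,
                "sv_type": v.sv_type, "sv_len": v.sv_len, "maf": v.maf,
                "zygosity": v.zygosity,
                "personal_only_context": v.personal_only_context,
                "provenance": v.provenance})
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Reference genome
# ---------------------------------------------------------------------------

def _random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(_BASES[rng.choice(4, size=length, p=p)])


def _diverge(rng: np.random.Generator, seq: str, rate: float) -> str:
    """Substitute a fraction ``rate`` of bases (per-copy repeat divergence)."""
    arr = np.array(list(seq))
    n_mut = int(round(rate * len(seq)))
    if n_mut == 0:
        return seq
    pos = rng.choice(len(seq), size=n_mut, replace=False)
    for p in pos:
        choices = [b for b in "ACGT" if b != arr[p]]
        arr[p] = choices[rng.integers(3)]
    return "".join(arr)


def generate_reference_genome(config: SimulationConfig
                              ) -> tuple[ScaffoldSet, list[RepeatPlacement],
                                         dict[str, str]]:
    """Deterministic random reference with planted repeat copies and a small
    circular chrM scaffold.

    Returns the genome, the recorded repeat placements, and the repeat
    family consensus sequences (used again when planting personal-only
    copies).
    """
    rng = np.random.default_rng(config.seed)
    total_repeat = sum(v["length"] * v["reference_copies"]
                       for v in config.repeat_library.values())
    if total_repeat > 0.5 * config.n_scaffolds * config.scaffold_length_bp:
        raise ValueError("scaffold_length_bp too small to host configured repeats")
    consensus = {fam: _random_seq(rng, fam_cfg["length"], config.gc_content)
                 for fam, fam_cfg in config.repeat_library.items()}
    scaffolds: dict[str, str] = {}
    placements: list[RepeatPlacement] = []
    lo, hi = config.repeat_divergence_range
    for s in range(config.n_scaffolds):
        name = f"scaffold_{s + 1}"
        seq = _random_seq(rng, config.scaffold_length_bp, config.gc_content)
        taken: list[tuple[int, int]] = []
        for fam, fam_cfg in config.repeat_library.items():
            length = fam_cfg["length"]
            n_here = _copies_on_scaffold(fam_cfg["reference_copies"],
                                         config.n_scaffolds, s)
            for c in range(n_here):
                start = _place_nonoverlapping(rng, len(seq), length, taken,
                                              margin=config.min_sv_separation_bp)
                copy_seq = _diverge(rng, consensus[fam], rng.uniform(lo, hi))
                seq = seq[:start - 1] + copy_seq + seq[start - 1 + length:]
                placements.append(RepeatPlacement(
                    repeat_id=f"{fam}.{name}.{c}", family=fam, scaffold=name,
                    start=start, length=length))
        scaffolds[name] = seq
    sset = ScaffoldSet(scaffolds)
    sset.add("chrM", _random_seq(rng, config.chrm_length_bp, config.gc_content),
             circular=True)
    return sset, placements, consensus


def _copies_on_scaffold(total: int, n_scaffolds: int, index: int) -> int:
    base, extra = divmod(total, n_scaffolds)
    return base + (1 if index < extra else 0)


def _place_nonoverlapping(rng: np.random.Generator, scaffold_len: int,
                          length: int, taken: list[tuple[int, int]],
                          margin: int, max_tries: int = 1000) -> int:
    for _ in range(max_tries):
        start = int(rng.integers(margin, scaffold_len - length - margin))
        if all(start + length + margin < a or start > b + margin
               for a, b in taken):
            taken.append((start, start + length - 1))
            return start
    raise RuntimeError("could not place a non-overlapping feature; "
                       "scaffold too crowded")


# ---------------------------------------------------------------------------
# Personal genome (germline edits)
# ---------------------------------------------------------------------------

def derive_personal_genome(reference: ScaffoldSet, config: SimulationConfig,
                           placements: Sequence[RepeatPlacement] = (),
                           consensus: dict[str, str] | None = None
                           ) -> tuple[ScaffoldSet, TruthSet]:
    """Apply germline SNVs, indels, repeat-element SVs, and homopolymer
    run-length differences to the reference, emitting the exact edit script.

    Overlapping candidate edits are rejected and resampled (logged).  With
    all germline rates and counts zero the personal genome is identical to
    the reference and the lift map is the identity.
    """
    rng = np.random.default_rng(config.seed + 1)
    consensus = consensus or {}
    script = EditScript()
    alt_seqs: dict[str, dict[tuple[int, int, int], str]] = {}
    germline: list[TruthVariant] = []
    personal_repeats: list[RepeatPlacement] = []

    nuclear = [n for n in reference.names() if not reference.is_circular(n)]
    for chrom in nuclear:
        seq = reference[chrom]
        n = len(seq)
        alt_seqs[chrom] = {}
        occupied: list[tuple[int, int]] = []

        def _claim(start: int, end: int) -> bool:
            for a, b in occupied:
                if start <= b and a <= end:
                    return False
            occupied.append((start, end))
            return True

        # --- structural germline edits first (they need elbow room) ---
        sv_jobs: list[tuple[str, str | None]] = []
        for sv_type, count in config.germline_sv_counts.items():
            sv_jobs += [(sv_type, None)] * _copies_on_scaffold(
                count, len(nuclear), nuclear.index(chrom))
        for fam, fam_cfg in config.repeat_library.items():
            n_here = _copies_on_scaffold(fam_cfg.get("personal_only_copies", 0),
                                         len(nuclear), nuclear.index(chrom))
            sv_jobs += [("repeat_insertion", fam)] * n_here
        for sv_type, fam in sv_jobs:
            for attempt in range(1000):
                ok = _plant_germline_sv(rng, config, chrom, seq, sv_type, fam,
                                        consensus, _claim, script,
                                        alt_seqs[chrom], germline,
                                        personal_repeats)
                if ok:
                    break
                logger.debug("resampled overlapping germline SV on %s", chrom)
            else:
                raise RuntimeError("could not place germline SV")

        # --- homopolymer run-length differences ---
        n_homo = _copies_on_scaffold(config.homopolymer_diff_count,
                                     len(nuclear), nuclear.index(chrom))
        for _ in range(n_homo):
            for attempt in range(1000):
                pos = int(rng.integers(1000, n - 1000))
                extra = int(rng.integers(5, 20))
                if not _claim(pos - 10, pos + 10):
                    continue
                base = seq[pos - 1]
                edit = (pos, 1, 1 + extra)
                script.add(chrom, *edit)
                alt_seqs[chrom][edit] = base * (1 + extra)
                germline.append(TruthVariant(
                    kind="indel", is_somatic=False, chrom=chrom,
                    ref_pos=pos, personal_pos=None, ref_allele=base,
                    alt_allele=base * (1 + extra), zygosity="hom",
                    provenance=f"homopolymer+{extra}"))
                break

        # --- point SNVs and small indels ---
        n_snv = rng.binomial(n, config.germline_snv_rate)
        n_indel = rng.binomial(n, config.germline_indel_rate)
        positions = rng.choice(np.arange(1000, n - 1000), size=n_snv + n_indel,
                               replace=False)
        for i, pos in enumerate(int(p) for p in positions):
            if not _claim(pos - 1, pos + 20):
                continue
            base = seq[pos - 1]
            if base == "N":
                continue
            zyg = "het" if rng.random() < 0.6 else "hom"
            if i < n_snv:
                alt = str(rng.choice([b for b in "ACGT" if b != base]))
                if zyg == "hom":   # only hom-alt germline changes the assembly
                    edit = (pos, 1, 1)
                    script.add(chrom, *edit)
                    alt_seqs[chrom][edit] = alt
                germline.append(TruthVariant(
                    kind="snv", is_somatic=False, chrom=chrom, ref_pos=pos,
                    personal_pos=None, ref_allele=base, alt_allele=alt,
                    zygosity=zyg))
            else:
                del_len = int(rng.integers(1, 10))
                ref_allele = seq[pos - 1:pos + del_len]
                if "N" in ref_allele or len(ref_allele) < del_len + 1:
                    continue
                if zyg == "hom":
                    edit = (pos, del_len + 1, 1)
                    script.add(chrom, *edit)
                    alt_seqs[chrom][edit] = base
                germline.append(TruthVariant(
                    kind="indel", is_somatic=False, chrom=chrom, ref_pos=pos,
                    personal_pos=None, ref_allele=ref_allele, alt_allele=base,
                    zygosity=zyg))

    personal = ScaffoldSet()
    for chrom in reference.names():
        if chrom in alt_seqs:
            personal.add(chrom, script.apply(chrom, reference[chrom],
                                             alt_seqs[chrom]),
                         circular=reference.is_circular(chrom))
        else:
            personal.add(chrom, reference[chrom],
                         circular=reference.is_circular(chrom))

    germline = [_fill_personal_coords(v, script) for v in germline]
    truth = TruthSet(germline_variants=germline, somatic_variants=[],
                     edit_script=script, repeat_placements=personal_repeats)
    return personal, truth


def _plant_germline_sv(rng, config, chrom, seq, sv_type, fam, consensus,
                       _claim, script, alt_seqs, germline,
                       personal_repeats) -> bool:
    n = len(seq)
    margin = config.min_sv_separation_bp
    if sv_type == "repeat_insertion":
        motif = consensus.get(fam) or _random_seq(
            rng, config.repeat_library[fam]["length"], config.gc_content)
        lo, hi = config.repeat_divergence_range
        ins = _diverge(rng, motif, rng.uniform(lo, hi))
        pos = int(rng.integers(margin, n - margin))
        if not _claim(pos - margin // 2, pos + margin // 2):
            return False
        edit = (pos, 1, 1 + len(ins))
        script.add(chrom, *edit)
        alt_seqs[edit] = seq[pos - 1] + ins
        germline.append(TruthVariant(
            kind="sv", is_somatic=False, chrom=chrom, ref_pos=pos,
            personal_pos=None, sv_type="INS", sv_len=len(ins),
            ref_end=pos, zygosity="hom",
            provenance=f"personal_only:{fam}"))
        personal_repeats.append(RepeatPlacement(
            repeat_id=f"{fam}.{chrom}.personal",
            family=fam, scaffold=chrom, start=pos + 1, length=len(ins),
            personal_only=True))
        return True
    if sv_type == "DEL":
        length = int(rng.integers(50, 1000))
        pos = int(rng.integers(margin, n - margin - length))
        if not _claim(pos - margin // 2, pos + length + margin // 2):
            return False
        edit = (pos, 1 + length, 1)
        script.add(chrom, *edit)
        alt_seqs[edit] = seq[pos - 1]
        germline.append(TruthVariant(
            kind="sv", is_somatic=False, chrom=chrom, ref_pos=pos,
            personal_pos=None, sv_type="DEL", sv_len=-length,
            ref_end=pos + length, zygosity="hom"))
        return True
    if sv_type == "INS":
        length = int(rng.integers(50, 500))
        ins = _random_seq(rng, length, config.gc_content)
        pos = int(rng.integers(margin, n - margin))
        if not _claim(pos - margin // 2, pos + margin // 2):
            return False
        edit = (pos, 1, 1 + length)
        script.add(chrom, *edit)
        alt_seqs[edit] = seq[pos - 1] + ins
        germline.append(TruthVariant(
            kind="sv", is_somatic=False, chrom=chrom, ref_pos=pos,
            personal_pos=None, sv_type="INS", sv_len=length,
            ref_end=pos, zygosity="hom"))
        return True
    if sv_type == "tandem_expansion":
        unit = int(rng.integers(50, 300))
        pos = int(rng.integers(margin, n - margin - unit))
        if not _claim(pos - margin // 2, pos + unit + margin // 2):
            return False
        segment = seq[pos - 1:pos - 1 + unit]
        if "N" in segment:
            return False
        edit = (pos + unit - 1, 1, 1 + unit)   # duplicate the unit in place
        script.add(chrom, *edit)
        alt_seqs[edit] = seq[pos + unit - 2] + segment
        germline.append(TruthVariant(
            kind="sv", is_somatic=False, chrom=chrom, ref_pos=pos,
            personal_pos=None, sv_type="tandem_expansion", sv_len=unit,
            ref_end=pos + unit - 1, zygosity="hom"))
        return True
    raise ValueError(f"unsupported germline sv_type {sv_type!r}")


def _fill_personal_coords(v: TruthVariant, script: EditScript) -> TruthVariant:
    personal_pos = (script.ref_to_personal(v.chrom, v.ref_pos)
                    if v.ref_pos is not None else None)
    personal_end = (script.ref_to_personal(v.chrom, v.ref_end)
                    if v.ref_end is not None else None)
    return replace(v, personal_pos=personal_pos, personal_end=personal_end)


# ---------------------------------------------------------------------------
# Somatic truth
# ---------------------------------------------------------------------------

def _draw_maf(rng: np.random.Generator, config: SimulationConfig) -> float:
    return 0.5 if rng.random() < config.somatic_maf_clonal_fraction else 1.0


def plant_somatic_variants(personal: ScaffoldSet, config: SimulationConfig,
                           truth: TruthSet) -> TruthSet:
    """Plant somatic SNVs and SVs on the personal genome.

    Positions are drawn on the personal genome (the tumor's reference
    frame); reference-assembly coordinates come from the inverse lift and
    are ``None`` — with ``personal_only_context=True`` — when the variant
    falls in personal-only sequence.  A configurable number of somatic DELs
    deliberately removes a personal-only repeat copy to emulate
    repeat-mediated deletions detectable only on the personal genome.
    """
    rng = np.random.default_rng(config.seed + 2)
    script = truth.edit_script
    somatic: list[TruthVariant] = []
    nuclear = [n for n in personal.names() if not personal.is_circular(n)]
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in nuclear}

    def _claim(chrom: str, start: int, end: int) -> bool:
        for a, b in occupied[chrom]:
            if start <= b and a <= end:
                return False
        occupied[chrom].append((start, end))
        return True

    # germline SVs own their neighborhoods: somatic SVs planted within the
    # merge radius of one would (correctly) be removed by germline
    # subtraction, so keep them apart by construction
    for g in truth.germline_variants:
        if g.kind != "sv" or g.personal_pos is None:
            continue
        g_end = g.personal_end if g.personal_end is not None else g.personal_pos
        occupied[g.chrom].append((g.personal_pos - config.min_sv_separation_bp,
                                  g_end + abs(g.sv_len)
                                  + config.min_sv_separation_bp))

    # somatic DELs inside personal-only repeat copies
    personal_only = [p for p in truth.repeat_placements if p.personal_only]
    for placement in personal_only[:config.somatic_sv_in_personal_repeat]:
        chrom = placement.scaffold
        # the repeat body sits on the personal genome; find its personal span
        start_p = None
        for e_pos, ref_len, alt_len in script.edits(chrom):
            if alt_len > ref_len and e_pos + 1 == placement.start:
                start_p = script.ref_to_personal(chrom, e_pos) + 1
                break
        if start_p is None:
            continue
        end_p = start_p + placement.length - 1
        _claim(chrom, start_p - config.min_sv_separation_bp,
               end_p + config.min_sv_separation_bp)
        somatic.append(TruthVariant(
            kind="sv", is_somatic=True, chrom=chrom,
            personal_pos=start_p, personal_end=end_p,
            ref_pos=None, ref_end=None,
            sv_type="DEL", sv_len=-placement.length,
            maf=1.0, personal_only_context=True,
            provenance=f"del_of:{placement.repeat_id}"))

    # regular somatic SVs
    for sv_type, count in config.somatic_sv_counts.items():
        planted = 0
        tries = 0
        while planted < count and tries < 10_000:
            tries += 1
            chrom = nuclear[int(rng.integers(len(nuclear)))]
            n = len(personal[chrom])
            length = int(rng.integers(50, 1000))
            pos = int(rng.integers(config.min_sv_separation_bp,
                                   n - config.min_sv_separation_bp - length))
            end = pos if sv_type == "INS" else pos + length - 1
            if not _claim(chrom, pos - config.min_sv_separation_bp,
                          end + config.min_sv_separation_bp):
                continue
            ref_pos = script.personal_to_ref(chrom, pos)
            ref_end = script.personal_to_ref(chrom, end)
            personal_only = ref_pos is None or ref_end is None
            somatic.append(TruthVariant(
                kind="sv", is_somatic=True, chrom=chrom,
                personal_pos=pos, personal_end=end,
                ref_pos=ref_pos, ref_end=ref_end,
                sv_type=sv_type,
                sv_len=-length if sv_type == "DEL" else length,
                maf=_draw_maf(rng, config),
                personal_only_context=personal_only))
            planted += 1
        if planted < count:
            raise RuntimeError(f"could not place {count} somatic {sv_type}s")

    # somatic SNVs
    planted = 0
    tries = 0
    while planted < config.somatic_snv_count and tries < 100_000:
        tries += 1
        chrom = nuclear[int(rng.integers(len(nuclear)))]
        n = len(personal[chrom])
        pos = int(rng.integers(200, n - 200))
        if not _claim(chrom, pos - 150, pos + 150):
            continue
        base = personal[chrom][pos - 1]
        if base == "N":
            continue
        alt = str(rng.choice([b for b in "ACGT" if b != base]))
        ref_pos = script.personal_to_ref(chrom, pos)
        somatic.append(TruthVariant(
            kind="snv", is_somatic=True, chrom=chrom,
            personal_pos=pos, ref_pos=ref_pos,
            ref_allele=base, alt_allele=alt,
            maf=_draw_maf(rng, config),
            personal_only_context=ref_pos is None))
        planted += 1
    if planted < config.somatic_snv_count:
        raise RuntimeError("could not place the requested somatic SNVs")

    truth.somatic_variants = somatic
    return truth


def simulate_truth(config: SimulationConfig
                   ) -> tuple[ScaffoldSet, ScaffoldSet, TruthSet]:
    """Reference genome + personal genome + full germline/somatic truth."""
    reference, placements, consensus = generate_reference_genome(config)
    personal, truth = derive_personal_genome(reference, config,
                                             placements, consensus)
    truth.repeat_placements = placements + truth.repeat_placements
    truth = plant_somatic_variants(personal, config, truth)
    return reference, personal, truth


# ---------------------------------------------------------------------------
# Simulated caller callsets
# ---------------------------------------------------------------------------

def _truth_to_record(v: TruthVariant, target: str,
                     profile: CallerProfile,
                     rng: np.random.Generator,
                     rec_id: str) -> SmallVariant | SvRecord | None:
    pos = v.personal_pos if target == "personal" else v.ref_pos
    end = v.personal_end if target == "personal" else v.ref_end
    if pos is None:
        return None   # no coordinates on this assembly
    if v.kind in ("snv", "indel"):
        return SmallVariant(chrom=v.chrom, pos=pos, ref_allele=v.ref_allele,
                            alt_allele=v.alt_allele, filter_status="PASS")
    jitter = (int(round(rng.normal(0, profile.jitter_sd_bp)))
              if profile.jitter_sd_bp > 0 else 0)
    jitter2 = (int(round(rng.normal(0, profile.jitter_sd_bp)))
               if profile.jitter_sd_bp > 0 else 0)
    start = max(1, pos + jitter)
    end = max(start, (end if end is not None else pos) + jitter2)
    return SvRecord(sv_type=v.sv_type, chrom=v.chrom, start=start, end=end,
                    sv_len=v.sv_len, quality=profile.base_quality,
                    filter_status="PASS", record_id=rec_id,
                    caller=profile.name)


def simulate_caller_callset(truth_variants: Sequence[TruthVariant],
                            target_assembly: str,
                            caller_profile: CallerProfile,
                            seed: int = 0) -> list[SmallVariant | SvRecord]:
    """One caller's callset against one assembly.

    Drops each truth record with probability ``fn_rate``, adds
    Poisson-distributed false positives, jitters SV breakpoints, and stamps
    the caller's quality.  Truth records without coordinates on the target
    assembly (personal-only context) are silently absent from a
    reference-assembly callset.
    """
    if target_assembly not in ("reference", "personal"):
        raise ValueError("target_assembly must be 'reference' or 'personal'")
    name_tag = zlib.crc32(caller_profile.name.encode()) & 0x7FFFFFFF
    rng = np.random.default_rng((seed, name_tag))
    out: list[SmallVariant | SvRecord] = []
    for i, v in enumerate(truth_variants):
        if caller_profile.fn_rate > 0 and rng.random() < caller_profile.fn_rate:
            continue
        rec = _truth_to_record(v, target_assembly, caller_profile, rng,
                               rec_id=f"{caller_profile.name}.{i}")
        if rec is not None:
            out.append(rec)
    n_fp = (rng.poisson(caller_profile.fp_rate * len(truth_variants))
            if caller_profile.fp_rate > 0 else 0)
    chroms = sorted({v.chrom for v in truth_variants}) or ["scaffold_1"]
    for j in range(n_fp):
        chrom = chroms[int(rng.integers(len(chroms)))]
        pos = int(rng.integers(1000, 100_000))
        length = int(rng.integers(50, 500))
        out.append(SvRecord(sv_type="DEL", chrom=chrom, start=pos,
                            end=pos + length - 1, sv_len=-length,
                            quality=caller_profile.base_quality,
                            filter_status="PASS",
                            record_id=f"{caller_profile.name}.fp{j}",
                            caller=caller_profile.name))
    return out


def simulate_joint_genotyped_sv_vcf(truth_variants: Sequence[TruthVariant],
                                    caller_profile: CallerProfile = NOISE_FREE,
                                    target_assembly: str = "personal",
                                    depth: int = 30,
                                    seed: int = 0) -> list[SvRecord]:
    """Jointly genotyped tumor+normal SV records.

    Germline SVs are genotyped in both samples (het 0/1, AF ~0.5 or hom 1/1,
    AF ~1); somatic SVs are 0/0 with zero alternate depth in the normal and
    genotyped at the truth MAF in the tumor (0/1 for MAF 0.5, 1/1 for
    MAF 1.0), with alternate depths drawn around MAF x depth.
    """
    rng = np.random.default_rng((seed, 17))
    out = []
    for i, v in enumerate(truth_variants):
        if v.kind != "sv":
            continue
        rec = _truth_to_record(v, target_assembly, caller_profile, rng,
                               rec_id=f"joint.{i}")
        if rec is None:
            continue
        if v.is_somatic:
            maf = v.maf if v.maf is not None else 0.5
            t_alt = int(round(maf * depth))
            tumor = GenotypeEntry("tumor", "1/1" if maf > 0.75 else "0/1",
                                  alt_depth=t_alt, allele_fraction=maf)
            normal = GenotypeEntry("normal", "0/0", alt_depth=0,
                                   allele_fraction=0.0)
        else:
            af = 0.5 if v.zygosity == "het" else 1.0
            gt = "0/1" if v.zygosity == "het" else "1/1"
            alt = int(round(af * depth))
            tumor = GenotypeEntry("tumor", gt, alt_depth=alt,
                                  allele_fraction=af)
            normal = GenotypeEntry("normal", gt, alt_depth=alt,
                                   allele_fraction=af)
        out.append(replace(rec, samples=(tumor, normal)))
    return out


# ---------------------------------------------------------------------------
# Scenario: SNV cross-mapping recovery study
# ---------------------------------------------------------------------------

@dataclass
class SnvCrossmapStudy:
    reference: ScaffoldSet
    personal: ScaffoldSet
    edit_script: EditScript
    source_snvs: list[SmallVariant]          # reference-assembly coordinates
    target_consensus: list[SmallVariant]     # personal-assembly coordinates
    expected_category: dict[tuple[str, int], str]   # keyed by source site


def simulate_snv_crossmap_study(seed: int = 0,
                                genome_length_bp: int = 2_000_000,
                                n_clean: int = 300,
                                n_flank_germline: int = 150,
                                n_destroyed: int = 50,
                                flank: int = 50) -> SnvCrossmapStudy:
    """A genome pair built for SNV cross-mapping recovery scoring.

    Somatic SNVs are planted in three flank-context classes: clean flanks
    (identical between assemblies), 1-3 germline SNVs in the 50 bp flanks
    (placed at least 5 bp from the window edges and 3 bp from the center, so
    local alignment cannot clip them away), and destroyed flanks (both 50 bp
    flanks replaced with random sequence on the personal assembly).  A few
    germline insertions elsewhere shift coordinates so the lift map is
    exercised.  Callsets are noise-free.
    """
    rng = np.random.default_rng(seed)
    n_total = n_clean + n_flank_germline + n_destroyed
    ref_seq = _random_seq(rng, genome_length_bp, 0.41)
    chrom = "scaffold_1"

    # well-separated somatic sites (window diameter 101 bp; keep 400 bp apart)
    n_slots = genome_length_bp // 400 - 2
    if n_slots < n_total:
        raise ValueError("genome too small for the requested SNV count")
    slot_ids = rng.choice(n_slots, size=n_total, replace=False)
    sites = sorted(int(800 + s * 400 + rng.integers(0, 200)) for s in slot_ids)
    classes = (["clean"] * n_clean + ["flank_germline"] * n_flank_germline
               + ["destroyed"] * n_destroyed)
    rng.shuffle(classes)

    script = EditScript()
    alt_seqs: dict[tuple[int, int, int], str] = {}

    # germline insertions between sites to exercise the coordinate lift
    for _ in range(10):
        while True:
            pos = int(rng.integers(1000, genome_length_bp - 1000))
            if all(abs(pos - s) > 300 for s in sites):
                break
        length = int(rng.integers(100, 400))
        edit = (pos, 1, 1 + length)
        script.add(chrom, *edit)
        alt_seqs[edit] = ref_seq[pos - 1] + _random_seq(rng, length, 0.41)

    expected: dict[tuple[str, int], str] = {}
    source_snvs: list[SmallVariant] = []
    planted: list[tuple[int, str, str]] = []   # (ref site, alt, class)
    for pos, cls in zip(sites, classes):
        base = ref_seq[pos - 1]
        alt = str(rng.choice([b for b in "ACGT" if b != base]))
        if cls == "flank_germline":
            n_g = int(rng.integers(1, 4))
            offsets = rng.choice(
                [o for o in range(-flank + 5, flank - 4) if abs(o) >= 3],
                size=n_g, replace=False)
            for off in offsets:
                gpos = pos + int(off)
                gbase = ref_seq[gpos - 1]
                galt = str(rng.choice([b for b in "ACGT" if b != gbase]))
                edit = (gpos, 1, 1)
                script.add(chrom, *edit)
                alt_seqs[edit] = galt
        elif cls == "destroyed":
            for start in (pos - flank, pos + 1):
                edit = (start, flank, flank)
                script.add(chrom, *edit)
                alt_seqs[edit] = _random_seq(rng, flank, 0.41)
        expected[(chrom, pos)] = {"clean": "identical",
                                  "flank_germline": "equivalent",
                                  "destroyed": "unmapped"}[cls]
        source_snvs.append(SmallVariant(chrom=chrom, pos=pos,
                                        ref_allele=base, alt_allele=alt))
        planted.append((pos, alt, cls))

    personal_seq = script.apply(chrom, ref_seq, alt_seqs)
    reference = ScaffoldSet({chrom: ref_seq})
    personal = ScaffoldSet({chrom: personal_seq})

    target_consensus = []
    for pos, alt, cls in planted:
        p_pos = script.ref_to_personal(chrom, pos)
        assert p_pos is not None
        p_base = personal_seq[p_pos - 1]
        if p_base == alt:      # destroyed-flank randomization may collide
            continue
        target_consensus.append(SmallVariant(chrom=chrom, pos=p_pos,
                                             ref_allele=p_base,
                                             alt_allele=alt))
    return SnvCrossmapStudy(reference=reference, personal=personal,
                            edit_script=script, source_snvs=source_snvs,
                            target_consensus=target_consensus,
                            expected_category=expected)
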