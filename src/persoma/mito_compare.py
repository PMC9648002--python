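"""Circular mitochondrial genome extraction, rotation to a canonical
anchor, and substitution calling between two mitogenomes.

An assembled mitochondrial contig is an arbitrary rotation (possibly
reverse-complemented) of the circular molecule.  Both sequences are rotated
to begin at a shared anchor (for instance the start of the canonical
reference mitogenome), then globally aligned; substitution columns are
reported with indel columns listed separately.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import edlib
import numpy as np

from .core_model import revcomp
from .flank_mapper import encode_seq

ANCHOR_MIN_LEN = 20
ANCHOR_MAX_MISMATCHES = 2


class AnchorError(ValueError):
    """Anchor absent from the contig or located more than once."""


@dataclass(frozen=True)
class Substitution:
    position: int   # 1-based on the anchored coordinate system of seq_a
    base_a: str
    base_b: str


@dataclass(frozen=True)
class IndelEvent:
    position: int   # 1-based position on seq_a before/at which the event sits
    kind: str       # "ins" (extra bases in b) | "del" (missing from b)
    length: int


@dataclass(frozen=True)
class MitoComparison:
    rotated_seq_a: str
    rotated_seq_b: str
    substitutions: tuple[Substitution, ...]
    indels: tuple[IndelEvent, ...]
    alignment_len: int

    def __post_init__(self):
        positions = [s.position for s in self.substitutions]
        assert positions == sorted(set(positions)), "positions must increase"
        assert all(s.base_a != s.base_b for s in self.substitutions)


def _anchor_occurrences(contig: str, anchor: str,
                        max_mismatches: int) -> list[int]:
    """0-based circular start offsets where the anchor matches with at most
    ``max_mismatches`` substitutions (no indels)."""
    n, m = len(contig), len(anchor)
    doubled = encode_seq(contig + contig[:m - 1])
    a_codes = encode_seq(anchor)
    counts = np.zeros(n, dtype=np.int32)
    for i in range(m):
        counts += doubled[i:i + n] != a_codes[i]
    return [int(i) for i in np.nonzero(counts <= max_mismatches)[0]]


def rotate_circular_to_anchor(contig: str, anchor_seq: str,
                              max_mismatches: int = ANCHOR_MAX_MISMATCHES) -> str:
    """Rotate (and strand-correct) a circular contig to begin at the anchor.

    The anchor (>= 20 bp) must occur exactly once in the contig or its
    reverse complement, allowing at most 2 mismatches.  Length is preserved.
    """
    contig = contig.upper()
    anchor_seq = anchor_seq.upper()
    if len(anchor_seq) < ANCHOR_MIN_LEN:
        raise ValueError(f"anchor must be >= {ANCHOR_MIN_LEN} bp")
    if len(contig) < len(anchor_seq):
        raise AnchorError("contig shorter than anchor")
    fwd = _anchor_occurrences(contig, anchor_seq, max_mismatches)
    rc = revcomp(contig)
    rev = _anchor_occurrences(rc, anchor_seq, max_mismatches)
    total = len(fwd) + len(rev)
    if total == 0:
        raise AnchorError("anchor not found in contig on either strand")
    if total > 1:
        raise AnchorError(f"anchor located {total} times; rotation ambiguous")
    if fwd:
        i = fwd[0]
        return contig[i:] + contig[:i]
    i = rev[0]
    return rc[i:] + rc[:i]


def compare_mitogenomes(seq_a: str, seq_b: str) -> MitoComparison:
    """Global pairwise alignment of two anchored mitogenomes.

    Reports substitution columns in seq_a coordinates; indel columns are
    listed separately and excluded from the substitution list.  Requires the
    two lengths to agree within 1%.
    """
    seq_a, seq_b = seq_a.upper(), seq_b.upper()
    if abs(len(seq_a) - len(seq_b)) > 0.01 * max(len(seq_a), len(seq_b)):
        raise ValueError("sequence lengths diverge by more than 1%; "
                         "inputs are probably not the same molecule")
    result = edlib.align(seq_b, seq_a, task="path", mode="NW")
    nice = edlib.getNiceAlignment(result, seq_b, seq_a)
    target_aln = nice["target_aligned"]   # seq_a with gaps
    query_aln = nice["query_aligned"]     # seq_b with gaps
    subs: list[Substitution] = []
    indels: list[IndelEvent] = []
    pos_a = 0
    run_kind: str | None = None
    run_len = 0
    run_pos = 0

    def _flush():
        nonlocal run_kind, run_len
        if run_kind is not None:
            indels.append(IndelEvent(position=run_pos, kind=run_kind,
                                     length=run_len))
        run_kind, run_len = None, 0

    for ca, cb in zip(target_aln, query_aln):
        if ca != "-":
            pos_a += 1
        if ca == "-" or cb == "-":
            kind = "ins" if ca == "-" else "del"
            if run_kind == kind:
                run_len += 1
            else:
                _flush()
                run_kind, run_len = kind, 1
                run_pos = pos_a if kind == "del" else pos_a + 1
            continue
        _flush()
        if ca != cb:
            subs.append(Substitution(position=pos_a, base_a=ca, base_b=cb))
    _flush()
    return MitoComparison(
        rotated_seq_a=seq_a, rotated_seq_b=seq_b,
        substitutions=tuple(subs), indels=tuple(indels),
        alignment_len=len(target_aln))


def annotate_substitutions(comparison: MitoComparison,
                           gene_intervals: Sequence[tuple[str, int, int]]
                           ) -> list[tuple[Substitution, str | None]]:
    """Label each substitution with the gene interval containing it, if any.

    ``gene_intervals`` is a user-supplied (name, start, end) table in the
    anchored coordinate system; no external database is queried.
    """
    out = []
    for sub in comparison.substitutions:
        gene = next((name for name, start, end in gene_intervals
                     if start <= sub.position <= end), None)
        out.append((sub, gene))
    return out
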