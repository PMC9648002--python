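"""Local alignment of short flank queries against a target assembly.

Seed-and-extend engine: exact k-mer seeds (default k=11) chained on nearby
diagonals select candidate target windows; each window is scored with a
Gotoh local-alignment DP.  The DP maximizes the pair (score, n_matches)
lexicographically, so "the best mapping location with the maximum number of
matching bases" is well defined even among co-optimal alignments.

Scoring follows default nucleotide-search practice: match +1, mismatch -2,
gap open -2.5, gap extend -2.5 (scores are held as x2-scaled integers
internally).  Percent identity is 100 x matches / alignment columns, with
gap columns counted in the denominator; identity/length thresholds — not
e-values — are the acceptance gates.  N bases never count as matches.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from numba import njit

from .core_model import ScaffoldSet, revcomp

DEFAULT_K = 11
MAX_HITS_PER_QUERY = 10
_DIAG_CHAIN_BP = 50
_MAX_SEED_OCCURRENCES = 2000

# x2-scaled integer scores
MATCH_SCORE = 2
MISMATCH_SCORE = -4
GAP_OPEN_SCORE = -5
GAP_EXTEND_SCORE = -5

_ENCODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i


def encode_seq(seq: str) -> np.ndarray:
    """Encode A/C/G/T as 0-3 and anything else (N) as 4."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass(frozen=True)
class MappingCriteria:
    """Identity/length acceptance gate for a hit."""

    min_identity_pct: float
    min_alignment_len_bp: int

    def __post_init__(self):
        if not 0 < self.min_identity_pct <= 100:
            raise ValueError("min_identity_pct must be in (0, 100]")
        if self.min_alignment_len_bp < 1:
            raise ValueError("min_alignment_len_bp must be >= 1")

    def accepts(self, hit: "AlignmentHit") -> bool:
        return (hit.identity_pct >= self.min_identity_pct - 1e-9
                and hit.alignment_len >= self.min_alignment_len_bp)


@dataclass(frozen=True)
class AlignmentHit:
    """One local alignment of a query against a target scaffold.

    ``ops`` is one character per alignment column, in the orientation of the
    aligned query ('=' match, 'X' mismatch, 'I' query base vs gap, 'D' target
    base vs gap).  For strand '-', the aligned query is the reverse
    complement of the original query; target coordinates are always on the
    forward strand.  All coordinates 1-based inclusive.
    """

    query_id: str
    target_scaffold: str
    target_start: int
    target_end: int
    strand: str
    query_start: int
    query_end: int
    query_len: int
    n_matches: int
    n_mismatches: int
    n_gap_columns: int
    score: float
    ops: str

    @property
    def alignment_len(self) -> int:
        return self.n_matches + self.n_mismatches + self.n_gap_columns

    @property
    def identity_pct(self) -> float:
        return 100.0 * self.n_matches / self.alignment_len

    def _aligned_query_range(self) -> tuple[int, int]:
        """query_start/end expressed in aligned (strand-corrected) orientation."""
        if self.strand == "+":
            return self.query_start, self.query_end
        return (self.query_len + 1 - self.query_end,
                self.query_len + 1 - self.query_start)

    def project_query_pos(self, qpos: int) -> int | None:
        """Target position aligned to original-query position ``qpos``.

        Returns ``None`` when the position falls outside the aligned range or
        is aligned against a gap.
        """
        aq = qpos if self.strand == "+" else self.query_len + 1 - qpos
        qp, _ = self._aligned_query_range()
        tp = self.target_start
        for op in self.ops:
            if op in "=X":
                if qp == aq:
                    return tp
                qp += 1
                tp += 1
            elif op == "I":
                if qp == aq:
                    return None
                qp += 1
            else:  # D
                tp += 1
        return None

    def mismatch_query_positions(self) -> list[int]:
        """Original-query positions aligned as mismatches."""
        out = []
        qp, _ = self._aligned_query_range()
        for op in self.ops:
            if op in "=X":
                if op == "X":
                    out.append(qp if self.strand == "+"
                               else self.query_len + 1 - qp)
                qp += 1
            elif op == "I":
                qp += 1
        return sorted(out)


# ---------------------------------------------------------------------------
# DP kernel
# ---------------------------------------------------------------------------

_NEG = np.int32(-(10 ** 9))


@njit(cache=True)
def _gotoh_local_kernel(q, t, match, mismatch, gap_open, gap_ext):  # pragma: no cover
    m, n = q.shape[0], t.shape[0]
    HS = np.zeros((m + 1, n + 1), np.int32)
    HM = np.zeros((m + 1, n + 1), np.int32)
    ES = np.full((m + 1, n + 1), _NEG, np.int32)
    EM = np.zeros((m + 1, n + 1), np.int32)
    FS = np.full((m + 1, n + 1), _NEG, np.int32)
    FM = np.zeros((m + 1, n + 1), np.int32)
    best_s = np.int32(0)
    best_m = np.int32(0)
    best_i = 0
    best_j = 0
    for i in range(1, m + 1):
        qi = q[i - 1]
        for j in range(1, n + 1):
            # E: gap in query consuming target (horizontal)
            s_open = HS[i, j - 1] + gap_open
            s_ext = ES[i, j - 1] + gap_ext
            if s_open > s_ext or (s_open == s_ext and HM[i, j - 1] >= EM[i, j - 1]):
                ES[i, j] = s_open
                EM[i, j] = HM[i, j - 1]
            else:
                ES[i, j] = s_ext
                EM[i, j] = EM[i, j - 1]
            # F: gap in target consuming query (vertical)
            s_open = HS[i - 1, j] + gap_open
            s_ext = FS[i - 1, j] + gap_ext
            if s_open > s_ext or (s_open == s_ext and HM[i - 1, j] >= FM[i - 1, j]):
                FS[i, j] = s_open
                FM[i, j] = HM[i - 1, j]
            else:
                FS[i, j] = s_ext
                FM[i, j] = FM[i - 1, j]
            # H: lexicographic max over diag / F / E / zero
            is_match = 1 if (qi < 4 and qi == t[j - 1]) else 0
            ds = HS[i - 1, j - 1] + (match if is_match == 1 else mismatch)
            dm = HM[i - 1, j - 1] + is_match
            hs, hm = ds, dm
            if FS[i, j] > hs or (FS[i, j] == hs and FM[i, j] > hm):
                hs, hm = FS[i, j], FM[i, j]
            if ES[i, j] > hs or (ES[i, j] == hs and EM[i, j] > hm):
                hs, hm = ES[i, j], EM[i, j]
            if hs < 0 or (hs == 0 and hm < 0):
                hs, hm = np.int32(0), np.int32(0)
            HS[i, j] = hs
            HM[i, j] = hm
            if hs > best_s or (hs == best_s and hm > best_m):
                best_s, best_m, best_i, best_j = hs, hm, i, j
    # traceback from (best_i, best_j) in state H
    ops = np.empty(m + n, np.uint8)  # 0:'=', 1:'X', 2:'I', 3:'D'
    nops = 0
    i, j = best_i, best_j
    state = 0  # 0 H, 1 E, 2 F
    n_mm = 0
    while i > 0 or j > 0:
        if state == 0:
            if HS[i, j] == 0 and HM[i, j] == 0:
                # could still be a genuine zero-score alignment start; stop here
                break
            if i > 0 and j > 0:
                is_match = 1 if (q[i - 1] < 4 and q[i - 1] == t[j - 1]) else 0
                ds = HS[i - 1, j - 1] + (match if is_match == 1 else mismatch)
                dm = HM[i - 1, j - 1] + is_match
                if ds == HS[i, j] and dm == HM[i, j]:
                    ops[nops] = 0 if is_match == 1 else 1
                    if is_match == 0:
                        n_mm += 1
                    nops += 1
                    i -= 1
                    j -= 1
                    continue
            if i > 0 and FS[i, j] == HS[i, j] and FM[i, j] == HM[i, j]:
                state = 2
                continue
            if j > 0 and ES[i, j] == HS[i, j] and EM[i, j] == HM[i, j]:
                state = 1
                continue
            break
        elif state == 1:
            ops[nops] = 3
            nops += 1
            s_open = HS[i, j - 1] + gap_open
            if ES[i, j] == s_open and EM[i, j] == HM[i, j - 1]:
                state = 0
            j -= 1
        else:
            ops[nops] = 2
            nops += 1
            s_open = HS[i - 1, j] + gap_open
            if FS[i, j] == s_open and FM[i, j] == HM[i - 1, j]:
                state = 0
            i -= 1
    return (best_s, best_m, n_mm, i + 1, best_i, j + 1, best_j,
            ops[:nops][::-1].copy())


_OPS_CHARS = np.array([ord("="), ord("X"), ord("I"), ord("D")], dtype=np.uint8)


def local_align_window(q_codes: np.ndarray, t_codes: np.ndarray
                       ) -> tuple[int, int, int, int, int, int, int, str]:
    """Best local alignment of encoded query vs encoded target window.

    Returns (score_x2, n_matches, n_mismatches, q_start, q_end, t_start,
    t_end, ops) with 1-based inclusive coordinates relative to the inputs.
    A zero-score result means no alignment.
    """
    (s, nmatch, nmm, qs, qe, ts, te, ops) = _gotoh_local_kernel(
        q_codes, t_codes,
        np.int32(MATCH_SCORE), np.int32(MISMATCH_SCORE),
        np.int32(GAP_OPEN_SCORE), np.int32(GAP_EXTEND_SCORE))
    ops_str = _OPS_CHARS[ops].tobytes().decode("ascii") if len(ops) else ""
    return int(s), int(nmatch), int(nmm), int(qs), int(qe), int(ts), int(te), ops_str


# ---------------------------------------------------------------------------
# Seed index
# ---------------------------------------------------------------------------

class SeedIndex:
    """Exact k-mer index over a ScaffoldSet (forward strand storage; minus
    strand queries are served by looking up the reverse complement)."""

    def __init__(self, genome: ScaffoldSet, k: int = DEFAULT_K):
        if not 7 <= k <= 15:
            raise ValueError("k must be in [7, 15]")
        self.k = k
        self.genome = genome
        self.names = genome.names()
        sep = "N" * k
        concat = sep.join(genome[name] for name in self.names)
        self._codes_full = encode_seq(concat)
        self.offsets = np.empty(len(self.names), dtype=np.int64)
        self.lengths = np.empty(len(self.names), dtype=np.int64)
        off = 0
        for i, name in enumerate(self.names):
            self.offsets[i] = off
            self.lengths[i] = len(genome[name])
            off += self.lengths[i] + k
        kmers, valid = _rolling_kmers(self._codes_full, k)
        positions = np.nonzero(valid)[0]
        codes = kmers[positions]
        order = np.argsort(codes, kind="stable")
        self._sorted_codes = codes[order]
        self._sorted_positions = positions[order]

    def _lookup_code(self, code: int) -> np.ndarray:
        code = np.uint64(code)
        lo = np.searchsorted(self._sorted_codes, code, side="left")
        hi = np.searchsorted(self._sorted_codes, code, side="right")
        return self._sorted_positions[lo:hi]

    def _lookup_codes(self, codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Vectorized range lookup: (lo, hi) slice bounds per code."""
        lo = np.searchsorted(self._sorted_codes, codes, side="left")
        hi = np.searchsorted(self._sorted_codes, codes, side="right")
        return lo, hi

    def global_to_local(self, gpos: int) -> tuple[int, int]:
        """Map a 0-based concatenated position to (scaffold index, 0-based pos)."""
        idx = int(np.searchsorted(self.offsets, gpos, side="right")) - 1
        return idx, int(gpos - self.offsets[idx])

    def positions(self, kmer: str, strand: str = "+") -> list[tuple[str, int]]:
        """1-based forward-strand start positions of ``kmer`` occurrences.

        With ``strand='-'`` the reverse complement of ``kmer`` is located, so
        both strands of the genome are retrievable from the one stored index.
        """
        if len(kmer) != self.k:
            raise ValueError(f"kmer must have length k={self.k}")
        if strand == "-":
            kmer = revcomp(kmer)
        codes = encode_seq(kmer)
        if (codes >= 4).any():
            return []
        code = 0
        for c in codes:
            code = (code << 2) | int(c)
        out = []
        for gpos in self._lookup_code(code):
            sidx, local = self.global_to_local(int(gpos))
            out.append((self.names[sidx], local + 1))
        return out


def _rolling_kmers(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    n = codes.shape[0]
    if n < k:
        return np.empty(0, np.uint64), np.empty(0, bool)
    m = n - k + 1
    kmers = np.zeros(m, dtype=np.uint64)
    invalid = np.zeros(m, dtype=np.int32)
    for i in range(k):
        kmers = (kmers << np.uint64(2)) | codes[i:i + m].astype(np.uint64)
        invalid += (codes[i:i + m] >= 4)
    return kmers, invalid == 0


def index_genome(genome: ScaffoldSet, k: int = DEFAULT_K) -> SeedIndex:
    """Build a deterministic exact k-mer seed index (k in [7, 15])."""
    return SeedIndex(genome, k)


# ---------------------------------------------------------------------------
# Seed-and-extend search
# ---------------------------------------------------------------------------

def _candidate_windows(index: SeedIndex, q_codes: np.ndarray
                       ) -> list[tuple[int, int, int]]:
    """Seed the query and chain diagonals into (scaffold_idx, start, end)
    candidate windows (0-based half-open, scaffold-local)."""
    k = index.k
    qlen = q_codes.shape[0]
    kmers, valid = _rolling_kmers(q_codes, k)
    qoffs = np.nonzero(valid)[0]
    if qoffs.shape[0] == 0:
        return []
    lo, hi = index._lookup_codes(kmers[qoffs])
    gpos_list = []
    qoff_list = []
    for i in range(qoffs.shape[0]):
        count = hi[i] - lo[i]
        if 0 < count <= _MAX_SEED_OCCURRENCES:
            gpos_list.append(index._sorted_positions[lo[i]:hi[i]])
            qoff_list.append(np.full(count, qoffs[i], dtype=np.int64))
    if not gpos_list:
        return []
    gpos = np.concatenate(gpos_list)
    qoff = np.concatenate(qoff_list)
    diag = gpos - qoff
    order = np.lexsort((gpos, diag))
    gpos, qoff, diag = gpos[order], qoff[order], diag[order]
    windows: list[tuple[int, int, int]] = []
    pad = qlen + _DIAG_CHAIN_BP
    # Any alignment passing the identity/length gates used downstream
    # retains long exact-match runs, hence many exact k-mer seeds
    # (pigeonhole: >= 90 matched columns with <= 5 interruptions leave
    # >= 25 k-mers at k=11), so demanding two seeds per cluster for long
    # queries cannot lose a qualifying hit while skipping most chance
    # single-seed windows.
    min_seeds = 2 if qlen >= 8 * k else 1
    i = 0
    n = diag.shape[0]
    while i < n:
        j = i
        while (j + 1 < n and diag[j + 1] - diag[j] <= _DIAG_CHAIN_BP
               and abs(int(gpos[j + 1]) - int(gpos[j])) <= qlen + _DIAG_CHAIN_BP):
            j += 1
        if j - i + 1 < min_seeds:
            i = j + 1
            continue
        cluster_start = int((gpos[i:j + 1] - qoff[i:j + 1]).min())
        cluster_end = int((gpos[i:j + 1] - qoff[i:j + 1]).max()) + qlen
        sidx, local_start = index.global_to_local(max(cluster_start, 0))
        win_start = max(local_start - pad, 0)
        win_end = min(int(cluster_end - index.offsets[sidx]) + pad,
                      int(index.lengths[sidx]))
        if win_end > win_start:
            windows.append((sidx, win_start, win_end))
        i = j + 1
    # merge overlapping windows on the same scaffold
    windows.sort()
    merged: list[tuple[int, int, int]] = []
    for w in windows:
        if merged and merged[-1][0] == w[0] and w[1] <= merged[-1][2]:
            merged[-1] = (w[0], merged[-1][1], max(merged[-1][2], w[2]))
        else:
            merged.append(w)
    return merged


def local_align_query(query: str, index: SeedIndex, genome: ScaffoldSet,
                      criteria: MappingCriteria, query_id: str = "query",
                      max_hits: int = MAX_HITS_PER_QUERY) -> list[AlignmentHit]:
    """All criteria-passing hits of ``query`` on either strand.

    Hits are sorted by n_matches descending (then identity, scaffold name,
    start).  Returns an empty list when nothing qualifies.
    """
    if len(query) < index.k:
        raise ValueError("query shorter than seed size k")
    qlen = len(query)
    hits: dict[tuple, AlignmentHit] = {}
    for strand in "+-":
        q = query if strand == "+" else revcomp(query)
        q_codes = encode_seq(q)
        for sidx, wstart, wend in _candidate_windows(index, q_codes):
            scaffold = index.names[sidx]
            t_codes = encode_seq(genome[scaffold][wstart:wend])
            score, nmatch, nmm, qs, qe, ts, te, ops = local_align_window(
                q_codes, t_codes)
            if score <= 0:
                continue
            if strand == "+":
                query_start, query_end = qs, qe
            else:
                query_start, query_end = qlen + 1 - qe, qlen + 1 - qs
            hit = AlignmentHit(
                query_id=query_id, target_scaffold=scaffold,
                target_start=wstart + ts, target_end=wstart + te,
                strand=strand, query_start=query_start, query_end=query_end,
                query_len=qlen, n_matches=nmatch, n_mismatches=nmm,
                n_gap_columns=len(ops) - nmatch - nmm,
                score=score / 2.0, ops=ops)
            if not criteria.accepts(hit):
                continue
            key = (scaffold, strand, hit.target_start, hit.target_end,
                   hit.query_start, hit.query_end)
            hits.setdefault(key, hit)
    ranked = sorted(hits.values(),
                    key=lambda h: (-h.n_matches, -h.identity_pct,
                                   h.target_scaffold, h.target_start, h.strand))
    return ranked[:max_hits]


def select_best_hit(hits: Sequence[AlignmentHit]) -> AlignmentHit | None:
    """The hit maximizing n_matches; ties broken by identity (desc), scaffold
    name (asc), target start (asc).  ``None`` for an empty list."""
    if not hits:
        return None
    return min(hits, key=lambda h: (-h.n_matches, -h.identity_pct,
                                    h.target_scaffold, h.target_start, h.strand))


def hits_to_table(hits: Sequence[AlignmentHit]) -> list[dict[str, object]]:
    """Tabular hit rows in the 15-column qseqid..bitscore layout (the score
    column carries the raw alignment score)."""
    rows = []
    for h in hits:
        rows.append({
            "qseqid": h.query_id, "sseqid": h.target_scaffold,
            "qlen": h.query_len, "slen": None,
            "pident": round(h.identity_pct, 3), "length": h.alignment_len,
            "mismatch": h.n_mismatches, "gapopen": _count_gap_opens(h.ops),
            "qstart": h.query_start, "qend": h.query_end,
            "sstart": h.target_start, "send": h.target_end,
            "sstrand": "plus" if h.strand == "+" else "minus",
            "evalue": None, "bitscore": h.score,
        })
    return rows


def _count_gap_opens(ops: str) -> int:
    opens = 0
    prev = "="
    for op in ops:
        if op in "ID" and prev not in "ID":
            opens += 1
        prev = op
    return opens
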