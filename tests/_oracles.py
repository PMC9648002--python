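"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's seed-and-extend machinery: the
alignment oracle scans the full dynamic-programming matrix over the entire
target with a single-matrix linear-gap recurrence (exact here because the
gap open and extend penalties are equal), and the clustering oracle builds
the full pairwise graph and takes connected components.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# x2-scaled scores, matching the package's documented scheme
_MATCH = 2
_MISMATCH = -4
_GAP = 5   # per gap column


@njit(cache=True)
def _full_dp(q, t):  # pragma: no cover
    m, n = q.shape[0], t.shape[0]
    S = np.zeros((m + 1, n + 1), np.int32)
    M = np.zeros((m + 1, n + 1), np.int32)
    best = (np.int32(0), np.int32(0), 0, 0)
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            is_match = 1 if (q[i - 1] < 4 and q[i - 1] == t[j - 1]) else 0
            ds = S[i - 1, j - 1] + (_MATCH if is_match == 1 else _MISMATCH)
            dm = M[i - 1, j - 1] + is_match
            us, um = S[i - 1, j] - _GAP, M[i - 1, j]
            ls, lm = S[i, j - 1] - _GAP, M[i, j - 1]
            bs, bm = ds, dm
            if us > bs or (us == bs and um > bm):
                bs, bm = us, um
            if ls > bs or (ls == bs and lm > bm):
                bs, bm = ls, lm
            if bs < 0:
                bs, bm = 0, 0
            S[i, j] = bs
            M[i, j] = bm
            if bs > best[0] or (bs == best[0] and bm > best[1]):
                best = (bs, bm, i, j)
    # traceback for column counts (priority: diagonal, up, left)
    i, j = best[2], best[3]
    n_mm = 0
    n_gap = 0
    qend, tend = i, j
    while i > 0 or j > 0:
        if S[i, j] == 0 and M[i, j] == 0:
            break
        moved = False
        if i > 0 and j > 0:
            is_match = 1 if (q[i - 1] < 4 and q[i - 1] == t[j - 1]) else 0
            ds = S[i - 1, j - 1] + (_MATCH if is_match == 1 else _MISMATCH)
            dm = M[i - 1, j - 1] + is_match
            if ds == S[i, j] and dm == M[i, j]:
                if is_match == 0:
                    n_mm += 1
                i -= 1
                j -= 1
                moved = True
        if not moved and i > 0 and S[i - 1, j] - _GAP == S[i, j] \
                and M[i - 1, j] == M[i, j]:
            n_gap += 1
            i -= 1
            moved = True
        if not moved and j > 0 and S[i, j - 1] - _GAP == S[i, j] \
                and M[i, j - 1] == M[i, j]:
            n_gap += 1
            j -= 1
            moved = True
        if not moved:
            break
    return best[0], best[1], n_mm, n_gap, i + 1, qend, j + 1, tend


_ENC = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENC[ord(_b)] = _i


def _encode(seq: str) -> np.ndarray:
    return _ENC[np.frombuffer(seq.encode(), dtype=np.uint8)]


def oracle_best_local_alignment(query: str, target: str):
    """Exhaustive best local alignment of query vs target, both strands.

    Returns (strand, score, n_matches, n_mismatches, n_gap_columns,
    q_start, q_end, t_start, t_end) for the lexicographic (score, matches)
    optimum, preferring '+' on an exact tie.
    """
    comp = str.maketrans("ACGTN", "TGCAN")
    results = {}
    for strand in "+-":
        q = query if strand == "+" else query.translate(comp)[::-1]
        s, m, mm, g, qs, qe, ts, te = _full_dp(_encode(q), _encode(target))
        results[strand] = (int(s), int(m), int(mm), int(g),
                           int(qs), int(qe), int(ts), int(te))
    plus, minus = results["+"], results["-"]
    if (minus[0], minus[1]) > (plus[0], plus[1]):
        return ("-",) + minus
    return ("+",) + plus


def brute_force_single_linkage(records, max_dist: int, type_aware: bool,
                               harmonize) -> list[frozenset[int]]:
    """Connected components of the full pairwise breakpoint-distance graph."""
    n = len(records)
    adj = [set() for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            a, b = records[i], records[j]
            if a.chrom != b.chrom:
                continue
            if type_aware and harmonize(a) != harmonize(b):
                continue
            if a.is_translocation != b.is_translocation:
                continue
            if a.is_translocation:
                close = (a.mate_chrom == b.mate_chrom
                         and abs(a.start - b.start) <= max_dist
                         and abs(a.mate_pos - b.mate_pos) <= max_dist)
            else:
                close = (abs(a.start - b.start) <= max_dist
                         and abs(a.end - b.end) <= max_dist)
            if close:
                adj[i].add(j)
                adj[j].add(i)
    seen = [False] * n
    components = []
    for start in range(n):
        if seen[start]:
            continue
        stack, comp = [start], set()
        while stack:
            x = stack.pop()
            if seen[x]:
                continue
            seen[x] = True
            comp.add(x)
            stack.extend(adj[x] - comp)
        components.append(frozenset(comp))
    return components


def brute_force_scaffold_stats(lengths, top_k=50, min_len=0):
    """Sort-and-scan contiguity statistics."""
    ls = sorted([x for x in lengths if x >= min_len], reverse=True)
    total = sum(ls)
    acc = 0
    for rank, length in enumerate(ls, 1):
        acc += length
        if 2 * acc >= total:
            return {"total": total, "n50": length, "l50": rank,
                    "top": sum(ls[:top_k]), "largest": ls[0], "n": len(ls)}
    raise AssertionError("unreachable for non-empty input")
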