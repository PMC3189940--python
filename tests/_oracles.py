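"""Independent brute-force oracles used to pin down expected values.

These deliberately share no code with the implementation paths they check:
the repeat oracle enumerates every substring pair, the trinucleotide oracle
counts with a plain dictionary, and the motif oracle maximizes
non-overlapping matches by dynamic programming over all match positions.
"""

from __future__ import annotations

import re

import numpy as np

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
_COMPARR = np.array([3, 2, 1, 0, 4])


def _enc(seq: str) -> np.ndarray:
    return np.array([_CODE[c] for c in seq], dtype=np.int64)


def repeat_oracle(seq: str, min_len: int, min_identity: float) -> set[tuple]:
    """All maximal qualifying ungapped intra-genome pairs, exhaustively.

    A qualifying interval pair has length >= min_len, identity >=
    min_identity, matching first and last columns, and is maximal when not
    properly contained in another qualifying pair on the same diagonal.
    Returns (a_start, a_end, b_start, b_end, strand) with 1-based inclusive
    coordinates and the a-side lexicographically smallest.
    """
    a = _enc(seq)
    hits: set[tuple] = set()
    for strand in ("direct", "inverted"):
        yb = a if strand == "direct" else _COMPARR[a[::-1]]
        nb = len(yb)
        for d in range(-(len(a) - 1), nb):
            lo, hi = max(0, -d), min(len(a), nb - d)
            if hi - lo < min_len:
                continue
            if strand == "direct" and d == 0:
                continue
            m = a[lo:hi] == yb[lo + d : hi + d]
            n = len(m)
            cs = np.concatenate([[0], np.cumsum(m)])
            quals = []
            for i in range(0, n - min_len + 1):
                if not m[i]:
                    continue
                j = np.arange(i + min_len, n + 1)
                feas = (cs[j] - cs[i] >= min_identity * (j - i) - 1e-9) & m[j - 1]
                for jj in j[feas]:
                    quals.append((i, int(jj)))
            maximal = [
                q for q in quals
                if not any(p[0] <= q[0] and q[1] <= p[1] and p != q for p in quals)
            ]
            for i, j in maximal:
                ai, aj = lo + i, lo + j
                bi, bj = ai + d, aj + d
                if strand == "inverted":
                    bi, bj = nb - bj, nb - bi
                A, B = (ai + 1, aj), (bi + 1, bj)
                if A == B:
                    continue
                if A > B:
                    A, B = B, A
                hits.add((A[0], A[1], B[0], B[1], strand))
    return hits


def trinuc_chi2_oracle(seq: str, win_start0: int, window_bp: int,
                       circular: bool = True) -> float:
    """Direct dictionary-count chi-square of one window vs whole genome."""
    n = len(seq)

    def tri_counts(positions) -> dict[str, int]:
        counts: dict[str, int] = {}
        for i in positions:
            tri = "".join(seq[(i + t) % n] for t in range(3)) if circular else seq[i:i + 3]
            if "N" in tri or len(tri) < 3:
                continue
            counts[tri] = counts.get(tri, 0) + 1
        return counts

    global_positions = range(n) if circular else range(n - 2)
    window_positions = (
        range(win_start0, win_start0 + window_bp) if circular
        else range(win_start0, min(win_start0 + window_bp - 2, n - 2))
    )
    gc = tri_counts(global_positions)
    wc = tri_counts(window_positions)
    total = sum(gc.values())
    n_valid = sum(wc.values())
    chi2 = 0.0
    for tri, cnt in gc.items():
        e = cnt / total * n_valid
        o = wc.get(tri, 0)
        if e > 0:
            chi2 += (o - e) ** 2 / e
    # classes observed in the window but absent genome-wide cannot occur
    return chi2


def max_nonoverlapping_motifs(protein: str, pattern: str = "GGXGXD") -> int:
    """Max number of non-overlapping motif matches, by DP over all matches."""
    rx = re.compile("(?=(" + "".join("." if c == "X" else f"[{c}X]" for c in pattern)
                    + "))")
    starts = sorted(m.start() for m in rx.finditer(protein))
    L = len(pattern)
    best: dict[int, int] = {}

    def solve(k: int) -> int:
        if k >= len(starts):
            return 0
        if k in best:
            return best[k]
        skip = solve(k + 1)
        nxt = k + 1
        while nxt < len(starts) and starts[nxt] < starts[k] + L:
            nxt += 1
        take = 1 + solve(nxt)
        best[k] = max(skip, take)
        return best[k]

    return solve(0)
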