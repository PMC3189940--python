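"""Intra- and cross-genome ungapped repeat detection.

A repeat hit is a pair of equal-length ungapped segments (direct or
inverted orientation) whose identity — matches over alignment columns — is
at least ``min_identity`` and whose length is at least ``min_len_bp``.
Only *maximal* hits are reported: in dotplot terms a hit is a diagonal
segment, and a segment properly contained in a longer qualifying segment on
the same diagonal is suppressed.  Gaps are not modelled; the thresholds
this module is built for (50 bp / 97% for the repeat inventory, 100 bp /
97% for the cross-genome lateral-transfer screen) are stated without gap
semantics, and the ungapped reading is recorded in every output header.

Detection is seed-and-extend on exact k-mers: a segment of length L with at
most m mismatches contains an exact run of at least (L - m)/(m + 1) bases,
so with the default k = 16 no qualifying hit at 50 bp / 97% identity can be
missed.  Within each seeded diagonal the full set of maximal qualifying
intervals is recovered exactly (not greedily) from prefix mismatch counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np

from predaseq._intervals import union_length
from predaseq.composition import encode
from predaseq.genome_io import GenomeRecord

_COMP = np.array([3, 2, 1, 0, 4], dtype=np.int64)


@dataclass(frozen=True)
class RepeatParams:
    min_len_bp: int = 50
    min_identity: float = 0.97
    cross_genome: bool = False

    def __post_init__(self) -> None:
        if self.min_len_bp < 20:
            raise ValueError("min_len_bp must be >= 20")
        if not (0 < self.min_identity <= 1):
            raise ValueError("min_identity must be in (0, 1]")


@dataclass(frozen=True)
class RepeatHit:
    """One ungapped repeat pair; coordinates 1-based inclusive."""

    a_start: int
    a_end: int
    b_start: int
    b_end: int
    identity: float
    length_bp: int
    strand: str  # "direct" or "inverted"

    def key(self) -> tuple:
        return (self.a_start, self.a_end, self.b_start, self.b_end, self.strand)


def _maximal_intervals(match: np.ndarray, min_len: int, min_identity: float
                       ) -> list[tuple[int, int, int]]:
    """All maximal [i, j) with j-i >= min_len, matches/(j-i) >= min_identity,
    and matching columns at both ends (alignment end-trimming convention).

    Returns (i, j, n_matches) triples.  Feasibility of [i, j) is equivalent
    to g[j] <= g[i] where g[t] = mismatches_before_t - (1 - p) * t; for each
    admissible left end the rightmost admissible right end is found via the
    stack of right-to-left records of g, then non-maximal (contained)
    intervals are swept out.
    """
    n = len(match)
    if n < min_len:
        return []
    mm = np.concatenate([[0], np.cumsum(~match)])
    g = mm - (1.0 - min_identity) * np.arange(n + 1)
    # stack over admissible right ends j (m[j-1] must match), scanned from
    # the right keeping strict records of g: reversed arrays are ascending
    # in both j and g
    js: list[int] = []
    gs: list[float] = []
    for j in range(n, 0, -1):
        if match[j - 1] and (not gs or g[j] < gs[-1]):
            js.append(j)
            gs.append(g[j])
    if not js:
        return []
    js_a = np.array(js[::-1])
    gs_a = np.array(gs[::-1])
    cands: list[tuple[int, int]] = []
    eps = 1e-9
    for i in range(0, n - min_len + 1):
        if not match[i]:
            continue
        pos = int(np.searchsorted(gs_a, g[i] + eps, side="right")) - 1
        if pos < 0:
            continue
        j = int(js_a[pos])
        if j - i >= min_len:
            cands.append((i, j))
    out: list[tuple[int, int, int]] = []
    best_j = -1
    for i, j in cands:
        if j > best_j:
            n_match = int(match[i:j].sum())
            out.append((i, j, n_match))
            best_j = j
    return out


def _kmer_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Rolling 2-bit k-mer encoding; kmers containing N get -1."""
    n = len(codes)
    if n < k:
        return np.empty(0, dtype=np.int64)
    valid = codes < 4
    enc = np.where(valid, codes, 0).astype(np.int64)
    km = np.zeros(n - k + 1, dtype=np.int64)
    ok = np.ones(n - k + 1, dtype=bool)
    for t in range(k):
        km = km * 4 + enc[t : n - k + 1 + t]
        ok &= valid[t : n - k + 1 + t]
    return np.where(ok, km, -1)


def _seed_diagonals(xa: np.ndarray, xb: np.ndarray, k: int, same: bool
                    ) -> dict[int, list[int]]:
    """Candidate diagonals d = j - i with the seed i positions hitting them."""
    ka = _kmer_codes(xa, k)
    kb = ka if same else _kmer_codes(xb, k)
    diags: dict[int, list[int]] = {}
    if len(ka) == 0 or len(kb) == 0:
        return diags
    if same:
        order = np.argsort(ka, kind="stable")
        sorted_k = ka[order]
        boundaries = np.flatnonzero(np.diff(sorted_k) != 0) + 1
        groups = np.split(order, boundaries)
        for grp in groups:
            if len(grp) < 2 or ka[grp[0]] < 0:
                continue
            grp = np.sort(grp)
            for ii in range(len(grp)):
                for jj in range(ii + 1, len(grp)):
                    d = int(grp[jj] - grp[ii])
                    diags.setdefault(d, []).append(int(grp[ii]))
    else:
        common, ia, ib = np.intersect1d(ka, kb, return_indices=True)
        # intersect1d keeps one occurrence; recover all via dict of positions
        pos_b: dict[int, list[int]] = {}
        for j, v in enumerate(kb):
            if v >= 0:
                pos_b.setdefault(int(v), []).append(j)
        seen = set(common[common >= 0])
        for i, v in enumerate(ka):
            if int(v) in seen:
                for j in pos_b[int(v)]:
                    diags.setdefault(j - i, []).append(i)
    return diags


def find_repeats(
    genome_a: GenomeRecord,
    genome_b: GenomeRecord | None = None,
    params: RepeatParams = RepeatParams(),
    k: int = 16,
    max_extension: int = 5000,
) -> list[RepeatHit]:
    """Find maximal ungapped repeat pairs within or between genomes.

    Without ``genome_b`` the search is intra-genome: the trivial self-match
    of every position against itself is excluded and each pair is reported
    once with the lexicographically smaller interval as the ``a`` side.
    Both orientations are searched.  ``max_extension`` bounds how far beyond
    the outermost seed a diagonal is examined.
    """
    if params.min_len_bp < k:
        raise ValueError(f"min_len_bp {params.min_len_bp} < seed size k={k}: "
                         "seed cannot anchor all hits; lower k")
    a = encode(genome_a.sequence)
    same = genome_b is None
    b = a if same else encode(genome_b.sequence)
    hits: dict[tuple, RepeatHit] = {}
    for strand in ("direct", "inverted"):
        yb = b if strand == "direct" else _COMP[b[::-1]]
        for d, seeds in _seed_diagonals(a, yb, k, same and strand == "direct").items():
            if same and strand == "direct" and d == 0:
                continue
            lo = max(0, -d)
            hi = min(len(a), len(yb) - d)
            if hi - lo < params.min_len_bp:
                continue
            s_lo = max(lo, min(seeds) - max_extension)
            s_hi = min(hi, max(seeds) + k + max_extension)
            seg_a = a[s_lo:s_hi]
            seg_b = yb[s_lo + d : s_hi + d]
            match = (seg_a == seg_b) & (seg_a < 4) & (seg_b < 4)
            for i, j, n_match in _maximal_intervals(
                match, params.min_len_bp, params.min_identity
            ):
                ai, aj = s_lo + i, s_lo + j  # 0-based half-open on a
                bi, bj = ai + d, aj + d  # on yb
                if strand == "inverted":
                    nb = len(yb)
                    bi, bj = nb - bj, nb - bi  # map back from revcomp coords
                hit = RepeatHit(
                    a_start=ai + 1, a_end=aj,
                    b_start=bi + 1, b_end=bj,
                    identity=n_match / (aj - ai),
                    length_bp=aj - ai,
                    strand=strand,
                )
                if same:
                    ka_iv, kb_iv = (hit.a_start, hit.a_end), (hit.b_start, hit.b_end)
                    if ka_iv == kb_iv:
                        continue  # palindrome matching itself
                    if ka_iv > kb_iv:
                        hit = RepeatHit(
                            a_start=hit.b_start, a_end=hit.b_end,
                            b_start=hit.a_start, b_end=hit.a_end,
                            identity=hit.identity, length_bp=hit.length_bp,
                            strand=hit.strand,
                        )
                hits[hit.key()] = hit
    return sorted(hits.values(), key=lambda h: h.key())


def repetitive_fraction(genome: GenomeRecord, hits: Iterable[RepeatHit]) -> float:
    """Percent of the genome covered by any repeat-hit interval (union)."""
    intervals = []
    for h in hits:
        intervals.append((h.a_start - 1, h.a_end))
        intervals.append((h.b_start - 1, h.b_end))
    return 100.0 * union_length(intervals) / len(genome)


def write_hits_tsv(hits: Iterable[RepeatHit], path: str | Path,
                   params: RepeatParams | None = None) -> None:
    with open(path, "w") as fh:
        if params is not None:
            fh.write(f"# min_len_bp={params.min_len_bp} min_identity={params.min_identity}"
                     " identity=ungapped\n")
        fh.write("a_start\ta_end\tb_start\tb_end\tlength_bp\tidentity\tstrand\n")
        for h in hits:
            fh.write(f"{h.a_start}\t{h.a_end}\t{h.b_start}\t{h.b_end}\t"
                     f"{h.length_bp}\t{h.identity:.4f}\t{h.strand}\n")


def write_hits_bed(hits: Iterable[RepeatHit], path: str | Path,
                   seqid: str = "genome", side: str = "a") -> None:
    """Write hit intervals of one side as BED (0-based half-open)."""
    with open(path, "w") as fh:
        for h in hits:
            s, e = (h.a_start, h.a_end) if side == "a" else (h.b_start, h.b_end)
            fh.write(f"{seqid}\t{s - 1}\t{e}\trepeat\t{h.identity:.4f}\t"
                     f"{'+' if h.strand == 'direct' else '-'}\n")
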