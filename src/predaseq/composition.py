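"""GC skew, replication origin/terminus inference and genomic-island detection.

The island scan scores sliding windows by a chi-square goodness-of-fit of
their 64 overlapping trinucleotide counts against whole-genome expectation;
compositionally alien segments (laterally transferred islands, ICEs) stand
out as runs of high-scoring windows.  Significance is calibrated against a
mononucleotide-shuffled copy of the genome scanned with identical
parameters, because overlapping trinucleotide counts are not independent and
the analytic chi-square(63) tail is badly anti-conservative.

All windows are laid out from position 1 at a fixed step and wrap around the
origin of circular genomes, so a window equal to the whole genome reproduces
the genome-wide counts exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np

from predaseq.genome_io import Feature, GenomeRecord

logger = logging.getLogger(__name__)

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
_COMP = np.array([3, 2, 1, 0, 4], dtype=np.int64)  # A<->T, C<->G, N->N

#: defaults chosen so the smallest islands of interest (~11 kb) span >= 10 windows
DEFAULT_WINDOW_BP = 2000
DEFAULT_STEP_BP = 1000


def encode(sequence: str) -> np.ndarray:
    """Map a nucleotide string to integer codes A=0 C=1 G=2 T=3 N=4."""
    arr = np.frombuffer(sequence.encode(), dtype=np.uint8)
    lut = np.full(256, 4, dtype=np.int64)
    for base, code in _CODE.items():
        lut[ord(base)] = code
    return lut[arr]


@dataclass
class SkewProfile:
    window_bp: int
    step_bp: int
    positions: np.ndarray  # 1-based window midpoints
    skew: np.ndarray  # (G - C) / (G + C) per window
    cumulative: np.ndarray  # running sum of per-window skew


@dataclass
class WindowScoreTrack:
    window_bp: int
    step_bp: int
    starts: np.ndarray  # 1-based inclusive
    ends: np.ndarray
    chi2: np.ndarray
    both_strands: bool = False

    def __len__(self) -> int:
        return len(self.starts)


@dataclass
class OriTerPrediction:
    ori: int  # 1-based position of the cumulative-skew minimum
    ter: int  # 1-based position of the cumulative-skew maximum
    ori_cumulative: float
    ter_cumulative: float
    confident: bool


@dataclass
class GenomicIsland:
    start: int  # 1-based inclusive
    end: int
    size_bp: int
    mean_chi2: float
    trna_flanked: bool = False
    has_integrase: bool = False

    def interval(self) -> tuple[int, int]:
        """0-based half-open footprint."""
        return (self.start - 1, self.end)


def _window_starts(length: int, window_bp: int, step_bp: int, circular: bool) -> np.ndarray:
    if window_bp < 1 or step_bp < 1:
        raise ValueError("window_bp and step_bp must be >= 1")
    if window_bp > length:
        raise ValueError(f"window {window_bp} bp larger than genome ({length} bp)")
    if circular:
        return np.arange(0, length, step_bp)
    return np.arange(0, length - window_bp + 1, step_bp)


def gc_skew(
    genome: GenomeRecord,
    window_bp: int = DEFAULT_WINDOW_BP,
    step_bp: int = DEFAULT_STEP_BP,
) -> SkewProfile:
    """Per-window GC skew (G-C)/(G+C) and its cumulative sum.

    Windows with no G or C score 0.  On the leading strand of bacterial
    replication G typically outnumbers C, so the cumulative curve descends
    over one replichore and ascends over the other, with extrema at the
    origin and terminus.
    """
    codes = encode(genome.sequence)
    n = len(codes)
    starts = _window_starts(n, window_bp, step_bp, genome.circular)
    is_g = (codes == 2).astype(np.int64)
    is_c = (codes == 1).astype(np.int64)
    if genome.circular:
        is_g = np.concatenate([is_g, is_g[: window_bp]])
        is_c = np.concatenate([is_c, is_c[: window_bp]])
    cg = np.concatenate([[0], np.cumsum(is_g)])
    cc = np.concatenate([[0], np.cumsum(is_c)])
    g = cg[starts + window_bp] - cg[starts]
    c = cc[starts + window_bp] - cc[starts]
    denom = g + c
    skew = np.where(denom > 0, (g - c) / np.maximum(denom, 1), 0.0)
    mids = (starts + window_bp // 2) % n + 1
    return SkewProfile(
        window_bp=window_bp,
        step_bp=step_bp,
        positions=mids,
        skew=skew,
        cumulative=np.cumsum(skew),
    )


def predict_ori_ter(profile: SkewProfile, min_sigma: float = 5.0) -> OriTerPrediction:
    """Locate origin and terminus from cumulative GC skew extrema.

    ori is placed at the global minimum and ter at the global maximum of the
    cumulative skew (G-rich leading strand convention).  Extrema are taken
    on the mean-centered cumulative — centering zeroes the circular total,
    which makes the prediction exactly equivariant under genome rotation.
    The call is flagged low-confidence when the cumulative range is smaller
    than ``min_sigma`` standard random-walk deviations (noise sd of the
    per-window skew times sqrt(n)), as expected for a genome without
    replichore structure.
    """
    skew = np.asarray(profile.skew, dtype=float)
    if len(skew) < 2 or np.allclose(skew, skew.mean()):
        raise ValueError("no transition detected: cumulative skew profile is flat")
    cum = np.cumsum(skew - skew.mean())
    i_min = int(np.argmin(cum))
    i_max = int(np.argmax(cum))
    amplitude = cum[i_max] - cum[i_min]
    # noise level from first differences: detrends the slowly varying
    # replichore mean so the signal does not inflate its own threshold
    sigma = float(np.std(np.diff(profile.skew))) / np.sqrt(2.0)
    threshold = min_sigma * sigma * np.sqrt(len(cum))
    return OriTerPrediction(
        ori=int(profile.positions[i_min]),
        ter=int(profile.positions[i_max]),
        ori_cumulative=float(cum[i_min]),
        ter_cumulative=float(cum[i_max]),
        confident=bool(amplitude >= threshold and sigma > 0),
    )


def _trinuc_indices(codes: np.ndarray, circular: bool) -> tuple[np.ndarray, np.ndarray]:
    """Trinucleotide index (0..63) per start position and validity mask."""
    n = len(codes)
    if circular:
        a = codes
        b = np.roll(codes, -1)
        c = np.roll(codes, -2)
    else:
        a, b, c = codes[:-2], codes[1:-1], codes[2:]
    valid = (a < 4) & (b < 4) & (c < 4)
    idx = np.where(valid, 16 * a + 4 * b + c, 64)
    return idx, valid


def _revcomp_trinuc_map() -> np.ndarray:
    k = np.arange(64)
    a, b, c = k // 16, (k // 4) % 4, k % 4
    return 16 * _COMP[c] + 4 * _COMP[b] + _COMP[a]


def trinuc_chi2_scan(
    genome: GenomeRecord,
    window_bp: int = DEFAULT_WINDOW_BP,
    step_bp: int = DEFAULT_STEP_BP,
    both_strands: bool = False,
    exclude_intervals: Iterable[tuple[int, int]] = (),
) -> WindowScoreTrack:
    """Windowed trinucleotide chi-square scores against genome expectation.

    For each window the 64 overlapping trinucleotide counts O_k are compared
    with E_k = f_k * n_valid, where f_k are whole-genome frequencies and
    n_valid is the window's count of N-free trinucleotides, giving
    chi2 = sum (O_k - E_k)^2 / E_k over classes with E_k > 0.  Trinucleotides
    are counted on the given strand only unless ``both_strands`` is set.
    Windows with fewer than one valid trinucleotide are skipped and logged.

    ``exclude_intervals`` (0-based half-open) removes regions from the
    genome-wide frequency estimate only — windows there are still scored.
    This supports robust re-estimation of the background once candidate
    islands are known, since large alien segments otherwise contaminate
    f_k and inflate every other window's score.
    """
    if window_bp < 100:
        raise ValueError("window_bp must be >= 100 for a stable chi-square")
    codes = encode(genome.sequence)
    n = len(codes)
    starts0 = _window_starts(n, window_bp, step_bp, genome.circular)
    idx, valid = _trinuc_indices(codes, genome.circular)
    fold = _revcomp_trinuc_map() if both_strands else None

    def counts_of(index_slice: np.ndarray) -> np.ndarray:
        cnt = np.bincount(index_slice, minlength=65)[:64].astype(float)
        if fold is not None:
            cnt = cnt + cnt[fold]
        return cnt

    bg_idx = idx
    excl = list(exclude_intervals)
    if excl:
        keep = np.ones(len(idx), dtype=bool)
        for s, e in excl:
            keep[max(0, s) : min(len(idx), e)] = False
        bg_idx = idx[keep]
    global_counts = counts_of(bg_idx)
    total = global_counts.sum()
    if total == 0:
        raise ValueError("genome has no N-free trinucleotides")
    freqs = global_counts / total

    # per-window counts from the (wrapped) index array
    m = len(idx)
    if genome.circular:
        ext = np.concatenate([idx, idx[: window_bp]])
    else:
        ext = idx
    out_starts, out_ends, out_chi2 = [], [], []
    for s in starts0:
        stop = s + window_bp if genome.circular else min(s + window_bp - 2, m)
        win = ext[s:stop]
        obs = counts_of(win)
        n_valid = obs.sum()
        if n_valid < 1:
            logger.warning(
                "window %d-%d skipped: fewer than 3 non-N bases", s + 1, s + window_bp
            )
            continue
        exp = freqs * n_valid
        nz = exp > 0
        chi2 = float(np.sum((obs[nz] - exp[nz]) ** 2 / exp[nz]))
        out_starts.append(s + 1)
        # wrapped windows are reported clipped at the genome end
        out_ends.append(min(s + window_bp, n))
        out_chi2.append(chi2)
    return WindowScoreTrack(
        window_bp=window_bp,
        step_bp=step_bp,
        starts=np.array(out_starts, dtype=np.int64),
        ends=np.array(out_ends, dtype=np.int64),
        chi2=np.array(out_chi2, dtype=float),
        both_strands=both_strands,
    )


def shuffled_null_track(
    genome: GenomeRecord,
    window_bp: int,
    step_bp: int,
    seed: int = 0,
    both_strands: bool = False,
    n_shuffles: int = 10,
) -> WindowScoreTrack:
    """Score distribution under the mononucleotide-shuffle null.

    Scores from ``n_shuffles`` independent shuffles are pooled: a single
    shuffle yields only one score per window position, which makes extreme
    quantiles (the 0.999 used for island calling) little more than a noisy
    sample maximum.
    """
    rng = np.random.default_rng(seed)
    letters = np.frombuffer(genome.sequence.encode(), dtype=np.uint8)
    tracks = []
    for _ in range(max(1, n_shuffles)):
        shuffled = bytes(rng.permutation(letters)).decode()
        null_genome = GenomeRecord(id=f"{genome.id}|shuffled", sequence=shuffled,
                                   circular=genome.circular)
        tracks.append(trinuc_chi2_scan(null_genome, window_bp, step_bp,
                                       both_strands=both_strands))
    first = tracks[0]
    return WindowScoreTrack(
        window_bp=window_bp,
        step_bp=step_bp,
        starts=np.concatenate([t.starts for t in tracks]),
        ends=np.concatenate([t.ends for t in tracks]),
        chi2=np.concatenate([t.chi2 for t in tracks]),
        both_strands=both_strands,
    )


def _as_intervals(exclusion_features: Iterable) -> list[tuple[int, int]]:
    out = []
    for item in exclusion_features:
        if isinstance(item, Feature):
            out.extend(item.footprint())
        else:
            s, e = item
            out.append((int(s) - 1, int(e)))
    return out


def call_islands(
    track: WindowScoreTrack,
    genome: GenomeRecord,
    null_quantile: float = 0.999,
    merge_gap_bp: int = DEFAULT_STEP_BP * 2,
    min_island_bp: int = 8000,
    exclusion_features: Iterable = (),
    null_track: WindowScoreTrack | None = None,
    seed: int = 0,
    refine_passes: int = 3,
) -> list[GenomicIsland]:
    """Call genomic islands as merged runs of chi-square-anomalous windows.

    The score threshold is the ``null_quantile`` of window scores from a
    mononucleotide-shuffled genome scanned with the same window/step
    (computed here unless a precomputed ``null_track`` is supplied).
    Above-threshold windows closer than ``merge_gap_bp`` are merged; merged
    intervals overlapping any exclusion feature (rRNA operons,
    ribosomal-protein clusters — compositionally biased for reasons other
    than foreign origin) are dropped, as are intervals shorter than
    ``min_island_bp``.

    Because alien islands contaminate the whole-genome frequency estimate
    the scores rest on, calling is iterated (up to ``refine_passes`` extra
    rounds): after each round the genome-wide frequencies are re-estimated
    with the called intervals excluded, the genome re-scored and calling
    repeated, stopping once the call set converges.  The procedure is
    deterministic: re-calling with identical inputs returns the identical
    list.
    """
    if len(track) == 0:
        raise ValueError("empty score track")
    if null_track is None:
        null_track = shuffled_null_track(genome, track.window_bp, track.step_bp,
                                         seed=seed, both_strands=track.both_strands)
    if (null_track.window_bp, null_track.step_bp) != (track.window_bp, track.step_bp):
        raise ValueError("null scan and observed scan use different window/step")
    threshold = float(np.quantile(null_track.chi2, null_quantile))

    islands = _call_islands_once(track, threshold, merge_gap_bp, min_island_bp,
                                 exclusion_features)
    for _ in range(refine_passes):
        if not islands:
            break
        refined_track = trinuc_chi2_scan(
            genome, track.window_bp, track.step_bp,
            both_strands=track.both_strands,
            exclude_intervals=[isl.interval() for isl in islands],
        )
        refined = _call_islands_once(refined_track, threshold, merge_gap_bp,
                                     min_island_bp, exclusion_features)
        if [(i.start, i.end) for i in refined] == [(i.start, i.end) for i in islands]:
            break
        islands = refined
    return islands


def _call_islands_once(
    track: WindowScoreTrack,
    threshold: float,
    merge_gap_bp: int,
    min_island_bp: int,
    exclusion_features: Iterable,
) -> list[GenomicIsland]:
    hot = track.chi2 > threshold
    islands: list[GenomicIsland] = []
    exclusions = _as_intervals(exclusion_features)
    cur: list[int] | None = None  # indices of windows in the current island
    order = np.argsort(track.starts)
    for i in order:
        if not hot[i]:
            continue
        if cur is not None and track.starts[i] - track.ends[cur[-1]] - 1 <= merge_gap_bp:
            cur.append(i)
        else:
            if cur is not None:
                islands.append(_make_island(track, cur))
            cur = [i]
    if cur is not None:
        islands.append(_make_island(track, cur))

    kept = []
    for isl in islands:
        if isl.size_bp < min_island_bp:
            continue
        iv = isl.interval()
        if any(iv[0] < e and s < iv[1] for s, e in exclusions):
            continue
        kept.append(isl)
    kept.sort(key=lambda x: x.start)
    return kept


def _make_island(track: WindowScoreTrack, idxs: list[int]) -> GenomicIsland:
    start = int(min(track.starts[i] for i in idxs))
    end = int(max(track.ends[i] for i in idxs))
    return GenomicIsland(
        start=start,
        end=end,
        size_bp=end - start + 1,
        mean_chi2=float(np.mean([track.chi2[i] for i in idxs])),
    )


def annotate_islands(
    islands: Sequence[GenomicIsland],
    genome: GenomeRecord,
    flank_bp: int = 2000,
    integrase_keywords: Iterable[str] = ("integrase",),
) -> list[GenomicIsland]:
    """Flag tRNA-flanked islands and islands containing integrase CDS.

    ``trna_flanked`` is set when a tRNA feature lies within ``flank_bp`` of
    either island boundary; ``has_integrase`` when any CDS overlapping the
    island has a product matching one of the (case-insensitive, substring)
    keywords.  tRNA insertion sites and lambda-type integrases are the
    hallmarks of integrative and conjugative elements.
    """
    keywords = [k.lower() for k in integrase_keywords]
    out = []
    for isl in islands:
        s0, e0 = isl.interval()
        flank = (max(0, s0 - flank_bp), min(len(genome), e0 + flank_bp))
        trna = any(
            fs < flank[1] and flank[0] < fe
            for f in genome.features_of("tRNA")
            for fs, fe in f.footprint()
        )
        integrase = any(
            fs < e0 and s0 < fe and any(k in f.product.lower() for k in keywords)
            for f in genome.features_of("CDS")
            for fs, fe in f.footprint()
        )
        out.append(replace(isl, trna_flanked=trna, has_integrase=integrase))
    return out
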