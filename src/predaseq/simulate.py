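"""Synthetic genomes, coverage and Ct tables with known ground truth.

The generator emulates the structure of a small predatory-bacterium
genome/transcriptome study so that every pipeline stage can be scored
against truth without external data:

* a circular genome with two oppositely GC-skewed replichores meeting at a
  known origin and terminus;
* compositionally divergent islands (drawn from a tilted nucleotide model
  at a requested total-variation distance from the background trinucleotide
  distribution), each with a tRNA gene at one boundary and, with
  probability 7/9, an integrase CDS inside;
* planted repeat pairs with mismatch-insulated flanks, so their exact
  extents are recoverable;
* densely tiled CDS genes (~90% coding) with a two-phase expression design:
  a known fraction of genes transcribed per phase, a gene set with a known
  mean fold change and a strongly phase-switched porin-like gene;
* per-position Poisson coverage, with residual-rRNA and prey-read
  contamination entering the read counters;
* Ct tables produced by inverting the ddCt chain with Gaussian replicate
  noise.

All outputs are deterministic functions of the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from predaseq.composition import encode
from predaseq.expression import ClassificationScheme, CoverageTrack, classify
from predaseq.genome_io import Feature, GenomeRecord
from predaseq.qpcr import CtTable

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SyntheticTruth:
    """Ground truth sufficient to score every downstream stage."""

    ori: int = 1
    ter: int = 0
    islands: list[dict] = field(default_factory=list)  # start/end 1-based, divergence
    repeats: list[dict] = field(default_factory=list)
    rrna_operon: tuple[int, int] | None = None  # 1-based inclusive
    true_gei: dict[str, pd.Series] = field(default_factory=dict)  # per condition
    true_category: dict[str, pd.Series] = field(default_factory=dict)
    set_fold_changes: dict[str, dict] = field(default_factory=dict)
    background_coverage: float = 0.7
    rrna_fraction: dict[str, float] = field(default_factory=dict)
    prey_fraction: dict[str, float] = field(default_factory=dict)
    depth_factor: dict[str, float] = field(default_factory=dict)

    def island_intervals(self) -> list[tuple[int, int]]:
        """0-based half-open island footprints."""
        return [(isl["start"] - 1, isl["end"]) for isl in self.islands]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "ori": self.ori,
            "ter": self.ter,
            "islands": self.islands,
            "repeats": self.repeats,
            "rrna_operon": self.rrna_operon,
            "true_gei": {c: s.to_dict() for c, s in self.true_gei.items()},
            "true_category": {c: s.to_dict() for c, s in self.true_category.items()},
            "set_fold_changes": self.set_fold_changes,
            "background_coverage": self.background_coverage,
            "rrna_fraction": self.rrna_fraction,
            "prey_fraction": self.prey_fraction,
            "depth_factor": self.depth_factor,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, default=str)
            fh.write("\n")


def _trinuc_dist(p: np.ndarray) -> np.ndarray:
    """Trinucleotide distribution implied by an independent base model."""
    return np.einsum("i,j,k->ijk", p, p, p).ravel()


def island_base_probs(background: np.ndarray, divergence: float) -> np.ndarray:
    """Tilt base probabilities until the implied trinucleotide distributions
    differ from the background's by the requested total-variation distance."""
    direction = np.array([-1.0, 1.0, 1.0, -1.0])  # push composition toward G+C
    ref = _trinuc_dist(background)

    def tv(t: float) -> float:
        q = background * np.exp(t * direction)
        q = q / q.sum()
        return 0.5 * np.abs(_trinuc_dist(q) - ref).sum()

    lo, hi = 0.0, 0.05
    while tv(hi) < divergence:
        hi *= 2
        if hi > 50:
            raise ValueError(f"divergence {divergence} not reachable")
    for _ in range(60):
        mid = (lo + hi) / 2
        if tv(mid) < divergence:
            lo = mid
        else:
            hi = mid
    q = background * np.exp(hi * direction)
    return q / q.sum()


def _place_intervals(rng: np.random.Generator, length: int, sizes: Sequence[int],
                     occupied: list[tuple[int, int]], gap: int = 5000,
                     max_tries: int = 10000) -> list[tuple[int, int]]:
    """Place non-overlapping [start, end) intervals avoiding occupied ones."""
    placed: list[tuple[int, int]] = []
    for size in sizes:
        for _ in range(max_tries):
            start = int(rng.integers(0, length - size))
            cand = (start, start + size)
            clash = any(
                cand[0] - gap < e and s < cand[1] + gap
                for s, e in occupied + placed
            )
            if not clash:
                placed.append(cand)
                break
        else:
            raise RuntimeError("could not place interval; genome too crowded")
    return placed


def make_genome(
    length: int = 500_000,
    gc: float = 0.547,
    skew_amplitude: float = 0.05,
    n_islands: int = 3,
    island_len_range: tuple[int, int] = (11_000, 28_000),
    island_divergence: float = 0.3,
    n_repeats: int = 2,
    repeat_len: int = 300,
    repeat_mismatches: int = 0,
    integrase_prob: float = 7 / 9,
    gene_length: int = 900,
    intergenic_length: int = 100,
    with_rrna_operon: bool = True,
    seed: int = 0,
) -> tuple[GenomeRecord, SyntheticTruth]:
    """Generate a circular genome with known compositional structure.

    The origin is at position 1 and the terminus at ``length // 2``; the
    first replichore carries GC skew ``+skew_amplitude`` and the second the
    opposite, so the cumulative skew has its minimum at the origin and its
    maximum at the terminus.  Island lengths are drawn uniformly from
    ``island_len_range``; each island gets a ~75 bp tRNA gene at its left
    boundary and an integrase CDS with probability ``integrase_prob``
    (default 7/9, a typical observed share of integrase-bearing ICEs).
    CDS genes of ``gene_length`` bp are tiled at ``intergenic_length``
    spacing (~90% coding, as in streamlined bacterial genomes).
    """
    rng = np.random.default_rng(seed)
    ter0 = length // 2
    p_lead = np.array([(1 - gc) / 2, gc / 2 * (1 - skew_amplitude),
                       gc / 2 * (1 + skew_amplitude), (1 - gc) / 2])
    p_lag = p_lead[[0, 2, 1, 3]]  # swap C and G
    codes = np.concatenate([
        rng.choice(4, size=ter0, p=p_lead),
        rng.choice(4, size=length - ter0, p=p_lag),
    ]).astype(np.uint8)

    truth = SyntheticTruth(ori=1, ter=ter0 + 1)
    occupied: list[tuple[int, int]] = []

    # islands
    if n_islands > 0:
        sizes = rng.integers(island_len_range[0], island_len_range[1] + 1,
                             size=n_islands)
        p_bg = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
        q = island_base_probs(p_bg, island_divergence)
        for s, e in sorted(_place_intervals(rng, length, sizes.tolist(), occupied)):
            codes[s:e] = rng.choice(4, size=e - s, p=q)
            occupied.append((s, e))
            truth.islands.append(
                {"start": s + 1, "end": e, "divergence": float(island_divergence)}
            )

    # rRNA operon (an exclusion interval and the rRNA-read sink)
    features: list[Feature] = []
    if with_rrna_operon:
        (rs, re_), = _place_intervals(rng, length, [4500], occupied)
        occupied.append((rs, re_))
        truth.rrna_operon = (rs + 1, re_)
        for i, (off, sz) in enumerate(((0, 1500), (1600, 2900), (4380, 120))):
            features.append(Feature(
                locus_tag=f"rrna{i}", kind="rRNA",
                start=rs + off + 1, end=min(rs + off + sz, re_),
                strand="+", product=("16S", "23S", "5S")[i] + " ribosomal RNA",
            ))

    # planted repeat pairs, flanks forced to mismatch so extents are exact
    if n_repeats > 0:
        spots = _place_intervals(rng, length, [repeat_len] * (2 * n_repeats), occupied)
        for r in range(n_repeats):
            (a_s, a_e), (b_s, b_e) = sorted(spots[2 * r : 2 * r + 2])
            segment = codes[a_s:a_e].copy()
            if repeat_mismatches > 0:
                mut = rng.choice(repeat_len, size=repeat_mismatches, replace=False)
                segment[mut] = (segment[mut] + rng.integers(1, 4, len(mut))) % 4
            codes[b_s:b_e] = segment
            # insulate flanks with a run of forced-mismatch columns wide
            # enough that no extension across it can keep identity >= 0.97,
            # so the planted extents are recovered exactly
            guard = int(np.ceil(repeat_len * 0.03 / 0.97)) + 2
            offsets = list(range(-guard, 0)) + list(range(0, guard))
            for off in offsets:
                flank_a = (a_s + off) if off < 0 else (a_e + off)
                flank_b = (b_s + off) if off < 0 else (b_e + off)
                if 0 <= flank_a < length and 0 <= flank_b < length:
                    if codes[flank_b] == codes[flank_a]:
                        codes[flank_b] = (codes[flank_b] + 1) % 4
            occupied.extend([(a_s, a_e), (b_s, b_e)])
            truth.repeats.append({
                "a_start": a_s + 1, "a_end": a_e, "b_start": b_s + 1, "b_end": b_e,
                "length_bp": repeat_len,
                "identity": 1.0 - repeat_mismatches / repeat_len,
                "strand": "direct",
            })

    # tRNA at the left boundary of each island
    for i, isl in enumerate(truth.islands):
        t_end = isl["start"] - 1
        t_start = max(1, t_end - 74)
        if t_end >= 1:
            features.append(Feature(
                locus_tag=f"trna{i}", kind="tRNA", start=t_start, end=t_end,
                strand="+", product="tRNA-Leu",
            ))

    # integrase CDS inside islands
    for i, isl in enumerate(truth.islands):
        if rng.random() < integrase_prob:
            start = isl["start"] + 500
            end = min(start + 1199, isl["end"])
            features.append(Feature(
                locus_tag=f"int{i}", kind="CDS", start=start, end=end,
                strand="+", product="phage integrase family protein",
            ))

    # tiled CDS genes, skipping anything colliding with rRNA/tRNA/integrase
    blocked = [iv for f in features for iv in f.footprint()]
    period = gene_length + intergenic_length
    gi = 0
    for s in range(intergenic_length // 2, length - gene_length, period):
        cand = (s, s + gene_length)
        if any(cand[0] < e and bs < cand[1] for bs, e in blocked):
            continue
        gi += 1
        features.append(Feature(
            locus_tag=f"g{gi:04d}", kind="CDS", start=s + 1, end=s + gene_length,
            strand="+" if rng.random() < 0.5 else "-",
            product="hypothetical protein",
        ))

    sequence = bytes(_BASES[codes]).decode()
    genome = GenomeRecord(id=f"synth{seed}", sequence=sequence, circular=True,
                          features=features)
    return genome, truth


def design_two_phase(
    genome: GenomeRecord,
    truth: SyntheticTruth,
    seed: int = 0,
    frac_on: Mapping[str, float] = None,
    set_size: int = 10,
    set_fold: float = 17.0,
    porin_fold_floor: float = 400.0,
    scheme: ClassificationScheme | None = None,
) -> SyntheticTruth:
    """Assign true per-gene GEI for the attack and attachment phases.

    Exactly ``frac_on`` of genes are transcribed per phase (defaults: 80%
    attachment, 33.4% attack).  Transcribed genes draw GEI from a lognormal
    spanning the low/medium/high range; silent genes sit well below the
    0.7 threshold.  A ``set_size``-gene "sec" set is planted at a uniform
    ``set_fold`` attachment/attack ratio, and one porin-like gene is
    silent in attack but high in attachment so its pseudocounted ratio
    exceeds ``porin_fold_floor``.
    """
    rng = np.random.default_rng(seed)
    scheme = scheme or ClassificationScheme()
    frac_on = dict(frac_on or {"attachment": 0.80, "attack": 0.334})
    tags = [f.locus_tag for f in genome.features_of("CDS")]
    n = len(tags)
    if n < set_size + 2:
        raise ValueError("too few genes for the requested design")

    def draw_on(k: int) -> np.ndarray:
        vals = 10 ** rng.normal(0.9, 0.45, size=k)
        lo = max(scheme.t_off + 0.25, 0.95)
        bad = vals < lo
        while bad.any():
            vals[bad] = 10 ** rng.normal(0.9, 0.45, size=int(bad.sum()))
            bad = vals < lo
        return vals

    order = rng.permutation(n)
    sec_genes = [tags[i] for i in order[:set_size]]
    porin_gene = tags[order[set_size]]
    rest = [tags[i] for i in order[set_size + 1 :]]

    gei = {c: pd.Series(0.0, index=tags) for c in ("attachment", "attack")}
    # sec set: moderately expressed in attack, exactly set_fold higher attached
    atk_base = rng.uniform(2.0, 5.0, size=set_size)
    gei["attack"].loc[sec_genes] = atk_base
    gei["attachment"].loc[sec_genes] = set_fold * atk_base
    # porin-like gene: off in attack, high in attachment
    gei["attack"].loc[porin_gene] = 0.0
    gei["attachment"].loc[porin_gene] = 60.0

    for cond in ("attachment", "attack"):
        target_on = int(round(frac_on[cond] * n))
        forced_on = set_size + (1 if cond == "attachment" else 0)
        k = max(0, target_on - forced_on)
        chosen = rng.permutation(len(rest))[:k]
        on_tags = [rest[i] for i in chosen]
        gei[cond].loc[on_tags] = draw_on(len(on_tags))
        off_tags = [t for t in rest if t not in set(on_tags)]
        gei[cond].loc[off_tags] = rng.uniform(0.0, 0.45, size=len(off_tags))
        if cond == "attack":
            pass  # porin already silent in attack
    # silent-phase values for the forced genes are already set above

    truth.true_gei = gei
    truth.true_category = {
        c: s.map(lambda v: classify(v, scheme)) for c, s in gei.items()
    }
    pc = 0.1
    sec_design_fc = float(np.mean(
        (gei["attachment"].loc[sec_genes] + pc) / (gei["attack"].loc[sec_genes] + pc)
    ))
    truth.set_fold_changes = {
        "sec": {"genes": sec_genes, "fold": set_fold,
                "pseudocounted_fold": sec_design_fc},
        "porin": {"genes": [porin_gene], "fold_floor": porin_fold_floor},
    }
    return truth


def make_coverage(
    genome: GenomeRecord,
    truth: SyntheticTruth,
    condition: str = "attachment",
    depth_factor: float = 2.0,
    rrna_fraction: float = 0.05,
    prey_fraction: float = 0.0,
    seed: int = 0,
    sam_path: str | Path | None = None,
    read_length: int = 50,
) -> CoverageTrack:
    """Poisson coverage for one condition, optionally emitted as SAM reads.

    Per-position depth is Poisson(true GEI x depth_factor) inside genes and
    Poisson(background x depth_factor) elsewhere.  Residual rRNA reads and
    unmappable prey reads inflate the read counters only: rRNA reads never
    enter the non-rRNA denominator and prey reads never contribute depth.
    With ``sam_path`` the track is realized as concrete reads whose pileup
    is returned, so re-quantifying the SAM reproduces the track exactly.
    """
    rng = np.random.default_rng(seed)
    n = len(genome)
    lam = np.full(n, truth.background_coverage * depth_factor, dtype=float)
    gei = truth.true_gei.get(condition)
    if gei is None:
        raise ValueError(f"truth has no expression design for condition {condition!r};"
                         " run design_two_phase first")
    for f in genome.features_of("CDS"):
        for s, e in f.footprint():
            lam[s:e] = gei[f.locus_tag] * depth_factor

    midpoints = None
    if sam_path is None:
        depth = rng.poisson(lam)
    else:
        starts_count = rng.poisson(lam[: n - read_length + 1] / read_length)
        diff = np.zeros(n + 1, dtype=np.int64)
        np.add.at(diff, np.arange(n - read_length + 1), starts_count)
        np.subtract.at(diff, np.arange(n - read_length + 1) + read_length, starts_count)
        depth = np.cumsum(diff[:-1])
        _write_sam(genome, starts_count, read_length, sam_path)
        pos = np.repeat(np.arange(n - read_length + 1), starts_count)
        midpoints = pos + (read_length - 1) // 2

    n_nonrrna = (int(midpoints.size) if midpoints is not None
                 else int(round(depth.sum() / read_length)))
    n_mapped = int(round(n_nonrrna / (1 - rrna_fraction))) if rrna_fraction else n_nonrrna
    n_total = int(round(n_mapped / (1 - prey_fraction))) if prey_fraction else n_mapped
    truth.depth_factor[condition] = depth_factor
    truth.rrna_fraction[condition] = rrna_fraction
    truth.prey_fraction[condition] = prey_fraction
    return CoverageTrack(
        condition=condition,
        depth=depth,
        n_reads_total=n_total,
        n_reads_mapped=n_mapped,
        n_reads_nonrrna=n_nonrrna,
        read_midpoints=midpoints,
    )


def _write_sam(genome: GenomeRecord, starts_count: np.ndarray, read_length: int,
               path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:coordinate\n")
        fh.write(f"@SQ\tSN:{genome.id}\tLN:{len(genome)}\n")
        qual = "I" * read_length
        idx = 0
        for pos0 in np.flatnonzero(starts_count):
            seq = genome.sequence[pos0 : pos0 + read_length]
            for _ in range(int(starts_count[pos0])):
                idx += 1
                fh.write(
                    f"r{idx}\t0\t{genome.id}\t{pos0 + 1}\t60\t{read_length}M\t"
                    f"*\t0\t0\t{seq}\t{qual}\n"
                )


def write_depth_tsv(track: CoverageTrack, path: str | Path) -> None:
    """Per-base depth as a 2-column TSV (1-based position, depth)."""
    with open(path, "w") as fh:
        fh.write("# position\tdepth\n")
        for i, d in enumerate(track.depth, start=1):
            fh.write(f"{i}\t{int(d)}\n")


def make_ct_table(
    true_folds: Mapping[str, float],
    reference_gene: str = "refA",
    noise_sd: float = 0.0,
    seed: int = 0,
    n_replicates: int = 3,
    calibrator_sample: str = "attack",
    sample: str = "attachment",
) -> CtTable:
    """Ct table realizing given fold changes through the inverse ddCt chain.

    Gene Ct in the calibrator is drawn uniformly in [22, 28]; the test
    sample's Ct is lowered by log2(fold); the reference gene sits at Ct 18
    in both samples.  Gaussian noise of sd ``noise_sd`` is added per
    replicate, so ``noise_sd=0`` recovers the folds exactly.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for gene, fold in true_folds.items():
        if fold <= 0:
            raise ValueError(f"fold for {gene} must be positive")
        ct_cal = rng.uniform(22.0, 28.0)
        ct_sample = ct_cal - np.log2(fold)
        for smp, ct in ((calibrator_sample, ct_cal), (sample, ct_sample)):
            for ct_rep in ct + rng.normal(0.0, noise_sd, size=n_replicates):
                rows.append((gene, smp, float(ct_rep)))
    for smp in (calibrator_sample, sample):
        for ct_rep in 18.0 + rng.normal(0.0, noise_sd, size=n_replicates):
            rows.append((reference_gene, smp, float(ct_rep)))
    data = pd.DataFrame(rows, columns=["gene", "sample", "ct"])
    return CtTable(data=data, reference_gene=reference_gene,
                   calibrator_sample=calibrator_sample)


def calibrated_ct_noise(true_folds: Mapping[str, float], target_r2: float = 0.85,
                        n_replicates: int = 3) -> float:
    """Replicate Ct noise sd that targets a given log-log R^2 against GEI.

    With GEI proportional to the true folds, the only scatter is qPCR
    noise: each gene's averaged ddCt picks up variance 2*sd^2/n_replicates
    (sample and calibrator terms; reference-gene noise shifts all genes
    alike and is absorbed by the intercept).  Solving
    R^2 = v_signal / (v_signal + v_noise) for the noise gives the sd.
    """
    if not (0 < target_r2 < 1):
        raise ValueError("target_r2 must be in (0, 1)")
    logf = np.log10(np.array(list(true_folds.values()), dtype=float))
    v_signal = float(np.var(logf))
    if v_signal == 0:
        raise ValueError("true folds are constant; R^2 target unreachable")
    v_noise_log10 = v_signal * (1 - target_r2) / target_r2
    sd_log2 = np.sqrt(v_noise_log10) / np.log10(2.0)
    return float(sd_log2 * np.sqrt(n_replicates / 2.0))


def write_outputs(genome: GenomeRecord, truth: SyntheticTruth,
                  outdir: str | Path) -> dict[str, Path]:
    """Emit FASTA + GFF3 + truth JSON for a generated genome."""
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    from predaseq.genome_io import write_gff3

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": outdir / "genome.fasta",
        "gff3": outdir / "genome.gff3",
        "truth": outdir / "truth.json",
    }
    SeqIO.write([SeqRecord(Seq(genome.sequence), id=genome.id, description="")],
                str(paths["fasta"]), "fasta")
    write_gff3(genome.features, paths["gff3"], seqid=genome.id)
    truth.to_json(paths["truth"])
    return paths
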