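"""Gene Expression Index quantification from read coverage.

The Gene Expression Index (GEI) of a gene is its mean per-base coverage
depth normalized by the library's total count of reads mapped outside rRNA
regions, which makes values comparable between libraries of different
depth.  With the default scale (the track's own non-rRNA read count) the
GEI equals raw mean depth; pass ``scale`` explicitly — e.g. the reference
library's read count, or 1e6 for a per-million convention — to put several
libraries on a common footing.

Genes are classified on the GEI scale into four categories with
lower-inclusive boundaries: not expressed (< t_off), low ([t_off, 10)),
medium ([10, 25)) and high (>= 25).  The default t_off of 0.7 is the
intergenic background level, which :func:`intergenic_background` can
re-derive from data as the median normalized coverage of intergenic
regions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from predaseq._intervals import complement, merge_intervals
from predaseq.genome_io import Feature, GenomeRecord

CATEGORIES = ("not_expressed", "low", "medium", "high")


@dataclass
class ClassificationScheme:
    t_off: float = 0.7
    t_low_hi: float = 10.0
    t_med_hi: float = 25.0
    categories: tuple[str, ...] = CATEGORIES

    def __post_init__(self) -> None:
        if not (0 < self.t_off < self.t_low_hi < self.t_med_hi):
            raise ValueError("thresholds must satisfy 0 < t_off < t_low_hi < t_med_hi")


@dataclass
class CoverageTrack:
    condition: str
    depth: np.ndarray  # per-position depth over the genome
    n_reads_total: int
    n_reads_mapped: int
    n_reads_nonrrna: int
    read_midpoints: np.ndarray | None = None  # 0-based, when reads were seen

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth)
        if np.any(self.depth < 0):
            raise ValueError("negative depth")
        if not (self.n_reads_nonrrna <= self.n_reads_mapped <= self.n_reads_total):
            raise ValueError(
                "require n_reads_nonrrna <= n_reads_mapped <= n_reads_total"
            )


@dataclass
class GeneExpression:
    locus_tag: str
    gei: dict[str, float] = field(default_factory=dict)  # per condition
    category: dict[str, str] = field(default_factory=dict)
    transcribed: dict[str, bool] = field(default_factory=dict)
    fold_change: float | None = None


@dataclass
class ComparisonReport:
    numerator: str  # condition in the fold-change numerator
    denominator: str
    pseudocount: float
    table: pd.DataFrame  # per-gene gei/category/fold_change
    frac_transcribed: dict[str, float]  # per condition, in [0, 1]
    transitions: pd.DataFrame  # denominator categories (rows) x numerator (cols)

    def top_up(self, n: int = 20) -> pd.DataFrame:
        return self.table.sort_values("fold_change", ascending=False).head(n)

    def top_down(self, n: int = 20) -> pd.DataFrame:
        return self.table.sort_values("fold_change").head(n)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# fold_change = ({self.numerator} + {self.pseudocount}) / "
                     f"({self.denominator} + {self.pseudocount})\n")
            self.table.to_csv(fh, sep="\t")


def coverage_from_alignments(
    source: str | Path,
    genome: GenomeRecord,
    rrna_intervals: Iterable = (),
    masked: bool = False,
    condition: str = "",
    format: str | None = None,
    read_length: int = 50,
    n_reads_total: int | None = None,
) -> CoverageTrack:
    """Build a coverage track from a SAM file or a per-base depth TSV.

    SAM input yields exact read counters and midpoints.  Reads overlapping
    an rRNA interval are excluded from ``n_reads_nonrrna`` (and from depth
    too when ``masked`` is set).  Depth-TSV input (two columns: 1-based
    position, depth) carries no read records, so read counters are
    estimated as covered bases / ``read_length`` unless supplied.
    ``n_reads_total`` may be given to account for reads that did not map
    (e.g. prey-derived reads in an attachment-phase library).
    """
    source = Path(source)
    if format is None:
        format = "sam" if source.suffix.lower() == ".sam" else "tsv"
    rrna = merge_intervals(_to_intervals(rrna_intervals))
    if format == "sam":
        return _coverage_from_sam(source, genome, rrna, masked, condition, n_reads_total)
    depth = np.zeros(len(genome), dtype=np.int64)
    data = pd.read_csv(source, sep="\t", header=None, comment="#").to_numpy()
    pos = data[:, 0].astype(int) - 1
    if pos.min() < 0 or pos.max() >= len(genome):
        raise ValueError(f"{source}: positions outside genome of length {len(genome)}")
    depth[pos] = data[:, 1].astype(int)
    in_rrna = np.zeros(len(genome), dtype=bool)
    for s, e in rrna:
        in_rrna[s:e] = True
    n_nonrrna = int(round(depth[~in_rrna].sum() / read_length))
    n_mapped = int(round(depth.sum() / read_length))
    if masked:
        depth = np.where(in_rrna, 0, depth)
    return CoverageTrack(
        condition=condition,
        depth=depth,
        n_reads_total=n_reads_total if n_reads_total is not None else n_mapped,
        n_reads_mapped=n_mapped,
        n_reads_nonrrna=n_nonrrna,
    )


def _to_intervals(items: Iterable) -> list[tuple[int, int]]:
    out: list[tuple[int, int]] = []
    for item in items:
        if isinstance(item, Feature):
            out.extend(item.footprint())
        else:
            s, e = item
            out.append((int(s) - 1, int(e)))
    return out


def _coverage_from_sam(path: Path, genome: GenomeRecord, rrna, masked,
                       condition, n_reads_total) -> CoverageTrack:
    import pysam

    n = len(genome)
    diff = np.zeros(n + 1, dtype=np.int64)
    midpoints: list[int] = []
    n_mapped = 0
    n_rrna = 0
    n_records = 0
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for ref in sam.references:
            length = sam.get_reference_length(ref)
            if ref != genome.id or length != n:
                raise ValueError(
                    f"{path}: reference {ref} ({length} bp) does not match "
                    f"genome {genome.id} ({n} bp)"
                )
        for read in sam.fetch(until_eof=True):
            n_records += 1
            if read.is_unmapped:
                continue
            s, e = read.reference_start, read.reference_end
            if e is None or e <= s:
                continue
            n_mapped += 1
            hits_rrna = any(s < re_ and rs < e for rs, re_ in rrna)
            if hits_rrna:
                n_rrna += 1
            if not (hits_rrna and masked):
                diff[s] += 1
                diff[e] -= 1
            midpoints.append((s + e - 1) // 2)
    depth = np.cumsum(diff[:-1])
    total = n_reads_total if n_reads_total is not None else n_records
    return CoverageTrack(
        condition=condition,
        depth=depth,
        n_reads_total=max(total, n_mapped),
        n_reads_mapped=n_mapped,
        n_reads_nonrrna=n_mapped - n_rrna,
        read_midpoints=np.array(midpoints, dtype=np.int64),
    )


DEFAULT_GEI_SCALE = 1_000_000.0


def gei(track: CoverageTrack, gene: Feature, scale: float | None = None) -> float:
    """Gene Expression Index: mean gene depth * scale / non-rRNA read count.

    The default scale is 10^6, so a library with a million non-rRNA reads
    reports raw mean depth and duplicating every read leaves the value
    unchanged.  Pass the reference library's non-rRNA read count as
    ``scale`` to keep values on that library's coverage scale (the scale
    the 0.7/10/25 classification thresholds live on).
    """
    if track.n_reads_nonrrna <= 0:
        raise ValueError("track has no non-rRNA reads; GEI undefined")
    total = 0
    length = 0
    for s, e in gene.footprint():
        total += int(track.depth[s:e].sum())
        length += e - s
    if length == 0:
        raise ValueError(f"gene {gene.locus_tag} has zero length")
    if scale is None:
        scale = DEFAULT_GEI_SCALE
    return (total / length) * scale / track.n_reads_nonrrna


def classify(gei_value: float, scheme: ClassificationScheme | None = None) -> str:
    """Map a GEI value to its expression category (lower bound inclusive)."""
    if scheme is None:
        scheme = ClassificationScheme()
    if gei_value < 0:
        raise ValueError("GEI must be non-negative")
    if gei_value < scheme.t_off:
        return scheme.categories[0]
    if gei_value < scheme.t_low_hi:
        return scheme.categories[1]
    if gei_value < scheme.t_med_hi:
        return scheme.categories[2]
    return scheme.categories[3]


def intergenic_background(
    track: CoverageTrack,
    genome: GenomeRecord,
    scale: float | None = None,
    stat: str = "median",
) -> float:
    """Median (or mean) normalized coverage of intergenic regions.

    Intergenic regions are the complement of all annotated feature
    footprints; each region contributes its mean normalized coverage and
    the median across regions is returned.  This is the data-derived
    estimate of the "not expressed" threshold.
    """
    if track.n_reads_nonrrna <= 0:
        raise ValueError("track has no non-rRNA reads")
    if scale is None:
        scale = DEFAULT_GEI_SCALE
    footprints = [iv for f in genome.features for iv in f.footprint()]
    regions = complement(footprints, len(genome))
    if not regions:
        raise ValueError("genome has no intergenic positions")
    values = [
        float(track.depth[s:e].mean()) * scale / track.n_reads_nonrrna
        for s, e in regions
    ]
    if stat == "median":
        return float(np.median(values))
    if stat == "mean":
        return float(np.mean(values))
    raise ValueError(f"unknown stat {stat!r}")


def quantify(
    track: CoverageTrack,
    genome: GenomeRecord,
    scheme: ClassificationScheme | None = None,
    scale: float | None = None,
    kinds: tuple[str, ...] = ("CDS",),
) -> pd.DataFrame:
    """Per-gene GEI and category for one condition, as a DataFrame."""
    scheme = scheme or ClassificationScheme()
    rows = []
    for f in genome.features_of(*kinds):
        value = gei(track, f, scale=scale)
        cat = classify(value, scheme)
        rows.append((f.locus_tag, value, cat, cat != scheme.categories[0]))
    return pd.DataFrame(
        rows, columns=["locus_tag", "gei", "category", "transcribed"]
    ).set_index("locus_tag")


def build_gene_expression(
    tables: Mapping[str, pd.DataFrame],
) -> list[GeneExpression]:
    """Combine per-condition :func:`quantify` tables into GeneExpression rows."""
    conditions = list(tables)
    index = tables[conditions[0]].index
    for cond in conditions[1:]:
        if not index.equals(tables[cond].index):
            raise ValueError("conditions quantify different gene sets")
    out = []
    for tag in index:
        ge = GeneExpression(locus_tag=tag)
        for cond in conditions:
            row = tables[cond].loc[tag]
            ge.gei[cond] = float(row["gei"])
            ge.category[cond] = str(row["category"])
            ge.transcribed[cond] = bool(row["transcribed"])
        out.append(ge)
    return out


def compare_phases(
    expr: Sequence[GeneExpression],
    pseudocount: float = 0.1,
    numerator: str = "attachment",
    denominator: str = "attack",
) -> ComparisonReport:
    """Compare two conditions gene by gene.

    Sets each gene's ``fold_change`` to (GEI_num + c) / (GEI_den + c) with
    pseudocount c, and reports the fraction of genes transcribed per
    condition, the category-transition matrix and the full per-gene table.
    """
    if not expr:
        raise ValueError("no genes to compare")
    for ge in expr:
        if numerator not in ge.gei or denominator not in ge.gei:
            raise ValueError(
                f"gene {ge.locus_tag} lacks condition "
                f"{numerator if numerator not in ge.gei else denominator}"
            )
    rows = []
    for ge in expr:
        fc = (ge.gei[numerator] + pseudocount) / (ge.gei[denominator] + pseudocount)
        ge.fold_change = fc
        rows.append(
            (ge.locus_tag, ge.gei[numerator], ge.gei[denominator],
             ge.category[numerator], ge.category[denominator], fc)
        )
    table = pd.DataFrame(
        rows,
        columns=["locus_tag", f"gei_{numerator}", f"gei_{denominator}",
                 f"category_{numerator}", f"category_{denominator}", "fold_change"],
    ).set_index("locus_tag")
    frac = {
        cond: float(np.mean([ge.transcribed[cond] for ge in expr]))
        for cond in (numerator, denominator)
    }
    transitions = pd.DataFrame(
        0, index=list(CATEGORIES), columns=list(CATEGORIES), dtype=int
    )
    for ge in expr:
        transitions.loc[ge.category[denominator], ge.category[numerator]] += 1
    return ComparisonReport(
        numerator=numerator,
        denominator=denominator,
        pseudocount=pseudocount,
        table=table,
        frac_transcribed=frac,
        transitions=transitions,
    )


def gene_set_fold_change(
    expr: Sequence[GeneExpression],
    gene_set: Iterable[str],
    pseudocount: float = 0.1,
    method: str = "arithmetic",
    numerator: str = "attachment",
    denominator: str = "attack",
) -> float:
    """Mean fold change of a gene set (arithmetic by default, geometric option)."""
    genes = set(gene_set)
    if not genes:
        raise ValueError("empty gene set")
    by_tag = {ge.locus_tag: ge for ge in expr}
    missing = genes - set(by_tag)
    if missing:
        raise ValueError(f"gene set members not quantified: {sorted(missing)}")
    fcs = [
        (by_tag[g].gei[numerator] + pseudocount)
        / (by_tag[g].gei[denominator] + pseudocount)
        for g in sorted(genes)
    ]
    if method == "arithmetic":
        return float(np.mean(fcs))
    if method == "geometric":
        return float(np.exp(np.mean(np.log(fcs))))
    raise ValueError(f"unknown method {method!r}")


def coverage_summaries(track: CoverageTrack, genome: GenomeRecord) -> dict:
    """Genome-wide coverage summaries.

    Returns the percent of genome positions covered by at least one read
    and the percent of mapped reads whose midpoint falls in a CDS
    footprint.  When the track carries no read records (depth-TSV input)
    the reads-in-ORF figure falls back to the share of depth mass inside
    CDS footprints.
    """
    n = len(genome)
    covered = 100.0 * float(np.count_nonzero(track.depth[:n])) / n
    in_cds = np.zeros(n, dtype=bool)
    for f in genome.features_of("CDS"):
        for s, e in f.footprint():
            in_cds[s:e] = True
    if track.read_midpoints is not None and len(track.read_midpoints) > 0:
        reads_in_orfs = 100.0 * float(np.mean(in_cds[track.read_midpoints]))
    elif track.depth.sum() > 0:
        reads_in_orfs = 100.0 * float(track.depth[in_cds].sum() / track.depth.sum())
    else:
        warnings.warn("track has no reads; reads-in-ORFs reported as 0")
        reads_in_orfs = 0.0
    return {
        "genome_covered_percent": covered,
        "reads_in_orfs_percent": reads_in_orfs,
    }


def write_bedgraph(track: CoverageTrack, path: str | Path, seqid: str = "genome",
                   scale: float | None = None) -> None:
    """Export normalized coverage as bedGraph (0-based half-open runs)."""
    if scale is None:
        scale = DEFAULT_GEI_SCALE
    norm = track.depth * scale / track.n_reads_nonrrna
    with open(path, "w") as fh:
        fh.write(f'track type=bedGraph name="{track.condition or seqid}"\n')
        start = 0
        for i in range(1, len(norm) + 1):
            if i == len(norm) or norm[i] != norm[start]:
                if norm[start] != 0:
                    fh.write(f"{seqid}\t{start}\t{i}\t{norm[start]:.6g}\n")
                start = i
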