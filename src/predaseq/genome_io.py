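"""Genome records, standard-format I/O and summary statistics.

Coordinates follow the GenBank/GFF convention (1-based, inclusive) in the
public :class:`Feature` fields and in all written files; interval arithmetic
is done internally on 0-based half-open coordinates via ``footprint()``.
Features that wrap the origin of a circular genome are stored as two
sub-intervals (``parts``) split at position 1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

from Bio import SeqIO

from predaseq._intervals import union_length

FeatureKind = Literal["CDS", "tRNA", "rRNA", "other"]

_KIND_MAP = {"CDS": "CDS", "tRNA": "tRNA", "rRNA": "rRNA"}


@dataclass
class Feature:
    """An annotated genome feature (1-based inclusive coordinates)."""

    locus_tag: str
    kind: FeatureKind
    start: int
    end: int
    strand: str = "+"
    product: str = ""
    translation: str | None = None
    #: sub-intervals for origin-wrapping features; defaults to [(start, end)]
    parts: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if not self.parts:
            self.parts = ((self.start, self.end),)
        for s, e in self.parts:
            if s > e:
                raise ValueError(
                    f"feature {self.locus_tag}: part start {s} > end {e}; "
                    "wrapping features must be split into two parts"
                )
        if self.strand not in "+-":
            raise ValueError(f"feature {self.locus_tag}: strand must be + or -")

    def footprint(self) -> list[tuple[int, int]]:
        """0-based half-open intervals covered by this feature."""
        return [(s - 1, e) for s, e in self.parts]

    @property
    def length(self) -> int:
        return sum(e - s + 1 for s, e in self.parts)


@dataclass
class GenomeRecord:
    """A (possibly circular) nucleotide sequence with typed features."""

    id: str
    sequence: str
    circular: bool = True
    features: list[Feature] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise ValueError(f"genome {self.id}: empty sequence")
        bad = set(self.sequence) - set("ACGTN")
        if bad:
            raise ValueError(f"genome {self.id}: invalid characters {sorted(bad)}")
        n = len(self.sequence)
        tags: set[str] = set()
        for f in self.features:
            if f.locus_tag in tags:
                raise ValueError(f"duplicate locus tag {f.locus_tag}")
            tags.add(f.locus_tag)
            for s, e in f.parts:
                if not (1 <= s <= e <= n):
                    raise ValueError(
                        f"feature {f.locus_tag}: [{s},{e}] outside [1,{n}]"
                    )

    def __len__(self) -> int:
        return len(self.sequence)

    def features_of(self, *kinds: str) -> list[Feature]:
        return [f for f in self.features if f.kind in kinds]


@dataclass
class GenomeStats:
    length_bp: int
    gc_percent: float
    n_cds: int
    n_trna: int
    n_rrna_genes: int
    mean_cds_length_bp: float
    coding_fraction_percent: float

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def _feature_from_seqfeature(sf, locus_fallback: str, genome_len: int) -> Feature:
    quals = sf.qualifiers
    tag = quals.get("locus_tag", quals.get("gene", [locus_fallback]))[0]
    kind = _KIND_MAP.get(sf.type, "other")
    strand = "-" if sf.location.strand == -1 else "+"
    product = quals.get("product", [""])[0]
    translation = quals.get("translation", [None])[0]
    part_locs = sorted(
        ((int(p.start) + 1, int(p.end)) for p in sf.location.parts),
        key=lambda p: p[0],
    )
    start = part_locs[0][0]
    end = part_locs[-1][1]
    return Feature(
        locus_tag=tag,
        kind=kind,
        start=start,
        end=end,
        strand=strand,
        product=product,
        translation=translation,
        parts=tuple(part_locs),
    )


def read_genome(
    path: str | Path,
    format: str = "genbank",
    gff3: str | Path | None = None,
    circular: bool = True,
) -> GenomeRecord:
    """Read a genome from a FASTA or GenBank flat file.

    FASTA input carries no annotation; pass ``gff3`` to attach features.
    Only the first record of a multi-record file is read.
    """
    path = Path(path)
    if format not in ("fasta", "genbank"):
        raise ValueError(f"unknown format {format!r}; use 'fasta' or 'genbank'")
    try:
        record = next(SeqIO.parse(str(path), format))
    except StopIteration:
        raise ValueError(f"{path}: no records found (empty or wrong format)")
    except ValueError as exc:
        raise ValueError(f"{path}: parse error in {format} input: {exc}") from exc
    seq = str(record.seq).upper()
    if not seq:
        raise ValueError(f"{path}: record {record.id} has an empty sequence")
    features: list[Feature] = []
    if format == "genbank":
        seen: set[str] = set()
        for i, sf in enumerate(record.features):
            if sf.type not in ("CDS", "tRNA", "rRNA"):
                continue
            feat = _feature_from_seqfeature(sf, f"feat{i:05d}", len(seq))
            if feat.locus_tag in seen:  # e.g. gene + CDS pair sharing a tag
                feat.locus_tag = f"{feat.locus_tag}.{i}"
            seen.add(feat.locus_tag)
            features.append(feat)
    genome = GenomeRecord(id=record.id, sequence=seq, circular=circular, features=features)
    if gff3 is not None:
        genome.features = read_gff3(gff3, genome_len=len(seq))
    return genome


def read_gff3(path: str | Path, genome_len: int | None = None) -> list[Feature]:
    """Read CDS/tRNA/rRNA features from a GFF3 file."""
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    features: list[Feature] = []
    for i, f in enumerate(db.all_features()):
        kind = _KIND_MAP.get(f.featuretype, "other")
        if kind == "other" and f.featuretype not in ("gene",):
            pass
        if f.featuretype not in ("CDS", "tRNA", "rRNA"):
            continue
        tag = f.attributes.get("locus_tag", f.attributes.get("ID", [f"feat{i:05d}"]))[0]
        product = f.attributes.get("product", [""])[0]
        features.append(
            Feature(
                locus_tag=tag,
                kind=kind,
                start=f.start,
                end=f.end,
                strand=f.strand if f.strand in "+-" else "+",
                product=product,
            )
        )
    return features


def write_gff3(features: Iterable[Feature], path: str | Path, seqid: str = "genome") -> None:
    """Write features as GFF3 (one line per sub-interval part)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            attrs = f"ID={f.locus_tag};locus_tag={f.locus_tag}"
            if f.product:
                attrs += f";product={f.product}"
            for s, e in f.parts:
                fh.write(
                    f"{seqid}\tpredaseq\t{f.kind}\t{s}\t{e}\t.\t{f.strand}\t.\t{attrs}\n"
                )


def genome_stats(genome: GenomeRecord) -> GenomeStats:
    """Summary statistics of a genome: GC%, feature counts, coding density.

    GC% ignores N bases; the coding fraction is the length of the union of
    CDS footprints (overlapping genes counted once) over the genome length.
    """
    seq = genome.sequence
    gc = seq.count("G") + seq.count("C")
    at = seq.count("A") + seq.count("T")
    gc_percent = 100.0 * gc / (gc + at) if gc + at else 0.0
    cds = genome.features_of("CDS")
    trna = genome.features_of("tRNA")
    rrna = genome.features_of("rRNA")
    cds_footprints = [iv for f in cds for iv in f.footprint()]
    coding_bp = union_length(cds_footprints)
    return GenomeStats(
        length_bp=len(seq),
        gc_percent=round(gc_percent, 1),
        n_cds=len(cds),
        n_trna=len(trna),
        n_rrna_genes=len(rrna),
        mean_cds_length_bp=(sum(f.length for f in cds) / len(cds)) if cds else 0.0,
        coding_fraction_percent=round(100.0 * coding_bp / len(seq), 1),
    )


def write_stats(stats: GenomeStats, tsv_path: str | Path | None = None,
                json_path: str | Path | None = None) -> None:
    """Write a stats report as TSV (one row per metric) and/or JSON."""
    d = stats.to_dict()
    if tsv_path is not None:
        with open(tsv_path, "w") as fh:
            fh.write("metric\tvalue\n")
            for k, v in d.items():
                fh.write(f"{k}\t{v}\n")
    if json_path is not None:
        with open(json_path, "w") as fh:
            json.dump(d, fh, indent=2)
            fh.write("\n")
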