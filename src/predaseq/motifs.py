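"""Hemolysin-type (RTX) calcium-binding repeat counting.

RTX toxins carry tandem copies of the glycine-rich GGXGXD nonapeptide core
("X" = any residue).  The scanner counts non-overlapping occurrences with a
left-to-right greedy scan, which for a fixed-length pattern yields the
maximum possible non-overlapping count.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

_AA = set("ACDEFGHIKLMNPQRSTVWYX*")


@dataclass
class MotifReport:
    locus_tag: str
    protein_length_aa: int
    n_repeats: int
    match_positions: list[int] = field(default_factory=list)  # 1-based offsets


def _pattern_to_regex(pattern: str) -> re.Pattern:
    return re.compile("".join("." if ch == "X" else re.escape(ch) for ch in pattern))


def count_ggxgxd(protein: str, pattern: str = "GGXGXD",
                 locus_tag: str = "") -> MotifReport:
    """Count non-overlapping GGXGXD-style motifs in a protein sequence.

    The sequence may contain X (wildcard, matches any pattern position).
    Matching is greedy left-to-right and non-overlapping, the convention for
    counting tandem repeats.
    """
    if not protein:
        raise ValueError("empty protein sequence")
    protein = protein.upper().rstrip("*")
    bad = set(protein) - _AA
    if bad:
        raise ValueError(f"invalid amino-acid characters: {sorted(bad)}")
    # X in the sequence matches anything, including literal pattern positions
    rx = re.compile(
        "".join(
            "." if ch == "X" else f"[{ch}X]" for ch in pattern
        )
    )
    positions = [m.start() + 1 for m in rx.finditer(protein)]
    return MotifReport(
        locus_tag=locus_tag,
        protein_length_aa=len(protein),
        n_repeats=len(positions),
        match_positions=positions,
    )


def scan_fasta(path: str | Path, pattern: str = "GGXGXD") -> list[MotifReport]:
    """Scan a protein FASTA file; one report per record."""
    from Bio import SeqIO

    return [
        count_ggxgxd(str(rec.seq), pattern=pattern, locus_tag=rec.id)
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_reports_tsv(reports: Iterable[MotifReport], path: str | Path,
                      pattern: str = "GGXGXD") -> None:
    with open(path, "w") as fh:
        fh.write(f"# pattern={pattern} counting=greedy-non-overlapping\n")
        fh.write("locus_tag\tprotein_length_aa\tn_repeats\tpositions\n")
        for r in reports:
            pos = ",".join(map(str, r.match_positions))
            fh.write(f"{r.locus_tag}\t{r.protein_length_aa}\t{r.n_repeats}\t{pos}\n")
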