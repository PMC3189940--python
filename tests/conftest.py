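from __future__ import annotations

import textwrap

import numpy as np
import pytest

from predaseq.genome_io import Feature, GenomeRecord

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def random_sequence(rng: np.random.Generator, n: int) -> str:
    return bytes(_BASES[rng.integers(0, 4, n)]).decode()


@pytest.fixture
def tiny_genome() -> GenomeRecord:
    """100 bp circular genome, GC 50%, CDS union covers 80 bp."""
    seq = "GC" * 25 + "AT" * 25
    return GenomeRecord(
        id="tiny",
        sequence=seq,
        circular=True,
        features=[
            Feature("c1", "CDS", 1, 30, "+", "protein one"),
            Feature("c2", "CDS", 21, 80, "-", "protein two"),
            Feature("t1", "tRNA", 85, 95, "+", "tRNA-Gly"),
        ],
    )


@pytest.fixture
def tiny_genbank(tmp_path):
    """GenBank flat file matching the tiny_genome fixture."""
    seq = "gc" * 25 + "at" * 25
    lines = []
    for i in range(0, 100, 60):
        chunk = seq[i : i + 60]
        blocks = " ".join(chunk[j : j + 10] for j in range(0, len(chunk), 10))
        lines.append(f"{i + 1:>9} {blocks}")
    origin = "\n".join(lines)
    text = textwrap.dedent(
        """\
        LOCUS       tiny                     100 bp    DNA     circular BCT 01-JAN-2020
        DEFINITION  synthetic two-gene test genome.
        ACCESSION   tiny
        VERSION     tiny
        FEATURES             Location/Qualifiers
             source          1..100
             CDS             1..30
                             /locus_tag="c1"
                             /product="protein one"
             CDS             complement(21..80)
                             /locus_tag="c2"
                             /product="protein two"
             tRNA            85..95
                             /locus_tag="t1"
                             /product="tRNA-Gly"
        ORIGIN
        """
    ) + origin + "\n//\n"
    path = tmp_path / "tiny.gbk"
    path.write_text(text)
    return path


@pytest.fixture
def uniform_genome() -> GenomeRecord:
    """50 kb i.i.d. uniform-composition circular genome (fixed seed)."""
    rng = np.random.default_rng(42)
    return GenomeRecord(id="uniform", sequence=random_sequence(rng, 50_000))
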