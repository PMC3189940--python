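# predaseq

Compositional genome scanning and coverage-based expression quantification
for small bacterial genomes — built around the analyses used to
characterize predatory bacteria such as *Micavibrio aeruginosavorus*, an
obligate epibiotic predator with a free-swimming **attack** phase and a
prey-attached **attachment** phase.

The package re-implements, as a tested and reusable library + CLI, the
bespoke computations such a genome/transcriptome study needs:

- **Genome summary statistics** — length, GC%, CDS/tRNA/rRNA counts, mean
  ORF length, coding fraction (union of CDS footprints).
- **GC skew and replication origin/terminus** — per-window
  *s* = (G−C)/(G+C); the mean-centered cumulative skew attains its minimum
  at *ori* and maximum at *ter* on the G-rich leading-strand convention.
- **Genomic-island detection** — each window's 64 overlapping
  trinucleotide counts *O<sub>k</sub>* are tested against whole-genome
  expectation *E<sub>k</sub>* = *f<sub>k</sub>* · *n* with
  χ² = Σ<sub>k</sub> (O<sub>k</sub>−E<sub>k</sub>)²/E<sub>k</sub>.
  The calling threshold is the 0.999 quantile of scores from
  mononucleotide-shuffled genomes (overlapping counts break the analytic
  χ²₆₃ null); anomalous windows are merged into islands, background
  frequencies are re-estimated excluding them, and calling iterates to
  convergence. Called islands are annotated with tRNA-flank and integrase
  flags, the hallmarks of integrative and conjugative elements (ICEs).
- **Repeat search** — maximal ungapped repeat pairs (direct and inverted)
  above a length/identity threshold (canonically ≥50 bp at ≥97%), via
  exact k-mer seeding with provably lossless sensitivity at those
  thresholds; also the cross-genome shared-segment screen (>100 bp, 97%)
  used to test predator→prey lateral transfer.
- **RTX motif counting** — greedy non-overlapping counts of the
  hemolysin-type calcium-binding GGXGXD repeat in protein sequences.
- **Gene Expression Index (GEI)** — per-gene mean coverage depth
  normalized by the library's non-rRNA mapped read count, classified into
  not expressed (<0.7), low ([0.7,10)), medium ([10,25)) and high (≥25),
  with the 0.7 background re-derivable as the median normalized coverage
  of intergenic regions; attachment-vs-attack comparison with pseudocounted
  fold changes and gene-set means.
- **qPCR validation** — 2^(−ΔΔCt) relative quantification and the log–log
  OLS agreement (R²) between qPCR folds and GEI.
- **Synthetic data** — a generator producing circular two-replichore
  genomes with planted islands, repeats, annotations, two-phase expression
  designs, Poisson coverage (with rRNA/prey read contamination), SAM/depth
  emission and Ct tables, all with a ground-truth record.

## Worked example

```python
from predaseq import simulate as sim
from predaseq.composition import (gc_skew, predict_ori_ter, trinuc_chi2_scan,
                                  call_islands, annotate_islands)
from predaseq.genome_io import genome_stats

genome, truth = sim.make_genome(length=500_000, n_islands=3,
                                island_len_range=(15_000, 15_001), seed=1)
print(genome_stats(genome))
print(predict_ori_ter(gc_skew(genome)))
track = trinuc_chi2_scan(genome, both_strands=True)
islands = annotate_islands(
    call_islands(track, genome,
                 exclusion_features=genome.features_of("rRNA"), seed=1),
    genome)
for isl in islands:
    print(isl)
```

prints

```
GenomeStats(length_bp=500000, gc_percent=56.7, n_cds=490, n_trna=3,
            n_rrna_genes=3, mean_cds_length_bp=901.2, coding_fraction_percent=88.3)
OriTerPrediction(ori=1, ter=250001, ori_cumulative=-0.0,
                 ter_cumulative=10.67, confident=True)
GenomicIsland(start=71001,  end=88000,  size_bp=17000, mean_chi2=2850.0, trna_flanked=True, has_integrase=True)
GenomicIsland(start=303001, end=320000, size_bp=17000, mean_chi2=2783.5, trna_flanked=True, has_integrase=False)
GenomicIsland(start=410001, end=428000, size_bp=18000, mean_chi2=2692.3, trna_flanked=True, has_integrase=True)
```

The three planted 15 kb islands (truth: 71784–86784, 304103–319102,
411331–426331) are each recovered to within about one 2 kb window of their
true boundaries; the origin and terminus land exactly on the planted
replichore junctions. On the expression side, the same seed's two-phase
design quantifies to 80.0% of genes transcribed in the attachment phase
versus 33.5% in the attack phase, and the planted 17-fold up-regulated
"sec" gene set is estimated at 16.6-fold (the small deficit is the
pseudocount in the fold-change ratio).

The same stages are available from the shell — `predaseq stats`, `skew`,
`islands`, `repeats`, `motifs`, `quant`, `compare`, `qpcr`, `simulate`,
`report` — each writing TSV/JSON outputs plus a YAML file with the resolved
parameters. To analyse a real genome (for example the *M. aeruginosavorus*
chromosome, GenBank accession CP002382), download its GenBank flat file and
run:

```sh
predaseq report --genome CP002382.gbk --format genbank --out-dir results/
```

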