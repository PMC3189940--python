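# Methods

This note records the models, conventions, parameter choices and known
limitations behind each stage of the package. Coordinates are 1-based
inclusive at every external boundary (GenBank/GFF convention) and 0-based
half-open in internal arithmetic.

## Genome statistics

GC% is 100·(G+C)/(A+C+G+T), ignoring N (undefined composition). The coding
fraction is the union of CDS footprints over the genome length — summing
gene lengths would exceed 100% wherever genes overlap. Mean CDS length is
the arithmetic mean of per-CDS spans (sum of part lengths for
origin-wrapping genes, which are stored split at position 1 so all interval
arithmetic stays linear). rRNA features are counted as genes; the module
deliberately does not infer operon structure from them.

## GC skew and origin/terminus

Per-window skew is (G−C)/(G+C), zero when a window has no G or C. Windows
are laid out from position 1 at a fixed step and wrap around circular
genomes. The origin is placed at the global minimum and the terminus at the
global maximum of the cumulative skew (leading strand G-rich). Two
numerical choices matter:

- Extrema are located on the *mean-centered* cumulative (Σ(sᵢ − s̄)). On a
  circle the plain running sum depends on where the coordinate origin
  happens to cut the genome; centering zeroes the circular total and makes
  the prediction exactly equivariant under genome rotation.
- The confidence flag compares the cumulative range against
  `min_sigma` (default 5) random-walk standard deviations, σ√n, with σ
  estimated from first differences of the window skews. First differences
  detrend the slowly varying replichore mean, so a strong signal does not
  inflate its own null scale. Uniform-composition genomes fall below the
  threshold and are flagged low-confidence.

## Trinucleotide chi-square scan

Each window's 64 overlapping trinucleotide counts O_k are compared with
E_k = f_k·n_valid, where f_k are genome-wide frequencies and n_valid the
window's count of N-free trinucleotides (this automatically rescales
expectations in windows containing N); χ² = Σ(O−E)²/E over classes with
E > 0. Circular genomes are counted circularly everywhere, so a window
equal to the whole genome reproduces the global counts exactly and scores
an exact 0.

Counting is single-strand by default; a strand-symmetric option folds each
trinucleotide with its reverse complement. The folded count is exactly
invariant to replichore strand bias (the lagging strand's composition is
the complement of the leading strand's), which matters for island calling
(below).

Window/step default to 2000/1000 bp, chosen so islands at the small end of
the biologically reported range (~11 kb) span ≥10 windows; windows with
fewer than one valid trinucleotide are skipped and logged.

## Island calling

Thresholding uses a permutation null: the genome is mononucleotide-shuffled
and re-scanned with identical parameters, and the calling threshold is the
`null_quantile` (default 0.999) of the null scores. Overlapping
trinucleotide counts violate the independence assumptions of the analytic
χ² distribution with 63 df and inflate its tail, hence the empirical null.
Ten shuffles are pooled: a single shuffle yields one score per window
position (~500 values on a 500 kb genome), making a 0.999 quantile little
more than a noisy sample maximum.

Above-threshold windows merge across gaps ≤ `merge_gap_bp` (default 2000,
one window); merged intervals shorter than `min_island_bp` (default 8000)
are dropped, as are intervals overlapping caller-supplied exclusion
features (rRNA operons and ribosomal-protein clusters are compositionally
biased for reasons other than foreign origin, so they are excluded by
annotation rather than auto-detected). The island-calling pipeline scans
strand-symmetrically by default; single-strand scores remain available and
are the scan function's own default.

Two refinements proved necessary and are part of the method:

1. **Iterative background re-estimation.** Alien islands sit inside the
   genome-wide frequencies f_k that the scores are measured against; with
   ~9% of a genome in islands this mixture contamination inflates every
   background window's score and blurs island edges. After each calling
   round the genome-wide frequencies are re-estimated with called intervals
   excluded and the genome re-scored; calling iterates (≤3 extra rounds)
   until the call set converges. The procedure is deterministic and
   idempotent.
2. **Strand-symmetric counting for calling.** Replichore GC skew is a
   genuine compositional difference between genome halves that the shuffle
   null destroys; single-strand scores on skewed genomes therefore sit
   systematically above the null. Folded counts remove this confound
   exactly.

Annotation flags: `trna_flanked` if a tRNA lies within `flank_bp` (default
2000) of either boundary; `has_integrase` if any CDS overlapping the island
has a product containing an integrase keyword (case-insensitive substring,
default {"integrase"}).

Limitations: an island spanning the coordinate origin would be reported as
two intervals; island boundaries are quantized to the window grid (called
extents run ~1–2 kb beyond true edges at the default window size).

## Repeat finding

A hit is a pair of equal-length ungapped segments (direct or inverted) with
length ≥ `min_len_bp`, identity ≥ `min_identity`, matching first and last
alignment columns (standard end-trimming), and maximality: in dotplot terms
a hit is a diagonal segment, and segments properly contained in a longer
qualifying segment on the same diagonal are suppressed. Gaps are not
modelled; the canonical thresholds (50 bp/97%, 100 bp/97%) are stated
without gap semantics and every output header records the ungapped reading.

Detection seeds on exact k-mers (k = 16): a segment of length L with m
mismatches contains an exact run ≥ (L−m)/(m+1), which at 50 bp/97% (m ≤ 1)
guarantees a 24-mer — so no qualifying hit can be missed. Within each
seeded diagonal *all* maximal qualifying intervals are recovered exactly
from prefix mismatch counts (a monotone-record structure gives each left
end its rightmost feasible right end in O(n log n)), not greedily. The
test suite proves hit-set identity with an exhaustive all-substring-pairs
oracle on random sequences. `max_extension` (default 5000 bp) bounds how
far beyond the outermost seed a diagonal is examined — ample for
bacterial-scale repeats (~1 kb), but a single repeat longer than the bound
would be truncated.

The repetitive fraction is the union of all hit intervals (both copies)
over genome length, as a percent.

## Motif counting

GGXGXD (X = any residue) is counted by a greedy left-to-right
non-overlapping scan; for a fixed-length pattern the leftmost-first rule
attains the maximum non-overlapping count (interval scheduling). X in the
protein sequence acts as a wildcard in both directions. Counts from domain
annotation pipelines need not coincide with regex counts, so motif counts
here are a screening statistic, not a reproduction of curated domain
tables.

## Expression quantification

GEI(g) = mean depth over the gene span × scale / N_nonrRNA, where
N_nonrRNA is the library's count of reads mapped outside rRNA regions. The
default scale is 10⁶ (a library of one million non-rRNA reads reports raw
mean depth), making GEI exactly invariant under uniform read duplication;
passing the reference library's own count as `scale` keeps values on that
library's coverage scale, which is where the classification thresholds
live. rRNA-overlapping reads are excluded from the denominator only, by
default; a masked mode also removes them from depth (which of the two the
canonical analysis used is not documented, so both exist).

Classification: not expressed < 0.7 ≤ low < 10 ≤ medium < 25 ≤ high, lower
bounds inclusive, implemented bit-exactly. The 0.7 threshold equals the
intergenic background, computed as the *median* over intergenic regions of
their mean normalized coverage ("medium coverage" in the source convention
is read as median; a mean option exists).

Phase comparison: fold change = (GEI_attachment + c)/(GEI_attack + c) with
pseudocount c = 0.1 (smallest category boundary / 7), keeping ">400-fold"
style ratios finite for genes silent in one phase; gene-set fold changes
are arithmetic means of per-gene ratios by default (a geometric option
exists). Reads are attributed to ORFs by span midpoint; coverage ignores
strand (library strandedness is treated as unknown).

## qPCR

Replicate Cts are averaged first; ΔCt = Ct_gene − Ct_ref within a sample;
ΔΔCt subtracts the calibrator's ΔCt; relative abundance is 2^(−ΔΔCt) with
amplification efficiency fixed at 2. A plate-wide Ct shift on any sample
cancels exactly. Agreement with expression estimates is OLS on
log10–log10 axes, reporting R²; non-positive values and constant
predictors are rejected rather than silently dropped.

## Synthetic data generator

The generator emulates the study design the pipeline targets, and its
defaults are the study conditions:

- **Genome**: circular, default GC 54.7%, two replichores with ±0.05
  per-window GC skew (a realistic bacterial amplitude) meeting at ori
  (position 1) and ter (length/2); CDS genes of 900 bp tiled at 100 bp
  spacing (~90% coding); one 4.5 kb rRNA operon.
- **Islands**: lengths drawn from 11–28 kb; composition from a base model
  exponentially tilted toward G+C until the implied trinucleotide
  distribution sits at the requested total-variation distance (default
  0.3) from the background; a ~75 bp tRNA at the left boundary and an
  integrase CDS inside with probability 7/9 (a typical observed share of
  integrase-bearing ICEs).
- **Repeats**: exact (or near-exact) copies whose flanks are insulated
  with a run of forced-mismatch columns wide enough (⌈0.031·L⌉+2) that no
  ungapped extension at ≥97% identity can cross, so planted extents are
  recoverable exactly.
- **Expression**: exactly 80% of genes transcribed in attachment and
  33.4% in attack; transcribed genes draw GEI from a lognormal
  (log₁₀ GEI ~ N(0.9, 0.45), truncated ≥0.95) spanning the low/medium/high
  range; silent genes sit in [0, 0.45], below the 0.7 threshold with
  margin; a 10-gene "sec" set planted at exactly 17-fold
  attachment/attack, and a porin-like gene silent in attack and high in
  attachment (pseudocounted ratio > 400).
- **Coverage**: per-position depth ~ Poisson(GEI·depth_factor) in genes
  and Poisson(0.7·depth_factor) intergenic (positions are independent; no
  overdispersion in v1 — real RNA-seq coverage is locally correlated and
  overdispersed, so recovery rates here are an upper bound on real-data
  behavior). Residual rRNA reads (default 5%) and unmappable prey reads
  (defaults 40% attachment / 4% attack, matching the mapped-read fractions
  such libraries show) inflate the read counters only: prey reads never
  touch depth, mirroring unambiguous-mapping bookkeeping. With SAM
  emission the track is realized as 50 bp reads whose pileup is returned,
  so re-quantifying the SAM reproduces the track bit-exactly (read starts
  are not placed in the final read-length−1 positions, slightly thinning
  coverage at the linearized end).
- **Ct tables**: calibrator Cts uniform in [22,28], sample Ct lowered by
  log₂(fold), reference gene at Ct 18, Gaussian replicate noise. The noise
  level targeting a given log–log R² is computed analytically: per-gene
  averaged ΔΔCt noise variance is 2σ²/n_replicates (reference-gene noise
  shifts all genes alike and is absorbed by the intercept), and
  R² = v_signal/(v_signal+v_noise) is solved for σ.

Problem sizes used by the test suite and acceptance script — 500 kb
genomes for island calling (20 seeds), ~200-gene genomes at depth factor 2
for expression recovery (20 seeds), sequences ≤300 bp for the exhaustive
repeat oracle (50 seeds), 100 seeds for the qPCR noise grid — were chosen
to exercise each stage at full statistical fidelity while keeping any
single run in the tens of seconds.

## Statistical conventions in the tests

The i.i.d.-genome calibration check (observed window scores vs the shuffle
null) runs a Mann-Whitney test per seed and combines the 20 p-values with
Fisher's method at α = 0.01, additionally bounding per-seed rejections by
the binomial expectation; requiring every individual test to be
non-significant would fail ~18% of the time under a true null, which is a
property of multiplicity, not of the scanner.
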