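# Methods

## Model and pipeline

`tescope` treats each TE family as a single consensus sequence and interprets
the read alignments against it as draws from the population of that family's
copies. The pipeline is: optional quality filtering → local alignment →
per-read HSP chaining → per-position profiling → normalization/abundance →
plotting. All internal coordinates are 0-based half-open; every user-facing
table and plot coordinate is 1-based inclusive (matching SAM/GFF conventions).

### Quality filtering

FASTQ reads are 3'-trimmed at quality < 15, then dropped if shorter than
50 bp or with mean quality < 15 (all three thresholds are flags). FASTA input
(e.g. Sanger reads without qualities) bypasses the filter. These defaults are
deliberately mild: aggressive filtering would distort the coverage on which
every downstream estimate rests.

### Alignment contract

Reads are aligned with `bwa bwasw` at default scoring. The contract is
deliberately thin: downstream code consumes plain SAM/BAM and uses only
standard flags, MAPQ and CIGAR, so alignments from any local aligner can be
substituted. One read may appear as several records (HSPs); records whose
CIGAR contains a deletion of ≥ 30 bp are split into separate HSPs on ingest,
making the "one record with a long D" and "two split records" encodings of a
junction equivalent. Records with inconsistent CIGAR/sequence lengths are
counted and skipped, never silently dropped. An HSP is *ambiguous* iff
MAPQ < 1 — MAPQ 0 is the aligner-portable multi-mapping signal.

We examined more permissive scoring (lower mismatch penalty and alignment
threshold), which extends divergence sensitivity at 100 bp, but kept the
aligner's defaults: they already support the operating range documented below
and introduce no package-specific behaviour.

### Chaining

For each read, all non-empty subsets of its HSPs are enumerated (up to 10
HSPs; beyond that a greedy longest-first chain plus all singletons is used and
the chain is flagged). A subset is *consistent* iff all HSPs share one contig
and strand, consecutive HSPs (in read order) overlap by ≤ 15 bp on the read,
leave ≤ 20 bp of the read unaligned between them, and are colinear on the
reference (ascending for +, descending for −; no contained intervals).
Inversions, tandem duplications and inter-family chimeras are therefore
rejected by construction. Among consistent subsets the one aligning the
largest fraction of the read wins; ties break by fewest HSPs, smallest
leftmost reference start, longest first HSP, and finally the full coordinate
tuple, making the order total and the result deterministic. Reference gaps of
≥ 30 bp between consecutive HSPs of the winning chain become internal-deletion
junctions; smaller gaps are treated as aligner slack. The 20/15/30 bp bounds
are flags; 30 bp matches the aligner's own minimum sub-alignment length.

### Profiling

Per consensus position the profile accumulates base counts (A/C/G/T) from all
aligned HSP bases, a separate unambiguous-only count layer, physical coverage
(+1 across each junction's skipped interval), and short-indel counts at their
anchor positions. SNP calls use the unambiguous layer only, so multi-mapping
reads cannot create phantom SNPs (flag-switchable): a site is *fixed* when one
non-reference base reaches frequency ≥ 0.95, *segregating* when a
non-reference base has count ≥ 2, frequency ≥ 0.1, and the reference allele
is still above 0.05. Divergence is the mean over covered positions of
(1 − reference-base fraction); it is undefined (not zero) for uncovered
families.

### Internal deletions and the detection correction

A local aligner only reports sub-alignments of ≥ m bp (m = 30 for bwa-sw), so
of the L placements of a junction within a read of length L, only those with
both flanks ≥ m — i.e. L − 2m + 1 — are visible:

    p(L) = (L − 2m + 1) / L         (L > 2m)

Junctions agreeing within ±5 bp on both breakpoints are merged at the modal
breakpoints. Each junction read contributes 1/p(L_read) to the corrected
count, using its own length (so mixed-length data are handled per read); when
all reads are ≤ 2m the call is reported with raw counts and flagged
uncorrected. Two frequency estimates are reported:

* the **naive** estimate, raw junction reads / mean base coverage across the
  gap. Its expectation is f·p/(1 − f) for true frequency f: it
  *underestimates* for short reads (p = 0.41 at 100 bp) and *overestimates*
  for long reads (p = 0.941 at 1000 bp) — the characteristic read-length bias;
* the **corrected** estimate, corrected count / (corrected count + mean gap
  base coverage), a per-copy proportion with expectation f. The denominator
  choice makes frequency a proportion of copies and is validated by the
  frequency-recovery experiments (regression slope vs truth within [0.9, 1.1]
  across read lengths 100/300/1000 and frequencies 0.1–0.9).

The analytic p assumes the aligner's m; `tescope calibrate` re-estimates p by
simulation for aligners with a different minimum segment.

### Terminal truncations

A chain whose reference-left end sits at an internal consensus position
(> 10 bp from the consensus start) with ≥ 30 bp of unexplained soft clip is
evidence for copies missing the consensus 5' of that position (mirrored for
the right side). Clips explained by another HSP of the same read (on any
contig) are discarded; anchors cluster with the same ±5 bp tolerance as
deletions. Calls report the first/last retained base, 1-based.

### Abundance

With single-copy genes in the library, Î (insertions per haploid genome) =
mean total TE coverage / pooled mean gene base coverage. Genes pool
position-weighted — the pooled value equals the mean depth of the concatenated
single-copy fraction — with per-gene diagnostics emitted for outlier
detection. Total TE coverage uses base coverage plus *detection-corrected*
physical coverage (each junction read weighted 1/p), so deleted copies
contribute their full coverage share; the uncorrected physical layer is what
the table stores. A `--robust` flag switches means to 5%-trimmed means.
Per-million normalization scales all coverage-like fields (including base
counts, so frequencies are invariant) by 10⁶ / mapped reads, counting reads
with ≥ 1 retained chain over all contigs; per-million and gene normalization
are never combined, and Î is invariant under per-million pre-scaling.

## The simulator

`tescope.sim` emulates a TE landscape: per haploid genome a uniform-random
(hence non-repetitive) background receives one or more TE copies and
optionally single-copy genes, with insertion points re-drawn until pairwise
separation exceeds the read length (so no read straddles two elements). Each
copy carries independent per-base substitutions at the configured divergence;
internal deletions, truncations and planted SNPs are assigned to exactly
round(frequency × copies) carriers, so manifest frequencies are exact rather
than binomial draws. Reads are sampled uniformly per genome with
round(C·(len − L + 1)/L) reads, giving interior positions (where all planted
elements sit) expected depth exactly C. Substitution read errors are explicit
(qualities constant Q40); indel errors are per-base single-base events.

`emit_truth_alignments` writes SAM records straight from the manifest with
exact CIGARs (M runs, D runs for deletions, soft clips for background
overhang), applying the m = 30 minimum-segment rule so that junction reads
with off-centre breakpoints lose their junction exactly as a local aligner
would. This gives deterministic, aligner-free fixtures on which coverage
recovery is exact.

What the simulator does **not** emulate: sequencing-quality profiles and GC
bias, transition/transversion bias (substitutions are uniform over the three
alternatives), nested/recursive insertions, and real genomic backgrounds with
low-complexity or repetitive sequence. Passing tests therefore demonstrate
correctness of the estimators under idealized sampling, not robustness to
library-preparation artefacts or to repeat-rich flanks.

## Validation experiments and their designs

All experiments live in `tescope.validation` and are re-run from scratch by
`scripts/acceptance.py` (~90 simulate-and-align cycles, a few minutes on one
CPU). Problem sizes: 3 kb consensus, 50× depth for divergence/coverage
experiments, 20-genome pools for frequency experiments.

* **Divergence recovery** sweeps 1–25% (1% grid) per read length on
  single-haplotype landscapes (one genome, one copy) and reports the largest
  grid value up to which the estimate stays within 10% relative error of the
  realized (manifest) divergence. Single-haplotype landscapes are the design
  of record because with one haplotype every read covering a substituted
  position carries the substitution, so the frequency-based estimator
  degrades only when positions lose coverage entirely — the read-length
  accuracy cliffs (≈15% at 100 bp, ≈18% at 150 bp, ≈22% at 1000 bp) emerge
  from the aligner, not from mixture effects.
* **Coverage error under read errors**: reads drawn from the TE template with
  10% per-base mismatches, mean total coverage evaluated over interior
  positions (≥ L − 1 from the template ends, where simulated depth is exactly
  50×) and averaged over replicates, isolating aligner-induced loss from
  sampling noise. Long reads lose ~1%; 100 bp reads lose several percent to
  score-threshold censoring plus end trimming.
* **Allele-frequency recovery**: two TE haplotypes differing by one planted
  SNP mixed at frequencies 0.05–0.95 (0.05 grid) among 20 haploid genomes,
  with 5% background divergence per copy. Pooled coverage is 500× so that the
  binomial sampling floor (var ≈ f(1−f)/coverage) consumes under half the
  residual budget implied by the adjusted-r² criteria; at 50× the floor alone
  caps adjusted r² near 0.95 regardless of estimator quality.
* **Deletion-frequency correction**: truth-alignment landscapes per
  (read length, frequency) pair; the naive estimator shows its sign-definite
  biases on f ∈ [0.1, 0.5] (below/above truth at 100/1000 bp respectively —
  outside that range the short-read naive ratio changes sign), while the
  corrected estimator's regression slope against truth stays within [0.9, 1.1]
  over the full 0.1–0.9 grid.
* **Copy-number recovery**: one copy per haploid genome, half carrying a
  600 bp deletion (20% of the consensus, so deleted coverage fraction 10%).
  The base-only estimator underestimates Î by ≈ that fraction; the
  total-coverage estimator recovers 1.0.

## Real-data protocol (external)

The published P-element invasion pools (experimentally evolving *D. simulans*
populations, sequenced as pools every 10 generations) reproduce with:
download the generation-0 and generation-60 pool FASTQ files, build a library
FASTA containing the P-element consensus (PPI251) plus *rpl32*, place them
under `data/pelement/` as `G0.fastq`, `G60.fastq`, `library.fasta`, and run
`tescope run G0.fastq G60.fastq --library library.fasta --gene rpl32
--norm per-million`. Expected: Î ≈ 0.95 at G0 rising to ≈ 15.8 at G60, and
the diagnostic segregating SNP at P-element position 2040. This protocol
needs external downloads and is exercised by
`tests/test_acceptance.py::TestPElementInvasionProtocol`, which fails with
instructions when the data are absent.

## Numerical choices and limitations

* Frequencies divide by the relevant coverage with zero-coverage positions
  reported as absent calls, never as zeros masquerading as estimates.
* Composition tables serialize floats with `repr`, so write → read round-trips
  are bit-exact; the table is the single source for plotting (a re-read table
  renders byte-identically to in-memory results).
* Breakpoint clustering tolerance (±5 bp) trades resolution against junction
  jitter from aligner tie-breaking; recurrent deletions closer than the
  tolerance merge.
* Arc width in plots is linear in corrected junction support (capped);
  truncation-line opacity is linear in frequency clamped to [0.15, 1] so rare
  events remain visible.
* Known limitations: no inversions/duplications/chimeras (rejected as
  inconsistent chains); no genomic insertion positions (there is no assembly);
  families more diverged than the read-length-dependent limits above are
  underestimated; very short reads (≤ 60 bp at m = 30) cannot evidence
  internal deletions at all and are reported uncorrected with a warning.
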