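# Methods

This note documents the models implemented in `somaticscan`, the choices
made where the method descriptions left details open, what the simulator
does and does not emulate, and the known limitations.

## SNV detection

### Model

A pileup column holds, per strand, the called bases and phred qualities
covering one locus. Calling proceeds per strand:

1. **Trimming.** Bases with quality 0 are removed before any comparison.
2. **Error rate.** The strand's miscall probability is the mean of
   `10^(−Q/10)` over its remaining bases. Using a per-locus-per-strand mean
   (rather than per-read weights) keeps the statistic a plain distance
   between two distributions and makes it exactly reproducible by
   enumeration; per-read weighting was considered and rejected for
   testability.
3. **Expected distributions.** For each of the 10 unordered diploid
   genotypes `{a₁,a₂}` over {A,C,G,T}, the expected base distribution is
   `q(b) = Σ_a ½·[(1−e) if b=a else e/3]` — each allele contributes half
   the mass, spread uniformly over the three other bases at the error rate.
4. **Distance.** `D = max |cum(p̂) − cum(q)|` over the fixed base order
   A < C < G < T — a Kolmogorov–Smirnov statistic on the discrete base
   alphabet. `D` is symmetric, lies in [0,1], and is 0 iff the
   distributions coincide. The order is a convention; it is fixed and
   documented so results are deterministic.
5. **Combination.** The per-strand best genotype minimises `D`; the
   combined call minimises the *maximum* over strands, so a variant must
   be supported by both strands. A non-reference combined call is demoted
   to `ambiguous` unless every participating strand's own best genotype
   contains the same non-reference allele(s). Argmin ties prefer fewer
   non-reference alleles, then lexicographic order — deterministic output.

### Somatic workflow

Tumor loci are screened with a sensitive **variant consensus** rule: the
most frequent non-reference allele must have at least
`consensus_min_alt_per_strand` supporting reads on each strand and a pooled
fraction of at least `consensus_min_alt_fraction`. The matched normal must
be a **high-quality homozygous-reference** call: genotype ref/ref, callable,
combined distance ≤ `hq_d_max`, depth ≥ `hq_min_depth`, pooled non-reference
fraction ≤ `hq_max_alt_fraction`. A site passing both gates is somatic.

Two profiles bundle the thresholds:

| parameter | strict | lenient |
|---|---|---|
| min_depth_total | 10 | 6 |
| min_depth_strand | 3 | 2 |
| d_max | 0.10 | 0.20 |
| consensus_min_alt_per_strand | 3 | 2 |
| consensus_min_alt_fraction | 0.10 | 0.05 |

with shared high-quality-normal gates `hq_min_depth = 8`, `hq_d_max = 0.05`,
`hq_max_alt_fraction = 0.02`. The numeric values are this package's own
calibration (the *roles* of the thresholds are part of the method); all are
configurable, and strict is uniformly no looser than lenient, so every
strict call is also a lenient call. Running `profile="both"` records
per-call provenance (`strict`/`lenient`/`both`) in the VCF in lieu of a
manual review step; the KS distances are emitted as machine-readable
confidence values for the same reason.

Ambiguous bases and deletion placeholders are dropped when pileups are read
from SAM. For genome-scale scans a vectorised pre-screen applies the
consensus rule to per-locus count arrays and only materialises full pileup
columns at candidate loci; the per-column code path and the vectorised
screen implement the identical rule.

## Copy-number scanning

**Physical coverage**: for each proper pair with mate on the same
chromosome and outer insert in `(0, mean + 3·SD]`, every base of
`[start, start + insert)` is incremented. The insert model is the plain
sample mean/SD (ddof = 1) over proper-pair inserts, untrimmed. Spans past
the chromosome end are clipped with a warning.

**Windows**: 2 kb wide at a 1 kb step. The step is a choice — the window
width sets the resolution, the half-window step smooths segment
boundaries; both are configurable. Trailing partial windows are dropped
rather than rescaled so every window statistic has the same variance.

**Normalisation**: each sample's window values are divided by the
genome-wide median of its positive window values. The median is robust to
focal events and cancels tumor/normal depth differences. Whether zero
windows are replaced before or after normalisation was an open choice;
replacement (by `zero_replacement = 1`) happens on the raw window means
*before* normalisation, which reproduces a finite floor near −3 at typical
sequencing depths — the floor is depth-dependent, not a hard constant, and
deeper data push it lower.

**Masking**: windows with `log2(normal normalised) > 3` are masked as
high-repeat (centromere-like pileups) and carry no ratio. Masked windows
are exactly the windows over the threshold — nothing else is masked.

**Segmentation**: maximal runs of consecutive unmasked windows with
`log2 ≥ +1` (gain) or `≤ −1` (loss) merge into segments carrying the mean
log2 of their member windows. No change-point model is used; at a true
single-copy-gain level of log2 ≈ 1 the ±1.0 threshold sits in the middle of
the sampling noise, so a long gain is typically reported as several
shorter segments at the correct level rather than one span. The threshold
is deliberately conservative and should be lowered for low-cellularity
tumors, where the signal is compressed toward 0.

## Somatic indels

Step 1 removes tumor reads whose |outer insert| lies outside **[50, 500] bp**
(bounds inclusive: "outside the interval" is read as < 50 or > 500).
Candidates are then exact-match groups of gapped alignment operations —
identical (chrom, start, type, length, sequence) — with ≥ 3 supporting
reads. This grouping is the package's stand-in for an external candidate
generator; an externally produced candidate list can be fed to the region
test directly.

Step 2 examines the normal sample over the candidate's footprint extended
5 bp upstream and 5 bp downstream. The test uses *raw gapped reads* (not
re-called indels): if any normal read carries an indel operation
intersecting the region the candidate is `germline_or_artifact`; if the
region is clean but fewer than 8 normal reads overlap it the candidate is
`low_normal_coverage` (reported but excluded from the somatic set — an
uncovered normal cannot certify a somatic event); otherwise it is
`somatic`. The flanked region is intersected with chromosome bounds at
contig ends. No left-normalisation of equivalent indels is attempted
beyond exact-match grouping, and events longer than the read scale are out
of scope.

## Translocations

Non-overlapping 2 kb windows (non-overlapping because the outlier model
treats window proportions as independent draws) count, per window: all
aligned reads (individual reads, not pairs — the denominator convention is
documented here because it is ambiguous in prose descriptions of such
methods), reads whose mapped mate lies on a different chromosome, and a
histogram of mate chromosomes. The modal mate chromosome is the *highest
hit* (ties break to reference header order), and the statistic is
`hit reads / total reads`.

Per chromosome (scope configurable to genome-wide), the cutoff is
`mean + 3·SD` over window proportions, sample SD (ddof = 1) so small scopes
are stable and the arithmetic is exactly reproducible. A window is flagged
when its proportion strictly exceeds the cutoff *and* carries at least 5
hit reads; the support floor replaces manual inspection of low-depth
windows (a pure proportion test flags nearly empty windows), and a z-score
is emitted with every call. Breakpoint regions are the spans of the hit
reads' positions and their mates' positions; adjacent flagged windows with
the same highest hit merge, and the two reciprocal views of one junction
(A-side windows pointing at B, B-side windows pointing at A) are collapsed
into a single call, keeping the better-supported orientation.

Somatic filtering calls tumor and normal separately and removes tumor
calls whose regions, padded by 1 kb, overlap any normal call's regions on
the same chromosome. Only interchromosomal events are considered.

## The simulator

The simulator generates the statistical structure the detectors assume —
and nothing more:

* uniform fragment placement per chromosome at the configured mean
  sequence depth (no GC or mappability bias, because the detectors do not
  model bias);
* outer inserts from a normal distribution truncated at 2× read length
  (mean 300 bp, SD 50 bp by default), so mates never overlap and the
  CNV insert gate is exercised;
* FR read pairs of fixed 100 bp length; no FASTQ, no realignment, no
  mapping ambiguity;
* germline variants in both samples at genotype allele fraction (0.5 het /
  1.0 hom); somatic variants in the tumor only, carried per fragment with
  probability `VAF × cellularity` — the purity dilution the SNV benchmark
  measures. Defaults emulate a biopsy in the 30–60% cellularity range;
* copy-number segments multiply tumor fragment density by the configured
  ratio, which is therefore the *effective* (purity-folded) density ratio;
  ratio 0 removes every tumor fragment whose span overlaps the segment.
  Coverage hotspots multiply density in both samples to stand in for
  high-repeat regions and exercise the masking rule;
* translocations emit `0.5 × depth` discordant pairs per junction with
  reads within ~500 bp of each breakpoint; a 0.1% background of randomly
  placed chimeric pairs emulates library chimeras and keeps the outlier
  null non-degenerate;
* base qualities per base from Normal(33, 3) clipped to [2, 41] — a
  realistic short-read quality profile — with 1% of bases forced to
  quality 0 (and randomised identity) so the trimming rule has work to do;
  miscalls are injected at each base's own `10^(-Q/10)`.

A single seed drives named substreams per (sample, stage, chromosome), so
identical configurations are byte-identical and each stage is reproducible
in isolation. Reads that carry an indel operation leave the reference
coordinate grid after the event; they are excluded from SNV pileup
aggregation (their indel evidence is what the indel detector consumes).
Truth is emitted as VCF v4.2 (SNVs and indels, with origin and VAF in
INFO), BED (CNV segments, 0-based half-open) and BEDPE (translocations);
internal coordinates are 0-based half-open, VCF and the pileup TSV are
1-based.

Because the generator contains no error-context models, no subclonal
structure and no alignment artifacts, passing benchmarks here demonstrates
that the detector logic implements its rules correctly and recovers events
under its own model assumptions — not that the thresholds are optimal for
real libraries, where artifact modes the simulator omits (strand bias,
indel-adjacent mismatches, mapping errors in repeats) dominate false calls.

## Benchmark problem sizes

The packaged benchmarks run megabase-scale genomes so the whole evaluation
completes in minutes on one CPU while keeping window statistics and allele
fractions stable: SNV recovery on 2 × 2 Mb at 40×/40× and cellularity 0.6
(100 somatic SNVs, VAF uniform on [0.3, 1], 200 germline hets); CNV levels
on 2 × 1 Mb at 40× (100 kb gain at ratio 2, 50 kb homozygous deletion,
20 kb ×12 hotspot); indels on 1 Mb at 40× (24 somatic events of 1–10 bp);
translocations on 3 × 1 Mb at 40× (two somatic junctions, one germline),
with the null behaviour measured over 20 replicates of a spike-free 2 ×
400 kb genome at 10×. Sites for the SNV and indel scenarios are placed
away from chromosome ends and from each other; the compact end-to-end
scenario additionally keeps SNV sites out of its homozygous deletion,
since a site with no tumor DNA is undetectable by construction.

## Degenerate inputs and numerical conventions

* Empty strand → the error rate is undefined and raised as an error; a
  column with no eligible strand is `low_depth`.
* All-zero coverage in a sample → normalisation error (nothing to scale by).
* SD = 0 in the translocation cutoff → cutoff equals the mean and only
  strictly greater proportions can flag, so uniform scopes yield no calls;
  scopes with fewer than two windows yield none either.
* Distribution validity is checked to 1e-6 on input; KS oracle agreement is
  asserted to 1e-12 in the tests.
* Damaging-fraction percentages round half away from zero.
* Insert spans and flanked regions are clipped at chromosome bounds.

## Limitations

* Diploid model only; no multi-sample joint calling, no base-quality
  recalibration, no annotation or effect prediction.
* CNV: no GC/mappability correction, no HMM/CBS segmentation, no
  allele-specific copy number, no purity/ploidy deconvolution — at 30%
  cellularity a single-copy change is ~0.35 in log2 and falls below the
  default call threshold.
* Indels: exact-match candidate grouping does not merge alignment-shifted
  representations of the same event.
* Translocations: breakpoint regions are read-span resolution (no split
  reads or assembly), and mate spans can be inflated by unrelated chimeric
  reads falling in a flagged window.
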