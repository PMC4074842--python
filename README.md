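# somaticscan

Somatic alteration detection in matched tumor/normal whole-genome
sequencing, built as a single reusable pipeline with four detectors and a
read simulator that knows its own ground truth:

* **SNVs** — a per-strand pileup genotyper based on a Kolmogorov–Smirnov-style
  statistic, with a matched-normal somatic subtraction workflow;
* **CNVs** — a 2 kb sliding-window scanner of *physical* coverage (insert
  spans, not read bases) reporting tumor/normal log2 ratios;
* **indels** — a two-step somatic filter: insert-size read filtering, then a
  ±5 bp region test against the matched normal;
* **translocations** — interchromosomal discordant-read-pair outlier
  detection with per-chromosome mean + 3 SD cutoffs and normal subtraction.

It is aimed at method developers and teaching settings: every detector can
be exercised end to end on simulated matched samples with spiked events
(germline/somatic SNVs and indels, copy-number gains and homozygous
deletions, translocations, tumor cellularity dilution), and scored against
the simulator's truth set — no patient data required.

## The statistics in brief

**SNV genotyping.** At a locus, each strand's quality-trimmed pileup gives
an empirical base distribution `p̂`. For a diploid genotype `g = {a₁, a₂}`
and strand error rate `e = mean(10^(−Q/10))`, the expected distribution is

    q_g(b) = Σ_{a ∈ g} ½ · [(1 − e) if b = a else e/3]

and the test statistic is the KS-style distance
`D(p̂, q_g) = max_b |cum(p̂) − cum(q_g)|` over the fixed order A < C < G < T.
The per-strand best genotype minimises `D`; the combined call minimises the
worse strand's distance, so **both strands must support a variant**. A site
is somatic when the tumor passes a variant-consensus screen (≥ k alt reads
on *each* strand plus a pooled alt-fraction floor) while the normal is a
high-quality homozygous-reference call. Strict and lenient threshold
profiles can run side by side with per-call provenance.

**Copy number.** Each accepted proper pair (outer insert ≤ mean + 3 SD)
increments every base under its insert span. Window means (2 kb window,
1 kb step) are normalised per sample by the genome-wide median; the
reported statistic is `log2(tumor/normal)`. Windows whose germline
normalised coverage exceeds `2³` are masked as high-repeat; zero window
coverages are replaced by 1 before normalisation so homozygous deletions
stay finite. Runs of windows with `|log2| ≥ 1` become gain/loss segments.

**Indels.** Tumor reads with outer insert outside [50, 500] bp are removed;
identical gapped alignment operations are grouped into candidates (≥ 3
reads); a candidate is somatic only if no normal read carries an indel
intersecting the candidate ± 5 bp and the normal covers that region.

**Translocations.** Non-overlapping 2 kb windows count reads whose mates
map to another chromosome; the modal mate chromosome is the *highest hit*.
Windows whose hit-discordant proportion exceeds the chromosome's
mean + 3 SD (and carry ≥ 5 hit reads) become calls whose breakpoint regions
are the spans of the hit reads and of their mates; calls overlapping a
normal-sample call (± 1 kb) are eliminated as germline.

## Worked example

Simulate a small matched pair (two 60 kb chromosomes, 40×, cellularity 0.6)
with one somatic SNV and one somatic 3 bp deletion, then call both:

```bash
$ somaticscan simulate --config cfg.yaml --out sim/
simulated 48000 normal / 48000 tumor reads

$ somaticscan snv --normal sim/normal.sam --tumor sim/tumor.sam \
      --ref sim/reference.fa --profile both --out snv.vcf
1 somatic SNVs -> snv.vcf

$ grep -v "^#" snv.vcf
chr1  30001  .  A  C  .  PASS  SOMATIC;PROFILE=both;NKS=0.0006  DP:ADF:ADR:DPF:DPR  41:8:5:21:20

$ somaticscan indel --normal sim/normal.sam --tumor sim/tumor.sam --out indels.vcf
1 candidates (1 somatic) -> indels.vcf
```

Reading the SNV record: the spiked A→C variant at chr1:30001 was called
under **both** the strict and lenient profiles; the tumor column had depth
41 (21 forward / 20 reverse) with 8 and 5 alt reads per strand — an
observed alt fraction of 0.32, consistent with VAF 0.5 at cellularity 0.6 —
and the matched normal's KS distance from homozygous reference was 0.0006,
i.e. a clean normal. A self-contained run of all four detectors plus
truth-set evaluation is `somaticscan run --config cfg.yaml` (see
`tests/test_pipeline.py` for a config template).

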