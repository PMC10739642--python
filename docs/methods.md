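# Methods

This note documents the models, conventions and deliberate choices behind
`meriptools`: what each stage assumes, which parameters matter, what the
synthetic generator does and does not emulate, and where the design was
genuinely open.

## The measurement model

MeRIP-seq compares an antibody-enriched library (IP) against a matched
unenriched library (input) from the same fragmented RNA. Fragments carrying
m6A are over-represented in the IP; everything else appears at a
nonspecific background rate. All downstream statistics treat the input as
the expression/background reference and the IP/input contrast as the
methylation signal. The package starts from *aligned fragments* (BED12
intervals with exonic blocks); read QC, alignment, multi-mapper and rRNA
filtering are upstream concerns and out of scope.

## Peak calling

- **Candidate unit.** The 10-bp bin of the coverage grid, not per-base
  pileup. At fragment lengths near 150 bp this loses no localization and
  keeps the caller deterministic and fast. The per-bin statistic is the
  *fragment-overlap count*: the number of fragments whose exonic blocks
  touch the bin (a fragment counts once per bin even when two blocks fall
  in the same bin).
- **Local background.** The expected IP count in a bin is estimated from
  the input as the maximum of a genome-wide rate
  `lambda_BG = depth_ratio × Σ_b count_b / (G / bin_width)` and centred
  sliding means of the input count track over several window sizes, all
  scaled by `depth_ratio = N_IP / N_input`. Windows span `2*(w/bin/2)+1`
  bins and are renormalized at chromosome edges (they are never diluted by
  out-of-genome zeros — important for short spike-in contigs).
- **Window sizes.** 1 kb, 5 kb and 10 kb capture transcript- and
  region-scale background, plus a 50-bp near-point window (`d_window`)
  that floors lambda at the local control coverage itself. The near-point
  term is what makes the caller's null contract structural: a library
  tested against itself (or a replicate of itself) can never appear
  self-enriched, because the expected count tracks the observed count.
  Disabling it (`d_window=0`) reverts to purely regional backgrounds.
- **Testing and merging.** `p_b = P(Poisson(lambda_local) ≥ k_b)` computed
  with scipy's survival function (stable for lambda up to at least 1e4);
  Benjamini–Hochberg across *bins with nonzero pileup only* — all-zero bins
  carry no evidence and would only dilute the FDR denominator. Significant
  bins (`q < q_cutoff`, default 0.05) merge when their gap is ≤ 100 bp;
  merged intervals shorter than 150 bp (≈ one sonicated fragment) are
  dropped. The peak's p/q come from its minimum-p bin; the summit is the
  centre of the maximum-pileup bin, leftmost on ties; fold enrichment is
  summit pileup over its lambda. One summit per peak — no sub-peak
  deconvolution.
- **Effective genome size** `G` defaults to the summed length of the
  chromosomes actually present; analyses of real genomes should pass the
  mappable-transcriptome size appropriate to the organism.
- **Duplicates** are collapsed once, before calling (identical
  chrom/start/end/strand/blocks), never inside the caller.
- **Direction asymmetry.** With strong IP enrichment, the off-site portion
  of the IP library is genuinely depleted relative to input; swapping IP
  and input therefore detects that complement as enriched intervals. The
  meaningful asymmetry is that forward peaks localize methylation (high
  precision against planted truth) while swapped peaks do not — that is
  the property the test suite asserts.

## Signal, abundance, correlation, PCA

- m6A signal per bin: `log2((IP RPKM + 1)/(input RPKM + 1))`; RPKM is
  `count / (bin_kb × fragments_in_millions)`.
- TPM assigns each input fragment to the transcript containing its genomic
  midpoint (largest exonic overlap wins among several, then lexicographic
  id), normalizes counts by exonic kb and rescales rates to sum to 1e6.
- Correlation and PCA aggregate tracks to 1-kb windows restricted to the
  exon union of all annotated transcripts (a window's value is the mean of
  its exonic bins; windows without exonic bins are excluded). Windows that
  are zero in every sample are dropped before Pearson r; a zero-variance
  track yields missing correlations rather than a crash. PCA centres
  features, takes the top-2 singular directions, and fixes signs so the
  largest-magnitude loading is positive — coordinates are reproducible
  across runs and BLAS builds.

## Annotation and metagene

- Feature priority: stop codon, 3'UTR, 5'UTR, CDS, exon, intron,
  intergenic. The stop-codon window is *genomic* ±200 bp around the
  annotated stop, so bases beyond the transcript 3' end still count.
  Noncoding exons fall through to the `exon` class.
- Expected counts for the enrichment score are proportional to
  priority-masked feature length: every genomic base is painted with the
  single class that would claim a summit there, so expected fractions sum
  to one. Whether the original analysis used length-based or
  shuffle-based expectations is not derivable; length-based is this
  package's documented convention.
- A gene is m6A-marked when any of its features (not intergenic) holds a
  summit; with replicate support required, the gene must be marked in each
  replicate independently.
- Metagene profiles use each gene's highest-TPM coding isoform (ties:
  longer transcript, then id), position summits fractionally within
  5'UTR/CDS/3'UTR segments mapped to [0,1)/[1,2)/[2,3], and report a
  density normalized to unit area. Summits outside the selected isoforms'
  exons are dropped and counted.

## Motif analysis

RRACH is scanned as DNA (`[AG][AG]AC[ACT]`; U↔T is notation) on the strand
deduced from overlapping transcripts (higher TPM wins two-strand
conflicts; unresolvable summits are excluded). Enrichment is a binomial
upper-tail test of the peak-window hit fraction against the hit rate of
random exonic 400-bp windows scanned on their host-transcript strand —
exonic, not genome-wide, because peaks live in transcribed sequence. This
is a targeted consensus test, not de novo motif discovery.

## Retrotransposons

Loci are kept when ≥ 90% of consensus length and < 50% of their bases are
exon-covered (numerator: locus bases under the exon union). Per-locus
expression and signal are means of the input-RPKM and signal tracks over
overlapping 10-bp bins, averaged arithmetically across replicates; a
subfamily's methylated fraction counts loci with mean signal strictly > 0.
Consensus profiles map genomic bins to consensus coordinates by affine
scaling (minus-strand loci reversed) — an approximation to
alignment-based repeat coordinates, adequate for near-full-length copies.

## qPCR

Input Cts are corrected by `− log2(1/input_fraction)` (no correction at
full input amount); the S/N ratio assumes perfect per-cycle doubling, and
efficiency is deliberately not a parameter. Censored Cts (no
amplification) propagate as errors in ratios and as 0% in titration
recovery; they are never imputed. Titration levels are
`100 × 2^(Ct_norm − Ct_i)` against the 100% mix.

## The synthetic generator

What it emulates, per stage:

- **Genome/annotation** (`generate_annotation`): two 600-kb chromosomes by
  default; ~300 genes with 5'UTR (100–200 bp), CDS (900–1500 bp, multiple
  of 3, stop codon written as TAA), 3'UTR (300–600 bp), 1–3 exons, both
  strands; spike-in contigs (GLuc-like modified, CLuc-like unmodified,
  600 bp) carried as single-exon chromosomes through the whole pipeline;
  retrotransposon loci (default: MTA methylated, L1Md_A unmethylated, 20
  full-length copies each) placed intergenically.
- **Controlled motif density.** Background RRACH occurrences are scrubbed
  from the random sequence (both strands, iteratively) and a defined
  number of candidates injected per gene: 2 stop-proximal (Gaussian offset
  sd 150 bp, truncated at ±400 bp — methylation in this system is sharply
  stop-centred, and the metagene mode is then a property of the signal,
  not of histogram noise) and 2 distal (> 450 bp from the stop), plus
  copies on the modified spike-in and methylated retro loci. Without
  scrubbing, a uniform random genome carries RRACH every ~85 bp and every
  400-bp background window would be motif-positive, leaving the
  enrichment test nothing to measure.
- **Sites** (`plant_m6a_sites`): 200 sites drawn from the candidate pool;
  the stop-proximal count is Binomial(n, 0.7) by default; stoichiometry
  uniform on [0.5, 1.0]. Spike-in sites (stoichiometry 1) and
  methylated-retro sites live in separate registries of the same truth
  object. Multi-condition studies draw disjoint site sets.
- **Fragments** (`simulate_fragments`): per-library 2e5 fragments; unit
  choice proportional to expression × exonic length (expression
  log-normal(0,1); spike-ins at the 80th percentile of gene levels);
  start uniform; length Normal(150, 30) truncated at 30 bp; transcript
  intervals projected through exon blocks, so junction fragments are split
  (BED12 blocks). IP selection is per-fragment Bernoulli with weight
  `max stoichiometry covered × 8` vs background 0.1, renormalized by
  redrawing to the fixed depth — mimicking equimolar library pooling.
- **qPCR** (`simulate_qpcr`): `Ct = intercept − log2(concentration) +
  N(0, sd)`; sd 0 by default; zero concentration censored.
- **Determinism.** All randomness flows from one integer seed through
  named substreams (annotation / sites / expression / fragments / qpcr),
  so each stage is independently reproducible and the full pipeline is
  byte-identical across runs.

What it does **not** emulate: sequencing errors and base qualities,
multi-mapping, rRNA contamination, isoform complexity (one isoform per
gene), fragment GC/length biases, antibody off-target motifs, and overall
coverage sparsity — the simulated exome is covered far more densely than a
mammalian transcriptome at the same read count. Passing tests therefore
demonstrate the pipeline's correctness and calibration under a faithful
but idealized generative model, not performance on real libraries.

## Problem sizes

The test suite and the acceptance script run the default benchmark
(seed 1, ~300 genes over 1.2 Mb, 200 sites, 2e5 fragments/library, two
replicates), a two-condition variant of the same size for PCA, a smaller
study (40 genes, 150 kb, 2e4 fragments) for unit-level checks, a 1e5
fragment draw for the goodness-of-fit test, and 100 Monte-Carlo seeds for
noisy titration. Numerical oracles (Poisson series, naive BH) cover 100
random instances each.

## Known limitations

- The caller has no broad-peak mode and no sub-summit deconvolution;
  adjacent sites closer than the merge gap share one summit (the main
  source of missed recall at default conditions).
- Affine consensus mapping ignores indel structure of real repeat copies.
- The binomial motif test treats background windows as independent; for
  very small peak sets the background rate estimate dominates uncertainty.
- TPM assignment is midpoint-based, not an isoform-resolution EM; with the
  simulator's one-isoform genes this is exact, on real annotation it is a
  simplification.
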