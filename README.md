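# meriptools

Downstream analysis for MeRIP-seq (m6A RNA immunoprecipitation sequencing),
from aligned IP/input fragments to N6-methyladenosine peaks and the
statistics built on them — together with a synthetic-study generator that
plants a known m6A ground truth, so the whole pipeline can be exercised and
scored offline without any sequencing data.

It is aimed at people analyzing antibody-based m6A profiling experiments,
especially low-input/single-cell designs where every quality metric (motif
fraction, replicate overlap, spike-in false discovery, saturation) matters,
and at method developers who need a controlled test bed with planted truth.

## What it computes

**Peak calling.** Fragments are counted per 10-bp bin. The IP pileup
`k_b` in bin *b* is tested against a Poisson local background estimated
from the input library:

```
lambda_local(b) = max( lambda_BG, lambda_50bp(b), lambda_1k(b), lambda_5k(b), lambda_10k(b) ) * (N_IP / N_input)
p_b = P( X >= k_b ),  X ~ Poisson(lambda_local(b))
```

where `lambda_BG` is the genome-wide rate over an effective genome size *G*
and the window terms are centred sliding means of the input count track.
Benjamini–Hochberg correction is applied across all bins with nonzero
pileup; bins with `q < 0.05` are merged (gap ≤ 100 bp), intervals shorter
than 150 bp are dropped, and each peak reports its summit (maximum-pileup
bin), fold enrichment `k/lambda_local`, p and q.

**Signal and abundance.** Per-bin m6A signal is
`log2((IP RPKM + 1) / (input RPKM + 1))`; transcript abundance is TPM from
input fragment counts; sample relationships use Pearson correlation and PCA
of signal over 1-kb exonic windows.

**Annotation.** Each summit gets exactly one feature by priority —
stop codon (±200 bp genomic window), 3'UTR, 5'UTR, CDS, exon, intron,
intergenic — feeding m6A-gene calls, observed/expected feature enrichment
scores `log2(obs/exp)`, and metagene profiles over the rescaled
5'UTR/CDS/3'UTR axis (stop codon at coordinate 2.0).

**Motif.** RRACH (`[AG][AG]AC[ACT]`) is scanned in the 400-bp
strand-resolved window around each summit and compared with random exonic
background windows by a binomial upper-tail test.

**Quality control.** Replicate peak overlap, q-value robustness sweeps
(0.05 … 1e-100 from a single BH pass), downsampling saturation curves,
spike-in (modified GLuc / unmodified CLuc) false-discovery counts,
retrotransposon subfamily methylated fractions, and the MeRIP-qPCR
signal-to-noise ratio
`S/N = 2^(Ct_input_corr(pos) − Ct_IP(pos)) / 2^(Ct_input_corr(neg) − Ct_IP(neg))`
with titration-recovery analysis.

**Simulator.** `SimConfig`/`simulate_study` generate a toy genome with
5'UTR–CDS–3'UTR gene models on both strands, log-normal expression, m6A
sites planted on RRACH motifs with a stop-codon-proximal bias and per-site
stoichiometry, IP fragment selection at `stoichiometry × enrichment` odds
over a nonspecific background, spike-in contigs, retrotransposon loci with
subfamily-specific methylation, and Ct tables from a delta-Ct model. A
`SyntheticTruth` registry records every planted site for scoring.

## Worked example

```python
import meriptools as mt

cfg = mt.SimConfig(seed=1)           # the default benchmark: ~300 genes, 200 sites
study = mt.simulate_study(cfg)

ip = mt.deduplicate(study.get("cond0", 1, "IP"))
inp = mt.deduplicate(study.get("cond0", 1, "input"))
peaks = mt.call_peaks(ip, inp, mt.PeakCallerConfig(), study.annotation.chrom_lengths)
recall, precision = mt.evaluate_peak_calls(peaks, study.truth.all_sites)
print(f"{len(peaks)} peaks; recall {recall:.2f}, precision {precision:.2f}")

tpm = mt.tpm_lookup(mt.transcript_tpm(inp, study.annotation))
motif = mt.motif_enrichment(peaks, study.genome, study.annotation, tpm, seed=0)
print(f"RRACH in {motif.fraction:.0%} of peaks "
      f"(background {motif.background_fraction:.0%}, p = {motif.enrichment_p:.2g})")

profile = mt.metagene(peaks, study.annotation, tpm)
print(f"metagene mode at {profile.modal_coordinate:.2f} (stop codon = 2.0)")

print("spike-in peaks (modified, unmodified):",
      mt.spikein_fdr(peaks, study.truth.spikein_status))
```

prints

```
185 peaks; recall 0.87, precision 1.00
RRACH in 100% of peaks (background 60%, p = 3.3e-37)
metagene mode at 1.95 (stop codon = 2.0)
spike-in peaks (modified, unmodified): (1, 0)
```

i.e. the caller recovers 87% of planted sites with no false peaks, every
peak window carries the consensus motif against a 60% background rate, the
summit density peaks at the stop codon, and only the modified spike-in
contig yields a peak.

The same stages are available from the shell via the `merip` command
(`merip simulate`, `merip callpeaks`, `merip signal`, `merip motif`,
`merip annotate`, `merip metagene`, `merip sweep`, `merip retro`,
`merip qpcr sn`, …); `merip simulate --outdir d` writes FASTA, GTF, BED12
fragments, truth/retro/sample TSVs and a qPCR CSV that the other commands
consume.

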