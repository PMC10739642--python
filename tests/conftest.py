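"""Shared fixtures: one default simulated study (the benchmark conditions)
reused across the suite, a smaller study for cheap unit tests, and a
hand-constructed annotation for feature-assignment arithmetic."""

from __future__ import annotations

import numpy as np
import pytest

import meriptools as mt


@pytest.fixture(scope="session")
def default_cfg() -> mt.SimConfig:
    return mt.SimConfig()  # seed 1, ~300 genes, 200 sites, 8x enrichment


@pytest.fixture(scope="session")
def study(default_cfg) -> mt.StudyData:
    """The default benchmark simulation (two replicates, one condition)."""
    return mt.simulate_study(default_cfg)


@pytest.fixture(scope="session")
def dedup_rep1(study):
    ip = mt.deduplicate(study.get("cond0", 1, "IP"))
    inp = mt.deduplicate(study.get("cond0", 1, "input"))
    return ip, inp


@pytest.fixture(scope="session")
def dedup_rep2(study):
    ip = mt.deduplicate(study.get("cond0", 2, "IP"))
    inp = mt.deduplicate(study.get("cond0", 2, "input"))
    return ip, inp


@pytest.fixture(scope="session")
def called_peaks(study, dedup_rep1):
    ip, inp = dedup_rep1
    return mt.call_peaks(ip, inp, mt.PeakCallerConfig(), study.annotation.chrom_lengths)


@pytest.fixture(scope="session")
def called_peaks_rep2(study, dedup_rep2):
    ip, inp = dedup_rep2
    return mt.call_peaks(ip, inp, mt.PeakCallerConfig(), study.annotation.chrom_lengths)


@pytest.fixture(scope="session")
def rep1_tpm(study, dedup_rep1):
    return mt.tpm_lookup(mt.transcript_tpm(dedup_rep1[1], study.annotation))


@pytest.fixture(scope="session")
def sweep_table(study, dedup_rep1, called_peaks_rep2, rep1_tpm):
    ip, inp = dedup_rep1
    return mt.qvalue_sweep(
        ip, inp, called_peaks_rep2, None, study.genome, study.annotation,
        rep1_tpm, mt.PeakCallerConfig(), study.annotation.chrom_lengths,
    )


@pytest.fixture(scope="session")
def tiny_cfg() -> mt.SimConfig:
    return mt.SimConfig(
        n_genes=40,
        chrom_length_bp=150_000,
        n_m6a_sites=30,
        n_fragments_per_sample=20_000,
        retro_subfamilies=[("MTA", 500, 5, True), ("L1Md_A", 600, 5, False)],
    )


@pytest.fixture(scope="session")
def tiny_study(tiny_cfg) -> mt.StudyData:
    return mt.simulate_study(tiny_cfg)


@pytest.fixture(scope="session")
def two_condition_study() -> mt.StudyData:
    """Two conditions with disjoint planted site sets, two replicates each."""
    return mt.simulate_study(mt.SimConfig(conditions=2, replicates=2))


def make_transcript(
    transcript_id="txA",
    gene_id="geneA",
    chrom="chr1",
    strand="+",
    exons=((1000, 1600), (2000, 3000)),
    utr5_len=200,
    cds_len=900,
    utr3_len=500,
    biotype="protein_coding",
) -> mt.Transcript:
    return mt.Transcript(
        transcript_id=transcript_id,
        gene_id=gene_id,
        chrom=chrom,
        strand=strand,
        exons=tuple(tuple(e) for e in exons),
        utr5_len=utr5_len,
        cds_len=cds_len,
        utr3_len=utr3_len,
        biotype=biotype,
    )


@pytest.fixture()
def mini_annotation() -> mt.GenomeAnnotation:
    """One spliced coding (+) transcript on a 10-kb chromosome.

    txA: exons [1000,1600)+[2000,3000), 5'UTR 200 / CDS 900 / 3'UTR 500;
    stop codon at genomic [2497,2500) so its ±200 bp window is [2297,2700).
    """
    txa = make_transcript()
    return mt.GenomeAnnotation(chrom_lengths={"chr1": 10_000}, transcripts={"txA": txa})
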