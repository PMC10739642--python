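"""Readers and writers for the pipeline's interchange formats.

Conventions: FASTA for genomes; GTF (1-based inclusive, gene_id /
transcript_id attributes) for gene models; BED12 (0-based half-open, blocks
for splices) for aligned fragments; bedGraph for tracks; ENCODE narrowPeak
for peaks; TSV/CSV for tables.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from pyfaidx import Fasta

from .coverage import BinnedTrack, SignalTrack
from .fragments import AlignedFragmentSet, Fragment
from .genome import GenomeAnnotation, RetroLocus, Transcript
from .peaks import Peak
from .simulate import M6ASite, SyntheticTruth


# --- FASTA -----------------------------------------------------------------

def write_fasta(genome: Mapping[str, str], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path) -> Dict[str, str]:
    fa = Fasta(str(path), rebuild=True)
    return {name: str(fa[name][:]) for name in fa.keys()}


# --- GTF -------------------------------------------------------------------

def _gtf_line(chrom, source, feature, start0, end0, strand, attrs: str) -> str:
    return (
        f"{chrom}\t{source}\t{feature}\t{start0 + 1}\t{end0}\t.\t{strand}\t.\t{attrs}\n"
    )


def write_gtf(annotation: GenomeAnnotation, path) -> None:
    """Gene models as GTF: transcript, exon, CDS, UTRs and stop_codon rows."""
    with open(path, "w") as fh:
        for tx in sorted(annotation.transcripts.values(),
                         key=lambda t: (t.chrom, t.span[0], t.transcript_id)):
            attrs = (
                f'gene_id "{tx.gene_id}"; transcript_id "{tx.transcript_id}"; '
                f'biotype "{tx.biotype}";'
            )
            s, e = tx.span
            fh.write(_gtf_line(tx.chrom, "meriptools", "transcript", s, e, tx.strand, attrs))
            for es, ee in tx.exons:
                fh.write(_gtf_line(tx.chrom, "meriptools", "exon", es, ee, tx.strand, attrs))
            if tx.is_coding:
                u5, c1 = tx.utr5_len, tx.utr5_len + tx.cds_len
                for name, (a, b) in (
                    ("five_prime_utr", (0, u5)),
                    ("CDS", (u5, c1)),
                    ("three_prime_utr", (c1, tx.exonic_length)),
                ):
                    if b <= a:
                        continue
                    for bs, be in tx.tx_interval_to_blocks(a, b):
                        fh.write(_gtf_line(tx.chrom, "meriptools", name, bs, be, tx.strand, attrs))
                for bs, be in tx.stop_codon_blocks():
                    fh.write(
                        _gtf_line(tx.chrom, "meriptools", "stop_codon", bs, be, tx.strand, attrs)
                    )


def read_gtf(path, chrom_lengths: Mapping[str, int],
             spikein_contigs: Sequence[str] = ()) -> GenomeAnnotation:
    """Rebuild a GenomeAnnotation from a GTF written by :func:`write_gtf`."""
    cols = ["chrom", "source", "feature", "start", "end", "score", "strand",
            "frame", "attributes"]
    df = pd.read_csv(path, sep="\t", comment="#", header=None, names=cols)
    df["transcript_id"] = df["attributes"].str.extract(r'transcript_id "([^"]+)"')
    df["gene_id"] = df["attributes"].str.extract(r'gene_id "([^"]+)"')
    df["biotype"] = df["attributes"].str.extract(r'biotype "([^"]+)"').fillna("protein_coding")
    transcripts: Dict[str, Transcript] = {}
    for tid, grp in df.groupby("transcript_id", sort=True):
        exons = grp[grp["feature"] == "exon"]
        exon_ivs = tuple(
            sorted((int(s) - 1, int(e)) for s, e in zip(exons["start"], exons["end"]))
        )
        lens = {
            name: int(
                (grp[grp["feature"] == feat]["end"]
                 - grp[grp["feature"] == feat]["start"] + 1).sum()
            )
            for name, feat in (
                ("u5", "five_prime_utr"), ("cds", "CDS"), ("u3", "three_prime_utr"),
            )
        }
        row = grp.iloc[0]
        transcripts[tid] = Transcript(
            transcript_id=tid,
            gene_id=row["gene_id"],
            chrom=row["chrom"],
            strand=row["strand"],
            exons=exon_ivs,
            utr5_len=lens["u5"],
            cds_len=lens["cds"],
            utr3_len=lens["u3"],
            biotype=row["biotype"],
        )
    return GenomeAnnotation(
        chrom_lengths=dict(chrom_lengths),
        transcripts=transcripts,
        spikein_contigs=tuple(spikein_contigs),
    )


# --- fragments (BED12) -----------------------------------------------------

def write_bed12(frags: AlignedFragmentSet, path) -> None:
    with open(path, "w") as fh:
        for i, f in enumerate(frags.fragments):
            sizes = ",".join(str(e - s) for s, e in f.blocks)
            starts = ",".join(str(s - f.start) for s, _ in f.blocks)
            fh.write(
                f"{f.chrom}\t{f.start}\t{f.end}\tfrag{i}\t0\t{f.strand}\t"
                f"{f.start}\t{f.end}\t0,0,0\t{len(f.blocks)}\t{sizes},\t{starts},\n"
            )


def read_bed12(path, sample_id: str, role: str, condition: str = "cond0",
               replicate: int = 1) -> AlignedFragmentSet:
    frags: List[Fragment] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            p = line.rstrip("\n").split("\t")
            chrom, start, end, strand = p[0], int(p[1]), int(p[2]), p[5]
            sizes = [int(x) for x in p[10].rstrip(",").split(",")]
            offs = [int(x) for x in p[11].rstrip(",").split(",")]
            blocks = tuple((start + o, start + o + sz) for o, sz in zip(offs, sizes))
            frags.append(Fragment(chrom, start, end, strand, blocks))
    return AlignedFragmentSet(sample_id, role, condition, replicate, frags)


# --- tracks (bedGraph) -----------------------------------------------------

def write_bedgraph(track, path) -> None:
    """One line per constant-value run; zero runs are skipped."""
    bw = track.bin_width
    with open(path, "w") as fh:
        for chrom in track.values:
            v = np.asarray(track.values[chrom])
            if len(v) == 0:
                continue
            change = np.flatnonzero(np.diff(v) != 0)
            starts = np.concatenate([[0], change + 1])
            ends = np.concatenate([change + 1, [len(v)]])
            for s, e in zip(starts, ends):
                val = v[s]
                if val == 0:
                    continue
                fh.write(f"{chrom}\t{s * bw}\t{e * bw}\t{val:.6g}\n")


# --- peaks (narrowPeak) ----------------------------------------------------

_LOG10_FLOOR = 5e-324


def write_narrowpeak(peaks: Sequence[Peak], path) -> None:
    """ENCODE narrowPeak: signalValue = fold enrichment, pValue/qValue as
    -log10, peak = summit offset from start."""
    with open(path, "w") as fh:
        for pk in peaks:
            mlog_p = -math.log10(max(pk.p, _LOG10_FLOOR))
            mlog_q = -math.log10(max(pk.q, _LOG10_FLOOR))
            fh.write(
                f"{pk.chrom}\t{pk.start}\t{pk.end}\t{pk.name or '.'}\t0\t.\t"
                f"{pk.fold_enrichment:.5g}\t{mlog_p:.5g}\t{mlog_q:.5g}\t"
                f"{pk.summit - pk.start}\n"
            )


def read_narrowpeak(path) -> List[Peak]:
    peaks: List[Peak] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            p = line.rstrip("\n").split("\t")
            start = int(p[1])
            peaks.append(
                Peak(
                    chrom=p[0], start=start, end=int(p[2]),
                    summit=start + int(p[9]), pileup=0.0,
                    p=10 ** -float(p[7]), q=10 ** -float(p[8]),
                    fold_enrichment=float(p[6]), name=p[3],
                )
            )
    return peaks


# --- tables ----------------------------------------------------------------

def write_truth(truth: SyntheticTruth, path) -> None:
    truth.to_frame().to_csv(path, sep="\t", index=False)


def read_truth(path) -> SyntheticTruth:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    truth = SyntheticTruth()
    for row in df.itertuples(index=False):
        site = M6ASite(row.chrom, int(row.position), row.strand,
                       row.transcript_id, float(row.stoichiometry),
                       int(row.tx_position))
        getattr(truth, {"gene": "sites", "spikein": "spikein_sites",
                        "retro": "retro_sites"}[row.registry]).append(site)
    return truth


def write_retro_loci(loci: Sequence[RetroLocus], path) -> None:
    pd.DataFrame(
        [
            (l.chrom, l.start, l.end, l.strand, l.subfamily, l.consensus_length)
            for l in loci
        ],
        columns=["chrom", "start", "end", "strand", "subfamily", "consensus_length"],
    ).to_csv(path, sep="\t", index=False)


def read_retro_loci(path) -> List[RetroLocus]:
    df = pd.read_csv(path, sep="\t")
    return [
        RetroLocus(r.chrom, int(r.start), int(r.end), r.strand, r.subfamily,
                   int(r.consensus_length))
        for r in df.itertuples(index=False)
    ]


def write_chrom_sizes(chrom_lengths: Mapping[str, int], path) -> None:
    with open(path, "w") as fh:
        for c, n in chrom_lengths.items():
            fh.write(f"{c}\t{n}\n")


def read_chrom_sizes(path) -> Dict[str, int]:
    out: Dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if line.strip():
                c, n = line.split("\t")
                out[c] = int(n)
    return out
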