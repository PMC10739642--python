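"""Genome, gene-model and repeat-locus containers shared by all pipeline stages.

Coordinates are genomic, 0-based, half-open throughout. Transcript ("tx")
coordinates run 5'→3' on the transcript strand, 0-based, over the spliced
exonic sequence.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from intervaltree import IntervalTree

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class RetroLocus:
    """A RepeatMasker-style retrotransposon copy."""

    chrom: str
    start: int
    end: int
    strand: str
    subfamily: str
    consensus_length: int

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def locus_id(self) -> str:
        return f"{self.subfamily}:{self.chrom}:{self.start}-{self.end}"


@dataclass(frozen=True)
class Transcript:
    """A single-isoform gene model with optional coding structure.

    For coding transcripts ``utr5_len + cds_len + utr3_len`` equals the
    exonic length and the CDS includes the stop codon as its 3'-terminal
    three bases.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: Tuple[Tuple[int, int], ...]
    utr5_len: int = 0
    cds_len: int = 0
    utr3_len: int = 0
    biotype: str = "protein_coding"

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        for (s, e) in self.exons:
            if not (0 <= s < e):
                raise ValueError("malformed exon")

    @property
    def span(self) -> Tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def exonic_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def is_coding(self) -> bool:
        return self.cds_len > 0

    # --- coordinate maps -------------------------------------------------
    @functools.cached_property
    def _exon_tx_starts(self) -> np.ndarray:
        """Transcript coordinate of the 5' end of each exon, in exon order
        along the transcript (reversed genomic order on the minus strand)."""
        lens = [e - s for s, e in self.exons]
        if self.strand == "-":
            lens = lens[::-1]
        return np.concatenate([[0], np.cumsum(lens)])

    def tx_to_genome(self, pos: int) -> int:
        """Map a transcript coordinate to its genomic base position."""
        L = self.exonic_length
        if not (0 <= pos < L):
            raise ValueError(f"tx position {pos} outside [0, {L})")
        starts = self._exon_tx_starts
        i = int(np.searchsorted(starts, pos, side="right") - 1)
        off = pos - int(starts[i])
        if self.strand == "+":
            s, _ = self.exons[i]
            return s + off
        s, e = self.exons[len(self.exons) - 1 - i]
        return e - 1 - off

    def genome_to_tx(self, gpos: int) -> Optional[int]:
        """Map a genomic position to transcript coordinates; None if intronic
        or outside the transcript."""
        for i, (s, e) in enumerate(self.exons):
            if s <= gpos < e:
                starts = self._exon_tx_starts
                if self.strand == "+":
                    return int(starts[i]) + (gpos - s)
                j = len(self.exons) - 1 - i
                return int(starts[j]) + (e - 1 - gpos)
        return None

    def tx_interval_to_blocks(self, start: int, end: int) -> Tuple[Tuple[int, int], ...]:
        """Project a transcript interval [start, end) to sorted genomic blocks."""
        if not (0 <= start < end <= self.exonic_length):
            raise ValueError("tx interval out of range")
        starts = self._exon_tx_starts
        n = len(self.exons)
        blocks: List[Tuple[int, int]] = []
        i0 = int(np.searchsorted(starts, start, side="right") - 1)
        i1 = int(np.searchsorted(starts, end - 1, side="right") - 1)
        for i in range(i0, i1 + 1):
            seg_lo = max(start, int(starts[i]))
            seg_hi = min(end, int(starts[i + 1]))
            gi = i if self.strand == "+" else n - 1 - i
            s, e = self.exons[gi]
            if self.strand == "+":
                blocks.append((s + (seg_lo - int(starts[i])), s + (seg_hi - int(starts[i]))))
            else:
                blocks.append((e - (seg_hi - int(starts[i])), e - (seg_lo - int(starts[i]))))
        blocks.sort()
        return tuple(blocks)

    # --- coding-structure helpers ---------------------------------------
    @property
    def cds_tx_interval(self) -> Tuple[int, int]:
        if not self.is_coding:
            raise ValueError(f"{self.transcript_id} is non-coding")
        return self.utr5_len, self.utr5_len + self.cds_len

    @property
    def stop_codon_tx_interval(self) -> Tuple[int, int]:
        lo, hi = self.cds_tx_interval
        return hi - 3, hi

    def stop_codon_blocks(self) -> Tuple[Tuple[int, int], ...]:
        return self.tx_interval_to_blocks(*self.stop_codon_tx_interval)

    def stop_codon_window(self, pad: int, chrom_length: int) -> Tuple[int, int]:
        """Genomic window of ±pad bp around the annotated stop codon."""
        blocks = self.stop_codon_blocks()
        lo = max(0, blocks[0][0] - pad)
        hi = min(chrom_length, blocks[-1][1] + pad)
        return lo, hi

    def spliced_sequence(self, genome: Mapping[str, str]) -> str:
        """Exonic sequence 5'→3' on the transcript strand."""
        chrom = genome[self.chrom]
        seq = "".join(chrom[s:e] for s, e in self.exons)
        return revcomp(seq) if self.strand == "-" else seq


@dataclass
class GenomeAnnotation:
    """Chromosome sizes, gene models, spike-in contigs and repeat loci."""

    chrom_lengths: Dict[str, int]
    transcripts: Dict[str, Transcript] = field(default_factory=dict)
    retro_loci: List[RetroLocus] = field(default_factory=list)
    spikein_contigs: Tuple[str, ...] = ()

    def __post_init__(self) -> None:
        for tx in self.transcripts.values():
            if tx.chrom not in self.chrom_lengths:
                raise ValueError(f"{tx.transcript_id} on unknown chrom {tx.chrom}")
            if tx.span[1] > self.chrom_lengths[tx.chrom]:
                raise ValueError(f"{tx.transcript_id} exceeds chromosome bounds")

    @functools.cached_property
    def transcript_trees(self) -> Dict[str, IntervalTree]:
        trees: Dict[str, IntervalTree] = {c: IntervalTree() for c in self.chrom_lengths}
        for tx in self.transcripts.values():
            s, e = tx.span
            trees[tx.chrom].addi(s, e, tx.transcript_id)
        return trees

    def transcripts_at(self, chrom: str, pos: int) -> List[Transcript]:
        tree = self.transcript_trees.get(chrom)
        if tree is None:
            return []
        hits = [self.transcripts[iv.data] for iv in tree.at(pos)]
        hits.sort(key=lambda t: t.transcript_id)
        return hits

    def exon_union(self) -> Dict[str, np.ndarray]:
        """Merged exon intervals per chromosome as (n, 2) arrays."""
        per_chrom: Dict[str, List[Tuple[int, int]]] = {c: [] for c in self.chrom_lengths}
        for tx in self.transcripts.values():
            per_chrom[tx.chrom].extend(tx.exons)
        out: Dict[str, np.ndarray] = {}
        for chrom, ivs in per_chrom.items():
            if not ivs:
                out[chrom] = np.empty((0, 2), dtype=np.int64)
                continue
            ivs.sort()
            merged = [list(ivs[0])]
            for s, e in ivs[1:]:
                if s <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], e)
                else:
                    merged.append([s, e])
            out[chrom] = np.asarray(merged, dtype=np.int64)
        return out

    def exonic_bin_mask(self, bin_width: int) -> Dict[str, np.ndarray]:
        """Boolean per-bin mask: True where the bin overlaps any exon."""
        masks: Dict[str, np.ndarray] = {}
        union = self.exon_union()
        for chrom, length in self.chrom_lengths.items():
            n = -(-length // bin_width)
            m = np.zeros(n, dtype=bool)
            for s, e in union[chrom]:
                m[s // bin_width : (e - 1) // bin_width + 1] = True
            masks[chrom] = m
        return masks

    def genes(self) -> Dict[str, List[Transcript]]:
        by_gene: Dict[str, List[Transcript]] = {}
        for tx in self.transcripts.values():
            by_gene.setdefault(tx.gene_id, []).append(tx)
        return by_gene
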