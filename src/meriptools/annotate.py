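"""Peak-to-feature assignment, m6A gene calling, observed/expected feature
enrichment, and metagene profiles.

A peak summit receives exactly one genomic feature in priority order:
stop codon (annotated stop ±200 bp, genomic), 3'UTR, 5'UTR, CDS, exon,
intron, intergenic. The stop-codon window is genomic, so bases beyond the
transcript's 3' end still count.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .genome import GenomeAnnotation, Transcript
from .peaks import Peak

STOP_CODON_PAD = 200
FEATURES = ("stop_codon", "utr3", "utr5", "cds", "exon", "intron", "intergenic")


@dataclass(frozen=True)
class FeatureAssignment:
    peak_name: str
    feature: str
    gene_id: Optional[str] = None


class FeatureIndex:
    """Priority-ordered interval indexes over an annotation's features."""

    def __init__(self, annotation: GenomeAnnotation) -> None:
        self.annotation = annotation
        trees: Dict[str, Dict[str, IntervalTree]] = {
            f: {c: IntervalTree() for c in annotation.chrom_lengths}
            for f in FEATURES[:-1]
        }
        for tx in annotation.transcripts.values():
            clen = annotation.chrom_lengths[tx.chrom]
            if tx.is_coding:
                lo, hi = tx.stop_codon_window(STOP_CODON_PAD, clen)
                trees["stop_codon"][tx.chrom].addi(lo, hi, tx.gene_id)
                u5, c0 = tx.utr5_len, tx.utr5_len + tx.cds_len
                for name, (a, b) in (
                    ("utr5", (0, u5)),
                    ("cds", (u5, c0)),
                    ("utr3", (c0, tx.exonic_length)),
                ):
                    if b > a:
                        for s, e in tx.tx_interval_to_blocks(a, b):
                            trees[name][tx.chrom].addi(s, e, tx.gene_id)
            for s, e in tx.exons:
                trees["exon"][tx.chrom].addi(s, e, tx.gene_id)
            span_s, span_e = tx.span
            prev = span_s
            for s, e in tx.exons:
                if s > prev:
                    trees["intron"][tx.chrom].addi(prev, s, tx.gene_id)
                prev = e
        self.trees = trees

    def assign(self, chrom: str, summit: int, peak_name: str = "") -> FeatureAssignment:
        for feature in FEATURES[:-1]:
            tree = self.trees[feature].get(chrom)
            if tree is None:
                continue
            hits = tree.at(summit)
            if hits:
                gene = min(iv.data for iv in hits)  # deterministic gene choice
                return FeatureAssignment(peak_name, feature, gene)
        return FeatureAssignment(peak_name, "intergenic", None)


def assign_feature(
    summit_or_peak: Union[Peak, Tuple[str, int]],
    annotation: GenomeAnnotation,
    index: Optional[FeatureIndex] = None,
) -> FeatureAssignment:
    """Assign one summit (a Peak or a (chrom, position) pair) to its feature."""
    index = index or FeatureIndex(annotation)
    if isinstance(summit_or_peak, Peak):
        return index.assign(summit_or_peak.chrom, summit_or_peak.summit,
                            summit_or_peak.name)
    chrom, pos = summit_or_peak
    return index.assign(chrom, pos)


def assign_features(
    peaks: Sequence[Peak], annotation: GenomeAnnotation
) -> List[FeatureAssignment]:
    index = FeatureIndex(annotation)
    return [index.assign(pk.chrom, pk.summit, pk.name) for pk in peaks]


# ---------------------------------------------------------------------------
# m6A genes
# ---------------------------------------------------------------------------

def m6a_genes(
    peaks: Union[Sequence[Peak], Mapping[int, Sequence[Peak]]],
    annotation: GenomeAnnotation,
    require_both_replicates: bool = False,
) -> set:
    """Genes with at least one peak summit in any of their features
    (stop codon, UTRs, CDS, exon, intron — not intergenic).

    ``peaks`` may be a flat peak list or a mapping replicate -> peaks; with
    ``require_both_replicates`` a gene must be marked in every replicate.
    """
    if isinstance(peaks, Mapping):
        per_rep = {rep: list(pks) for rep, pks in peaks.items()}
    else:
        per_rep = {1: list(peaks)}
    if require_both_replicates and len(per_rep) < 2:
        raise ValueError("replicate-supported gene calling needs >=2 replicates")
    index = FeatureIndex(annotation)
    rep_sets: List[set] = []
    for pks in per_rep.values():
        genes = {
            a.gene_id
            for a in (index.assign(pk.chrom, pk.summit, pk.name) for pk in pks)
            if a.gene_id is not None
        }
        rep_sets.append(genes)
    if not rep_sets:
        return set()
    if require_both_replicates:
        return set.intersection(*rep_sets)
    return set.union(*rep_sets)


# ---------------------------------------------------------------------------
# feature enrichment
# ---------------------------------------------------------------------------

def priority_masked_lengths(annotation: GenomeAnnotation) -> Dict[str, int]:
    """Genomic bp per feature class, each base counted once under the same
    priority order used for assignment."""
    codes = {f: i for i, f in enumerate(FEATURES)}
    lengths = {f: 0 for f in FEATURES}
    for chrom, clen in annotation.chrom_lengths.items():
        paint = np.full(clen, codes["intergenic"], dtype=np.int8)
        # paint from lowest to highest priority so high priority overwrites
        txs = [t for t in annotation.transcripts.values() if t.chrom == chrom]
        for tx in txs:
            s, e = tx.span
            paint[s:e] = codes["intron"]
        for tx in txs:
            for s, e in tx.exons:
                paint[s:e] = codes["exon"]
        for tx in txs:
            if not tx.is_coding:
                continue
            u5, c0 = tx.utr5_len, tx.utr5_len + tx.cds_len
            for s, e in tx.tx_interval_to_blocks(u5, c0):
                paint[s:e] = codes["cds"]
        for tx in txs:
            if not tx.is_coding or tx.utr5_len == 0:
                continue
            for s, e in tx.tx_interval_to_blocks(0, tx.utr5_len):
                paint[s:e] = codes["utr5"]
        for tx in txs:
            if not tx.is_coding or tx.utr3_len == 0:
                continue
            c0 = tx.utr5_len + tx.cds_len
            for s, e in tx.tx_interval_to_blocks(c0, tx.exonic_length):
                paint[s:e] = codes["utr3"]
        for tx in txs:
            if tx.is_coding:
                lo, hi = tx.stop_codon_window(STOP_CODON_PAD, clen)
                paint[lo:hi] = codes["stop_codon"]
        binc = np.bincount(paint, minlength=len(FEATURES))
        for f, i in codes.items():
            lengths[f] += int(binc[i])
    return lengths


def feature_enrichment(
    assignments: Sequence[FeatureAssignment],
    annotation: GenomeAnnotation,
) -> pd.DataFrame:
    """log2(observed/expected) peak counts per feature, with expected counts
    proportional to priority-masked genomic feature length."""
    if not assignments:
        raise ValueError("no assignments")
    lengths = priority_masked_lengths(annotation)
    total_len = sum(lengths.values())
    total_peaks = len(assignments)
    observed = {f: 0 for f in FEATURES}
    for a in assignments:
        observed[a.feature] += 1
    rows = []
    for f in FEATURES:
        expected = total_peaks * lengths[f] / total_len
        if expected > 0:
            score = (
                float(np.log2(observed[f] / expected)) if observed[f] > 0 else -np.inf
            )
        else:
            score = np.nan
        rows.append((f, observed[f], expected, score))
    return pd.DataFrame(rows, columns=["feature", "observed", "expected", "score"])


# ---------------------------------------------------------------------------
# metagene
# ---------------------------------------------------------------------------

@dataclass
class MetageneProfile:
    coordinates: np.ndarray  # one value in [0, 3] per mapped summit
    bin_edges: np.ndarray
    density: np.ndarray  # integrates to one over [0, 3]
    n_dropped: int

    @property
    def modal_coordinate(self) -> float:
        i = int(np.argmax(self.density))
        return float((self.bin_edges[i] + self.bin_edges[i + 1]) / 2)


def select_top_isoforms(
    annotation: GenomeAnnotation, tpm: Mapping[str, float]
) -> Dict[str, Transcript]:
    """Per gene, the highest-TPM coding isoform (ties: longer transcript,
    then id)."""
    chosen: Dict[str, Transcript] = {}
    for gene, txs in annotation.genes().items():
        coding = [t for t in txs if t.is_coding]
        if not coding:
            continue
        coding.sort(
            key=lambda t: (-tpm.get(t.transcript_id, 0.0), -t.exonic_length,
                           t.transcript_id)
        )
        chosen[gene] = coding[0]
    return chosen


def metagene_coordinate(tx: Transcript, summit: int) -> Optional[float]:
    """Map a summit inside a coding transcript to [0, 3]: 5'UTR -> [0,1),
    CDS -> [1,2), 3'UTR -> [2,3]."""
    t = tx.genome_to_tx(summit)
    if t is None:
        return None
    u5, cds, u3 = tx.utr5_len, tx.cds_len, tx.utr3_len
    if t < u5:
        return t / u5
    if t < u5 + cds:
        return 1.0 + (t - u5) / cds
    return 2.0 + (t - u5 - cds) / u3 if u3 > 0 else 2.0


def metagene(
    peaks: Sequence[Peak],
    annotation: GenomeAnnotation,
    tpm: Mapping[str, float],
    bins_per_segment: int = 30,
) -> MetageneProfile:
    """Summit density along the rescaled 5'UTR/CDS/3'UTR metagene.

    Each summit is positioned within its host gene's top-expression isoform;
    summits outside any selected isoform's exons are dropped (counted in
    ``n_dropped``).
    """
    isoforms = select_top_isoforms(annotation, tpm)
    trees: Dict[str, IntervalTree] = {c: IntervalTree() for c in annotation.chrom_lengths}
    for tx in isoforms.values():
        s, e = tx.span
        trees[tx.chrom].addi(s, e, tx.transcript_id)
    coords: List[float] = []
    dropped = 0
    for pk in peaks:
        hits = sorted(trees[pk.chrom].at(pk.summit), key=lambda iv: iv.data)
        coord = None
        for iv in hits:
            coord = metagene_coordinate(annotation.transcripts[iv.data], pk.summit)
            if coord is not None:
                break
        if coord is None:
            dropped += 1
        else:
            coords.append(coord)
    edges = np.linspace(0.0, 3.0, 3 * bins_per_segment + 1)
    if coords:
        density, _ = np.histogram(coords, bins=edges, density=True)
    else:
        density = np.zeros(3 * bins_per_segment)
    return MetageneProfile(np.asarray(coords), edges, density, dropped)
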