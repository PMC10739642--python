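"""Retrotransposon-derived RNA methylation: locus filtering, per-locus
expression and m6A signal, subfamily methylated fractions and
consensus-coordinate profiles."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .coverage import BinnedTrack, SignalTrack
from .genome import GenomeAnnotation, RetroLocus


def filter_retro_loci(
    loci: Sequence[RetroLocus], annotation: GenomeAnnotation
) -> List[RetroLocus]:
    """Keep near-full-length, mostly non-exonic copies.

    A locus is retained iff its length is >= 90% of the subfamily consensus
    length AND less than 50% of its bases are covered by the exon union of
    annotated genes. The filter is idempotent and order-independent.
    """
    union = annotation.exon_union()
    kept = []
    for locus in loci:
        if locus.consensus_length <= 0:
            raise ValueError(f"{locus.locus_id}: consensus_length must be > 0")
        if locus.length < 0.9 * locus.consensus_length:
            continue
        ivs = union.get(locus.chrom)
        overlap = 0
        if ivs is not None and len(ivs):
            lo = np.searchsorted(ivs[:, 1], locus.start, side="right")
            for s, e in ivs[lo:]:
                if s >= locus.end:
                    break
                overlap += max(0, min(e, locus.end) - max(s, locus.start))
        if overlap / locus.length < 0.5:
            kept.append(locus)
    return kept


def _locus_bins(locus: RetroLocus, bin_width: int) -> Tuple[int, int]:
    """Inclusive-exclusive bin range overlapping the locus (at least one bin)."""
    b0 = locus.start // bin_width
    b1 = (locus.end - 1) // bin_width + 1
    return b0, max(b1, b0 + 1)


def retro_locus_stats(
    locus: RetroLocus,
    input_track: BinnedTrack,
    signal_track: SignalTrack,
) -> Tuple[float, float]:
    """(expression, m6A signal) for one locus: means of the input RPKM and
    m6A signal values over all 10-bp bins overlapping the locus."""
    bw = input_track.bin_width
    if signal_track.bin_width != bw:
        raise ValueError("tracks must share one bin grid")
    b0, b1 = _locus_bins(locus, bw)
    expr = float(input_track.values[locus.chrom][b0:b1].mean())
    sig = float(signal_track.values[locus.chrom][b0:b1].mean())
    return expr, sig


def retro_stats_table(
    loci: Sequence[RetroLocus],
    input_tracks: Sequence[BinnedTrack],
    signal_tracks: Sequence[SignalTrack],
    condition: str = "cond0",
) -> pd.DataFrame:
    """Per-locus expression and m6A signal, averaged arithmetically over
    replicate (input, signal) track pairs."""
    if len(input_tracks) != len(signal_tracks) or not input_tracks:
        raise ValueError("need matched, non-empty replicate track lists")
    rows = []
    for locus in loci:
        pairs = [
            retro_locus_stats(locus, it, st)
            for it, st in zip(input_tracks, signal_tracks)
        ]
        expr = float(np.mean([p[0] for p in pairs]))
        sig = float(np.mean([p[1] for p in pairs]))
        rows.append(
            (condition, locus.subfamily, locus.locus_id, locus.chrom,
             locus.start, locus.end, locus.strand, expr, sig)
        )
    return pd.DataFrame(
        rows,
        columns=["condition", "subfamily", "locus_id", "chrom", "start", "end",
                 "strand", "expression", "m6a_signal"],
    )


def subfamily_fractions(stats: pd.DataFrame) -> pd.DataFrame:
    """Per subfamily (and condition, if present): number of loci and the
    fraction with m6A signal > 0."""
    keys = [k for k in ("condition", "subfamily") if k in stats.columns]
    if "subfamily" not in keys:
        raise ValueError("stats table lacks a subfamily column")
    grouped = stats.groupby(keys, sort=True)
    out = grouped.agg(
        n_loci=("m6a_signal", "size"),
        fraction_methylated=("m6a_signal", lambda s: float((s > 0).mean())),
        mean_expression=("expression", "mean"),
        mean_signal=("m6a_signal", "mean"),
    ).reset_index()
    return out


def consensus_profile(
    loci: Sequence[RetroLocus],
    track,
    bin_width: Optional[int] = None,
) -> np.ndarray:
    """Mean track value per consensus-coordinate bin across a subfamily.

    Each genomic bin overlapping a locus maps proportionally (affine) to the
    consensus coordinate; minus-strand loci are reversed so profiles read
    5'->3' on the element. Returns one value per consensus bin.
    """
    if not loci:
        raise ValueError("no loci")
    subfamilies = {l.subfamily for l in loci}
    if len(subfamilies) != 1:
        raise ValueError("profile requires loci of a single subfamily")
    consensus_length = loci[0].consensus_length
    bw = bin_width or track.bin_width
    n_cbins = max(1, consensus_length // bw)
    sums = np.zeros(n_cbins)
    counts = np.zeros(n_cbins)
    for locus in loci:
        b0, b1 = _locus_bins(locus, track.bin_width)
        vals = track.values[locus.chrom][b0:b1]
        centers = (np.arange(b0, b1) + 0.5) * track.bin_width
        frac = (centers - locus.start) / locus.length
        if locus.strand == "-":
            frac = 1.0 - frac
        cbin = np.clip((frac * n_cbins).astype(int), 0, n_cbins - 1)
        np.add.at(sums, cbin, vals)
        np.add.at(counts, cbin, 1)
    with np.errstate(invalid="ignore"):
        return np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
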