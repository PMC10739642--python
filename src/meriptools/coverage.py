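"""Binned coverage tracks, RPKM/TPM normalization, the m6A signal,
transcriptome-wide correlation and PCA.

The per-bin statistic is the fragment-overlap count: the number of fragments
whose exonic blocks overlap the bin. RPKM divides that count by
(bin kb x total fragments in millions). The m6A signal of a bin is
log2((IP RPKM + 1) / (input RPKM + 1)).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from sklearn.decomposition import PCA

from .fragments import AlignedFragmentSet
from .genome import GenomeAnnotation


@dataclass
class BinnedTrack:
    """Fixed-width per-bin values over a genome (counts or RPKM)."""

    bin_width: int
    values: Dict[str, np.ndarray]
    total_fragments: int
    kind: str = "rpkm"  # "counts" | "rpkm"
    sample_id: str = ""

    def same_grid(self, other: "BinnedTrack") -> bool:
        return (
            self.bin_width == other.bin_width
            and set(self.values) == set(other.values)
            and all(len(self.values[c]) == len(other.values[c]) for c in self.values)
        )

    def total(self) -> float:
        return float(sum(v.sum() for v in self.values.values()))


@dataclass
class SignalTrack:
    """Per-bin m6A signal in log2 units."""

    bin_width: int
    values: Dict[str, np.ndarray]
    ip_sample: str = ""
    input_sample: str = ""
    sample_id: str = ""


def _bin_ranges(blocks: Sequence[Tuple[int, int]], bw: int) -> List[Tuple[int, int]]:
    """Half-open bin-index ranges covered by a fragment's blocks, merged so
    the fragment is counted at most once per bin."""
    ranges = [(s // bw, (e - 1) // bw + 1) for s, e in blocks]
    merged = [list(ranges[0])]
    for s, e in ranges[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def bin_coverage(
    frags: AlignedFragmentSet,
    chrom_lengths: Mapping[str, int],
    bin_width: int = 10,
    normalize: str = "rpkm",
) -> BinnedTrack:
    """Per-bin fragment-overlap counts, optionally RPKM-normalized."""
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    if normalize not in ("rpkm", "counts"):
        raise ValueError("normalize must be 'rpkm' or 'counts'")
    nbins = {c: -(-length // bin_width) for c, length in chrom_lengths.items()}
    # difference arrays: each fragment adds +1 over its covered bin range
    diffs = {c: np.zeros(n + 1, dtype=np.float64) for c, n in nbins.items()}
    for f in frags.fragments:
        d = diffs.get(f.chrom)
        if d is None:
            raise ValueError(f"fragment on unknown chromosome {f.chrom}")
        if f.end > chrom_lengths[f.chrom] or f.start < 0:
            raise ValueError(f"fragment out of bounds: {f}")
        if len(f.blocks) == 1:
            d[f.start // bin_width] += 1
            d[(f.end - 1) // bin_width + 1] -= 1
        else:
            for s, e in _bin_ranges(f.blocks, bin_width):
                d[s] += 1
                d[e] -= 1
    counts = {c: np.cumsum(d[:-1]) for c, d in diffs.items()}
    total = len(frags)
    if normalize == "rpkm" and total > 0:
        scale = 1.0 / ((bin_width / 1000.0) * (total / 1e6))
        values = {c: v * scale for c, v in counts.items()}
    else:
        values = counts
    return BinnedTrack(bin_width, values, total, kind=normalize, sample_id=frags.sample_id)


def m6a_signal(ip: BinnedTrack, inp: BinnedTrack) -> SignalTrack:
    """log2((IP RPKM + 1) / (input RPKM + 1)) per bin."""
    if not ip.same_grid(inp):
        raise ValueError("IP and input tracks are on different bin grids")
    values = {
        c: np.log2((ip.values[c] + 1.0) / (inp.values[c] + 1.0)) for c in ip.values
    }
    return SignalTrack(
        ip.bin_width, values, ip_sample=ip.sample_id, input_sample=inp.sample_id,
        sample_id=f"{ip.sample_id}/{inp.sample_id}",
    )


# ---------------------------------------------------------------------------
# transcript abundance
# ---------------------------------------------------------------------------

def transcript_tpm(
    input_frags: AlignedFragmentSet, annotation: GenomeAnnotation
) -> pd.DataFrame:
    """TPM per annotated transcript from an input library.

    A fragment is assigned to the transcript whose span contains its genomic
    midpoint; among several, the one with the largest exonic overlap with the
    fragment wins, ties broken by lexicographic transcript id.
    """
    counts = {tid: 0 for tid in annotation.transcripts}
    for f in input_frags.fragments:
        mid = (f.start + f.end) // 2
        hits = annotation.transcripts_at(f.chrom, mid)
        if not hits:
            continue
        if len(hits) == 1:
            counts[hits[0].transcript_id] += 1
            continue
        best, best_ov = None, -1
        for tx in hits:  # already id-sorted: first max wins lexicographic tie
            ov = 0
            for bs, be in f.blocks:
                for es, ee in tx.exons:
                    ov += max(0, min(be, ee) - max(bs, es))
            if ov > best_ov:
                best, best_ov = tx, ov
        counts[best.transcript_id] += 1
    rows = []
    for tid, tx in annotation.transcripts.items():
        length = tx.exonic_length
        rows.append((tid, length, counts[tid], counts[tid] / (length / 1000.0)))
    df = pd.DataFrame(rows, columns=["transcript_id", "length", "count", "rate"])
    total_rate = df["rate"].sum()
    df["tpm"] = 0.0 if total_rate == 0 else 1e6 * df["rate"] / total_rate
    return df.drop(columns="rate")


def tpm_lookup(tpm: pd.DataFrame) -> Dict[str, float]:
    return dict(zip(tpm["transcript_id"], tpm["tpm"]))


# ---------------------------------------------------------------------------
# window aggregation, correlation, PCA
# ---------------------------------------------------------------------------

def window_features(
    tracks: Sequence,
    annotation: GenomeAnnotation,
    window: int = 1000,
) -> np.ndarray:
    """Aggregate per-bin tracks to 1-kb exonic windows.

    A window's value is the mean over its exonic bins; windows without any
    exonic bin are excluded. Returns a (n_tracks, n_windows) matrix.
    """
    if not tracks:
        raise ValueError("no tracks")
    bw = tracks[0].bin_width
    if window % bw:
        raise ValueError("window must be a multiple of the bin width")
    wb = window // bw
    mask = annotation.exonic_bin_mask(bw)
    cols: List[np.ndarray] = []
    for chrom in tracks[0].values:
        m = mask[chrom]
        n = len(m)
        nw = -(-n // wb)
        pad = nw * wb - n
        mpad = np.concatenate([m, np.zeros(pad, dtype=bool)]).reshape(nw, wb)
        denom = mpad.sum(axis=1)
        keep = denom > 0
        if not keep.any():
            continue
        per_track = []
        for t in tracks:
            v = np.concatenate([t.values[chrom], np.zeros(pad)]).reshape(nw, wb)
            with np.errstate(invalid="ignore"):
                wv = np.where(keep, (v * mpad).sum(axis=1) / np.maximum(denom, 1), 0.0)
            per_track.append(wv[keep])
        cols.append(np.vstack(per_track))
    return np.hstack(cols)


def pairwise_correlation(
    tracks: Sequence[BinnedTrack],
    annotation: GenomeAnnotation,
    window: int = 1000,
) -> pd.DataFrame:
    """Pearson correlation matrix over 1-kb exonic windows.

    Windows that are zero in every sample are dropped; a zero-variance track
    yields NaN against every other track.
    """
    if len(tracks) < 2:
        raise ValueError("need at least two tracks")
    X = window_features(tracks, annotation, window)
    nonzero = (X != 0).any(axis=0)
    X = X[:, nonzero]
    n = len(tracks)
    r = np.full((n, n), np.nan)
    sd = X.std(axis=1)
    for i in range(n):
        for j in range(i, n):
            if i == j:
                r[i, j] = 1.0
            elif sd[i] > 0 and sd[j] > 0:
                r[i, j] = r[j, i] = float(np.corrcoef(X[i], X[j])[0, 1])
    ids = [t.sample_id or f"track{i}" for i, t in enumerate(tracks)]
    return pd.DataFrame(r, index=ids, columns=ids)


@dataclass
class PCAResult:
    coordinates: pd.DataFrame  # samples x (PC1, PC2)
    variance_explained: Tuple[float, float]


def pca_m6a(
    signal_tracks: Sequence[SignalTrack],
    annotation: GenomeAnnotation,
    window: int = 1000,
) -> PCAResult:
    """Top-2 principal components of per-sample m6A signal over 1-kb exonic
    windows. Component signs are fixed so the largest-magnitude loading is
    positive, making coordinates deterministic."""
    if len(signal_tracks) < 3:
        raise ValueError("PCA needs at least three samples")
    X = window_features(signal_tracks, annotation, window)
    pca = PCA(n_components=2, svd_solver="full")
    coords = pca.fit_transform(X)
    for k in range(2):
        load = pca.components_[k]
        if load[np.argmax(np.abs(load))] < 0:
            coords[:, k] *= -1
    ids = [t.sample_id or f"sample{i}" for i, t in enumerate(signal_tracks)]
    df = pd.DataFrame(coords, index=ids, columns=["PC1", "PC2"])
    ve = tuple(float(v) for v in pca.explained_variance_ratio_[:2])
    return PCAResult(df, ve)
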