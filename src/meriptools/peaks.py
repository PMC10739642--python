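"""Model-based m6A peak identification from IP vs input fragments.

The caller tests each 10-bp bin's IP fragment pileup against a Poisson local
background estimated from the input library: lambda_local is the maximum of
a genome-wide rate and sliding-window rates (fragment scale, 1 kb, 5 kb,
10 kb), all scaled by the IP/input depth ratio. The fragment-scale window
makes the background track point-matched control coverage, so a library
called against itself is never self-enriched. Per-bin upper-tail p-values are corrected by
Benjamini-Hochberg; significant bins are merged into peaks.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage, stats

from .coverage import BinnedTrack, bin_coverage
from .fragments import AlignedFragmentSet, Fragment
from .simulate import M6ASite

logger = logging.getLogger(__name__)


@dataclass
class PeakCallerConfig:
    """Caller parameters.

    effective_genome_size is the mappable-transcriptome size used for the
    genome-wide background rate; None means the summed length of the
    chromosomes actually present.
    """

    effective_genome_size: Optional[int] = None
    q_cutoff: float = 0.05
    bin_width: int = 10
    local_windows: Tuple[int, ...] = (1_000, 5_000, 10_000)
    d_window: int = 50  # near-point control window: floors lambda at local control coverage
    merge_gap: int = 100
    min_peak_length: int = 150

    @property
    def all_windows(self) -> Tuple[int, ...]:
        return ((self.d_window,) if self.d_window else ()) + tuple(self.local_windows)

    def __post_init__(self) -> None:
        if self.effective_genome_size is not None and self.effective_genome_size <= 0:
            raise ValueError("effective_genome_size must be > 0")
        if not (0.0 < self.q_cutoff <= 1.0):
            raise ValueError("q_cutoff must lie in (0, 1]")
        if self.bin_width <= 0:
            raise ValueError("bin_width must be > 0")


@dataclass
class LocalBackground:
    """Expected fragments/bin at one position: genome-wide and window-local
    rates, with lambda_local their maximum."""

    lambda_bg: float
    lambda_windows: Dict[int, float]
    lambda_local: float


@dataclass
class Peak:
    chrom: str
    start: int
    end: int
    summit: int
    pileup: float
    p: float
    q: float
    fold_enrichment: float
    name: str = ""

    @property
    def length(self) -> int:
        return self.end - self.start

    def __post_init__(self) -> None:
        if not (self.start <= self.summit < self.end):
            raise ValueError("summit must lie inside the peak")


def deduplicate(frags: AlignedFragmentSet) -> AlignedFragmentSet:
    """Collapse PCR duplicates: fragments identical in (chrom, start, end,
    strand, blocks) become one. The result is canonically sorted, hence
    independent of input order."""
    unique = sorted(set(frags.fragments))
    return AlignedFragmentSet(
        frags.sample_id, frags.role, frags.condition, frags.replicate, unique
    )


def poisson_upper_tail(k, lam):
    """P(X >= k) for X ~ Poisson(lam); stable for large lam.

    Accepts scalars or arrays.
    """
    k_arr = np.asarray(k)
    lam_arr = np.asarray(lam, dtype=float)
    if np.any(lam_arr <= 0):
        raise ValueError("lambda must be > 0")
    if np.any(k_arr < 0):
        raise ValueError("k must be >= 0")
    p = stats.poisson.sf(k_arr - 1, lam_arr)
    return float(p) if np.isscalar(k) and np.isscalar(lam) else p


def bh_qvalues(p: Sequence[float]) -> np.ndarray:
    """Step-up Benjamini-Hochberg adjusted values with enforced monotonicity;
    ties are handled stably."""
    p_arr = np.asarray(p, dtype=float)
    if p_arr.ndim != 1:
        raise ValueError("p must be one-dimensional")
    if len(p_arr) == 0:
        return np.array([])
    if np.any((p_arr < 0) | (p_arr > 1)) or np.any(np.isnan(p_arr)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p_arr)
    order = np.argsort(p_arr, kind="mergesort")
    q_sorted = p_arr[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


# ---------------------------------------------------------------------------
# local background
# ---------------------------------------------------------------------------

def _sliding_mean(x: np.ndarray, size_bins: int) -> np.ndarray:
    """Mean of x over a centered window of 2*(size_bins//2)+1 bins,
    normalized by the in-bounds part of the window (chromosome edges do not
    dilute the estimate)."""
    half = size_bins // 2
    if 2 * half + 1 >= len(x):
        return np.full_like(x, x.mean(), dtype=float)
    kernel = np.ones(2 * half + 1)
    num = np.convolve(x, kernel, mode="same")
    den = np.convolve(np.ones_like(x, dtype=float), kernel, mode="same")
    return num / den


def _lambda_bg(inp_counts: BinnedTrack, cfg: PeakCallerConfig,
               chrom_lengths: Mapping[str, int], depth_ratio: float) -> float:
    G = cfg.effective_genome_size or sum(chrom_lengths.values())
    total_bin_count = inp_counts.total()  # = fragments x mean bins/fragment
    return depth_ratio * total_bin_count / (G / cfg.bin_width)


def _lambda_local_tracks(
    inp_counts: BinnedTrack,
    cfg: PeakCallerConfig,
    chrom_lengths: Mapping[str, int],
    depth_ratio: float,
) -> Dict[str, np.ndarray]:
    lam_bg = _lambda_bg(inp_counts, cfg, chrom_lengths, depth_ratio)
    out: Dict[str, np.ndarray] = {}
    for chrom, counts in inp_counts.values.items():
        lam = np.full(len(counts), lam_bg)
        for w in cfg.all_windows:
            lam = np.maximum(lam, depth_ratio * _sliding_mean(counts, w // cfg.bin_width))
        out[chrom] = lam
    return out


def local_lambda(
    inp_counts: BinnedTrack,
    chrom: str,
    position: int,
    cfg: PeakCallerConfig,
    depth_ratio: float,
    chrom_lengths: Mapping[str, int],
) -> LocalBackground:
    """Local Poisson background (fragments/bin) at one genomic position.

    Window rates are the mean per-bin fragment-overlap count over the
    centered window, scaled by the depth ratio; lambda_local is the maximum
    of these and the genome-wide rate.
    """
    if depth_ratio <= 0:
        raise ValueError("depth_ratio must be > 0")
    lam_bg = _lambda_bg(inp_counts, cfg, chrom_lengths, depth_ratio)
    counts = inp_counts.values[chrom]
    b = position // cfg.bin_width
    lam_w: Dict[int, float] = {}
    for w in cfg.all_windows:
        half = (w // cfg.bin_width) // 2
        lo, hi = max(0, b - half), min(len(counts), b + half + 1)
        lam_w[w] = depth_ratio * float(counts[lo:hi].mean())
    return LocalBackground(lam_bg, lam_w, max(lam_bg, *lam_w.values()))


# ---------------------------------------------------------------------------
# calling
# ---------------------------------------------------------------------------

def call_peaks(
    ip: AlignedFragmentSet,
    inp: AlignedFragmentSet,
    cfg: PeakCallerConfig,
    chrom_lengths: Mapping[str, int],
) -> List[Peak]:
    """Call enriched intervals from deduplicated IP and input fragments.

    Per bin: IP pileup vs Poisson(lambda_local) upper tail; BH over all bins
    with nonzero pileup; bins with q below the cutoff merged when their gap
    is at most merge_gap; merged intervals shorter than min_peak_length are
    dropped. Peak p/q come from the minimum-p bin, the summit is the center
    of the maximum-pileup bin (leftmost on ties). Spike-in contigs are
    processed like chromosomes.
    """
    if len(ip) == 0:
        warnings.warn("empty IP fragment set: no peaks")
        return []
    if len(inp) == 0:
        warnings.warn(
            "empty input library: background from IP totals over the "
            "effective genome size"
        )
    bw = cfg.bin_width
    ip_counts = bin_coverage(ip, chrom_lengths, bw, normalize="counts")
    if len(inp) > 0:
        inp_counts = bin_coverage(inp, chrom_lengths, bw, normalize="counts")
        depth_ratio = len(ip) / len(inp)
        lam = _lambda_local_tracks(inp_counts, cfg, chrom_lengths, depth_ratio)
    else:
        # uniform prior from IP totals across the effective genome
        lam_bg = _lambda_bg(ip_counts, cfg, chrom_lengths, depth_ratio=1.0)
        lam = {c: np.full(len(v), lam_bg) for c, v in ip_counts.values.items()}

    chroms, bins, ks, lams = [], [], [], []
    for chrom, counts in ip_counts.values.items():
        nz = np.flatnonzero(counts > 0)
        if len(nz) == 0:
            continue
        chroms.append(chrom)
        bins.append(nz)
        ks.append(counts[nz])
        lams.append(np.maximum(lam[chrom][nz], 1e-12))
    if not bins:
        return []
    k_all = np.concatenate(ks)
    lam_all = np.concatenate(lams)
    p_all = poisson_upper_tail(k_all, lam_all)
    q_all = bh_qvalues(p_all)

    peaks: List[Peak] = []
    offset = 0
    for chrom, nz, k in zip(chroms, bins, ks):
        n = len(nz)
        p = p_all[offset : offset + n]
        q = q_all[offset : offset + n]
        offset += n
        sig = q < cfg.q_cutoff
        if not sig.any():
            continue
        sig_bins = nz[sig]
        sig_p = p[sig]
        sig_q = q[sig]
        counts = ip_counts.values[chrom]
        lam_c = lam[chrom]
        # merge significant bins whose gap is <= merge_gap
        breaks = np.flatnonzero((sig_bins[1:] - sig_bins[:-1] - 1) * bw > cfg.merge_gap)
        groups = np.split(np.arange(len(sig_bins)), breaks + 1)
        for g in groups:
            b0, b1 = int(sig_bins[g[0]]), int(sig_bins[g[-1]])
            start, end = b0 * bw, min((b1 + 1) * bw, chrom_lengths[chrom])
            if end - start < cfg.min_peak_length:
                continue
            member_bins = sig_bins[g]
            pile = counts[member_bins]
            best = int(member_bins[np.argmax(pile)])  # leftmost max
            summit = min(best * bw + bw // 2, end - 1)
            i_min = int(np.argmin(sig_p[g]))
            peaks.append(
                Peak(
                    chrom=chrom,
                    start=start,
                    end=end,
                    summit=summit,
                    pileup=float(pile.max()),
                    p=float(sig_p[g][i_min]),
                    q=float(sig_q[g][i_min]),
                    fold_enrichment=float(counts[best] / max(lam_c[best], 1e-12)),
                )
            )
    peaks.sort(key=lambda pk: (pk.chrom, pk.start))
    for i, pk in enumerate(peaks):
        pk.name = f"peak_{i + 1}"
    return peaks


def evaluate_peak_calls(
    peaks: Sequence[Peak],
    sites: Sequence[M6ASite],
    tolerance_bp: int = 200,
) -> Tuple[float, float]:
    """(recall, precision) of peak summits against planted sites.

    A site is recovered if some summit on its chromosome lies within
    tolerance_bp; a peak is a true positive if its summit lies within
    tolerance_bp of some site.
    """
    if not sites:
        return (float("nan"), 0.0 if peaks else float("nan"))
    site_pos: Dict[str, np.ndarray] = {}
    for s in sites:
        site_pos.setdefault(s.chrom, []).append(s.position)
    site_pos = {c: np.sort(np.asarray(v)) for c, v in site_pos.items()}
    summits: Dict[str, np.ndarray] = {}
    for pk in peaks:
        summits.setdefault(pk.chrom, []).append(pk.summit)
    summits = {c: np.sort(np.asarray(v)) for c, v in summits.items()}

    def hit(pos: int, arr: Optional[np.ndarray]) -> bool:
        if arr is None or len(arr) == 0:
            return False
        i = np.searchsorted(arr, pos)
        best = min(
            abs(int(arr[j]) - pos) for j in (max(i - 1, 0), min(i, len(arr) - 1))
        )
        return best <= tolerance_bp

    recovered = sum(hit(s.position, summits.get(s.chrom)) for s in sites)
    recall = recovered / len(sites)
    if not peaks:
        return recall, float("nan")
    tp = sum(hit(pk.summit, site_pos.get(pk.chrom)) for pk in peaks)
    return recall, tp / len(peaks)
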