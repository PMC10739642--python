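"""Replicate overlap, downsampling saturation, q-value robustness sweeps and
spike-in false-discovery assessment."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .annotate import FeatureIndex
from .fragments import AlignedFragmentSet
from .genome import GenomeAnnotation
from .motif import deduce_strand, scan_rrach
from .peaks import Peak, PeakCallerConfig, call_peaks

SWEEP_CUTOFFS = (0.05, 1e-5, 1e-20, 1e-50, 1e-100)


def overlap_fraction(
    query_peaks: Sequence[Peak],
    reference_peaks: Sequence[Peak],
    summit_in_peak: bool = False,
) -> Optional[float]:
    """Fraction of query peaks overlapping (>=1 bp) any reference peak.

    Asymmetric by design. With ``summit_in_peak`` a query peak counts only if
    its summit falls inside a reference peak. Empty query -> None (missing).
    """
    if not query_peaks:
        return None
    ref: Dict[str, List[Tuple[int, int]]] = {}
    for pk in reference_peaks:
        ref.setdefault(pk.chrom, []).append((pk.start, pk.end))
    starts_ends = {
        c: (np.array(sorted(s for s, _ in ivs)), sorted(ivs))
        for c, ivs in ref.items()
    }
    n_hit = 0
    for pk in query_peaks:
        ivs = ref.get(pk.chrom)
        if not ivs:
            continue
        q = (pk.summit, pk.summit + 1) if summit_in_peak else (pk.start, pk.end)
        if any(s < q[1] and q[0] < e for s, e in ivs):
            n_hit += 1
    return n_hit / len(query_peaks)


def downsample_saturation(
    ip: AlignedFragmentSet,
    inp: AlignedFragmentSet,
    fractions: Sequence[float],
    n_seeds: int,
    cfg: PeakCallerConfig,
    chrom_lengths: Mapping[str, int],
    base_seed: int = 0,
) -> pd.DataFrame:
    """Peak counts after subsampling both libraries without replacement.

    One row per (fraction, seed); fraction 1.0 reproduces the full call.
    """
    rows = []
    full_peaks = call_peaks(ip, inp, cfg, chrom_lengths)
    for fi, frac in enumerate(fractions):
        if not 0.0 < frac <= 1.0:
            raise ValueError("fractions must lie in (0, 1]")
        for seed_i in range(n_seeds):
            if frac == 1.0:
                n_peaks = len(full_peaks)
            else:
                rng = np.random.default_rng([base_seed, fi, seed_i])
                n_ip = int(round(frac * len(ip)))
                n_inp = int(round(frac * len(inp)))
                if n_ip < 1 or n_inp < 1:
                    raise ValueError(f"fraction {frac} leaves < 1 fragment")
                sub_ip = ip.subset(rng.choice(len(ip), size=n_ip, replace=False))
                sub_inp = inp.subset(rng.choice(len(inp), size=n_inp, replace=False))
                n_peaks = len(call_peaks(sub_ip, sub_inp, cfg, chrom_lengths))
            rows.append((frac, seed_i, n_peaks))
    return pd.DataFrame(rows, columns=["fraction", "seed", "n_peaks"])


@dataclass
class SweepRow:
    q_cutoff: float
    n_peaks: int
    frac_rrach: float
    frac_stop3utr: float
    frac_replicated: Optional[float]
    frac_vs_reference: Optional[float]


def _peak_class_fractions(
    peaks: Sequence[Peak],
    genome: Mapping[str, str],
    annotation: GenomeAnnotation,
    tpm: Mapping[str, float],
    index: Optional[FeatureIndex] = None,
) -> Tuple[float, float]:
    """(RRACH fraction over strand-resolved peaks, stop-codon/3'UTR fraction)."""
    index = index or FeatureIndex(annotation)
    n_scanned = n_rrach = 0
    n_stop3 = 0
    for pk in peaks:
        strand = deduce_strand(pk.chrom, pk.summit, annotation, tpm)
        if strand is not None:
            has, _ = scan_rrach(genome, pk.chrom, pk.summit, strand)
            n_scanned += 1
            n_rrach += int(has)
        if index.assign(pk.chrom, pk.summit).feature in ("stop_codon", "utr3"):
            n_stop3 += 1
    frac_rrach = n_rrach / n_scanned if n_scanned else float("nan")
    frac_stop3 = n_stop3 / len(peaks) if peaks else float("nan")
    return frac_rrach, frac_stop3


def qvalue_sweep(
    ip: AlignedFragmentSet,
    inp: AlignedFragmentSet,
    replicate2_peaks: Optional[Sequence[Peak]],
    reference_peaks: Optional[Sequence[Peak]],
    genome: Mapping[str, str],
    annotation: GenomeAnnotation,
    tpm: Mapping[str, float],
    cfg: PeakCallerConfig,
    chrom_lengths: Mapping[str, int],
    cutoffs: Sequence[float] = SWEEP_CUTOFFS,
) -> pd.DataFrame:
    """Evaluation factors across significance cutoffs.

    Peaks are called once at the loosest cutoff (a single BH pass); stricter
    rows filter that call by peak q-value, so no cutoff-dependent re-ranking
    occurs.
    """
    cutoffs = sorted(cutoffs, reverse=True)
    base_cfg = PeakCallerConfig(
        effective_genome_size=cfg.effective_genome_size,
        q_cutoff=max(cutoffs),
        bin_width=cfg.bin_width,
        local_windows=cfg.local_windows,
        merge_gap=cfg.merge_gap,
        min_peak_length=cfg.min_peak_length,
    )
    base = call_peaks(ip, inp, base_cfg, chrom_lengths)
    index = FeatureIndex(annotation)
    rows = []
    for c in cutoffs:
        peaks_c = [pk for pk in base if pk.q < c]
        frac_rrach, frac_stop3 = _peak_class_fractions(
            peaks_c, genome, annotation, tpm, index
        )
        frac_rep = (
            overlap_fraction(peaks_c, replicate2_peaks)
            if replicate2_peaks is not None else None
        )
        frac_ref = (
            overlap_fraction(peaks_c, reference_peaks)
            if reference_peaks is not None else None
        )
        rows.append(
            SweepRow(c, len(peaks_c), frac_rrach, frac_stop3, frac_rep, frac_ref)
        )
    return pd.DataFrame([r.__dict__ for r in rows])


def shared_vs_unique(
    peaks_rep1: Sequence[Peak],
    peaks_rep2: Sequence[Peak],
    genome: Mapping[str, str],
    annotation: GenomeAnnotation,
    tpm: Mapping[str, float],
) -> pd.DataFrame:
    """Replicate-1 peaks partitioned into shared (>=1 bp overlap with
    replicate 2) vs unique, with RRACH and stop-codon/3'UTR fractions per
    class."""
    ref = [(pk.chrom, pk.start, pk.end) for pk in peaks_rep2]
    shared: List[Peak] = []
    unique: List[Peak] = []
    for pk in peaks_rep1:
        if any(c == pk.chrom and s < pk.end and pk.start < e for c, s, e in ref):
            shared.append(pk)
        else:
            unique.append(pk)
    index = FeatureIndex(annotation)
    rows = []
    for name, cls in (("shared", shared), ("unique", unique)):
        frac_rrach, frac_stop3 = _peak_class_fractions(
            cls, genome, annotation, tpm, index
        )
        rows.append((name, len(cls), frac_rrach, frac_stop3))
    return pd.DataFrame(
        rows, columns=["class", "n_peaks", "frac_rrach", "frac_stop3utr"]
    )


def spikein_fdr(
    peaks: Sequence[Peak], spikein_status: Mapping[str, bool]
) -> Tuple[int, int]:
    """(peaks on modified spike-in contigs, peaks on unmodified ones)."""
    if not spikein_status:
        raise ValueError("no spike-in contigs declared")
    n_mod = sum(
        1 for pk in peaks if spikein_status.get(pk.chrom) is True
    )
    n_unmod = sum(
        1 for pk in peaks if spikein_status.get(pk.chrom) is False
    )
    return n_mod, n_unmod


def venn_counts(
    peaks_a: Sequence[Peak], peaks_b: Sequence[Peak]
) -> Dict[str, int]:
    """Pairwise overlap summary: A-only, B-only, both (>=1 bp criterion)."""
    ref_b = [(pk.chrom, pk.start, pk.end) for pk in peaks_b]
    ref_a = [(pk.chrom, pk.start, pk.end) for pk in peaks_a]

    def hits(pk: Peak, ref) -> bool:
        return any(c == pk.chrom and s < pk.end and pk.start < e for c, s, e in ref)

    both_a = sum(hits(pk, ref_b) for pk in peaks_a)
    both_b = sum(hits(pk, ref_a) for pk in peaks_b)
    return {
        "a_only": len(peaks_a) - both_a,
        "b_only": len(peaks_b) - both_b,
        "both": both_a,
    }
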