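"""Synthetic MeRIP-seq study generator.

Produces toy genomes with 5'UTR–CDS–3'UTR gene models on both strands,
plants m6A sites on RRACH motifs with a stop-codon-proximal bias and
per-site stoichiometry, simulates IP/input aligned fragments with antibody
enrichment over a nonspecific background, carries modified/unmodified
spike-in contigs and retrotransposon loci through the same machinery, and
emits qPCR Ct tables from a delta-Ct model.

All randomness derives from one integer seed via named substreams, so each
stage is independently reproducible.

The generated sequence has its background RRACH occurrences scrubbed and a
controlled number of RRACH candidates injected into exons. This gives the
simulation a defined motif density: planted sites always sit on an RRACH A,
while random exonic background windows are only sometimes motif-positive —
the contrast that motif-enrichment testing measures.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Mapping, NamedTuple, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .fragments import AlignedFragmentSet, Fragment, ROLE_INPUT, ROLE_IP
from .genome import GenomeAnnotation, RetroLocus, Transcript, revcomp

# motif on the transcript strand: R R A C H, methylated A at offset 2
RRACH_FWD = re.compile(r"(?=[AG][AG]AC[ACT])")
# genomic plus-strand pattern whose minus-strand reading is RRACH
RRACH_REV = re.compile(r"(?=[AGT]GT[CT][CT])")

_STREAMS = {
    "annotation": 0,
    "sites": 1,
    "fragments": 2,
    "qpcr": 3,
    "expression": 4,
    "background": 5,
}

CENSORED_CT = float("nan")


def substream(seed: int, name: str, *extra: int) -> np.random.Generator:
    """Named, independent random substream derived from the master seed."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(_STREAMS[name], *extra)))


class SimulationSizingError(ValueError):
    """Requested gene/repeat content exceeds genome capacity."""


class MotifDeficitError(ValueError):
    """Too few RRACH candidates to plant the requested number of sites."""


class RetroSubfamilySpec(NamedTuple):
    name: str
    consensus_length: int
    n_loci: int
    methylated: bool


@dataclass
class SimConfig:
    """Study conditions for the synthetic generator.

    Defaults describe the default benchmark simulation: ~300 genes over a
    1.2-Mb two-chromosome genome, 200 planted m6A sites with stoichiometry
    0.5–1.0, 8x IP enrichment over a 10% nonspecific background, and
    2x10^5 fragments per library.
    """

    seed: int = 1
    n_chroms: int = 2
    chrom_length_bp: int = 600_000
    n_genes: int = 300
    utr5_len_range: Tuple[int, int] = (100, 200)
    cds_len_range: Tuple[int, int] = (900, 1500)
    utr3_len_range: Tuple[int, int] = (300, 600)
    exons_per_gene_range: Tuple[int, int] = (1, 3)
    intron_len_range: Tuple[int, int] = (100, 500)
    gene_gap_range: Tuple[int, int] = (200, 2000)
    expression_lognormal_mu_sigma: Tuple[float, float] = (0.0, 1.0)
    n_m6a_sites: int = 200
    stop_codon_bias: float = 0.7
    stop_proximal_max_bp: int = 400
    stop_proximal_sd_bp: float = 150.0
    stoichiometry_range: Tuple[float, float] = (0.5, 1.0)
    fragment_length_mean_sd: Tuple[float, float] = (150.0, 30.0)
    min_fragment_length: int = 30
    n_fragments_per_sample: int = 200_000
    ip_enrichment_factor: float = 8.0
    background_binding_rate: float = 0.1
    spikein_lengths: Tuple[int, int] = (600, 600)
    spikein_names: Tuple[str, str] = ("GLuc", "CLuc")  # (modified, unmodified)
    spikein_expression_quantile: float = 0.8
    rrach_per_gene_stop: int = 2
    rrach_per_gene_distal: int = 2
    rrach_per_spikein: int = 4
    rrach_per_retro_locus: int = 3
    retro_subfamilies: Tuple[RetroSubfamilySpec, ...] = (
        RetroSubfamilySpec("MTA", 500, 20, True),
        RetroSubfamilySpec("L1Md_A", 600, 20, False),
    )
    conditions: int = 1
    replicates: int = 2
    qpcr_intercept: float = 20.0
    qpcr_ct_sd: float = 0.0

    def __post_init__(self) -> None:
        self.retro_subfamilies = tuple(
            RetroSubfamilySpec(*spec) for spec in self.retro_subfamilies
        )
        self.validate()

    def validate(self) -> None:
        positive = {
            "n_chroms": self.n_chroms,
            "chrom_length_bp": self.chrom_length_bp,
            "n_genes": self.n_genes,
        }
        for name, v in positive.items():
            if v <= 0:
                raise ValueError(f"{name} must be > 0, got {v}")
        for name, rng_ in (
            ("utr5_len_range", self.utr5_len_range),
            ("cds_len_range", self.cds_len_range),
            ("utr3_len_range", self.utr3_len_range),
        ):
            if rng_[0] <= 0 or rng_[1] < rng_[0]:
                raise ValueError(f"bad {name}: {rng_}")
        if not 0.0 <= self.stop_codon_bias <= 1.0:
            raise ValueError("stop_codon_bias must lie in [0, 1]")
        if not 0.0 <= self.background_binding_rate <= 1.0:
            raise ValueError("background_binding_rate must lie in [0, 1]")
        lo, hi = self.stoichiometry_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("stoichiometry_range must lie in [0, 1]")
        if self.ip_enrichment_factor < 1.0:
            raise ValueError("ip_enrichment_factor must be >= 1")
        if self.n_fragments_per_sample < 0 or self.n_m6a_sites < 0:
            raise ValueError("counts must be non-negative")


class M6ASite(NamedTuple):
    chrom: str
    position: int  # genomic coordinate of the methylated A (0-based)
    strand: str
    transcript_id: str
    stoichiometry: float
    tx_position: int  # transcript coordinate of the A


@dataclass
class SyntheticTruth:
    """Registry of planted modifications against which recovery is scored."""

    sites: List[M6ASite] = field(default_factory=list)  # gene-transcript sites
    spikein_sites: List[M6ASite] = field(default_factory=list)
    retro_sites: List[M6ASite] = field(default_factory=list)
    spikein_status: Dict[str, bool] = field(default_factory=dict)
    retro_truth: Dict[str, bool] = field(default_factory=dict)

    @property
    def all_sites(self) -> List[M6ASite]:
        return self.sites + self.spikein_sites + self.retro_sites

    def sites_by_unit(self) -> Dict[str, List[M6ASite]]:
        by_unit: Dict[str, List[M6ASite]] = {}
        for s in self.all_sites:
            by_unit.setdefault(s.transcript_id, []).append(s)
        return by_unit

    def to_frame(self) -> pd.DataFrame:
        rows = [
            s._asdict() | {"registry": reg}
            for reg, sites in (
                ("gene", self.sites),
                ("spikein", self.spikein_sites),
                ("retro", self.retro_sites),
            )
            for s in sites
        ]
        return pd.DataFrame(
            rows,
            columns=["chrom", "position", "strand", "transcript_id",
                     "stoichiometry", "tx_position", "registry"],
        )


# ---------------------------------------------------------------------------
# annotation + sequence
# ---------------------------------------------------------------------------

_BASES = np.frombuffer(b"ACGT", dtype="S1")


def _scrub_rrach(arr: np.ndarray, rng: np.random.Generator) -> None:
    """Destroy every RRACH occurrence (either strand) in a base array.

    Mutates a motif-invariant position; iterates with randomized replacement
    bases because a substitution can complete an overlapping motif.
    """
    fwd_repl = np.frombuffer(b"GT", dtype="S1")  # anything but the core C
    rev_repl = np.frombuffer(b"AC", dtype="S1")  # anything but the core T
    for _ in range(100):
        seq = arr.tobytes().decode()
        dirty = False
        for m in RRACH_FWD.finditer(seq):
            arr[m.start() + 3] = fwd_repl[rng.integers(2)]
            dirty = True
        if dirty:
            seq = arr.tobytes().decode()
        for m in RRACH_REV.finditer(seq):
            arr[m.start() + 2] = rev_repl[rng.integers(2)]
            dirty = True
        if not dirty:
            return
    raise RuntimeError("RRACH scrubbing failed to converge")


def _random_partition(rng: np.random.Generator, total: int, k: int, minimum: int) -> List[int]:
    """Split `total` into k parts each >= minimum."""
    if k == 1 or total < k * minimum:
        return [total]
    cuts = np.sort(rng.choice(total - k * minimum + k - 1, size=k - 1, replace=False))
    parts = np.diff(np.concatenate([[0], cuts + 1, [total - k * minimum + k - 1 + 1]]))
    return [int(p) - 1 + minimum for p in parts]


def generate_annotation(cfg: SimConfig) -> Tuple[GenomeAnnotation, Dict[str, str]]:
    """Build a toy genome: gene models, retro loci, spike-ins and sequence.

    Returns the annotation plus per-contig sequence. Exons carry injected
    RRACH candidates (stop-proximal and distal); all other RRACH occurrences
    are scrubbed from the sequence.
    """
    rng = substream(cfg.seed, "annotation")
    chroms = [f"chr{i + 1}" for i in range(cfg.n_chroms)]
    chrom_lengths = {c: cfg.chrom_length_bp for c in chroms}

    # --- lay out genes and retro loci along chromosomes ------------------
    cursors = {c: 0 for c in chroms}

    def place(span: int) -> Tuple[str, int]:
        order = sorted(chroms, key=lambda c: cursors[c])
        for c in order:
            gap = int(rng.integers(cfg.gene_gap_range[0], cfg.gene_gap_range[1] + 1))
            start = cursors[c] + gap
            if start + span <= chrom_lengths[c]:
                cursors[c] = start + span
                return c, start
        raise SimulationSizingError(
            f"cannot place a {span}-bp unit: genome capacity exhausted "
            f"({cfg.n_genes} genes on {cfg.n_chroms} x {cfg.chrom_length_bp} bp)"
        )

    transcripts: Dict[str, Transcript] = {}
    for i in range(cfg.n_genes):
        u5 = int(rng.integers(cfg.utr5_len_range[0], cfg.utr5_len_range[1] + 1))
        cds = int(rng.integers(cfg.cds_len_range[0], cfg.cds_len_range[1] + 1))
        cds -= cds % 3
        u3 = int(rng.integers(cfg.utr3_len_range[0], cfg.utr3_len_range[1] + 1))
        tx_len = u5 + cds + u3
        k = int(rng.integers(cfg.exons_per_gene_range[0], cfg.exons_per_gene_range[1] + 1))
        exon_lens = _random_partition(rng, tx_len, k, minimum=100)
        intron_lens = [
            int(rng.integers(cfg.intron_len_range[0], cfg.intron_len_range[1] + 1))
            for _ in range(len(exon_lens) - 1)
        ]
        span = sum(exon_lens) + sum(intron_lens)
        strand = "+" if rng.random() < 0.5 else "-"
        chrom, gstart = place(span)
        exons = []
        pos = gstart
        for j, el in enumerate(exon_lens):
            exons.append((pos, pos + el))
            pos += el
            if j < len(intron_lens):
                pos += intron_lens[j]
        # exon_lens are in transcript order; on the minus strand the first
        # transcript exon is the genomically rightmost one
        if strand == "-":
            lens_rev = exon_lens[::-1]
            exons = []
            pos = gstart
            for j, el in enumerate(lens_rev):
                exons.append((pos, pos + el))
                pos += el
                if j < len(intron_lens):
                    pos += intron_lens[j]
        tid = f"tx{i:04d}"
        transcripts[tid] = Transcript(
            transcript_id=tid,
            gene_id=f"gene{i:04d}",
            chrom=chrom,
            strand=strand,
            exons=tuple(exons),
            utr5_len=u5,
            cds_len=cds,
            utr3_len=u3,
        )

    retro_loci: List[RetroLocus] = []
    for spec in cfg.retro_subfamilies:
        for j in range(spec.n_loci):
            strand = "+" if rng.random() < 0.5 else "-"
            chrom, gstart = place(spec.consensus_length)
            retro_loci.append(
                RetroLocus(chrom, gstart, gstart + spec.consensus_length,
                           strand, spec.name, spec.consensus_length)
            )

    # --- spike-in contigs as single-exon transcripts ----------------------
    for name, length in zip(cfg.spikein_names, cfg.spikein_lengths):
        chrom_lengths[name] = length
        transcripts[name] = Transcript(
            transcript_id=name,
            gene_id=name,
            chrom=name,
            strand="+",
            exons=((0, length),),
            biotype="spikein",
        )

    # --- sequence ---------------------------------------------------------
    seqs: Dict[str, np.ndarray] = {
        c: _BASES[rng.integers(0, 4, size=n)].copy() for c, n in chrom_lengths.items()
    }

    # annotate-then-write stop codons as TAA, then scrub background motifs
    for tx in transcripts.values():
        if tx.is_coding:
            stop = "TAA" if tx.strand == "+" else revcomp("TAA")
            # stop codon occupies up to two blocks when split by an intron
            offset = 0
            blocks = tx.stop_codon_blocks()
            if tx.strand == "-":
                # genomic order of the codon bases is reversed on minus
                codon = revcomp("TAA")
                pos = 0
                for s, e in blocks:
                    for g in range(s, e):
                        seqs[tx.chrom][g] = codon[pos].encode()
                        pos += 1
            else:
                pos = 0
                for s, e in blocks:
                    for g in range(s, e):
                        seqs[tx.chrom][g] = "TAA"[pos].encode()
                        pos += 1
    for c in seqs:
        _scrub_rrach(seqs[c], rng)

    # --- inject RRACH candidates ------------------------------------------
    used: Dict[str, List[Tuple[int, int]]] = {c: [] for c in chrom_lengths}

    def write_motif(chrom: str, gstart: int, strand: str) -> bool:
        for s, e in used[chrom]:
            if gstart < e + 1 and gstart + 5 > s - 1:
                return False
        r1, r2 = rng.choice(["A", "G"], size=2)
        h = rng.choice(["A", "C", "T"])
        motif = f"{r1}{r2}AC{h}"
        if strand == "-":
            motif = revcomp(motif)
        for k, b in enumerate(motif):
            seqs[chrom][gstart + k] = b.encode()
        used[chrom].append((gstart, gstart + 5))
        return True

    def inject_tx(tx: Transcript, tx_pos: int) -> bool:
        tx_pos = int(np.clip(tx_pos, 0, tx.exonic_length - 5))
        blocks = tx.tx_interval_to_blocks(tx_pos, tx_pos + 5)
        if len(blocks) != 1:  # candidate must not straddle a junction
            return False
        return write_motif(tx.chrom, blocks[0][0], tx.strand)

    for tx in transcripts.values():
        if tx.biotype == "spikein":
            continue
        stop_lo, stop_hi = tx.stop_codon_tx_interval
        center = (stop_lo + stop_hi) // 2
        placed = 0
        for _ in range(40):
            if placed >= cfg.rrach_per_gene_stop:
                break
            off = int(round(rng.normal(0.0, cfg.stop_proximal_sd_bp)))
            off = int(np.clip(off, -cfg.stop_proximal_max_bp + 10, cfg.stop_proximal_max_bp - 10))
            if inject_tx(tx, center + off):
                placed += 1
        placed = 0
        for _ in range(60):
            if placed >= cfg.rrach_per_gene_distal:
                break
            tx_pos = int(rng.integers(0, tx.exonic_length - 5))
            if abs(tx_pos + 2 - center) <= cfg.stop_proximal_max_bp + 50:
                continue
            if inject_tx(tx, tx_pos):
                placed += 1

    modified_spikein = cfg.spikein_names[0]
    tx = transcripts[modified_spikein]
    for j in range(cfg.rrach_per_spikein):
        # evenly spread, jittered
        base = int((j + 0.5) * tx.exonic_length / cfg.rrach_per_spikein)
        for _ in range(20):
            pos = base + int(rng.integers(-20, 21))
            if 0 <= pos <= tx.exonic_length - 5 and inject_tx(tx, pos):
                break

    for locus in retro_loci:
        spec = next(s for s in cfg.retro_subfamilies if s.name == locus.subfamily)
        if not spec.methylated:
            continue
        for j in range(cfg.rrach_per_retro_locus):
            base = locus.start + int((j + 0.5) * locus.length / cfg.rrach_per_retro_locus)
            for _ in range(20):
                pos = base + int(rng.integers(-20, 21))
                if locus.start <= pos <= locus.end - 5 and write_motif(locus.chrom, pos, locus.strand):
                    break

    genome = {c: arr.tobytes().decode() for c, arr in seqs.items()}
    annotation = GenomeAnnotation(
        chrom_lengths=chrom_lengths,
        transcripts=transcripts,
        retro_loci=retro_loci,
        spikein_contigs=tuple(cfg.spikein_names),
    )
    return annotation, genome


# ---------------------------------------------------------------------------
# site planting
# ---------------------------------------------------------------------------

def rrach_candidates(
    annotation: GenomeAnnotation, genome: Mapping[str, str]
) -> pd.DataFrame:
    """All RRACH As in exons of gene transcripts, with stop-proximity flags."""
    rows = []
    for tx in annotation.transcripts.values():
        if tx.biotype != "protein_coding":
            continue
        seq = tx.spliced_sequence(genome)
        stop_lo, stop_hi = tx.stop_codon_tx_interval
        for m in RRACH_FWD.finditer(seq):
            if len(tx.tx_interval_to_blocks(m.start(), m.start() + 5)) != 1:
                continue  # junction-spanning pentamer: no genomic-space motif
            tx_a = m.start() + 2
            dist = max(stop_lo - tx_a, tx_a - (stop_hi - 1), 0)
            rows.append(
                (tx.chrom, tx.tx_to_genome(tx_a), tx.strand, tx.transcript_id,
                 tx_a, dist <= 400)
            )
    return pd.DataFrame(
        rows, columns=["chrom", "position", "strand", "transcript_id",
                       "tx_position", "stop_proximal"]
    )


def plant_m6a_sites(
    annotation: GenomeAnnotation,
    genome: Mapping[str, str],
    cfg: SimConfig,
    seed: Optional[int] = None,
    exclude: FrozenSet[Tuple[str, int]] = frozenset(),
    stream_index: int = 0,
) -> SyntheticTruth:
    """Select m6A sites among exonic RRACH candidates.

    A fraction ~``stop_codon_bias`` of sites (binomially drawn) falls within
    400 bp of a stop codon; stoichiometry is uniform over
    ``stoichiometry_range``. Spike-in and methylated-retro sites are planted
    in separate registries. ``exclude`` removes candidate positions (used to
    build disjoint site sets across conditions).
    """
    rng = substream(seed if seed is not None else cfg.seed, "sites", stream_index)
    truth = SyntheticTruth()

    cands = rrach_candidates(annotation, genome)
    if exclude:
        keep = [
            (c, p) not in exclude
            for c, p in zip(cands["chrom"], cands["position"])
        ]
        cands = cands[keep]

    n = cfg.n_m6a_sites
    if n > 0:
        prox = cands[cands["stop_proximal"]].reset_index(drop=True)
        dist = cands[~cands["stop_proximal"]].reset_index(drop=True)
        n_prox = int(rng.binomial(n, cfg.stop_codon_bias))
        n_dist = n - n_prox
        if n_prox > len(prox) or n_dist > len(dist):
            raise MotifDeficitError(
                f"need {n_prox} stop-proximal and {n_dist} distal RRACH candidates "
                f"but only {len(prox)} and {len(dist)} are available"
            )
        lo, hi = cfg.stoichiometry_range
        chosen = pd.concat(
            [
                prox.iloc[rng.choice(len(prox), size=n_prox, replace=False)],
                dist.iloc[rng.choice(len(dist), size=n_dist, replace=False)],
            ],
            ignore_index=True,
        )
        stoich = rng.uniform(lo, hi, size=len(chosen))
        for row, st in zip(chosen.itertuples(index=False), stoich):
            truth.sites.append(
                M6ASite(row.chrom, int(row.position), row.strand,
                        row.transcript_id, float(st), int(row.tx_position))
            )

    # spike-ins: every RRACH on the modified contig, stoichiometry 1
    modified, unmodified = cfg.spikein_names
    truth.spikein_status = {modified: True, unmodified: False}
    tx = annotation.transcripts[modified]
    seq = tx.spliced_sequence(genome)
    for m in RRACH_FWD.finditer(seq):
        tx_a = m.start() + 2
        truth.spikein_sites.append(
            M6ASite(tx.chrom, tx.tx_to_genome(tx_a), tx.strand,
                    tx.transcript_id, 1.0, tx_a)
        )

    # retrotransposons: every RRACH on loci of methylated subfamilies
    truth.retro_truth = {s.name: s.methylated for s in cfg.retro_subfamilies}
    lo, hi = cfg.stoichiometry_range
    for locus in annotation.retro_loci:
        if not truth.retro_truth[locus.subfamily]:
            continue
        seq = genome[locus.chrom][locus.start:locus.end]
        if locus.strand == "-":
            seq = revcomp(seq)
        for m in RRACH_FWD.finditer(seq):
            tx_a = m.start() + 2
            gpos = (locus.start + tx_a if locus.strand == "+"
                    else locus.end - 1 - tx_a)
            truth.retro_sites.append(
                M6ASite(locus.chrom, gpos, locus.strand, locus.locus_id,
                        float(rng.uniform(lo, hi)), tx_a)
            )
    return truth


def verify_sites_on_rrach(
    truth: SyntheticTruth, annotation: GenomeAnnotation, genome: Mapping[str, str]
) -> bool:
    """Check by sequence lookup that every planted A sits on an RRACH."""
    for s in truth.all_sites:
        chrom_seq = genome[s.chrom]
        if s.strand == "+":
            window = chrom_seq[s.position - 2 : s.position + 3]
        else:
            window = revcomp(chrom_seq[s.position - 2 : s.position + 3])
        if not RRACH_FWD.match(window):
            return False
    return True


# ---------------------------------------------------------------------------
# expression + fragments
# ---------------------------------------------------------------------------

class _Unit(NamedTuple):
    unit_id: str
    length: int
    transcript: Optional[Transcript]  # None for retro pseudo-units
    locus: Optional[RetroLocus]


def _sampling_units(annotation: GenomeAnnotation) -> List[_Unit]:
    units = [
        _Unit(tx.transcript_id, tx.exonic_length, tx, None)
        for tx in annotation.transcripts.values()
    ]
    units += [
        _Unit(loc.locus_id, loc.length, None, loc) for loc in annotation.retro_loci
    ]
    return units


def draw_expression(
    annotation: GenomeAnnotation, cfg: SimConfig, seed: Optional[int] = None
) -> Dict[str, float]:
    """Log-normal expression per transcript and retro locus; spike-ins fixed
    at a high quantile of the gene distribution (controls are added at
    defined, ample amounts)."""
    rng = substream(seed if seed is not None else cfg.seed, "expression")
    mu, sigma = cfg.expression_lognormal_mu_sigma
    expr: Dict[str, float] = {}
    gene_levels = []
    for unit in _sampling_units(annotation):
        if unit.transcript is not None and unit.transcript.biotype == "spikein":
            continue
        level = float(rng.lognormal(mu, sigma))
        expr[unit.unit_id] = level
        gene_levels.append(level)
    spike_level = float(np.quantile(gene_levels, cfg.spikein_expression_quantile))
    for name in annotation.spikein_contigs:
        expr[name] = spike_level
    return expr


def simulate_fragments(
    annotation: GenomeAnnotation,
    truth: SyntheticTruth,
    expression: Mapping[str, float],
    cfg: SimConfig,
    role: str,
    seed: Optional[int] = None,
    sample_id: Optional[str] = None,
    condition: str = "cond0",
    replicate: int = 1,
    stream_extra: Tuple[int, ...] = (),
    n_fragments: Optional[int] = None,
) -> AlignedFragmentSet:
    """Simulate one aligned-fragment library.

    Fragments are sampled per expression unit with probability proportional
    to expression x exonic length, start uniform along the unit, length
    normal (truncated at ``min_fragment_length``). For IP libraries a
    fragment covering a planted site is retained with probability
    proportional to stoichiometry x ``ip_enrichment_factor``, all others
    proportional to ``background_binding_rate``; accepted fragments are
    drawn until the library reaches its fixed depth (equimolar pooling).
    """
    if role not in (ROLE_IP, ROLE_INPUT):
        raise ValueError(f"role must be IP or input, got {role!r}")
    if not expression:
        raise ValueError("empty expression table")
    target = cfg.n_fragments_per_sample if n_fragments is None else n_fragments
    sid = sample_id or f"{condition}_rep{replicate}_{role}"
    out = AlignedFragmentSet(sid, role, condition, replicate)
    if target == 0:
        return out

    rng = substream(seed if seed is not None else cfg.seed, "fragments", *stream_extra)
    units = [u for u in _sampling_units(annotation) if expression.get(u.unit_id, 0.0) > 0]
    if not units:
        raise ValueError("no expressed units")
    weights = np.array([expression[u.unit_id] * u.length for u in units], dtype=float)
    probs = weights / weights.sum()
    lengths = np.array([u.length for u in units])
    sites_by_unit = truth.sites_by_unit()
    site_pos = {}
    site_sto = {}
    for i, u in enumerate(units):
        ss = sorted(sites_by_unit.get(u.unit_id, []), key=lambda s: s.tx_position)
        if ss:
            site_pos[i] = np.array([s.tx_position for s in ss])
            site_sto[i] = np.array([s.stoichiometry for s in ss])

    mean_len, sd_len = cfg.fragment_length_mean_sd
    w_max = max(cfg.ip_enrichment_factor, cfg.background_binding_rate)
    if role == ROLE_IP and w_max <= 0:
        return out
    if role == ROLE_IP and cfg.background_binding_rate == 0 and not site_pos:
        warnings.warn("IP library with zero background and no planted sites: empty")
        return out

    acc_idx: List[np.ndarray] = []
    acc_start: List[np.ndarray] = []
    acc_len: List[np.ndarray] = []
    n_acc = 0
    batch = 50_000
    while n_acc < target:
        idx = rng.choice(len(units), size=batch, p=probs)
        ln = np.rint(rng.normal(mean_len, sd_len, size=batch)).astype(np.int64)
        ln = np.maximum(ln, cfg.min_fragment_length)
        ln = np.minimum(ln, lengths[idx])
        # rng.integers with per-element high
        start = (rng.random(batch) * (lengths[idx] - ln + 1)).astype(np.int64)
        if role == ROLE_IP:
            w = np.full(batch, cfg.background_binding_rate, dtype=float)
            for ui in np.unique(idx):
                if ui not in site_pos:
                    continue
                mask = idx == ui
                pos = site_pos[ui]
                sto = site_sto[ui]
                lo = np.searchsorted(pos, start[mask])
                hi = np.searchsorted(pos, start[mask] + ln[mask])
                covered = hi > lo
                if covered.any():
                    mi = np.flatnonzero(mask)[covered]
                    lo_c, hi_c = lo[covered], hi[covered]
                    best = np.array(
                        [sto[a:b].max() for a, b in zip(lo_c, hi_c)]
                    )
                    w[mi] = np.maximum(
                        w[mi], best * cfg.ip_enrichment_factor
                    )
            keep = rng.random(batch) < (w / w_max)
        else:
            keep = np.ones(batch, dtype=bool)
        acc_idx.append(idx[keep])
        acc_start.append(start[keep])
        acc_len.append(ln[keep])
        n_acc += int(keep.sum())
        if role == ROLE_IP and n_acc == 0 and len(acc_idx) >= 20:
            warnings.warn("IP acceptance rate ~0; returning empty fragment set")
            return out

    idx = np.concatenate(acc_idx)[:target]
    start = np.concatenate(acc_start)[:target]
    ln = np.concatenate(acc_len)[:target]

    frags: List[Fragment] = []
    for ui, s0, l0 in zip(idx, start, ln):
        u = units[int(ui)]
        s0 = int(s0)
        l0 = int(l0)
        if u.transcript is not None:
            tx = u.transcript
            blocks = tx.tx_interval_to_blocks(s0, s0 + l0)
            frags.append(
                Fragment(tx.chrom, blocks[0][0], blocks[-1][1], tx.strand, blocks)
            )
        else:
            loc = u.locus
            if loc.strand == "+":
                gs = loc.start + s0
            else:
                gs = loc.end - s0 - l0
            frags.append(Fragment.contiguous(loc.chrom, gs, gs + l0, loc.strand))
    out.fragments = frags
    return out


# ---------------------------------------------------------------------------
# full study
# ---------------------------------------------------------------------------

@dataclass
class StudyData:
    """One simulated study: genome, truth(s) and all fragment libraries."""

    cfg: SimConfig
    annotation: GenomeAnnotation
    genome: Dict[str, str]
    expression: Dict[str, float]
    truths: List[SyntheticTruth]  # one per condition
    samples: List[AlignedFragmentSet]

    @property
    def truth(self) -> SyntheticTruth:
        return self.truths[0]

    def get(self, condition: str, replicate: int, role: str) -> AlignedFragmentSet:
        for s in self.samples:
            if (s.condition, s.replicate, s.role) == (condition, replicate, role):
                return s
        raise KeyError((condition, replicate, role))

    def sample_sheet(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"sample_id": s.sample_id, "condition": s.condition,
                 "replicate": s.replicate, "role": s.role,
                 "n_fragments": len(s)}
                for s in self.samples
            ]
        )


def simulate_study(cfg: SimConfig) -> StudyData:
    """Generate the complete study: annotation, planted sites per condition
    (disjoint across conditions), and IP/input libraries per replicate."""
    annotation, genome = generate_annotation(cfg)
    expression = draw_expression(annotation, cfg)
    truths: List[SyntheticTruth] = []
    exclude: set = set()
    for c in range(cfg.conditions):
        truth = plant_m6a_sites(
            annotation, genome, cfg, exclude=frozenset(exclude), stream_index=c
        )
        truths.append(truth)
        exclude.update((s.chrom, s.position) for s in truth.sites)
    samples: List[AlignedFragmentSet] = []
    for c in range(cfg.conditions):
        cond = f"cond{c}"
        for r in range(1, cfg.replicates + 1):
            for role_idx, role in enumerate((ROLE_IP, ROLE_INPUT)):
                samples.append(
                    simulate_fragments(
                        annotation, truths[c], expression, cfg, role,
                        condition=cond, replicate=r,
                        stream_extra=(c, r, role_idx),
                    )
                )
    return StudyData(cfg, annotation, genome, expression, truths, samples)


# ---------------------------------------------------------------------------
# qPCR simulation
# ---------------------------------------------------------------------------

def simulate_qpcr(
    design: pd.DataFrame,
    cfg: SimConfig,
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """Simulate Ct values from a delta-Ct model.

    ``design`` needs columns sample, target, assay, concentration and
    optionally input_fraction. Ct = intercept - log2(concentration) + noise;
    zero concentration is censored (no amplification, Ct = NaN).
    """
    required = {"sample", "target", "assay", "concentration"}
    missing = required - set(design.columns)
    if missing:
        raise ValueError(f"design lacks columns: {sorted(missing)}")
    if (design["concentration"] < 0).any():
        raise ValueError("concentrations must be >= 0")
    rng = substream(seed if seed is not None else cfg.seed, "qpcr")
    out = design.copy()
    conc = out["concentration"].to_numpy(dtype=float)
    noise = (
        rng.normal(0.0, cfg.qpcr_ct_sd, size=len(out)) if cfg.qpcr_ct_sd > 0
        else np.zeros(len(out))
    )
    with np.errstate(divide="ignore"):
        ct = cfg.qpcr_intercept - np.log2(conc) + noise
    ct[conc == 0] = CENSORED_CT
    out["Ct"] = ct
    if "input_fraction" not in out.columns:
        out["input_fraction"] = 1.0
    return out


def titration_design(
    levels: Sequence[float] = (100.0, 80.0, 50.0, 20.0, 0.0),
    target: str = "GLuc",
    base_concentration: float = 1.0,
) -> pd.DataFrame:
    """IP qPCR design for a methylation-level titration: IP'd material is
    proportional to the modified fraction of the mix."""
    return pd.DataFrame(
        {
            "sample": [f"mix{int(lv)}" for lv in levels],
            "target": target,
            "assay": "IP",
            "concentration": [base_concentration * lv / 100.0 for lv in levels],
            "expected_level": list(levels),
        }
    )
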