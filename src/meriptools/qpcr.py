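"""MeRIP-qPCR arithmetic: input-amount Ct correction, the IP signal-to-noise
ratio of a known positive over a known negative target, and titration
recovery of mixed methylation levels.

Amplification efficiency is fixed at perfect doubling (2.0 per cycle).
Censored Cts (no amplification) propagate as errors in ratios and as 0% in
titration recovery; they are never imputed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats


class CensoredCtError(ValueError):
    """A required Ct is censored (no amplification)."""


@dataclass(frozen=True)
class QpcrRecord:
    sample: str
    target: str
    assay: str  # "IP" | "input"
    ct: float  # NaN = censored
    input_fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.assay not in ("IP", "input"):
            raise ValueError(f"assay must be IP or input, got {self.assay!r}")
        if not (0.0 < self.input_fraction <= 1.0):
            raise ValueError("input_fraction must lie in (0, 1]")

    @property
    def censored(self) -> bool:
        return math.isnan(self.ct)


def corrected_input_ct(record: QpcrRecord) -> float:
    """Input Ct corrected for the fraction of IP starting material used.

    Ct_corrected = Ct - log2(1/input_fraction); with the full amount
    (input_fraction = 1) no correction applies.
    """
    if record.assay != "input":
        raise ValueError("correction applies to input assays only")
    if record.censored:
        raise CensoredCtError(f"censored input Ct for {record.sample}/{record.target}")
    return record.ct - math.log2(1.0 / record.input_fraction)


def sn_ratio(
    pos_input: QpcrRecord,
    pos_ip: QpcrRecord,
    neg_input: QpcrRecord,
    neg_ip: QpcrRecord,
) -> float:
    """Signal-to-noise ratio of IP enrichment:

    [2^(Ct_input_corrected(pos) - Ct_IP(pos))] /
    [2^(Ct_input_corrected(neg) - Ct_IP(neg))]
    """
    for rec in (pos_ip, neg_ip):
        if rec.censored:
            raise CensoredCtError(f"censored IP Ct for {rec.sample}/{rec.target}")
    signal = 2.0 ** (corrected_input_ct(pos_input) - pos_ip.ct)
    noise = 2.0 ** (corrected_input_ct(neg_input) - neg_ip.ct)
    return signal / noise


@dataclass
class TitrationResult:
    table: pd.DataFrame  # sample, expected, observed (%)
    pearson_r: float


def titration_levels(
    ip_records: Sequence[QpcrRecord],
    expected: Mapping[str, float],
    normalizer_sample: str,
) -> TitrationResult:
    """Observed methylation levels from IP Cts, normalized to one mix (100%).

    observed_i = 100 x 2^(Ct_normalizer - Ct_i); a censored Ct (no IP'd
    material amplified) is reported as 0%.
    """
    by_sample = {r.sample: r for r in ip_records}
    if normalizer_sample not in by_sample:
        raise ValueError(f"normalizer sample {normalizer_sample!r} missing")
    norm = by_sample[normalizer_sample]
    if norm.censored:
        raise CensoredCtError("normalizer Ct is censored")
    rows = []
    for sample, exp_level in expected.items():
        rec = by_sample.get(sample)
        if rec is None:
            raise ValueError(f"no IP record for sample {sample!r}")
        obs = 0.0 if rec.censored else 100.0 * 2.0 ** (norm.ct - rec.ct)
        rows.append((sample, float(exp_level), obs))
    table = pd.DataFrame(rows, columns=["sample", "expected", "observed"])
    if table["expected"].nunique() > 1 and table["observed"].nunique() > 1:
        r = float(stats.pearsonr(table["expected"], table["observed"])[0])
    else:
        r = float("nan")
    return TitrationResult(table, r)


def records_from_frame(df: pd.DataFrame) -> List[QpcrRecord]:
    """Build records from a qPCR table (sample, target, assay, Ct
    [, input_fraction])."""
    records = []
    for row in df.itertuples(index=False):
        records.append(
            QpcrRecord(
                sample=row.sample,
                target=row.target,
                assay=row.assay,
                ct=float(row.Ct),
                input_fraction=float(getattr(row, "input_fraction", 1.0)),
            )
        )
    return records
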