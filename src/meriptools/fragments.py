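"""Aligned-fragment containers: the universal input currency of the pipeline.

A fragment is the footprint of one sequenced RNA fragment after (simulated)
spliced alignment: a chromosome interval plus its exonic blocks. Fragments
spanning exon junctions carry multiple blocks and are counted by their exonic
footprint.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, NamedTuple, Tuple

ROLE_IP = "IP"
ROLE_INPUT = "input"


class Fragment(NamedTuple):
    chrom: str
    start: int
    end: int
    strand: str
    blocks: Tuple[Tuple[int, int], ...]

    @classmethod
    def contiguous(cls, chrom: str, start: int, end: int, strand: str = "+") -> "Fragment":
        return cls(chrom, start, end, strand, ((start, end),))


@dataclass
class AlignedFragmentSet:
    """One sample's aligned fragments (IP or input)."""

    sample_id: str
    role: str
    condition: str = "cond0"
    replicate: int = 1
    fragments: List[Fragment] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.role not in (ROLE_IP, ROLE_INPUT):
            raise ValueError(f"role must be {ROLE_IP!r} or {ROLE_INPUT!r}, got {self.role!r}")

    def __len__(self) -> int:
        return len(self.fragments)

    def validate_bounds(self, chrom_lengths) -> None:
        for f in self.fragments:
            if not (0 <= f.start < f.end <= chrom_lengths[f.chrom]):
                raise ValueError(f"fragment out of bounds: {f}")

    def subset(self, indices, sample_id: str | None = None) -> "AlignedFragmentSet":
        return AlignedFragmentSet(
            sample_id=sample_id or self.sample_id,
            role=self.role,
            condition=self.condition,
            replicate=self.replicate,
            fragments=[self.fragments[i] for i in indices],
        )
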