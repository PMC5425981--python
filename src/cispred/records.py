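"""Lightweight result records shared across modules."""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class GenomicRegion:
    """A 1-based, closed genomic interval [start, end]."""

    chrom: str
    start: int
    end: int
    label: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"region start {self.start} > end {self.end}")
        if self.start < 1:
            raise ValueError("coordinates are 1-based; start must be >= 1")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def contains(self, chrom: str, position: float) -> bool:
        return chrom == self.chrom and self.start <= position <= self.end


@dataclass
class GeneResult:
    """Per-gene prediction outcome: test-set R² for each fitted method."""

    gene_id: str
    chrom: str
    start: int
    end: int
    r2: dict[str, float] = field(default_factory=dict)

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0
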