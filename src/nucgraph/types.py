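"""Core domain types shared across the toolkit.

All genomic coordinates are 0-based half-open. SAM input is converted on
entry (-1); BED passes through unchanged.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional


@dataclass
class ReadPair:
    """One Hi-C contact: two aligned read ends.

    A pair is unordered — the constructor-facing helper :meth:`canonical`
    sorts the two ends by (chrom, pos) so that (a, b) and (b, a) compare
    equal. ``frag1_id``/``frag2_id`` stay ``None`` until fragment
    assignment; ``score`` stays ``None`` until normalization.
    """

    chrom1: str
    pos1: int
    strand1: str
    chrom2: str
    pos2: int
    strand2: str
    frag1_id: Optional[int] = None
    frag2_id: Optional[int] = None
    score: Optional[float] = None

    def __post_init__(self) -> None:
        if self.pos1 < 0 or self.pos2 < 0:
            raise ValueError("read positions must be >= 0")
        if not self.chrom1 or not self.chrom2:
            raise ValueError("chromosome names must be non-empty")
        if self.strand1 not in "+-" or self.strand2 not in "+-":
            raise ValueError("strand must be '+' or '-'")

    def canonical(self) -> "ReadPair":
        """Return the pair with ends sorted by (chrom, pos, strand)."""
        if (self.chrom1, self.pos1, self.strand1) <= (
                self.chrom2, self.pos2, self.strand2):
            return self
        return ReadPair(
            self.chrom2, self.pos2, self.strand2,
            self.chrom1, self.pos1, self.strand1,
            self.frag2_id, self.frag1_id, self.score,
        )

    @property
    def ends(self):
        return ((self.chrom1, self.pos1), (self.chrom2, self.pos2))

    def key(self):
        """Hashable identity of the contact (ends only, canonical order)."""
        c = self.canonical()
        return (c.chrom1, c.pos1, c.strand1, c.chrom2, c.pos2, c.strand2)


@dataclass(frozen=True)
class RestrictionFragment:
    """A digest interval with normalization covariates.

    Fragments tile each chromosome without overlap or gap; ``id`` is unique
    and ordered by (chrom, start).
    """

    id: int
    chrom: str
    start: int
    end: int
    gc: float = 0.0
    mappability: float = 1.0

    def __post_init__(self) -> None:
        if self.end - self.start < 1:
            raise ValueError(
                f"fragment {self.chrom}:{self.start}-{self.end} has length < 1"
            )
        if not 0.0 <= self.gc <= 1.0:
            raise ValueError("gc must be in [0, 1]")
        if not 0.0 <= self.mappability <= 1.0:
            raise ValueError("mappability must be in [0, 1]")

    @property
    def length_bp(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass(frozen=True)
class Gene:
    symbol: str
    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"gene {self.symbol}: start >= end")

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        return self.chrom == chrom and self.start < end and start < self.end


@dataclass
class FeatureTrack:
    """A named set of genomic intervals with numeric values.

    ``intervals`` holds (chrom, start, end, value) tuples kept sorted by
    (chrom, start); the value defaults to 1 for 3-column BED input.
    """

    name: str
    intervals: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.intervals = sorted(
            (str(c), int(s), int(e), float(v)) for c, s, e, v in self.intervals
        )

    def __len__(self) -> int:
        return len(self.intervals)

    def by_chrom(self) -> dict:
        out: dict = {}
        for c, s, e, v in self.intervals:
            out.setdefault(c, []).append((s, e, v))
        return out
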