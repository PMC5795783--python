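"""Core genomic domain types.

All coordinates are 0-based half-open (BED convention) internally; readers
for 1-based formats convert at the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

STRANDS = ("+", "-", ".")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A chromosome-anchored half-open span ``[start, end)``.

    Parameters
    ----------
    chrom : str
        Chromosome name. No dialect normalization is performed ("1" and
        "chr1" are distinct labels).
    start : int
        0-based inclusive start, in bp. Must be >= 0.
    end : int
        0-based exclusive end, in bp. Must be > ``start``.
    strand : str
        One of ``+``, ``-`` or ``.`` (unstranded).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be a non-empty string")
        if not isinstance(self.start, int) or not isinstance(self.end, int):
            raise TypeError("start and end must be integers")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must exceed start, got [{self.start}, {self.end})"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True if the two spans share at least one base."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains_point(self, chrom: str, position: int) -> bool:
        return self.chrom == chrom and self.start <= position < self.end

    def distance_to_point(self, position: int) -> int:
        """Minimum |base - position| over bases of the interval.

        Zero when the position lies inside the span. Chromosome equality is
        the caller's responsibility.
        """
        if self.start <= position < self.end:
            return 0
        if position < self.start:
            return self.start - position
        return position - (self.end - 1)

    def padded(self, pad: int) -> "GenomicInterval":
        """Extend by ``pad`` bp on each side, clipped at zero."""
        if pad < 0:
            raise ValueError("pad must be >= 0")
        return GenomicInterval(self.chrom, max(0, self.start - pad), self.end + pad, self.strand)


@dataclass(frozen=True)
class Peak:
    """A ChIP-seq binding-site interval for one transcription factor."""

    interval: GenomicInterval
    peak_id: str
    factor: str = ""
    score: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.peak_id:
            raise ValueError("peak_id must be non-empty")


@dataclass(frozen=True)
class TSSRecord:
    """A transcription start site: a single strand-aware base position."""

    gene_id: str
    chrom: str
    tss_position: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise ValueError("gene_id must be non-empty")
        if self.tss_position < 0:
            raise ValueError("tss_position must be >= 0")
        if self.strand not in ("+", "-"):
            raise ValueError(f"TSS strand must be + or -, got {self.strand!r}")


@dataclass(frozen=True)
class ContactPair:
    """One chromatin interaction between two anchor intervals.

    Anchor order carries no meaning: every consumer must treat the pair
    symmetrically.
    """

    anchor1: GenomicInterval
    anchor2: GenomicInterval
    contact_id: str
    score: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.contact_id:
            raise ValueError("contact_id must be non-empty")

    def swapped(self) -> "ContactPair":
        return ContactPair(self.anchor2, self.anchor1, self.contact_id, self.score)
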