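"""TSS-relative promoter coordinates.

Promoter positions follow the biology convention anchored at the initiator
adenine: the first transcribed base is +1, the base immediately upstream is
-1, and there is **no position 0**.  An interval such as ``-2..+33`` therefore
spans 35 bases, and ``-10..+40`` spans 50.

Genomic coordinates, by contrast, are 0-based half-open throughout the
package (BED convention).  This module is the only place where the two
systems meet; everything else converts through it.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "CoordinateError",
    "PromoterInterval",
    "check_coord",
    "interval_length",
    "to_string_index",
    "from_string_index",
    "promoter_to_genomic",
    "genomic_interval",
]


class CoordinateError(ValueError):
    """Raised for position 0 or positions outside the working window."""


def check_coord(c: int) -> int:
    if c == 0:
        raise CoordinateError("promoter coordinates have no position 0")
    return int(c)


def interval_length(start: int, end: int) -> int:
    """Number of bases in the promoter interval ``start..end`` (inclusive).

    Position 0 does not exist, so an interval straddling the TSS
    (``start < 0 < end``) has length ``end - start``; a same-sign interval
    has the usual ``end - start + 1``.
    """
    check_coord(start)
    check_coord(end)
    if start > end:
        raise CoordinateError(f"interval start {start} > end {end}")
    if start < 0 < end:
        return end - start
    return end - start + 1


def to_string_index(coord: int, window_start: int) -> int:
    """0-based index of promoter position *coord* in a window string
    beginning at *window_start*."""
    check_coord(coord)
    check_coord(window_start)
    if coord < window_start:
        raise CoordinateError(f"{coord:+d} precedes window start {window_start:+d}")
    idx = coord - window_start
    if window_start < 0 < coord:
        idx -= 1
    return idx


def from_string_index(idx: int, window_start: int) -> int:
    """Inverse of :func:`to_string_index`."""
    if idx < 0:
        raise CoordinateError("string index must be non-negative")
    check_coord(window_start)
    c = window_start + idx
    if window_start < 0 <= c:
        c += 1
    return c


def advance(coord: int, offset: int) -> int:
    """Move *offset* bases downstream of *coord*, skipping position 0."""
    c = check_coord(coord) + offset
    if coord < 0 <= c:
        c += 1
    elif coord > 0 and c <= 0:
        c -= 1
    return c


@dataclass(frozen=True)
class PromoterInterval:
    """Closed promoter-coordinate interval, e.g. ``-2..+33``."""

    start: int
    end: int

    def __post_init__(self) -> None:
        interval_length(self.start, self.end)  # validates

    def __len__(self) -> int:
        return interval_length(self.start, self.end)

    def __contains__(self, coord: int) -> bool:
        return coord != 0 and self.start <= coord <= self.end

    def contains_interval(self, other: "PromoterInterval") -> bool:
        return self.start <= other.start and other.end <= self.end

    def overlaps(self, other: "PromoterInterval") -> bool:
        return not (self.end < other.start or other.end < self.start)

    def positions(self) -> list[int]:
        return [c for c in range(self.start, self.end + 1) if c != 0]

    def __str__(self) -> str:
        return f"{self.start:+d}..{self.end:+d}"


def promoter_to_genomic(coord: int, tss: int, strand: str) -> int:
    """Map a promoter coordinate to a 0-based genomic position.

    *tss* is the 0-based genomic position of the A+1 base.  On the minus
    strand promoter coordinates run leftward along the genome.
    """
    check_coord(coord)
    offset = coord - 1 if coord > 0 else coord
    if strand == "+":
        return tss + offset
    if strand == "-":
        return tss - offset
    raise ValueError(f"strand must be '+' or '-', got {strand!r}")


def genomic_interval(interval: PromoterInterval, tss: int, strand: str) -> tuple[int, int]:
    """0-based half-open genomic interval covering *interval* around *tss*."""
    a = promoter_to_genomic(interval.start, tss, strand)
    b = promoter_to_genomic(interval.end, tss, strand)
    lo, hi = (a, b) if a <= b else (b, a)
    return lo, hi + 1
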