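"""Promoter sequence records."""

from __future__ import annotations

from dataclasses import dataclass, field

from .coords import PromoterInterval, interval_length, to_string_index

__all__ = ["PromoterRecord"]


@dataclass
class PromoterRecord:
    """A sequence window around a TSS, addressed in promoter coordinates.

    The window is a closed promoter-coordinate interval (default ``-40..+40``)
    and the sequence must have exactly its length.  ``shape_class`` carries
    the CAGE promoter shape ('peaked', 'unclassified' or 'broad'); only
    peaked/unclassified promoters enter composition analysis.
    """

    transcript_id: str
    sequence: str
    window: PromoterInterval = field(default_factory=lambda: PromoterInterval(-40, 40))
    gene_id: str = ""
    shape_class: str = "peaked"

    def __post_init__(self) -> None:
        if not self.gene_id:
            self.gene_id = self.transcript_id
        expected = interval_length(self.window.start, self.window.end)
        if len(self.sequence) != expected:
            raise ValueError(
                f"{self.transcript_id}: sequence length {len(self.sequence)} "
                f"!= window {self.window} length {expected}"
            )
        if self.shape_class not in ("peaked", "unclassified", "broad"):
            raise ValueError(f"unknown shape_class {self.shape_class!r}")

    def subsequence(self, interval: PromoterInterval) -> str:
        """Bases covering *interval* (closed, promoter coordinates)."""
        if not self.window.contains_interval(interval):
            raise ValueError(f"{interval} outside record window {self.window}")
        i = to_string_index(interval.start, self.window.start)
        j = to_string_index(interval.end, self.window.start)
        return self.sequence[i : j + 1]

    def base_at(self, coord: int) -> str:
        return self.sequence[to_string_index(coord, self.window.start)]
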