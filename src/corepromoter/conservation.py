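"""Exon-resampling conservation test for the downstream core promoter.

The question: is the 35-bp window at promoter positions -2..+33 as conserved
as the coding exons of the same gene?  The null distribution is built by
placing a 35-bp window at a uniformly random valid start inside the gene's
exons, recording its mean per-base conservation score (phyloP-style,
positive = conserved), and repeating 1000 times.  If the promoter window's
mean falls within ±2 SD of the resampled means the null (exon-level
conservation) is not refuted.  A 35-bp window at -275..-241 serves as an
upstream control.

Genomic coordinates are 0-based half-open; windows partially off the track
or crossing uncovered bases are errors, never silently truncated — the mean
is the test statistic and must not be computed on a different window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .coords import PromoterInterval, genomic_interval

__all__ = [
    "ConservationTrack",
    "ExonSet",
    "WindowTestResult",
    "PROMOTER_WINDOW",
    "CONTROL_WINDOW",
    "window_mean",
    "promoter_window",
    "control_window",
    "resample_exon_windows",
    "conservation_verdict",
    "gene_conservation_test",
]

PROMOTER_WINDOW = PromoterInterval(-2, 33)
CONTROL_WINDOW = PromoterInterval(-275, -241)


@dataclass
class ConservationTrack:
    """Per-base conservation scores over one contiguous genomic interval."""

    chrom: str
    origin: int  # 0-based genomic coordinate of scores[0]
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 1 or len(self.scores) == 0:
            raise ValueError("scores must be a non-empty 1-D array")

    @property
    def end(self) -> int:
        return self.origin + len(self.scores)

    def values(self, start: int, end: int) -> np.ndarray:
        """Scores for [start, end); errors name any uncovered span."""
        if start >= end:
            raise ValueError(f"empty window [{start}, {end})")
        if start < self.origin or end > self.end:
            raise ValueError(
                f"{self.chrom}:[{start}, {end}) not covered by track "
                f"[{self.origin}, {self.end})"
            )
        vals = self.scores[start - self.origin : end - self.origin]
        if np.isnan(vals).any():
            missing = start + np.flatnonzero(np.isnan(vals))
            raise ValueError(
                f"{self.chrom}: missing scores at {missing.min()}..{missing.max()} "
                f"inside window [{start}, {end})"
            )
        return vals


@dataclass
class ExonSet:
    """Exonic intervals of one gene; overlapping intervals merged on load."""

    intervals: list[tuple[str, int, int]]
    strand: str = "+"

    def __post_init__(self) -> None:
        if not self.intervals:
            raise ValueError("exon set cannot be empty")
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        merged: list[tuple[str, int, int]] = []
        for chrom, start, end in sorted(self.intervals):
            if end - start < 1:
                raise ValueError(f"exon {chrom}:{start}-{end} has length < 1")
            if merged and merged[-1][0] == chrom and start <= merged[-1][2]:
                prev = merged.pop()
                merged.append((chrom, prev[1], max(prev[2], end)))
            else:
                merged.append((chrom, start, end))
        self.intervals = merged

    def valid_starts(self, window_len: int) -> list[tuple[str, int]]:
        """(chrom, start) for every window placement inside a single exon."""
        starts = []
        for chrom, s, e in self.intervals:
            starts.extend((chrom, p) for p in range(s, e - window_len + 1))
        return starts


@dataclass(frozen=True)
class WindowTestResult:
    gene: str
    window_mean: float
    resample_mean: float
    resample_sd: float
    z: float
    within_2sd: bool
    n_resamples: int
    window_len: int
    seed: int
    sd_multiplier: float = 2.0


def window_mean(track: ConservationTrack, start: int, end: int) -> float:
    """Arithmetic mean of per-base scores over [start, end)."""
    return float(track.values(start, end).mean())


def promoter_window(tss: int, strand: str) -> tuple[int, int]:
    """Genomic [start, end) of promoter positions -2..+33 (35 bp)."""
    return genomic_interval(PROMOTER_WINDOW, tss, strand)


def control_window(tss: int, strand: str) -> tuple[int, int]:
    """Genomic [start, end) of the upstream control at -275..-241 (35 bp)."""
    return genomic_interval(CONTROL_WINDOW, tss, strand)


def resample_exon_windows(
    track: ConservationTrack,
    exons: ExonSet,
    window_len: int = 35,
    n: int = 1000,
    seed: int = 0,
    concatenate_exons: bool = False,
) -> tuple[np.ndarray, tuple[float, float]]:
    """Means of *n* random exonic windows, plus their (mean, sd).

    Starts are drawn uniformly (with replacement) over every valid
    single-exon placement, which weights each exon by its number of valid
    starts.  ``concatenate_exons=True`` instead joins the exons end-to-end
    so windows may span junctions.  The sample SD (ddof=1) summarises the
    null distribution.
    """
    if n < 2:
        raise ValueError("need n >= 2 resamples")
    rng = np.random.default_rng(seed)
    if concatenate_exons:
        joined = np.concatenate([track.values(s, e) for _, s, e in exons.intervals])
        if len(joined) < window_len:
            raise ValueError(f"concatenated exons shorter than the {window_len}-bp window")
        cs = np.concatenate([[0.0], np.cumsum(joined)])
        starts = rng.integers(0, len(joined) - window_len + 1, size=n)
        means = (cs[starts + window_len] - cs[starts]) / window_len
    else:
        placements = exons.valid_starts(window_len)
        if not placements:
            raise ValueError(f"no exon can contain a {window_len}-bp window")
        # validate coverage once, then use a cumulative sum for speed
        for chrom, s, e in exons.intervals:
            track.values(s, e)
        cs = np.concatenate([[0.0], np.cumsum(track.scores)])
        choice = rng.integers(0, len(placements), size=n)
        starts = np.array([placements[i][1] for i in choice]) - track.origin
        means = (cs[starts + window_len] - cs[starts]) / window_len
    if np.all(means == means[0]):  # forced placement: exactly degenerate
        summary = (float(means[0]), 0.0)
    else:
        summary = (float(means.mean()), float(means.std(ddof=1)))
    return means, summary


def conservation_verdict(
    wmean: float,
    summary: tuple[float, float],
    gene: str = "",
    n_resamples: int = 1000,
    window_len: int = 35,
    seed: int = 0,
    sd_multiplier: float = 2.0,
) -> WindowTestResult:
    """±2 SD verdict: is the window's mean within the exonic null band?

    With a degenerate null (sd = 0) the verdict requires exact equality and
    z is 0 or ±inf accordingly.
    """
    mu, sd = summary
    if sd > 0:
        z = (wmean - mu) / sd
        within = abs(wmean - mu) <= sd_multiplier * sd
    else:
        within = wmean == mu
        z = 0.0 if within else np.sign(wmean - mu) * np.inf
    return WindowTestResult(
        gene=gene, window_mean=float(wmean), resample_mean=mu, resample_sd=sd,
        z=float(z), within_2sd=bool(within), n_resamples=n_resamples,
        window_len=window_len, seed=seed, sd_multiplier=sd_multiplier,
    )


def gene_conservation_test(
    track: ConservationTrack,
    exons: ExonSet,
    tss: int,
    strand: str,
    gene: str = "",
    n: int = 1000,
    window_len: int = 35,
    seed: int = 0,
    sd_multiplier: float = 2.0,
    interval: PromoterInterval = PROMOTER_WINDOW,
) -> tuple[WindowTestResult, np.ndarray]:
    """Run the full test for one gene; returns the verdict and the resampled means."""
    start, end = genomic_interval(interval, tss, strand)
    wm = window_mean(track, start, end)
    means, summary = resample_exon_windows(track, exons, window_len, n, seed)
    result = conservation_verdict(
        wm, summary, gene=gene, n_resamples=n, window_len=window_len,
        seed=seed, sd_multiplier=sd_multiplier,
    )
    return result, means
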