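"""Multi-species scan for the combined initiator-BridgeI-DPE motif.

Per-species promoter windows are extracted from MAF alignment blocks around
a reference TSS (±500 bp) or supplied directly as gene-start-anchored
windows (±1000 bp).  Gaps are stripped per species and each window keeps an
*anchor*: the de-gapped index aligned with the reference TSS (or annotated
gene start).  The combined 35-column model is slid over the window; hits
must score strictly above the threshold (default 5 bits) and have their
initiator A+1 column within ±200 bp of the anchor, and the closest such hit
to the anchor is the species' motif call.  Calls across species become a
gene × species presence/absence matrix and a logo-ready position frequency
matrix of the hit sequences.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .coords import from_string_index
from .io import MafBlock
from .pwm import ALPHABET, CombinedMotifModel, MotifHit, _model_arrays, _scores_along

logger = logging.getLogger(__name__)

__all__ = [
    "SpeciesWindow",
    "OrthologHit",
    "PositionFrequencyMatrix",
    "extract_species_windows",
    "scan_species",
    "build_presence_matrix",
    "build_pfm",
]


@dataclass(frozen=True)
class SpeciesWindow:
    """One species' de-gapped sequence around the reference anchor.

    ``anchor`` is the 0-based index (into the de-gapped sequence) of the
    base aligned with the reference TSS or annotated gene start.
    """

    species: str
    gene: str
    sequence: str
    anchor: int
    flank: int = 500

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.species}/{self.gene}: empty sequence after de-gapping")
        if "-" in self.sequence:
            raise ValueError(f"{self.species}/{self.gene}: sequence still contains gaps")
        if not 0 <= self.anchor < len(self.sequence):
            raise ValueError(
                f"{self.species}/{self.gene}: anchor {self.anchor} outside sequence "
                f"of length {len(self.sequence)}"
            )


@dataclass(frozen=True)
class OrthologHit:
    species: str
    gene: str
    hit: MotifHit  # start/end in anchor-relative promoter coordinates
    distance_to_anchor: int

    def __post_init__(self) -> None:
        if self.distance_to_anchor < 0:
            raise ValueError("distance must be >= 0")


def extract_species_windows(
    blocks: Sequence[MafBlock],
    reference_species: str,
    reference_tss: int,
    flank: int = 500,
    gene: str = "",
) -> list[SpeciesWindow]:
    """Per-species de-gapped windows covering reference ±flank around the TSS.

    Alignment columns are kept while the reference coordinate lies within
    ``[tss - flank, tss + flank]``; insertion columns (reference gap) attach
    to the preceding reference base.  Species with no aligned base in the
    region are omitted with a logged note; a species must be aligned in the
    block containing the TSS column to receive an anchor.
    """
    ref_blocks = []
    for bi, block in enumerate(blocks):
        ref_rows = [r for r in block.rows if r.species == reference_species]
        if not ref_rows:
            raise ValueError(f"reference species {reference_species!r} absent from block {bi}")
        ref_blocks.append((ref_rows[0], block))
    ref_blocks.sort(key=lambda rb: rb[0].start)

    lo, hi = reference_tss - flank, reference_tss + flank
    seqs: dict[str, list[str]] = {}
    anchors: dict[str, int] = {}
    for ref, block in ref_blocks:
        if ref.strand != "+":
            raise ValueError("reference rows must be on the + strand")
        ref_pos = ref.start  # genomic coordinate of the next reference base
        keep = np.zeros(len(ref.text), dtype=bool)
        is_tss_col = np.zeros(len(ref.text), dtype=bool)
        last_in = False
        for i, base in enumerate(ref.text):
            if base == "-":
                keep[i] = last_in  # insertions attach to the preceding ref base
                continue
            last_in = lo <= ref_pos <= hi
            keep[i] = last_in
            if ref_pos == reference_tss:
                is_tss_col[i] = True
            ref_pos += 1
        if not keep.any():
            continue
        for row in block.rows:
            chars = np.array(list(row.text))
            kept = chars[keep]
            aligned = "".join(kept[kept != "-"])
            if not aligned:
                logger.info("%s: no aligned bases in the %s window; omitted", row.species, gene or "reference")
                continue
            prior = len(seqs.get(row.species, []))
            seqs.setdefault(row.species, []).append(aligned)
            if is_tss_col.any():
                tss_i = int(np.flatnonzero(is_tss_col)[0])
                if chars[tss_i] != "-":
                    before = chars[keep & (np.arange(len(chars)) < tss_i)]
                    offset = sum(len(s) for s in seqs[row.species][:prior + 1]) - len(aligned)
                    anchors[row.species] = offset + int((before != "-").sum())

    out = []
    for species, parts in seqs.items():
        if species not in anchors:
            logger.info("%s: not aligned at the TSS column; omitted", species)
            continue
        out.append(SpeciesWindow(species=species, gene=gene, sequence="".join(parts).upper(),
                                 anchor=anchors[species], flank=flank))
    return out


def scan_species(
    window: SpeciesWindow,
    model: CombinedMotifModel,
    score_threshold: float = 5.0,
    distance_limit: int = 200,
) -> OrthologHit | None:
    """Closest qualifying combined-motif hit to the anchor, if any.

    A hit qualifies when its score is strictly above *score_threshold* and
    its initiator A+1 column lies within ±*distance_limit* of the anchor.
    Ties on distance prefer the higher score, then the upstream hit.
    """
    lo, expected = _model_arrays(model)
    width = model.width
    seq = window.sequence.upper()
    if len(seq) < width:
        logger.warning("%s/%s: window shorter than the combined model; no scan",
                       window.species, window.gene)
        return None
    scores = _scores_along(lo, expected, seq)
    window_start = -window.anchor if window.anchor > 0 else 1  # promoter coord of index 0
    best: tuple[int, float, int] | None = None  # (distance, -score, offset)
    for i, s in enumerate(scores):
        if s <= score_threshold:
            continue
        distance = abs(i + model.tss_column - window.anchor)
        if distance > distance_limit:
            continue
        key = (distance, -float(s), i)
        if best is None or key < best:
            best = key
    if best is None:
        return None
    distance, neg_score, i = best
    start = from_string_index(i, window_start)
    end = from_string_index(i + width - 1, window_start)
    hit = MotifHit(model.name, start, end, -neg_score, seq[i : i + width])
    return OrthologHit(species=window.species, gene=window.gene, hit=hit,
                       distance_to_anchor=distance)


def build_presence_matrix(
    hits: Mapping[tuple[str, str], OrthologHit | None] | Iterable[tuple[str, str, OrthologHit | None]],
    genes: Sequence[str] | None = None,
    species: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Gene × species detection table as a boolean DataFrame (species rows).

    Accepts a {(gene, species): hit-or-None} mapping or an iterable of
    (gene, species, hit) triples; duplicate cells are an error.
    """
    if isinstance(hits, Mapping):
        entries = [(g, sp, h) for (g, sp), h in hits.items()]
    else:
        entries = list(hits)
    seen: dict[tuple[str, str], bool] = {}
    for g, sp, h in entries:
        if (g, sp) in seen:
            raise ValueError(f"duplicate presence entry for gene {g!r}, species {sp!r}")
        seen[(g, sp)] = h is not None
    genes = list(genes) if genes is not None else sorted({g for g, _ in seen})
    species = list(species) if species is not None else sorted({sp for _, sp in seen})
    df = pd.DataFrame(False, index=species, columns=genes)
    df.index.name = "species"
    for (g, sp), present in seen.items():
        df.loc[sp, g] = present
    return df


@dataclass(frozen=True)
class PositionFrequencyMatrix:
    """Column-wise base counts of gap-free hit sequences (logo input)."""

    counts: np.ndarray  # (width, 4) over A, C, G, T
    n_sequences: int

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2 or counts.shape[1] != 4:
            raise ValueError("counts must have shape (width, 4)")
        if not np.all(counts.sum(axis=1) == self.n_sequences):
            raise ValueError("every column must sum to the number of sequences")
        object.__setattr__(self, "counts", counts)

    @property
    def width(self) -> int:
        return self.counts.shape[0]

    def frequencies(self) -> np.ndarray:
        return self.counts / self.n_sequences

    def base_fraction(self, column: int, base: str) -> float:
        return float(self.counts[column, ALPHABET.index(base)] / self.n_sequences)


def build_pfm(hits: Sequence[OrthologHit], width: int = 35) -> PositionFrequencyMatrix:
    """Stack the hit sequences into per-column base counts."""
    if not hits:
        raise ValueError("need at least one hit")
    counts = np.zeros((width, 4), dtype=int)
    for oh in hits:
        seq = oh.hit.matched_seq.upper()
        if len(seq) != width:
            raise ValueError(
                f"{oh.species}/{oh.gene}: hit length {len(seq)} != {width}"
            )
        for j, base in enumerate(seq):
            counts[j, ALPHABET.index(base)] += 1
    return PositionFrequencyMatrix(counts=counts, n_sequences=len(hits))
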