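"""File formats: FASTA, TSV tables, BED, bedGraph/wiggle, MAF, MEME minimal.

All genomic interval I/O is 0-based half-open (BED convention).  Promoter
coordinates never appear in files except in the per-hit report columns,
where they are explicit signed integers.
"""

from __future__ import annotations

import io as _io
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .pwm import ALPHABET, PositionWeightMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_bed",
    "write_bed",
    "read_track",
    "write_bedgraph",
    "MafRow",
    "MafBlock",
    "read_maf",
    "write_maf",
    "read_meme",
    "write_meme",
    "read_pwm_metadata",
    "read_presence_tsv",
    "write_presence_tsv",
]


def _as_handle(source) -> _io.StringIO:
    """Accept a path or raw text content."""
    if isinstance(source, Path):
        return _io.StringIO(source.read_text())
    text = str(source)
    if "\n" not in text and Path(text).exists():
        return _io.StringIO(Path(text).read_text())
    return _io.StringIO(text)


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(source) -> dict[str, str]:
    """FASTA → ordered {id: sequence}; duplicate IDs are an error."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(_as_handle(source), "fasta"):
        if rec.id in out:
            raise ValueError(f"duplicate FASTA id {rec.id!r}")
        out[rec.id] = str(rec.seq)
    return out


def write_fasta(sequences: Mapping[str, str], path: Path | str) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta-2line")


# ---------------------------------------------------------------------------
# BED


def read_bed(source) -> list[tuple[str, int, int]]:
    """BED3+ → [(chrom, start, end)]; validates start < end."""
    intervals = []
    for ln, line in enumerate(_as_handle(source), 1):
        line = line.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise ValueError(f"BED line {ln}: fewer than 3 columns")
        chrom, start, end = parts[0], int(parts[1]), int(parts[2])
        if start >= end:
            raise ValueError(f"BED line {ln}: start {start} >= end {end}")
        intervals.append((chrom, start, end))
    return intervals


def write_bed(intervals: Iterable[tuple[str, int, int]], path: Path | str) -> None:
    with open(path, "w") as fh:
        for chrom, start, end in intervals:
            fh.write(f"{chrom}\t{start}\t{end}\n")


# ---------------------------------------------------------------------------
# Conservation tracks (bedGraph and wiggle dialects)


def read_track(source) -> dict[str, tuple[int, np.ndarray]]:
    """Per-base score track → {chrom: (origin, scores)}.

    Accepts bedGraph (4 columns) and fixedStep/variableStep wiggle.  Scores
    are stored per base from the first to the last covered position per
    chromosome; uncovered bases inside that range are NaN and rejected later
    by window queries (missing data must never silently shrink a mean).
    """
    per_chrom: dict[str, dict[int, float]] = {}

    def put(chrom: str, pos: int, value: float) -> None:
        per_chrom.setdefault(chrom, {})[pos] = value

    mode = None  # None → bedGraph lines; else ("fixed"|"variable", chrom, pos, step, span)
    for ln, raw in enumerate(_as_handle(source), 1):
        line = raw.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        if line.startswith("fixedStep"):
            kv = dict(f.split("=") for f in line.split()[1:])
            mode = ["fixed", kv["chrom"], int(kv["start"]) - 1, int(kv.get("step", 1)), int(kv.get("span", 1))]
            continue
        if line.startswith("variableStep"):
            kv = dict(f.split("=") for f in line.split()[1:])
            mode = ["variable", kv["chrom"], 0, 1, int(kv.get("span", 1))]
            continue
        fields = line.split()
        if mode is None or len(fields) == 4:
            if len(fields) != 4:
                raise ValueError(f"track line {ln}: expected bedGraph or wiggle data")
            chrom, start, end, value = fields[0], int(fields[1]), int(fields[2]), float(fields[3])
            if start >= end:
                raise ValueError(f"track line {ln}: start >= end")
            for p in range(start, end):
                put(chrom, p, value)
        elif mode[0] == "fixed":
            value = float(fields[0])
            _, chrom, pos, step, span = mode
            for p in range(pos, pos + span):
                put(chrom, p, value)
            mode[2] = pos + step
        else:  # variableStep: 1-based position, value
            pos1, value = int(fields[0]), float(fields[1])
            for p in range(pos1 - 1, pos1 - 1 + mode[4]):
                put(mode[1], p, value)

    out = {}
    for chrom, scores in per_chrom.items():
        lo, hi = min(scores), max(scores)
        arr = np.full(hi - lo + 1, np.nan)
        for pos, value in scores.items():
            arr[pos - lo] = value
        out[chrom] = (lo, arr)
    return out


def write_bedgraph(tracks: Mapping[str, tuple[int, np.ndarray]], path: Path | str) -> None:
    """Write per-base tracks as bedGraph, one line per base (NaN skipped)."""
    with open(path, "w") as fh:
        for chrom, (origin, scores) in tracks.items():
            for i, v in enumerate(scores):
                if not np.isnan(v):
                    fh.write(f"{chrom}\t{origin + i}\t{origin + i + 1}\t{v:.6g}\n")


# ---------------------------------------------------------------------------
# MAF (UCSC multiple alignment format)


@dataclass(frozen=True)
class MafRow:
    src: str  # "species.chrom"
    start: int  # 0-based on the source strand
    size: int  # aligned bases (gaps excluded)
    strand: str
    src_size: int
    text: str  # alignment row, may contain '-'

    @property
    def species(self) -> str:
        return self.src.split(".", 1)[0]


@dataclass(frozen=True)
class MafBlock:
    rows: tuple[MafRow, ...]

    def __post_init__(self) -> None:
        widths = {len(r.text) for r in self.rows}
        if len(widths) > 1:
            raise ValueError(f"MAF block with rows {[r.src for r in self.rows]}: mismatched row lengths {sorted(widths)}")
        for r in self.rows:
            if len(r.text.replace("-", "")) != r.size:
                raise ValueError(f"MAF row {r.src}: size {r.size} != {len(r.text.replace('-', ''))} non-gap bases")


def read_maf(source) -> list[MafBlock]:
    blocks: list[MafBlock] = []
    rows: list[MafRow] = []
    for ln, raw in enumerate(_as_handle(source), 1):
        line = raw.rstrip("\n")
        if line.startswith("a"):
            if rows:
                blocks.append(MafBlock(tuple(rows)))
                rows = []
        elif line.startswith("s "):
            parts = line.split()
            if len(parts) != 7:
                raise ValueError(f"MAF line {ln}: expected 7 fields in 's' line")
            _, src, start, size, strand, src_size, text = parts
            rows.append(MafRow(src, int(start), int(size), strand, int(src_size), text))
    if rows:
        blocks.append(MafBlock(tuple(rows)))
    if not blocks:
        raise ValueError("no alignment blocks found")
    return blocks


def write_maf(blocks: Iterable[MafBlock], path: Path | str) -> None:
    with open(path, "w") as fh:
        fh.write("##maf version=1\n")
        for block in blocks:
            fh.write("\na score=0.0\n")
            for r in block.rows:
                fh.write(f"s {r.src} {r.start} {r.size} {r.strand} {r.src_size} {r.text}\n")


# ---------------------------------------------------------------------------
# MEME minimal motif format


def read_meme(source) -> dict[str, PositionWeightMatrix]:
    """MEME minimal format → {motif name: probability PWM}."""
    lines = _as_handle(source).read().splitlines()
    background = np.full(4, 0.25)
    pwms: dict[str, PositionWeightMatrix] = {}
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("Background letter frequencies"):
            freq = lines[i + 1].split()
            background = np.array([float(freq[2 * k + 1]) for k in range(4)])
            i += 2
            continue
        if line.startswith("MOTIF"):
            name = line.split()[1]
            i += 1
            while not lines[i].strip().startswith("letter-probability matrix"):
                i += 1
            header = lines[i].strip()
            kv = dict(
                part.strip().split("=")
                for part in header.removeprefix("letter-probability matrix:").replace(" =", "=").replace("= ", "=").split()
                if "=" in part
            )
            width = int(kv["w"])
            rows = []
            for j in range(width):
                rows.append([float(x) for x in lines[i + 1 + j].split()])
            pwms[name] = PositionWeightMatrix(element_name=name, probs=np.array(rows), background=background)
            i += 1 + width
            continue
        i += 1
    if not pwms:
        raise ValueError("no MOTIF entries found")
    return pwms


def write_meme(pwms: Mapping[str, PositionWeightMatrix], path: Path | str) -> None:
    first = next(iter(pwms.values()))
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: +\n\n")
        fh.write("Background letter frequencies\n")
        fh.write(" ".join(f"{b} {f:.6g}" for b, f in zip(ALPHABET, first.background)) + "\n")
        for name, pwm in pwms.items():
            fh.write(f"\nMOTIF {name}\n")
            fh.write(f"letter-probability matrix: alength= 4 w= {pwm.width} nsites= 10000 E= 0\n")
            for row in pwm.probs:
                fh.write(" " + " ".join(f"{p:.6f}" for p in row) + "\n")


def read_pwm_metadata(source) -> dict[str, dict]:
    """YAML of per-element anchor, canonical_window [start, end], threshold."""
    meta = yaml.safe_load(_as_handle(source).read())
    if not isinstance(meta, dict):
        raise ValueError("PWM metadata must be a mapping of element name to fields")
    return meta


# ---------------------------------------------------------------------------
# Presence matrix (+/- TSV)


def read_presence_tsv(source) -> pd.DataFrame:
    df = pd.read_csv(_as_handle(source), sep="\t", index_col=0)
    bad = set(df.values.ravel()) - {"+", "-"}
    if bad:
        raise ValueError(f"presence matrix cells must be '+' or '-', got {sorted(bad)}")
    return df == "+"


def write_presence_tsv(presence: pd.DataFrame, path: Path | str) -> None:
    out = presence.map(lambda v: "+" if v else "-")
    out.to_csv(path, sep="\t")
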