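"""Synthetic inputs for every pipeline stage, plus the packaged fixtures.

No public dataset accompanies the analyses this package implements, so each
stage has a seeded generator that emulates the statistical structure of its
real input:

* a promoter population with configurable composition proportions and a
  target subset with one category's proportion inflated;
* a per-base conservation track with exon/intergenic mean-SD structure and
  a promoter window drawn from either distribution;
* a star-phylogeny multi-species alignment with a planted, spacing-
  constrained combined motif degraded by per-site substitution.

Every generator is a pure function of its configuration (seed included):
repeated calls are byte-identical.  The packaged wild-type and mutant
minimal promoter sequences (seven genes × four variants, window -10..+40)
and the 40-species combined-motif presence/absence table ship as plain TSV
fixtures with their printed letter case preserved.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .coords import PromoterInterval, advance, to_string_index
from .io import MafBlock, MafRow, read_presence_tsv
from .pwm import (
    ALPHABET,
    CombinedMotifModel,
    PositionWeightMatrix,
    combine_pwms,
    load_default_pwms,
)
from .records import PromoterRecord
from .conservation import ConservationTrack, ExonSet

__all__ = [
    "MutationSpec",
    "MUTATIONS",
    "SimulationConfig",
    "DEFAULT_PROPORTIONS",
    "apply_mutation",
    "load_promoter_variants",
    "load_presence_table",
    "enriched_proportions",
    "gen_promoter_population",
    "gen_conservation_fixture",
    "gen_species_alignment",
    "default_combined_model",
]


# ---------------------------------------------------------------------------
# Printed fixtures and mutation specifications


@dataclass(frozen=True)
class MutationSpec:
    """A fixed-coordinate replacement mutation of the downstream region."""

    name: str
    replacement: str
    span: PromoterInterval

    def __post_init__(self) -> None:
        if len(self.replacement) != len(self.span):
            raise ValueError(
                f"{self.name}: replacement length {len(self.replacement)} != "
                f"span {self.span} length {len(self.span)}"
            )


MUTATIONS: dict[str, MutationSpec] = {
    "mDPE": MutationSpec("mDPE", "CTCATGT", PromoterInterval(28, 34)),
    "mBridgeI": MutationSpec("mBridgeI", "ATCCA", PromoterInterval(18, 22)),
    "mDPE_27_29": MutationSpec("mDPE_27_29", "GTA", PromoterInterval(27, 29)),
}


def apply_mutation(wt: PromoterRecord, spec: MutationSpec) -> PromoterRecord:
    """Replace the bases in ``spec.span`` with ``spec.replacement`` (upper case)."""
    if not wt.window.contains_interval(spec.span):
        raise ValueError(f"{spec.name} span {spec.span} outside record window {wt.window}")
    i = to_string_index(spec.span.start, wt.window.start)
    j = to_string_index(spec.span.end, wt.window.start)
    seq = wt.sequence[:i] + spec.replacement.upper() + wt.sequence[j + 1 :]
    return replace(wt, transcript_id=f"{wt.transcript_id}_{spec.name}", sequence=seq)


def _data_text(name: str) -> str:
    from importlib.resources import files

    return files("corepromoter.data").joinpath(name).read_text()


def load_promoter_variants() -> dict[tuple[str, str], PromoterRecord]:
    """Packaged minimal promoter variants: {(gene, variant): record}.

    28 records (7 genes × WT, mDPE, mBridgeI, mDPE_27_29) with window
    -10..+40 and printed letter case preserved (uppercase marks PWM
    matches); all scoring upcases internally.
    """
    df = pd.read_csv(pd.io.common.StringIO(_data_text("promoter_variants.tsv")), sep="\t")
    out = {}
    for _, row in df.iterrows():
        out[(row.gene, row.variant)] = PromoterRecord(
            transcript_id=f"{row.gene}_{row.variant}",
            gene_id=row.gene,
            sequence=row.sequence,
            window=PromoterInterval(-10, 40),
        )
    return out


def load_presence_table() -> pd.DataFrame:
    """Packaged species × gene combined-motif presence table (39 species, 7 genes)."""
    return read_presence_tsv(_data_text("species_presence.tsv"))


# ---------------------------------------------------------------------------
# Configuration

DEFAULT_PROPORTIONS: dict[str, float] = {
    "Inr+BridgeI+DPE": 0.08,
    "TATA+Inr": 0.10,
    "Inr+MTE": 0.08,
    "Inr+DPE": 0.12,
    "TATA_only": 0.08,
    "Inr_only": 0.24,
    "none_detected": 0.30,
}

# which elements are planted per composition category
_CATEGORY_ELEMENTS: dict[str, tuple[str, ...]] = {
    "Inr+BridgeI+DPE": ("Inr_dros", "BridgeI", "DPE"),
    "TATA+Inr": ("TATA", "Inr_dros"),
    "Inr+MTE": ("Inr_dros", "MTE"),
    "Inr+DPE": ("Inr_dros", "DPE"),
    "TATA_only": ("TATA",),
    "Inr_only": ("Inr_dros",),
    "none_detected": (),
}
_TATA_PLANT_ANCHOR = -31  # spans -31..-24, inside the -40..-20 search window


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the synthetic generators, with study-scale defaults."""

    seed: int = 0
    # promoter population
    n_genome: int = 13964
    n_target: int = 285
    category_proportions: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PROPORTIONS)
    )
    enrichment_factor: float = 2.0
    enriched_category: str = "Inr+BridgeI+DPE"
    window: PromoterInterval = field(default_factory=lambda: PromoterInterval(-40, 40))
    background_base_probs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    positional_jitter: int = 0
    # conservation fixture
    exon_mean: float = 2.0
    exon_sd: float = 1.0
    background_mean: float = 0.0
    background_sd: float = 1.0
    n_exons: int = 4
    exon_len: int = 300
    intron_len: int = 200
    promoter_conserved: bool = True
    promoter_shift_sd: float = 0.0
    # species alignment
    n_species: int = 10
    n_preserved: int | None = None
    substitution_rate: float = 0.10
    motif_preservation: float = 0.25
    flank: int = 500
    score_threshold: float = 5.0
    distance_limit: int = 200

    def __post_init__(self) -> None:
        total = sum(self.category_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"category proportions sum to {total}, not 1")
        if any(not 0 <= p <= 1 for p in self.category_proportions.values()):
            raise ValueError("category proportions must lie in [0, 1]")
        for p in (self.substitution_rate, self.motif_preservation):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.enrichment_factor <= 0:
            raise ValueError("enrichment_factor must be > 0")
        if abs(sum(self.background_base_probs) - 1.0) > 1e-9:
            raise ValueError("background base probabilities must sum to 1")


def enriched_proportions(
    proportions: Mapping[str, float], category: str, factor: float
) -> dict[str, float]:
    """Inflate one category by *factor*, rescaling the rest to sum to 1."""
    p = proportions[category] * factor
    if p >= 1:
        raise ValueError(f"inflated proportion {p} >= 1 is infeasible")
    rest = 1.0 - proportions[category]
    out = {c: q * (1.0 - p) / rest for c, q in proportions.items()}
    out[category] = p
    return out


# ---------------------------------------------------------------------------
# Promoter population


def _sample_site(
    pwm: PositionWeightMatrix,
    rng: np.random.Generator,
    min_score: float | None = None,
) -> str:
    """Draw one site column-wise from the PWM probabilities.

    With *min_score* set, sampling is rejection-truncated to sites scoring
    at least that value: a planted element must be a functional instance of
    its own definition, otherwise the generator's truth label would be
    wrong by construction.  Falls back to the consensus if 100 draws fail.
    """
    probs = pwm.probs / pwm.probs.sum(axis=1, keepdims=True)  # file rounding
    lo = pwm.log_odds
    for _ in range(100):
        cols = [rng.choice(4, p=probs[j]) for j in range(pwm.width)]
        if min_score is None or sum(lo[j, c] for j, c in enumerate(cols)) >= min_score:
            return "".join(ALPHABET[c] for c in cols)
    return pwm.consensus


def gen_promoter_population(
    config: SimulationConfig,
    n: int | None = None,
    proportions: Mapping[str, float] | None = None,
    prefix: str = "t",
    seed_offset: int = 0,
) -> tuple[list[PromoterRecord], list[str]]:
    """Records with elements planted at canonical anchors per category.

    Each record's category is drawn from *proportions*; its elements are
    sampled column-wise from the packaged PWMs and written at their
    canonical anchors (TATA at -31..-24); all other bases are i.i.d. from
    the background composition.  Returns the records and the true category
    labels.  ``positional_jitter`` shifts each planted element by a uniform
    offset in ±jitter, which probes the strict spacing requirement (a
    shifted element leaves its canonical window and is no longer called).
    """
    n = config.n_genome if n is None else n
    proportions = dict(config.category_proportions if proportions is None else proportions)
    total = sum(proportions.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"proportions sum to {total}, not 1")
    unknown = set(proportions) - set(_CATEGORY_ELEMENTS)
    if unknown:
        raise ValueError(f"no planting recipe for categories {sorted(unknown)}")
    pwms = load_default_pwms()
    from .pwm import default_thresholds

    thresholds = default_thresholds()
    rng = np.random.default_rng(int(config.seed) + int(seed_offset))
    cats = list(proportions)
    probs = np.array([proportions[c] for c in cats])
    labels = rng.choice(len(cats), size=n, p=probs)
    window = config.window
    width = len(window)
    bg = np.array(config.background_base_probs)
    records, truth = [], []
    for i, li in enumerate(labels):
        cat = cats[li]
        seq = rng.choice(4, size=width, p=bg)
        for element in _CATEGORY_ELEMENTS[cat]:
            pwm = pwms[element]
            anchor = _TATA_PLANT_ANCHOR if element == "TATA" else pwm.anchor
            if config.positional_jitter:
                anchor = advance(anchor, int(rng.integers(-config.positional_jitter,
                                                          config.positional_jitter + 1)))
            site = _sample_site(pwm, rng, min_score=thresholds.get(element))
            j = to_string_index(anchor, window.start)
            seq[j : j + pwm.width] = [ALPHABET.index(b) for b in site]
        records.append(PromoterRecord(
            transcript_id=f"{prefix}{i:05d}",
            sequence="".join(ALPHABET[b] for b in seq),
            window=window,
        ))
        truth.append(cat)
    return records, truth


# ---------------------------------------------------------------------------
# Conservation fixture


def gen_conservation_fixture(
    config: SimulationConfig, seed_offset: int = 1
) -> tuple[ConservationTrack, ExonSet, pd.DataFrame, dict]:
    """One synthetic gene: track with exon structure, exon BED, TSS table, truth.

    Exonic bases score i.i.d. Normal(exon_mean, exon_sd); everything else
    Normal(background_mean, background_sd).  The -2..+33 promoter window is
    re-drawn from the exon distribution when ``promoter_conserved`` (with an
    optional mean shift of ``promoter_shift_sd`` null-SDs, i.e. exon_sd /
    sqrt(35) units, for power experiments); otherwise it keeps background
    scores.
    """
    rng = np.random.default_rng(int(config.seed) + int(seed_offset))
    chrom, tss, strand = "chrSim", 1000, "+"
    gene_start = 1100
    step = config.exon_len + config.intron_len
    exons = ExonSet(
        [(chrom, gene_start + k * step, gene_start + k * step + config.exon_len)
         for k in range(config.n_exons)],
        strand=strand,
    )
    length = gene_start + config.n_exons * step + 100
    scores = rng.normal(config.background_mean, config.background_sd, size=length)
    for _, s, e in exons.intervals:
        scores[s:e] = rng.normal(config.exon_mean, config.exon_sd, size=e - s)
    w0, w1 = tss - 2, tss + 33  # promoter window -2..+33 on the + strand
    if config.promoter_conserved:
        shift = config.promoter_shift_sd * config.exon_sd / np.sqrt(w1 - w0)
        scores[w0:w1] = rng.normal(config.exon_mean + shift, config.exon_sd, size=w1 - w0)
    track = ConservationTrack(chrom=chrom, origin=0, scores=scores)
    tss_table = pd.DataFrame(
        [dict(gene="simgene", chrom=chrom, tss=tss, strand=strand)]
    )
    truth = dict(gene="simgene", conserved=bool(config.promoter_conserved),
                 shift_sd=float(config.promoter_shift_sd))
    return track, exons, tss_table, truth


# ---------------------------------------------------------------------------
# Species alignment


def _naive_qualifying_hit(
    seq: str, model: CombinedMotifModel, anchor: int,
    score_threshold: float, distance_limit: int,
) -> bool:
    """Exhaustive check for any qualifying combined-motif window (generator truth)."""
    lo = model.log_odds
    width = model.width
    idx = [ALPHABET.index(b) for b in seq]
    for i in range(len(seq) - width + 1):
        if abs(i + model.tss_column - anchor) > distance_limit:
            continue
        s = 0.0
        for j in range(width):
            s += lo[j, idx[i + j]]
        if s > score_threshold:
            return True
    return False


def default_combined_model() -> CombinedMotifModel:
    pwms = load_default_pwms()
    return combine_pwms(pwms["Inr_dros"], pwms["BridgeI"], pwms["DPE"])


def gen_species_alignment(
    config: SimulationConfig,
    ancestor: str | None = None,
    gene: str = "simgene",
    model: CombinedMotifModel | None = None,
    seed_offset: int = 2,
) -> tuple[list[MafBlock], dict[str, bool], int]:
    """Star-phylogeny alignment with a planted combined motif, plus truth.

    The reference sequence carries the combined-model consensus at its
    centre anchor (spacer and flank bases i.i.d. background, resampled until
    the planted site is the only qualifying window).  Each of ``n_species``
    descendants receives i.i.d. substitutions at ``substitution_rate``;
    inside motif-informative columns the rate is multiplied by
    ``motif_preservation`` for the ``n_preserved`` preserved species, while
    ablated species get those columns redrawn uniformly.  A species'
    mutation draw is repeated until its truth (exhaustively computed
    existence of a qualifying hit) matches its planted design, so the truth
    table equals the design by construction.  Returns the alignment as one
    gap-free MAF block, the per-species truth (reference included), and the
    reference TSS coordinate.
    """
    model = model if model is not None else default_combined_model()
    rng = np.random.default_rng(int(config.seed) + int(seed_offset))
    flank = config.flank
    L = 2 * flank + 1
    anchor = flank
    bg = np.array(config.background_base_probs)
    informative = np.flatnonzero(np.any(model.log_odds != 0.0, axis=1))
    consensus_cols = np.argmax(model.log_odds, axis=1)
    motif_start = anchor - model.tss_column  # string index of model column 0

    if ancestor is None:
        for _ in range(200):
            seq = rng.choice(4, size=L, p=bg)
            seq[motif_start + informative] = consensus_cols[informative]
            text = "".join(ALPHABET[b] for b in seq)
            # the planted site must be the unique qualifying window
            without = seq.copy()
            without[motif_start + informative] = rng.choice(4, size=len(informative), p=bg)
            if _naive_qualifying_hit(text, model, anchor, config.score_threshold,
                                     config.distance_limit) and not _naive_qualifying_hit(
                "".join(ALPHABET[b] for b in without), model, anchor,
                config.score_threshold, config.distance_limit,
            ):
                ancestor = text
                break
        else:
            raise RuntimeError("could not construct a clean ancestor window")
    if len(ancestor) != L:
        raise ValueError(f"ancestor length {len(ancestor)} != 2*flank+1 = {L}")
    anc = np.array([ALPHABET.index(b) for b in ancestor.upper()])

    n_preserved = config.n_preserved
    if n_preserved is None:
        n_preserved = config.n_species // 2 + 1
    order = rng.permutation(config.n_species)
    preserved = {f"sp{int(i):02d}" for i in order[:n_preserved]}

    motif_mask = np.zeros(L, dtype=bool)
    motif_mask[motif_start + informative] = True
    rows = [MafRow(src="dmel_sim.chr2L", start=10000, size=L, strand="+",
                   src_size=1_000_000, text=ancestor.upper())]
    truth: dict[str, bool] = {"dmel_sim": True}
    for i in range(config.n_species):
        name = f"sp{i:02d}"
        keep = name in preserved
        for _ in range(80):
            seq = anc.copy()
            sub = rng.random(L) < config.substitution_rate
            if keep:
                sub[motif_mask] = rng.random(motif_mask.sum()) < (
                    config.substitution_rate * config.motif_preservation
                )
            else:
                seq[motif_mask] = rng.choice(4, size=motif_mask.sum(), p=bg)
            # substitutions draw one of the three other bases
            new = (seq[sub] + rng.integers(1, 4, size=int(sub.sum()))) % 4
            seq[sub] = new
            text = "".join(ALPHABET[b] for b in seq)
            has = _naive_qualifying_hit(text, model, anchor, config.score_threshold,
                                        config.distance_limit)
            if has == keep:
                break
        else:
            raise RuntimeError(f"{name}: could not realise the planted design")
        truth[name] = keep
        rows.append(MafRow(src=f"{name}.chrU", start=0, size=L, strand="+",
                           src_size=L, text=text))
    block = MafBlock(tuple(rows))
    reference_tss = 10000 + anchor
    return [block], truth, reference_tss
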