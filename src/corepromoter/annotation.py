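"""Promoter element annotation, composition categories, and enrichment.

Each promoter record is annotated with the best-scoring hit per element
inside that element's canonical window, assigned to exactly one composition
category by an ordered, most-specific-first rule list, and a target set's
category proportions are tested against genome-wide proportions with
per-category 1-df chi-square goodness-of-fit tests and Bonferroni control.

The initiator comes in two variants (Drosophila TCAKTY-like, mammalian
YYANWYY-like); a record's Inr call is the better-scoring variant that
passes its threshold, and category rules treat either variant as "Inr".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .pwm import MotifHit, PositionWeightMatrix, load_default_pwms, default_thresholds, scan
from .records import PromoterRecord

logger = logging.getLogger(__name__)

__all__ = [
    "INR_VARIANTS",
    "CategoryRule",
    "DEFAULT_RULES",
    "EnrichmentResult",
    "annotate",
    "classify",
    "classify_records",
    "count_categories",
    "enrichment_test",
    "annotation_table",
]

INR_VARIANTS = ("Inr_dros", "Inr_mamm")


def annotate(
    record: PromoterRecord,
    pwms: Mapping[str, PositionWeightMatrix] | None = None,
    thresholds: Mapping[str, float] | None = None,
) -> list[MotifHit]:
    """Best hit per element within its canonical window; at most one Inr.

    Elements whose canonical window is not covered by the record are logged
    as not assessable and skipped.  When both initiator variants pass their
    thresholds only the higher-scoring one is reported, so downstream code
    can read the variant off the hit's element name.
    """
    pwms = pwms if pwms is not None else load_default_pwms()
    thresholds = thresholds if thresholds is not None else default_thresholds()
    hits: list[MotifHit] = []
    for name, pwm in pwms.items():
        window = pwm.canonical_window
        if window is None:
            raise ValueError(f"{name}: packaged/annotation PWMs need a canonical window")
        if not record.window.contains_interval(window):
            logger.info("%s: %s window %s not assessable (record %s)",
                        record.transcript_id, name, window, record.window)
            continue
        found = scan(pwm, record, thresholds[name], positional_window=window)
        if found:
            hits.append(max(found, key=lambda h: h.score))
    inr = [h for h in hits if h.element_name in INR_VARIANTS]
    if len(inr) == 2:
        drop = min(inr, key=lambda h: h.score)
        hits.remove(drop)
    return sorted(hits, key=lambda h: h.start)


@dataclass(frozen=True)
class CategoryRule:
    """One composition category: present iff all required element groups hit.

    A required group is a tuple of element names of which at least one must
    be present (so ("Inr_dros", "Inr_mamm") means "any initiator").
    """

    name: str
    required: tuple[tuple[str, ...], ...]

    def matches(self, present: set[str]) -> bool:
        return all(any(e in present for e in group) for group in self.required)


_INR = (INR_VARIANTS,)
DEFAULT_RULES: tuple[CategoryRule, ...] = (
    CategoryRule("Inr+BridgeI+DPE", _INR + (("BridgeI",), ("DPE",))),
    CategoryRule("TATA+Inr", (("TATA",),) + _INR),
    CategoryRule("Inr+MTE", _INR + (("MTE",),)),
    CategoryRule("Inr+DPE", _INR + (("DPE",),)),
    CategoryRule("TATA_only", (("TATA",),)),
    CategoryRule("Inr_only", _INR),
    CategoryRule("none_detected", ()),
)
DEFAULT_CATEGORIES = tuple(r.name for r in DEFAULT_RULES)


def classify(hits: Iterable[MotifHit], rules: Sequence[CategoryRule] = DEFAULT_RULES) -> str:
    """First matching rule in priority order; falls through to the last rule."""
    present = {h.element_name for h in hits}
    for rule in rules:
        if rule.matches(present):
            return rule.name
    return rules[-1].name


def classify_records(
    records: Iterable[PromoterRecord],
    pwms: Mapping[str, PositionWeightMatrix] | None = None,
    thresholds: Mapping[str, float] | None = None,
    rules: Sequence[CategoryRule] = DEFAULT_RULES,
) -> pd.Series:
    """Category per transcript; broad-shape records are excluded."""
    pwms = pwms if pwms is not None else load_default_pwms()
    thresholds = thresholds if thresholds is not None else default_thresholds()
    out = {}
    for rec in records:
        if rec.shape_class == "broad":
            logger.info("%s: broad promoter excluded from composition analysis", rec.transcript_id)
            continue
        out[rec.transcript_id] = classify(annotate(rec, pwms, thresholds), rules)
    return pd.Series(out, name="category", dtype=object)


def count_categories(categories: Iterable[str], category_set: Sequence[str] = DEFAULT_CATEGORIES) -> pd.Series:
    counts = pd.Series(0, index=list(category_set), name="count")
    for c in categories:
        if c not in counts.index:
            raise ValueError(f"category {c!r} not in the configured category set")
        counts[c] += 1
    return counts


@dataclass(frozen=True)
class EnrichmentResult:
    category: str
    target_count: int
    target_total: int
    expected_proportion: float
    chi2_statistic: float
    p_raw: float
    p_adjusted: float
    n_tests: int
    direction: str  # enriched | depleted | none
    flagged: bool


def enrichment_test(
    target_counts: Mapping[str, int] | pd.Series,
    genome_counts: Mapping[str, int] | pd.Series,
    alpha: float = 0.05,
    yates: bool = False,
    two_sample: bool = False,
) -> list[EnrichmentResult]:
    """Per-category chi-square of the target composition against the genome.

    By default the genome is treated as the population: each category gets a
    1-df goodness-of-fit test of the target's in/out split against the
    genome proportion.  ``two_sample=True`` instead tests the 2x2 target ×
    genome contingency table per category.  P-values are Bonferroni-adjusted
    over the number of categories.
    """
    target = pd.Series(target_counts, dtype=float)
    genome = pd.Series(genome_counts, dtype=float)
    if set(target.index) != set(genome.index):
        raise ValueError("target and genome counts must cover the same categories")
    genome = genome.reindex(target.index)
    n_target, n_genome = target.sum(), genome.sum()
    if n_target <= 0 or n_genome <= 0:
        raise ValueError("both count vectors must have positive totals")
    k = len(target)
    results = []
    for cat in target.index:
        obs_in, obs_out = target[cat], n_target - target[cat]
        p0 = genome[cat] / n_genome
        if two_sample:
            table = np.array([[target[cat], n_target - target[cat]],
                              [genome[cat], n_genome - genome[cat]]])
            chi2, p_raw, _, _ = stats.chi2_contingency(table, correction=yates)
        else:
            expected = np.array([n_target * p0, n_target * (1 - p0)])
            observed = np.array([obs_in, obs_out])
            if np.any((expected == 0) & (observed > 0)):
                raise ValueError(
                    f"category {cat!r}: expected count 0 with nonzero observed; "
                    "genome proportions cannot explain the target"
                )
            with np.errstate(invalid="ignore", divide="ignore"):
                dev = np.abs(observed - expected)
                if yates:
                    dev = np.maximum(dev - 0.5, 0.0)
                terms = np.where(expected > 0, dev**2 / expected, 0.0)
            chi2 = float(terms.sum())
            p_raw = float(stats.chi2.sf(chi2, df=1))
        p_adj = min(1.0, p_raw * k)
        if obs_in / n_target > p0:
            direction = "enriched"
        elif obs_in / n_target < p0:
            direction = "depleted"
        else:
            direction = "none"
        results.append(EnrichmentResult(
            category=str(cat), target_count=int(obs_in), target_total=int(n_target),
            expected_proportion=float(p0), chi2_statistic=float(chi2),
            p_raw=float(p_raw), p_adjusted=float(p_adj), n_tests=k,
            direction=direction, flagged=bool(p_adj < alpha),
        ))
    return results


def annotation_table(
    records: Iterable[PromoterRecord],
    pwms: Mapping[str, PositionWeightMatrix] | None = None,
    thresholds: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Long-format per-transcript hit report (element, span, score, sequence)."""
    pwms = pwms if pwms is not None else load_default_pwms()
    thresholds = thresholds if thresholds is not None else default_thresholds()
    rows = []
    for rec in records:
        for h in annotate(rec, pwms, thresholds):
            rows.append(dict(transcript_id=rec.transcript_id, gene_id=rec.gene_id,
                             element=h.element_name, start=h.start, end=h.end,
                             score=round(h.score, 4), matched_seq=h.matched_seq))
    return pd.DataFrame(rows, columns=["transcript_id", "gene_id", "element", "start", "end", "score", "matched_seq"])
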