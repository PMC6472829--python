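"""Position weight matrices anchored to TSS-relative coordinates.

Matrices are stored as per-column base probabilities over {A, C, G, T} and
scored as summed log2 odds against a background composition.  Each packaged
matrix carries a *canonical window*: the promoter-coordinate interval where
hits count towards a composition call (e.g. DPE at +28..+33).  A combined
initiator-BridgeI-DPE model spans -2..+33 with zero-scoring spacer columns,
so its score at any 35-mer is exactly the sum of the three component scores.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .coords import (
    PromoterInterval,
    advance,
    from_string_index,
    to_string_index,
)
from .records import PromoterRecord

logger = logging.getLogger(__name__)

ALPHABET = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}
UNIFORM_BACKGROUND = np.full(4, 0.25)

__all__ = [
    "ALPHABET",
    "UNIFORM_BACKGROUND",
    "PositionWeightMatrix",
    "MotifHit",
    "CombinedMotifModel",
    "build_pwm",
    "score_window",
    "scan",
    "combine_pwms",
    "load_default_pwms",
    "default_thresholds",
]


@dataclass(frozen=True)
class PositionWeightMatrix:
    """Probability PWM with a TSS-relative anchor.

    ``probs`` has shape (width, 4) with columns over A, C, G, T; each row
    sums to 1.  ``anchor`` is the promoter coordinate of the first column
    and ``canonical_window`` the interval inside which hits are accepted
    for composition calls (defaults to the exact anchored span).
    """

    element_name: str
    probs: np.ndarray
    background: np.ndarray = field(default_factory=lambda: UNIFORM_BACKGROUND.copy())
    anchor: int | None = None
    canonical_window: PromoterInterval | None = None

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=float)
        if probs.ndim != 2 or probs.shape[1] != 4:
            raise ValueError("probs must have shape (width, 4)")
        if not np.allclose(probs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError(f"{self.element_name}: probability columns must sum to 1")
        if np.any(probs < 0):
            raise ValueError(f"{self.element_name}: negative probabilities")
        bg = np.asarray(self.background, dtype=float)
        if bg.shape != (4,) or not np.isclose(bg.sum(), 1.0):
            raise ValueError("background must be a length-4 probability vector")
        object.__setattr__(self, "probs", probs)
        object.__setattr__(self, "background", bg)
        if self.canonical_window is None and self.anchor is not None:
            end = advance(self.anchor, self.width - 1)
            object.__setattr__(self, "canonical_window", PromoterInterval(self.anchor, end))

    @property
    def width(self) -> int:
        return self.probs.shape[0]

    @property
    def log_odds(self) -> np.ndarray:
        """(width, 4) matrix of log2(p / background), in bits.

        Zero probabilities (possible only with pseudocount 0) map to -inf;
        any positive pseudocount guarantees finite weights.
        """
        with np.errstate(divide="ignore"):
            return np.log2(self.probs / self.background)

    @property
    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in np.argmax(self.probs, axis=1))

    def max_score(self) -> float:
        return float(self.log_odds.max(axis=1).sum())

    def with_anchor(self, anchor: int, canonical_window: PromoterInterval | None = None) -> "PositionWeightMatrix":
        return replace(self, anchor=anchor, canonical_window=canonical_window)


@dataclass(frozen=True)
class MotifHit:
    """One element occurrence in a promoter window."""

    element_name: str
    start: int  # promoter coordinate of first matched base
    end: int  # promoter coordinate of last matched base
    score: float
    matched_seq: str


def build_pwm(
    aligned_sites: Sequence[str],
    pseudocount: float = 0.01,
    background: np.ndarray | Sequence[float] = UNIFORM_BACKGROUND,
    element_name: str = "custom",
    anchor: int | None = None,
) -> PositionWeightMatrix:
    """Build a probability PWM from equal-length aligned sites.

    N bases are ignored in the counts; *pseudocount* is added per base per
    column before normalising, so any positive value guarantees strictly
    positive probabilities.
    """
    if not aligned_sites:
        raise ValueError("need at least one site")
    width = len(aligned_sites[0])
    if width == 0 or any(len(s) != width for s in aligned_sites):
        raise ValueError("sites must be non-empty and of uniform length")
    counts = np.zeros((width, 4))
    for site in aligned_sites:
        for j, base in enumerate(site.upper()):
            if base == "N":
                continue
            try:
                counts[j, _BASE_INDEX[base]] += 1
            except KeyError:
                raise ValueError(f"invalid base {base!r} in site {site!r}") from None
    counts += pseudocount
    totals = counts.sum(axis=1, keepdims=True)
    if np.any(totals == 0):
        raise ValueError("a column has no counts and pseudocount is 0")
    return PositionWeightMatrix(
        element_name=element_name,
        probs=counts / totals,
        background=np.asarray(background, dtype=float),
        anchor=anchor,
    )


def _scores_along(log_odds: np.ndarray, expected: np.ndarray, seq: str) -> np.ndarray:
    """Score every window of ``seq`` (upper-cased) against a log-odds matrix.

    Returns an array of length ``len(seq) - width + 1``; N bases contribute
    the background-expected column score.
    """
    width = log_odds.shape[0]
    n = len(seq) - width + 1
    idx = np.frompyfunc(lambda b: _BASE_INDEX.get(b, 4), 1, 1)(np.array(list(seq))).astype(int)
    padded = np.hstack([log_odds, expected[:, None]])  # column 4 = N
    out = np.zeros(n)
    for j in range(width):
        out += padded[j, idx[j : j + n]]
    return out


def score_window(pwm: "PositionWeightMatrix | CombinedMotifModel", seq: str) -> float:
    """Log-odds score (bits) of a sequence exactly as wide as the model."""
    lo, expected = _model_arrays(pwm)
    if len(seq) != lo.shape[0]:
        raise ValueError(f"sequence length {len(seq)} != model width {lo.shape[0]}")
    seq = seq.upper()
    bad = set(seq) - set(ALPHABET) - {"N"}
    if bad:
        raise ValueError(f"invalid bases {sorted(bad)}")
    return float(_scores_along(lo, expected, seq)[0])


def _model_arrays(model) -> tuple[np.ndarray, np.ndarray]:
    lo = model.log_odds
    return lo, lo @ model.background


def scan(
    pwm: "PositionWeightMatrix | CombinedMotifModel",
    record: PromoterRecord,
    threshold: float,
    positional_window: PromoterInterval | None = None,
) -> list[MotifHit]:
    """All sense-strand windows scoring at least *threshold*, sorted by start.

    With *positional_window* given, only hits lying entirely inside it are
    returned.  A record shorter than the model yields an empty list with a
    logged warning rather than an error.
    """
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    lo, expected = _model_arrays(pwm)
    width = lo.shape[0]
    seq = record.sequence.upper()
    if len(seq) < width:
        logger.warning(
            "%s: sequence (%d nt) shorter than %s model (%d nt); no scan",
            record.transcript_id, len(seq), _model_name(pwm), width,
        )
        return []
    scores = _scores_along(lo, expected, seq)
    hits: list[MotifHit] = []
    for i, s in enumerate(scores):
        if s < threshold:
            continue
        start = from_string_index(i, record.window.start)
        end = advance(start, width - 1)
        if end > record.window.end:
            continue
        if positional_window is not None and not positional_window.contains_interval(
            PromoterInterval(start, end)
        ):
            continue
        hits.append(MotifHit(_model_name(pwm), start, end, float(s), seq[i : i + width]))
    return hits


def _model_name(model) -> str:
    return model.element_name if isinstance(model, PositionWeightMatrix) else model.name


@dataclass(frozen=True)
class CombinedMotifModel:
    """Initiator + BridgeI + DPE scored jointly over a fixed -2..+33 frame.

    The model is a 35-column log-odds matrix: component columns carry the
    component log odds, spacer columns are all-zero, so the combined score
    of a 35-mer equals the sum of its three component window scores exactly.
    """

    components: tuple[PositionWeightMatrix, ...]
    log_odds: np.ndarray
    background: np.ndarray
    span: PromoterInterval = field(default_factory=lambda: PromoterInterval(-2, 33))
    name: str = "Inr+BridgeI+DPE"

    @property
    def width(self) -> int:
        return self.log_odds.shape[0]

    @property
    def element_name(self) -> str:
        return self.name

    @property
    def tss_column(self) -> int:
        """0-based model column aligned with promoter position +1."""
        return to_string_index(1, self.span.start)

    def max_score(self) -> float:
        return float(self.log_odds.max(axis=1).sum())


def combine_pwms(
    inr: PositionWeightMatrix,
    bridge: PositionWeightMatrix,
    dpe: PositionWeightMatrix,
    span: PromoterInterval = PromoterInterval(-2, 33),
) -> CombinedMotifModel:
    """Assemble the combined downstream core promoter model.

    Components must be anchored (``anchor`` set), lie inside *span* and not
    overlap; every unoccupied column becomes a zero-scoring spacer.
    """
    components = (inr, bridge, dpe)
    width = len(span)
    log_odds = np.zeros((width, 4))
    occupied = np.zeros(width, dtype=bool)
    bg = None
    for pwm in components:
        if pwm.anchor is None:
            raise ValueError(f"{pwm.element_name}: component PWM needs an anchor")
        start = pwm.anchor
        end = advance(start, pwm.width - 1)
        if not span.contains_interval(PromoterInterval(start, end)):
            raise ValueError(f"{pwm.element_name} at {start:+d}..{end:+d} exceeds span {span}")
        i = to_string_index(start, span.start)
        cols = slice(i, i + pwm.width)
        if occupied[cols].any():
            raise ValueError(f"{pwm.element_name} overlaps a previous component")
        occupied[cols] = True
        log_odds[cols] = pwm.log_odds
        if bg is None:
            bg = pwm.background
        elif not np.allclose(bg, pwm.background):
            raise ValueError("components disagree on background composition")
    name = "+".join(p.element_name for p in components)
    return CombinedMotifModel(components=components, log_odds=log_odds, background=bg, span=span, name=name)


# ---------------------------------------------------------------------------
# Packaged default matrices


def _data_path(name: str):
    from importlib.resources import files

    return files("corepromoter.data").joinpath(name)


def load_default_pwms() -> dict[str, PositionWeightMatrix]:
    """Packaged element matrices with anchors and canonical windows.

    These are reconstructions from published element consensus degeneracies
    and observed Drosophila promoter sites; they are data, not ground truth,
    and can be replaced by any MEME-minimal file plus an anchors YAML.
    """
    from .io import read_meme, read_pwm_metadata

    pwms = read_meme(_data_path("pwms.meme").read_text())
    meta = read_pwm_metadata(_data_path("pwm_anchors.yaml").read_text())
    out = {}
    for name, pwm in pwms.items():
        m = meta.get(name, {})
        anchor = m.get("anchor")
        window = m.get("canonical_window")
        out[name] = replace(
            pwm,
            anchor=anchor,
            canonical_window=PromoterInterval(*window) if window else None,
        )
        # re-derive the default window from the anchor when not given
        if window is None and anchor is not None:
            out[name] = out[name].with_anchor(anchor)
    return out


def default_thresholds() -> dict[str, float]:
    """Per-element default score thresholds (bits), from the anchors YAML."""
    from .io import read_pwm_metadata

    meta = read_pwm_metadata(_data_path("pwm_anchors.yaml").read_text())
    return {name: m["threshold"] for name, m in meta.items() if "threshold" in m}
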