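"""PWM log-odds scanning on both strands with relative-score thresholding,
plus per-column information content.

The relative score is the min-max normalized log2-odds score,
``(score - min_score) / (max_score - min_score)``; a site passes at the
default threshold when its relative score is at least 0.90. Overlapping
hits of the same TF are greedily pruned keeping the higher score.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .formats_io import GenomicInterval, Pwm

__all__ = [
    "MotifSite",
    "information_content",
    "log_odds",
    "score_bounds",
    "rel_score",
    "reverse_complement",
    "scan",
    "scan_sequence",
]

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass(frozen=True)
class MotifSite:
    """A scanned motif occurrence. ``rel_score`` is min-max normalized
    log-odds, in [0, 1]."""

    interval: GenomicInterval
    tf_name: str
    strand: str
    score: float
    rel_score: float

    def __post_init__(self) -> None:
        if not (-1e-9 <= self.rel_score <= 1 + 1e-9):
            raise ValueError(f"rel_score {self.rel_score} outside [0, 1]")


def information_content(pwm: Pwm) -> tuple[float, np.ndarray]:
    """Total and per-column information content in bits.

    Column c contributes sum_b p_bc * log2(p_bc / bg_b); with a uniform
    background this is the usual 2 - H(column) and is never negative.
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = pwm.probs * np.log2(pwm.probs / pwm.background)
    per_column = terms.sum(axis=1)
    return float(per_column.sum()), per_column


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _log_odds_matrix(pwm: Pwm) -> np.ndarray:
    return np.log2(pwm.probs / pwm.background)


def log_odds(seq: str, pwm: Pwm, strand: str = "+") -> float:
    """Log2-odds score of a sequence of exactly PWM width.

    N bases contribute 0 (neutral). On the minus strand the reverse
    complement is scored.
    """
    if len(seq) != pwm.width:
        raise ValueError(
            f"sequence length {len(seq)} != PWM width {pwm.width}"
        )
    if strand == "-":
        seq = reverse_complement(seq)
    lom = _log_odds_matrix(pwm)
    score = 0.0
    for c, base in enumerate(seq.upper()):
        if base == "N":
            continue
        try:
            score += lom[c, _BASE_INDEX[base]]
        except KeyError:
            raise ValueError(f"invalid base {base!r} at position {c}") from None
    return float(score)


def score_bounds(pwm: Pwm) -> tuple[float, float]:
    """(min, max) achievable log-odds over ACGT sequences."""
    lom = _log_odds_matrix(pwm)
    return float(lom.min(axis=1).sum()), float(lom.max(axis=1).sum())


def rel_score(score: float, pwm: Pwm) -> float:
    lo, hi = score_bounds(pwm)
    return (score - lo) / (hi - lo)


def _encode(seq: str) -> np.ndarray:
    """A,C,G,T -> 0..3; anything else (N) -> 4."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, 4, dtype=np.int8)
    for base, idx in _BASE_INDEX.items():
        out[arr == ord(base)] = idx
    return out


def _window_scores(codes: np.ndarray, lom5: np.ndarray) -> np.ndarray:
    """Scores of all length-W windows of an encoded sequence.

    ``lom5`` is the log-odds matrix padded with a zero column for N.
    """
    w = lom5.shape[0]
    n_win = len(codes) - w + 1
    if n_win <= 0:
        return np.zeros(0)
    scores = np.zeros(n_win)
    for c in range(w):
        scores += lom5[c, codes[c : c + n_win]]
    return scores


def scan_sequence(
    seq: str, pwm: Pwm, rel_threshold: float = 0.90
) -> list[tuple[int, str, float, float]]:
    """Scan one sequence on both strands.

    Returns (offset, strand, score, rel_score) tuples for every window whose
    relative score reaches the threshold, after greedy overlap pruning
    (higher score wins; leftmost, then '+', on ties), sorted by offset.
    """
    w = pwm.width
    if len(seq) < w:
        return []
    lo, hi = score_bounds(pwm)
    span = hi - lo
    lom = _log_odds_matrix(pwm)
    lom5 = np.hstack([lom, np.zeros((w, 1))])
    codes = _encode(seq)

    fwd = _window_scores(codes, lom5)
    # minus strand: score revcomp of each window == scan with the
    # reverse-complemented matrix at the same offset
    lom_rc = lom[::-1, ::-1]
    lom_rc5 = np.hstack([lom_rc, np.zeros((w, 1))])
    rev = _window_scores(codes, lom_rc5)

    candidates: list[tuple[int, str, float, float]] = []
    for strand, scores in (("+", fwd), ("-", rev)):
        rel = (scores - lo) / span
        for off in np.flatnonzero(rel >= rel_threshold - 1e-12):
            candidates.append(
                (int(off), strand, float(scores[off]), float(np.clip(rel[off], 0, 1)))
            )

    # greedy pruning: best score first, leftmost then '+' strand on ties
    candidates.sort(key=lambda t: (-t[2], t[0], t[1]))
    kept: list[tuple[int, str, float, float]] = []
    occupied: list[tuple[int, int]] = []
    for cand in candidates:
        s, e = cand[0], cand[0] + w
        if any(s < oe and os_ < e for os_, oe in occupied):
            continue
        kept.append(cand)
        occupied.append((s, e))
    kept.sort(key=lambda t: (t[0], t[1]))
    return kept


def scan(
    regions: Sequence[GenomicInterval],
    genome: Mapping[str, str],
    pwm: Pwm,
    rel_threshold: float = 0.90,
) -> list[MotifSite]:
    """Scan regions of a genome for PWM matches on either strand.

    Every window with relative score >= ``rel_threshold`` is returned,
    sorted by coordinate, with overlapping same-TF hits greedily pruned.
    """
    sites: list[MotifSite] = []
    for region in regions:
        if region.chrom not in genome:
            raise KeyError(f"chromosome {region.chrom!r} not in genome")
        seq = genome[region.chrom]
        if region.end > len(seq):
            raise IndexError(
                f"region {region.chrom}:{region.start}-{region.end} outside "
                f"sequence of length {len(seq)}"
            )
        sub = seq[region.start : region.end]
        for off, strand, score, rel in scan_sequence(sub, pwm, rel_threshold):
            start = region.start + off
            sites.append(
                MotifSite(
                    interval=GenomicInterval(
                        chrom=region.chrom,
                        start=start,
                        end=start + pwm.width,
                        strand=strand,
                        name=pwm.tf_name,
                    ),
                    tf_name=pwm.tf_name,
                    strand=strand,
                    score=score,
                    rel_score=rel,
                )
            )
    sites.sort(key=lambda s: (s.interval.chrom, s.interval.start, s.strand))
    return sites


def filter_by_ic(pwms: Iterable[Pwm], min_bits: float = 8.0) -> list[Pwm]:
    """Keep PWMs with total information content >= ``min_bits`` (the
    specificity pre-filter applied to TF panels before enrichment)."""
    return [p for p in pwms if information_content(p)[0] >= min_bits]
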