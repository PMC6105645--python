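"""Simplified MACS-style peak calling on cut-count tracks.

Sliding windows are tested for Poisson enrichment against the larger of the
genome-wide rate and local background rates, p-values are BH-corrected over
all tested windows, and significant windows are merged into peaks. This is a
deliberate, self-contained stand-in for MACS2 with the same q-value
contract; there is no fragment model or control track.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .formats_io import CutTrack, GenomicInterval, Peak

__all__ = ["PeakcallParams", "call_peaks", "poisson_sf"]


@dataclass
class PeakcallParams:
    window: int = 300
    step: int = 100
    # only the wide background by default: narrow local windows sit wholly
    # inside broad accessible regions and suppress their own peaks (same
    # reason MACS drops slocal without a control track)
    local_bg_widths: tuple[int, ...] = (10_000,)
    q_threshold: float = 0.01
    merge_gap: int = 100

    def __post_init__(self) -> None:
        if self.step > self.window:
            raise ValueError("step must be <= window")
        if not (0 < self.q_threshold < 1):
            raise ValueError("q_threshold must be in (0, 1)")
        if self.window < 1 or self.step < 1:
            raise ValueError("window and step must be positive")


def poisson_sf(observed: int, lam: float) -> float:
    """Upper-tail Poisson P(X >= observed | lam)."""
    if observed <= 0:
        return 1.0
    return float(stats.poisson.sf(observed - 1, lam))


def _window_sums(cum: np.ndarray, starts: np.ndarray, width: int) -> np.ndarray:
    ends = np.minimum(starts + width, len(cum) - 1)
    starts = np.maximum(starts, 0)
    return cum[ends] - cum[starts]


def call_peaks(track: CutTrack, params: PeakcallParams | None = None) -> list[Peak]:
    """Call enriched peaks on a cut-count track.

    For each window, lambda_local is the max of the genome-wide mean rate and
    the local mean rates over each background width (centered on the window),
    scaled to the window size; the upper-tail Poisson p-value is computed and
    BH-corrected over all windows of the run. Windows with q <= q_threshold
    are merged when separated by <= merge_gap bp; the summit is the leftmost
    argmax of the per-base counts within the merged peak.
    """
    if params is None:
        params = PeakcallParams()
    chroms = track.chroms
    if not chroms:
        raise ValueError("empty track")

    total_counts = sum(int(track[c].sum()) for c in chroms)
    total_len = sum(len(track[c]) for c in chroms)
    if total_len == 0:
        raise ValueError("track has zero total length")
    genome_rate = total_counts / total_len  # cuts per bp

    win_chrom: list[str] = []
    win_start: list[np.ndarray] = []
    win_obs: list[np.ndarray] = []
    win_lam: list[np.ndarray] = []

    for chrom in chroms:
        vec = track[chrom]
        n = len(vec)
        if n < params.window:
            raise ValueError(
                f"window {params.window} longer than chromosome {chrom} ({n} bp)"
            )
        cum = np.concatenate(([0], np.cumsum(vec)))
        starts = np.arange(0, n - params.window + 1, params.step)
        obs = _window_sums(cum, starts, params.window)

        rates = np.full((len(starts),), genome_rate)
        centers = starts + params.window // 2
        for bw in params.local_bg_widths:
            bg_starts = centers - bw // 2
            bg_lo = np.maximum(bg_starts, 0)
            bg_hi = np.minimum(bg_starts + bw, n)
            bg_counts = cum[bg_hi] - cum[bg_lo]
            rates = np.maximum(rates, bg_counts / np.maximum(bg_hi - bg_lo, 1))
        lam = rates * params.window

        win_chrom.extend([chrom] * len(starts))
        win_start.append(starts)
        win_obs.append(obs)
        win_lam.append(lam)

    starts_all = np.concatenate(win_start)
    obs_all = np.concatenate(win_obs)
    lam_all = np.concatenate(win_lam)
    chrom_all = np.asarray(win_chrom)

    pvals = stats.poisson.sf(obs_all - 1, lam_all)
    pvals = np.where(obs_all <= 0, 1.0, pvals)
    qvals = _bh_adjust(pvals)

    sig = qvals <= params.q_threshold
    peaks: list[Peak] = []
    for chrom in chroms:
        mask = sig & (chrom_all == chrom)
        if not mask.any():
            continue
        vec = track[chrom]
        s = starts_all[mask]
        order = np.argsort(s)
        s = s[order]
        e = s + params.window
        p = pvals[mask][order]
        q = qvals[mask][order]
        lam = lam_all[mask][order]
        obs = obs_all[mask][order]

        # merge windows whose gaps are <= merge_gap
        group_start = 0
        groups: list[tuple[int, int]] = []
        for i in range(1, len(s)):
            if s[i] - e[i - 1] > params.merge_gap:
                groups.append((group_start, i))
                group_start = i
        groups.append((group_start, len(s)))

        for lo, hi in groups:
            pk_start = int(s[lo])
            pk_end = int(e[hi - 1])
            counts = vec[pk_start:pk_end]
            summit = int(np.argmax(counts))  # leftmost max
            # fold at the member window with the largest count (leftmost tie)
            best = lo + int(np.argmax(obs[lo:hi]))
            fold = float(obs[best] / lam[best]) if lam[best] > 0 else 0.0
            best_p = float(p[lo:hi].min())
            best_q = float(q[lo:hi].min())
            peaks.append(
                Peak(
                    interval=GenomicInterval(
                        chrom=chrom,
                        start=pk_start,
                        end=pk_end,
                        name=f"{chrom}_peak{len(peaks) + 1}",
                    ),
                    summit_offset=summit,
                    fold_enrichment=fold,
                    neg_log10_p=_neg_log10(best_p),
                    neg_log10_q=_neg_log10(best_q),
                )
            )
    return peaks


def _bh_adjust(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (single global FDR per run)."""
    m = len(pvals)
    order = np.argsort(pvals, kind="stable")
    ranked = pvals[order] * m / np.arange(1, m + 1)
    # enforce monotonicity from the largest p down
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    return out


def _neg_log10(p: float) -> float:
    return float(-np.log10(max(p, 1e-300)))
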