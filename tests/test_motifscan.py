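import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ftcooc.formats_io import GenomicInterval, Pwm
from ftcooc.motifscan import (
    filter_by_ic,
    information_content,
    log_odds,
    rel_score,
    reverse_complement,
    scan,
    scan_sequence,
    score_bounds,
)

BASES = "ACGT"


# --- independent oracles -------------------------------------------------

def ic_oracle(pwm):
    """Direct per-column summation."""
    cols = []
    for c in range(pwm.width):
        v = 0.0
        for b in range(4):
            v += pwm.probs[c, b] * math.log2(pwm.probs[c, b] / pwm.background[b])
        cols.append(v)
    return sum(cols), cols


def log_odds_oracle(seq, pwm):
    total = 0.0
    for c, base in enumerate(seq):
        if base == "N":
            continue
        total += math.log2(pwm.probs[c, BASES.index(base)] / pwm.background[BASES.index(base)])
    return total


def exhaustive_scan_oracle(seq, pwm, rel_threshold):
    """Score every window on both strands, filter, greedily prune."""
    lo, hi = score_bounds(pwm)
    w = pwm.width
    cands = []
    for off in range(len(seq) - w + 1):
        window = seq[off : off + w]
        for strand in "+-":
            s = log_odds_oracle(
                window if strand == "+" else reverse_complement(window), pwm
            )
            rel = (s - lo) / (hi - lo)
            if rel >= rel_threshold - 1e-12:
                cands.append((off, strand, s, min(max(rel, 0.0), 1.0)))
    cands.sort(key=lambda t: (-t[2], t[0], t[1]))
    kept, occupied = [], []
    for cand in cands:
        span = (cand[0], cand[0] + w)
        if any(span[0] < e and s < span[1] for s, e in occupied):
            continue
        kept.append(cand)
        occupied.append(span)
    return sorted(kept, key=lambda t: (t[0], t[1]))


def random_pwm(rng, width):
    raw = rng.dirichlet(np.full(4, 0.7), size=width)
    raw = np.maximum(raw, 1e-3)
    raw /= raw.sum(axis=1, keepdims=True)
    return Pwm(tf_name="RND", probs=raw)


# --- information content -------------------------------------------------

class TestInformationContent:
    def test_uniform_column_is_zero(self, uniform_pwm):
        total, cols = information_content(uniform_pwm)
        assert total == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(cols, 0.0, atol=1e-12)

    def test_certain_column_is_two_bits(self):
        probs = np.full((1, 4), 1e-12)
        probs[0, 0] = 1 - 3e-12
        pwm = Pwm(tf_name="A", probs=probs / probs.sum(axis=1, keepdims=True))
        total, _ = information_content(pwm)
        assert total == pytest.approx(2.0, abs=1e-9)

    def test_matches_direct_summation_oracle(self, rng):
        for _ in range(10):
            pwm = random_pwm(rng, 6)
            total, cols = information_content(pwm)
            o_total, o_cols = ic_oracle(pwm)
            assert total == pytest.approx(o_total, abs=1e-10)
            np.testing.assert_allclose(cols, o_cols, atol=1e-10)

    def test_total_invariant_under_column_permutation(self, rng, sharp_pwm):
        perm = rng.permutation(sharp_pwm.width)
        shuffled = Pwm(tf_name="S", probs=sharp_pwm.probs[perm])
        assert information_content(shuffled)[0] == pytest.approx(
            information_content(sharp_pwm)[0], abs=1e-10
        )

    def test_ic_filter(self, sharp_pwm, uniform_pwm):
        kept = filter_by_ic([sharp_pwm, uniform_pwm], min_bits=8.0)
        assert kept == [sharp_pwm]


# --- log odds ------------------------------------------------------------

class TestLogOdds:
    def test_consensus_scores_max(self, sharp_pwm):
        s = log_odds(sharp_pwm.consensus, sharp_pwm)
        assert s == pytest.approx(score_bounds(sharp_pwm)[1], abs=1e-9)
        assert rel_score(s, sharp_pwm) == pytest.approx(1.0, abs=1e-12)

    def test_wrong_length_is_error(self, sharp_pwm):
        with pytest.raises(ValueError):
            log_odds("ACG", sharp_pwm)

    def test_n_contributes_zero(self, sharp_pwm):
        base = log_odds("ACGTAC", sharp_pwm)
        with_n = log_odds("NCGTAC", sharp_pwm)
        expected_drop = math.log2(sharp_pwm.probs[0, 0] / 0.25)
        assert base - with_n == pytest.approx(expected_drop, abs=1e-9)

    def test_palindromic_pwm_is_strand_symmetric(self):
        half = np.array([[0.7, 0.1, 0.1, 0.1], [0.1, 0.6, 0.2, 0.1]])
        probs = np.vstack([half, half[::-1, ::-1]])
        pwm = Pwm(tf_name="PAL", probs=probs)
        for seq in ("ACGT", "TTTT", "GATC"):
            assert log_odds(seq, pwm, "+") == pytest.approx(
                log_odds(seq, pwm, "-"), abs=1e-9
            )

    def test_matches_position_oracle(self, rng):
        for _ in range(20):
            pwm = random_pwm(rng, 8)
            seq = "".join(rng.choice(list("ACGTN"), size=8))
            assert log_odds(seq, pwm) == pytest.approx(
                log_odds_oracle(seq, pwm), abs=1e-9
            )


# --- scanning ------------------------------------------------------------

def _plant(seq, motif, offsets):
    chars = list(seq)
    for off in offsets:
        chars[off : off + len(motif)] = list(motif)
    return "".join(chars)


class TestScan:
    def test_planted_sites_recovered_exactly(self, rng, sharp_pwm):
        bg = "".join(rng.choice(list("ACGT"), size=2000))
        seq = _plant(bg, sharp_pwm.consensus, [100, 700, 1500])
        genome = {"chr1": seq}
        sites = scan(
            [GenomicInterval("chr1", 0, 2000)], genome, sharp_pwm, rel_threshold=0.95
        )
        starts = {s.interval.start for s in sites if s.rel_score == 1.0}
        assert {100, 700, 1500} <= starts

    def test_threshold_one_returns_only_consensus(self, rng, sharp_pwm):
        bg = "".join(rng.choice(list("ACGT"), size=500))
        seq = _plant(bg, sharp_pwm.consensus, [50])
        sites = scan(
            [GenomicInterval("chr1", 0, 500)], {"chr1": seq}, sharp_pwm,
            rel_threshold=1.0,
        )
        assert all(s.rel_score == pytest.approx(1.0) for s in sites)
        assert any(s.interval.start == 50 and s.strand == "+" for s in sites)

    def test_no_qualifying_window_is_empty(self, sharp_pwm):
        # poly-A cannot reach 99% of a sharp ACGTAC PWM on either strand
        sites = scan(
            [GenomicInterval("chr1", 0, 60)], {"chr1": "A" * 60}, sharp_pwm,
            rel_threshold=0.99,
        )
        assert sites == []

    def test_matches_exhaustive_oracle(self, rng):
        for trial in range(8):
            pwm = random_pwm(rng, 7)
            seq = "".join(rng.choice(list("ACGT"), size=300))
            got = scan_sequence(seq, pwm, rel_threshold=0.85)
            expected = exhaustive_scan_oracle(seq, pwm, 0.85)
            assert [(o, st) for o, st, _, _ in got] == [
                (o, st) for o, st, _, _ in expected
            ]
            for g, e in zip(got, expected):
                assert g[2] == pytest.approx(e[2], abs=1e-9)

    def test_reverse_complement_mirror(self, rng, sharp_pwm):
        seq = _plant(
            "".join(rng.choice(list("ACGT"), size=400)), sharp_pwm.consensus, [37, 200]
        )
        fwd = scan_sequence(seq, sharp_pwm, 0.9)
        rev = scan_sequence(reverse_complement(seq), sharp_pwm, 0.9)
        n, w = len(seq), sharp_pwm.width
        mirrored = sorted(
            (n - off - w, {"+": "-", "-": "+"}[strand], s, r)
            for off, strand, s, r in rev
        )
        assert [(o, st) for o, st, _, _ in mirrored] == [
            (o, st) for o, st, _, _ in fwd
        ]

    def test_region_outside_genome_is_error(self, sharp_pwm):
        with pytest.raises(IndexError):
            scan(
                [GenomicInterval("chr1", 0, 100)], {"chr1": "ACGT" * 10}, sharp_pwm
            )

    def test_overlap_pruning_keeps_higher_score(self, sharp_pwm):
        # consensus planted once; the window overlapping it on the other
        # strand must lose to the exact match
        seq = "T" * 30 + sharp_pwm.consensus + "T" * 30
        sites = scan_sequence(seq, sharp_pwm, 0.0)
        spans = [(o, o + sharp_pwm.width) for o, _, _, _ in sites]
        for i, a in enumerate(spans):
            for b in spans[i + 1 :]:
                assert a[1] <= b[0] or b[1] <= a[0]  # disjoint


@settings(max_examples=30, deadline=None)
@given(st.integers(min_value=0, max_value=2**32 - 1))
def test_scan_equals_oracle_property(seed):
    rng = np.random.default_rng(seed)
    pwm = random_pwm(rng, int(rng.integers(4, 10)))
    seq = "".join(rng.choice(list("ACGTN"), size=int(rng.integers(20, 200))))
    thr = float(rng.uniform(0.7, 1.0))
    got = scan_sequence(seq, pwm, thr)
    expected = exhaustive_scan_oracle(seq, pwm, thr)
    assert [(o, s) for o, s, _, _ in got] == [(o, s) for o, s, _, _ in expected]
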