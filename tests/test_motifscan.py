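"""PWM scanning: log-odds, exact DP null distributions, presence calls."""

import itertools

import numpy as np
import pytest

from methmotif.dataio import PWM, regularize_probs
from methmotif.motifscan import (
    ScanParams,
    build_log_odds,
    build_presence_matrix,
    encode_sequence,
    exact_score_threshold,
    scan_region_presence,
    score_distribution,
)
from methmotif.synthdata import reverse_complement

UNIFORM = np.full(4, 0.25)


def consensus_pwm(word: str, dominant: float = 0.97) -> PWM:
    idx = {b: i for i, b in enumerate("ACGT")}
    probs = np.full((len(word), 4), (1 - dominant) / 3)
    for i, b in enumerate(word):
        probs[i, idx[b]] = dominant
    return PWM(f"cons_{word}", "TF", probs)


def random_pwm(rng, width: int) -> PWM:
    return PWM(f"rnd{width}", "TF", regularize_probs(rng.dirichlet(np.full(4, 0.5), size=width)))


def brute_force_pmf(lom):
    """Exhaustive enumeration over all 4^w words on the integer score grid."""
    import math

    ints = lom.int_scores[:, :4]
    q = lom.background
    scores = {}
    for word in itertools.product(range(4), repeat=lom.width):
        s = sum(int(ints[i, b]) for i, b in enumerate(word))
        p = math.prod(q[b] for b in word)
        scores[s] = scores.get(s, 0.0) + p
    return scores


def word_pvalue_lookup(pmf: dict):
    """score -> exact P(score' >= score), from an enumerated pmf."""
    items = sorted(pmf.items())
    tails = np.cumsum([p for _, p in items][::-1])[::-1]
    scores = [s for s, _ in items]

    def pvalue(word_score: int) -> float:
        i = np.searchsorted(scores, word_score, side="left")
        return float(tails[i]) if i < len(scores) else 0.0

    return pvalue


class TestLogOdds:
    def test_uniform_column_scores_zero(self):
        pwm = PWM("u", "TF", np.full((3, 4), 0.25))
        lom = build_log_odds(pwm, UNIFORM)
        np.testing.assert_allclose(lom.scores, 0.0)

    def test_probability_half_scores_one_bit(self):
        pwm = PWM("h", "TF", np.array([[0.5, 0.5 / 3, 0.5 / 3, 0.5 / 3]]))
        lom = build_log_odds(pwm, UNIFORM)
        assert lom.scores[0, 0] == pytest.approx(1.0)

    def test_floored_probability_stays_finite(self):
        probs = regularize_probs(np.array([[1.0, 0.0, 0.0, 0.0]]))
        lom = build_log_odds(PWM("f", "TF", probs), UNIFORM)
        assert np.isfinite(lom.scores).all()
        assert lom.scores[0, 1] == pytest.approx(np.log2(probs[0, 1] / 0.25))

    def test_nonpositive_background_rejected(self):
        pwm = PWM("u", "TF", np.full((2, 4), 0.25))
        with pytest.raises(ValueError):
            build_log_odds(pwm, np.array([0.5, 0.5, 0.0, 0.0]))


class TestExactThreshold:
    def test_width7_consensus_passes_only_consensus(self):
        # unique top word has tail 0.25^7 ~ 6.1e-5 < 1e-4; runner-up tail >= 1e-4
        pwm = consensus_pwm("ACGTACG")
        lom = build_log_odds(pwm, UNIFORM)
        thr = exact_score_threshold(lom, ScanParams())
        assert thr.attainable
        assert thr.tail_p == pytest.approx(0.25**7, rel=1e-9)
        assert scan_region_presence("TTT" + "ACGTACG" + "TTT", lom, thr)
        assert not scan_region_presence("TTT" + "ACGTACC" + "TTT", lom, thr)

    def test_width6_consensus_unattainable(self):
        # best achievable tail 0.25^6 ~ 2.44e-4 >= 1e-4: zero presence calls anywhere
        pwm = consensus_pwm("ACGTAC")
        lom = build_log_odds(pwm, UNIFORM)
        thr = exact_score_threshold(lom, ScanParams())
        assert not thr.attainable
        assert thr.max_score_p == pytest.approx(0.25**6, rel=1e-9)
        assert not scan_region_presence("ACGTAC" * 17, lom, thr)

    def test_dp_distribution_sums_to_one(self, rng):
        for width in (3, 5, 8, 12):
            lom = build_log_odds(random_pwm(rng, width), UNIFORM)
            pmf, _ = score_distribution(lom)
            assert pmf.sum() == pytest.approx(1.0, abs=1e-9)

    def test_dp_matches_exhaustive_enumeration(self, rng):
        for width in (3, 4, 6, 8):
            lom = build_log_odds(random_pwm(rng, width), UNIFORM)
            pmf, min_score = score_distribution(lom)
            brute = brute_force_pmf(lom)
            for idx in np.flatnonzero(pmf > 0):
                assert brute.get(min_score + idx, 0.0) == pytest.approx(pmf[idx], abs=1e-12)

    def test_nonuniform_background_shifts_threshold(self, rng):
        pwm = consensus_pwm("CCCCCCC")
        skew = np.array([0.1, 0.4, 0.4, 0.1])
        thr_u = exact_score_threshold(build_log_odds(pwm, UNIFORM), ScanParams())
        lom_s = build_log_odds(pwm, skew)
        thr_s = exact_score_threshold(lom_s, ScanParams())
        # C-rich words are common under the skewed background: all-C is no longer rare
        assert thr_u.attainable and not thr_s.attainable


class TestPresence:
    def test_reverse_strand_match_detected(self):
        pwm = consensus_pwm("ACGTACGT")
        lom = build_log_odds(pwm, UNIFORM)
        thr = exact_score_threshold(lom, ScanParams())
        seq = "TTTT" + reverse_complement("ACGTACGT") + "TTTT"
        assert scan_region_presence(seq, lom, thr)

    def test_all_n_sequence_never_matches(self):
        pwm = consensus_pwm("ACGTACGT")
        lom = build_log_odds(pwm, UNIFORM)
        thr = exact_score_threshold(lom, ScanParams())
        assert not scan_region_presence("N" * 102, lom, thr)

    def test_sequence_shorter_than_motif_never_matches(self):
        pwm = consensus_pwm("ACGTACGT")
        lom = build_log_odds(pwm, UNIFORM)
        thr = exact_score_threshold(lom, ScanParams())
        assert not scan_region_presence("ACGT", lom, thr)

    def test_presence_agrees_with_word_pvalue_oracle(self, rng):
        # per-window call: present iff the window's exact word p-value < 1e-4
        params = ScanParams()
        for trial in range(8):
            width = int(rng.integers(4, 8))
            pwm = (
                consensus_pwm("".join(rng.choice(list("ACGT"), width)), dominant=0.85)
                if trial % 2
                else random_pwm(rng, width)
            )
            lom = build_log_odds(pwm, UNIFORM)
            thr = exact_score_threshold(lom, params)
            rc = lom.reverse_complement()
            pvalue_of = {id(m): word_pvalue_lookup(brute_force_pmf(m)) for m in (lom, rc)}
            for _ in range(20):
                seq = "".join(rng.choice(list("ACGT"), 30))
                enc = encode_sequence(seq)
                expected = False
                for off in range(len(seq) - width + 1):
                    window = enc[off : off + width]
                    for matrix in (lom, rc):
                        s = sum(int(matrix.int_scores[i, b]) for i, b in enumerate(window))
                        if pvalue_of[id(matrix)](s) < params.p_threshold:
                            expected = True
                assert scan_region_presence(seq, lom, thr) == expected

    def test_presence_invariant_under_reverse_complement(self, rng):
        pwms = [random_pwm(rng, 6), consensus_pwm("ACGTTACA", dominant=0.9)]
        seqs = {f"r{i}": "".join(rng.choice(list("ACGT"), 102)) for i in range(30)}
        rc_seqs = {k: reverse_complement(v) for k, v in seqs.items()}
        m1 = build_presence_matrix(seqs, pwms)
        m2 = build_presence_matrix(rc_seqs, pwms)
        assert m1.equals(m2)


class TestPresenceMatrix:
    def test_shape_and_determinism(self, rng):
        pwms = [random_pwm(rng, 5), consensus_pwm("ACGTACGT")]
        seqs = {f"r{i}": "".join(rng.choice(list("ACGT"), 102)) for i in range(10)}
        m1 = build_presence_matrix(seqs, pwms)
        m2 = build_presence_matrix(seqs, pwms)
        assert m1.shape == (10, 2)
        assert m1.equals(m2)

    def test_duplicate_region_ids_rejected(self, rng):
        import pandas as pd

        pwms = [consensus_pwm("ACGTACGT")]
        seqs = pd.Series(["A" * 102, "C" * 102], index=["r1", "r1"])
        with pytest.raises(ValueError, match="duplicate"):
            build_presence_matrix(seqs, pwms)

    def test_false_positive_rate_matches_exact_tail(self, rng):
        # on random uniform sequences the per-region hit rate is ~ the union
        # bound tail_p * n_windows * 2 strands (matches are nearly independent
        # for a high-information motif)
        pwm = consensus_pwm("ACGTTAGC", dominant=0.9)
        lom = build_log_odds(pwm, UNIFORM)
        thr = exact_score_threshold(lom, ScanParams())
        n_regions, length = 10_000, 102
        seqs = {
            f"r{i}": "".join(s)
            for i, s in enumerate(
                rng.choice(list("ACGT"), size=(n_regions, length))
            )
        }
        m = build_presence_matrix(seqs, [pwm])
        rate = m.to_numpy().mean()
        n_tests = 2 * (length - pwm.width + 1)
        expected = 1.0 - (1.0 - thr.tail_p) ** n_tests
        sd = np.sqrt(expected * (1 - expected) / n_regions)
        assert abs(rate - expected) < 3 * sd
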