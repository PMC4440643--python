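"""PWM scanning with exact p-value thresholds.

A motif's log-odds matrix scores a window as sum_i log2(p_i(b_i)/q(b_i)).
The null distribution of that score under a zero-order background (i.i.d.
positions) is computed exactly by dynamic programming over scores
discretized on a fixed grid; the presence threshold is the smallest
discretized score s with P(score >= s) strictly below the per-window
p-value cutoff (default 1e-4). Low-information motifs can be *unattainable*:
no score is rare enough, and such motifs are never called present.

A motif is "present" in a region when at least one window on either strand
reaches the threshold; overlapping matches collapse into a single Boolean,
yielding the region x motif presence matrix. Windows containing N are
skipped. Scanning the reverse strand is implemented by scanning the forward
sequence with the reverse-complemented matrix, so presence is invariant
under reverse complement of the region.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataio import PWM

UNIFORM_BG = np.full(4, 0.25)
_N_SCORE = -(1 << 40)  # any window containing N can never reach a threshold

_ENCODE_LUT = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _ENCODE_LUT[ord(_b)] = _i
    _ENCODE_LUT[ord(_b.lower())] = _i


def encode_sequence(seq: str) -> np.ndarray:
    """Sequence -> int8 codes (A,C,G,T -> 0..3; anything else -> 4)."""
    return _ENCODE_LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass
class ScanParams:
    p_threshold: float = 1e-4
    background: str | np.ndarray = "uniform"
    score_granularity: float = 1e-4

    def __post_init__(self) -> None:
        if not (0.0 < self.p_threshold < 1.0):
            raise ValueError("p_threshold must lie in (0,1)")


@dataclass
class LogOddsMatrix:
    """Discretized log-odds scores for one motif against a background."""

    motif_id: str
    width: int
    scores: np.ndarray          # width x 4, log2(p/q), floats
    background: np.ndarray      # length 4, sums to 1
    granularity: float
    int_scores: np.ndarray = field(init=False)   # width x 5 (last column = N)

    def __post_init__(self) -> None:
        ints = np.rint(self.scores / self.granularity).astype(np.int64)
        self.int_scores = np.concatenate(
            [ints, np.full((self.width, 1), _N_SCORE, dtype=np.int64)], axis=1
        )

    def reverse_complement(self) -> "LogOddsMatrix":
        # complement permutes A<->T, C<->G; reverse flips positions
        rc = self.scores[::-1, [3, 2, 1, 0]].copy()
        return LogOddsMatrix(self.motif_id, self.width, rc, self.background, self.granularity)


@dataclass
class ThresholdResult:
    """Presence threshold for one motif (integer grid units and score scale)."""

    motif_id: str
    attainable: bool
    int_threshold: int | None
    score_threshold: float | None
    tail_p: float       # P(score >= threshold); < p_threshold when attainable
    max_score_p: float  # tail mass at the best achievable score


def resolve_background(params: ScanParams, region_sequences=None) -> np.ndarray:
    if isinstance(params.background, str):
        if params.background == "uniform":
            return UNIFORM_BG.copy()
        if params.background == "zero_order_from_regions":
            if region_sequences is None:
                raise ValueError("zero_order_from_regions background needs region sequences")
            return estimate_background(region_sequences)
        raise ValueError(f"unknown background {params.background!r}")
    q = np.asarray(params.background, dtype=float)
    if q.shape != (4,) or np.any(q <= 0) or abs(q.sum() - 1) > 1e-9:
        raise ValueError("background must be 4 positive frequencies summing to 1")
    return q


def estimate_background(sequences) -> np.ndarray:
    """Zero-order base frequencies over a collection of sequences (N ignored)."""
    counts = np.zeros(4)
    for seq in sequences:
        enc = encode_sequence(seq)
        counts += np.bincount(enc[enc < 4], minlength=4)
    if counts.sum() == 0:
        raise ValueError("no ACGT characters to estimate a background from")
    q = counts / counts.sum()
    return np.maximum(q, 1e-6) / np.maximum(q, 1e-6).sum()


def build_log_odds(pwm: PWM, background, granularity: float = 1e-4) -> LogOddsMatrix:
    """score(i, b) = log2(p_i(b) / q(b)); finite because the PWM is regularized."""
    q = np.asarray(background, dtype=float)
    if np.any(q <= 0):
        raise ValueError("background entries must be > 0")
    scores = np.log2(pwm.probs / q[None, :])
    return LogOddsMatrix(pwm.motif_id, pwm.width, scores, q, granularity)


def score_distribution(lom: LogOddsMatrix) -> tuple[np.ndarray, int]:
    """Exact null pmf of the window score on the integer grid.

    Returns (pmf, min_score): pmf[i] = P(score == min_score + i) under the
    background, summing to 1.
    """
    ints = lom.int_scores[:, :4]
    q = lom.background
    mins = ints.min(axis=1)
    pmf = np.array([1.0])
    for i in range(lom.width):
        width_i = int(ints[i].max() - mins[i])
        new = np.zeros(len(pmf) + width_i)
        for b in range(4):
            off = int(ints[i, b] - mins[i])
            new[off : off + len(pmf)] += q[b] * pmf
        pmf = new
    return pmf, int(mins.sum())


def exact_score_threshold(lom: LogOddsMatrix, params: ScanParams) -> ThresholdResult:
    """Smallest discretized score with tail probability below the cutoff."""
    pmf, min_score = score_distribution(lom)
    sf = np.cumsum(pmf[::-1])[::-1]  # sf[i] = P(score >= min_score + i)
    # threshold ranges over achievable scores (pmf > 0), so it is a score some
    # word can actually attain; presence calls are unchanged either way
    passing = np.flatnonzero((sf < params.p_threshold) & (pmf > 0))
    max_score_p = float(sf[-1])
    if len(passing) == 0:
        return ThresholdResult(lom.motif_id, False, None, None, 1.0, max_score_p)
    idx = int(passing[0])
    thr = min_score + idx
    return ThresholdResult(
        lom.motif_id, True, thr, thr * lom.granularity, float(sf[idx]), max_score_p
    )


def _window_scores(encoded: np.ndarray, int_scores: np.ndarray) -> np.ndarray:
    """All window scores for a batch of equal-length encoded sequences.

    ``encoded`` is (n_seqs, L) int8 in 0..4; returns (n_seqs, L - w + 1) int64.
    """
    w = len(int_scores)
    n, L = encoded.shape
    n_windows = L - w + 1
    if n_windows <= 0:
        return np.zeros((n, 0), dtype=np.int64)
    S = np.zeros((n, n_windows), dtype=np.int64)
    for i in range(w):
        S += int_scores[i][encoded[:, i : i + n_windows]]
    return S


def scan_region_presence(sequence: str, lom: LogOddsMatrix, threshold: ThresholdResult) -> bool:
    """True iff any window on either strand scores at or above the threshold."""
    if not threshold.attainable or len(sequence) < lom.width:
        return False
    enc = encode_sequence(sequence)[None, :]
    for matrix in (lom, lom.reverse_complement()):
        scores = _window_scores(enc, matrix.int_scores)
        if scores.size and scores.max() >= threshold.int_threshold:
            return True
    return False


def motif_thresholds(pwms, params: ScanParams, region_sequences=None):
    """Per-motif log-odds matrices and exact thresholds under one background."""
    q = resolve_background(params, region_sequences)
    loms = {p.motif_id: build_log_odds(p, q, params.score_granularity) for p in pwms}
    thresholds = {mid: exact_score_threshold(lom, params) for mid, lom in loms.items()}
    return loms, thresholds


def thresholds_table(thresholds: dict) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "motif_id": t.motif_id,
                "attainable": t.attainable,
                "score_threshold": t.score_threshold,
                "tail_p": t.tail_p if t.attainable else np.nan,
                "best_achievable_p": t.max_score_p,
            }
            for t in thresholds.values()
        ]
    )


def build_presence_matrix(region_sequences, pwms, params: ScanParams | None = None) -> pd.DataFrame:
    """Boolean region x motif presence matrix.

    ``region_sequences`` maps region id -> equal-length sequence (a dict or
    pandas Series). Fully deterministic; duplicate region ids are an error.
    """
    params = params or ScanParams()
    seqs = pd.Series(dict(region_sequences)) if not isinstance(region_sequences, pd.Series) else region_sequences
    if seqs.index.duplicated().any():
        raise ValueError("duplicate region ids")
    lengths = {len(s) for s in seqs}
    loms, thresholds = motif_thresholds(pwms, params, region_sequences=seqs.values)

    presence = pd.DataFrame(
        False, index=seqs.index, columns=[p.motif_id for p in pwms], dtype=bool
    )
    if seqs.empty:
        return presence
    by_len = {L: np.stack([encode_sequence(s) for s in seqs[seqs.str.len() == L]]) for L in lengths}
    ids_by_len = {L: seqs.index[seqs.str.len() == L] for L in lengths}
    for pwm in pwms:
        thr = thresholds[pwm.motif_id]
        if not thr.attainable:
            continue
        lom = loms[pwm.motif_id]
        rc = lom.reverse_complement()
        for L, enc in by_len.items():
            if L < pwm.width:
                continue
            hit = np.zeros(enc.shape[0], dtype=bool)
            for matrix in (lom, rc):
                scores = _window_scores(enc, matrix.int_scores)
                if scores.size:
                    hit |= scores.max(axis=1) >= thr.int_threshold
            presence.loc[ids_by_len[L], pwm.motif_id] = hit
    return presence
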