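"""PWM log-odds scanning of element sequences on both strands.

Scores are log2 odds against a background base distribution (uniform by
default), with matrix probabilities floored at 1e-3 so zero counts never
produce -inf. A window is a hit when its score reaches the motif's
threshold; motifs without an explicit threshold use a fraction (default
0.80) of their maximum achievable score. N bases score zero (they are
taken as background).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import PWMotif

__all__ = [
    "MotifHit",
    "log_odds_matrix",
    "max_score",
    "scan_sequence",
    "annotate_elements",
    "UNIFORM_BACKGROUND",
    "DEFAULT_THRESHOLD_FRACTION",
    "PROB_FLOOR",
]

UNIFORM_BACKGROUND = (0.25, 0.25, 0.25, 0.25)
DEFAULT_THRESHOLD_FRACTION = 0.80
PROB_FLOOR = 1e-3

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass(frozen=True)
class MotifHit:
    """One motif match within an element sequence.

    ``position`` is the window start in forward-strand coordinates, for
    hits on either strand; ``score`` is the log-odds score in bits.
    """

    peak_id: str
    motif_id: str
    position: int
    strand: str
    score: float


def _check_background(background: Sequence[float]) -> np.ndarray:
    bg = np.asarray(background, dtype=float)
    if bg.shape != (4,) or (bg <= 0).any() or abs(bg.sum() - 1.0) > 1e-6:
        raise ValueError("background must be 4 strictly positive frequencies summing to 1")
    return bg


def log_odds_matrix(
    pwm: PWMotif, background: Sequence[float] = UNIFORM_BACKGROUND
) -> np.ndarray:
    """Per-position, per-base log2 odds of the floored, renormalised PWM.

    Probabilities are floored at 1e-3 (so zero counts never score -inf)
    and each position renormalised to sum to 1 before taking
    ``log2(p / bg)``; a (1, 0, 0, 0) column therefore scores
    ``log2(0.997/0.25) ~ 1.996`` bits, not exactly 2.
    """
    bg = _check_background(background)
    p = np.maximum(pwm.matrix, PROB_FLOOR)
    p = p / p.sum(axis=1, keepdims=True)
    return np.log2(p / bg)


def max_score(pwm: PWMotif, background: Sequence[float] = UNIFORM_BACKGROUND) -> float:
    """Maximum achievable log-odds score: sum of per-position maxima."""
    return float(log_odds_matrix(pwm, background).max(axis=1).sum())


def _effective_threshold(pwm: PWMotif, background: Sequence[float]) -> float:
    if pwm.threshold is not None:
        return pwm.threshold
    return DEFAULT_THRESHOLD_FRACTION * max_score(pwm, background)


def _window_scores(seq: str, lom: np.ndarray) -> np.ndarray:
    """Score of every length-L window of seq (N contributes 0)."""
    L = lom.shape[0]
    n = len(seq)
    if n < L:
        return np.empty(0)
    idx = np.fromiter((_BASE_INDEX.get(c, 4) for c in seq), dtype=np.int64, count=n)
    # pad the score table with a zero column for N
    table = np.hstack([lom, np.zeros((L, 1))])  # (L, 5)
    windows = np.lib.stride_tricks.sliding_window_view(idx, L)  # (n-L+1, L)
    return table[np.arange(L), windows].sum(axis=1)


def scan_sequence(
    seq: str,
    pwm: PWMotif,
    background: Sequence[float] = UNIFORM_BACKGROUND,
    peak_id: str = "",
) -> list[MotifHit]:
    """All windows on both strands scoring at or above the motif threshold.

    Reverse-strand windows are scored on the reverse complement; their
    positions are reported as the forward-coordinate window start. Hits
    are sorted by position then strand ('+' first).
    """
    seq = seq.upper()
    bad = set(seq) - set(_BASE_INDEX)
    if bad:
        raise ValueError(f"sequence contains non-ACGTN characters: {sorted(bad)}")
    lom = log_odds_matrix(pwm, background)
    L = lom.shape[0]
    thr = _effective_threshold(pwm, background)
    hits: list[MotifHit] = []
    fwd = _window_scores(seq, lom)
    for i in np.nonzero(fwd >= thr)[0]:
        hits.append(MotifHit(peak_id, pwm.motif_id, int(i), "+", float(fwd[i])))
    rc = seq.translate(_COMPLEMENT)[::-1]
    rev = _window_scores(rc, lom)
    n = len(seq)
    for j in np.nonzero(rev >= thr)[0]:
        # window start j in revcomp coordinates maps to forward start n-L-j
        hits.append(MotifHit(peak_id, pwm.motif_id, int(n - L - j), "-", float(rev[j])))
    hits.sort(key=lambda h: (h.position, h.strand))
    return hits


def annotate_elements(
    sequences: Mapping[str, str],
    pwms: Sequence[PWMotif],
    background: Sequence[float] = UNIFORM_BACKGROUND,
    element_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Binary element x motif matrix: 1 iff >= 1 hit of the motif.

    ``element_ids`` restricts and orders the rows; elements without a
    sequence are an error (listed by id).
    """
    if element_ids is None:
        element_ids = sorted(sequences)
    missing = [e for e in element_ids if e not in sequences]
    if missing:
        raise KeyError(f"elements without sequences: {missing}")
    motif_ids = [p.motif_id for p in pwms]
    mat = np.zeros((len(element_ids), len(pwms)), dtype=int)
    for j, pwm in enumerate(pwms):
        for i, eid in enumerate(element_ids):
            if scan_sequence(sequences[eid], pwm, background, peak_id=eid):
                mat[i, j] = 1
    return pd.DataFrame(mat, index=list(element_ids), columns=motif_ids)
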