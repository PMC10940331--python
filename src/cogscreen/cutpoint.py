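"""Fixed-threshold classification on a single score and optimal-cut search.

A cut rule is a threshold plus an explicit direction.  Comparisons are
strict, which matters at boundary patients: a patient whose score
equals the threshold is always classified into the "not past the cut"
group (e.g., Composite5 = 0.92 is predicted normal at cut 0.925 under
``impaired-if-above``).

The search enumerates every achievable labelling: candidate thresholds
are the midpoints of consecutive sorted unique scores plus one sentinel
below the minimum and one above the maximum, evaluated in both
directions.  The sentinels guarantee the all-0 and all-1 rules are
considered, so the optimal mismatch count never exceeds
min(#positives, #negatives).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["CutRule", "classify_by_cut", "count_mismatches", "search_optimal_cut"]

BELOW = "impaired-if-below"
ABOVE = "impaired-if-above"


@dataclass(frozen=True)
class CutRule:
    """Threshold on a score scale with an explicit direction."""

    threshold: float
    direction: str = BELOW

    def __post_init__(self) -> None:
        if self.direction not in (BELOW, ABOVE):
            raise ValueError(f"direction must be {BELOW!r} or {ABOVE!r}, got {self.direction!r}")


def classify_by_cut(scores: np.ndarray, rule: CutRule) -> np.ndarray:
    """Binary predictions: 1 iff strictly past the threshold."""
    s = np.asarray(scores, dtype=float)
    if np.isnan(s).any():
        raise ValueError("scores contain missing values")
    if rule.direction == BELOW:
        return (s < rule.threshold).astype(int)
    return (s > rule.threshold).astype(int)


def count_mismatches(predictions: np.ndarray, labels: np.ndarray) -> int:
    """Number of positions where prediction differs from label."""
    p = np.asarray(predictions)
    y = np.asarray(labels)
    if p.shape != y.shape:
        raise ValueError(f"length mismatch: {p.shape} predictions vs {y.shape} labels")
    return int(np.sum(p != y))


def search_optimal_cut(scores: np.ndarray, labels: np.ndarray) -> tuple[CutRule, int]:
    """Exhaustive search for the mismatch-minimizing cut rule.

    Ties are broken deterministically: prefer ``impaired-if-below``,
    then the smallest threshold.  The returned mismatch count is the
    global minimum over all threshold/direction pairs.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if s.size < 1:
        raise ValueError("need at least one score")
    if s.shape != y.shape:
        raise ValueError("scores and labels differ in length")
    uniq = np.unique(s)
    candidates = np.concatenate(
        [[uniq[0] - 1.0], (uniq[:-1] + uniq[1:]) / 2.0, [uniq[-1] + 1.0]]
    )
    best: tuple[int, int, float] | None = None  # (mismatches, direction order, threshold)
    for k, direction in enumerate((BELOW, ABOVE)):
        for t in candidates:
            m = count_mismatches(classify_by_cut(s, CutRule(t, direction)), y)
            key = (m, k, t)
            if best is None or key < best:
                best = key
    m, k, t = best
    return CutRule(t, (BELOW, ABOVE)[k]), m
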