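"""Cross-entropy-driven sample reweighting.

Each boosting iteration scores every training sample by its cross-entropy
under the current classifier, d_j = -log P(true class of j), and updates the
sample weight multiplicatively by the ratio of the current score to the
previous iteration's score, then renormalizes to a probability vector:

    r_j = d_j^{(i)} / d_j^{(i-1)}
    w_j <- w_j * r_j ;  w <- w / sum(w)

A sample whose predicted probability of its true class moves toward 1 sees
its score (and hence weight) shrink; a sample that remains hard to classify
keeps or gains weight.  On the first update after (re)initialization the
previous scores are taken as 1, so uniform weights are multiplied by the raw
cross-entropy.  Weights are reset to the uniform 1/n vector at phase
boundaries of the selection loop.

Numerical guards: predicted probabilities are clipped to [eps, 1] before the
log (eps = 1e-12), and previous-iteration scores below eps are floored at
eps before division.  Natural log throughout; only relative ratios matter
after normalization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

__all__ = [
    "EPS",
    "SampleWeights",
    "CrossEntropyScores",
    "cross_entropy_scores",
    "update_weights",
    "reset_weights",
]

EPS = 1e-12
_log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SampleWeights:
    """Nonnegative weight vector summing to 1, with an iteration counter."""

    w: np.ndarray
    iteration: int = 0

    def __post_init__(self) -> None:
        w = np.asarray(self.w, dtype=float)
        object.__setattr__(self, "w", w)
        if w.ndim != 1 or len(w) == 0:
            raise ValueError("weights must be a non-empty 1-D vector")
        if (w < 0).any():
            raise ValueError("weights must be nonnegative")
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValueError(f"weights must sum to 1 (got {w.sum():.12g})")

    def __len__(self) -> int:
        return len(self.w)


@dataclass(frozen=True)
class CrossEntropyScores:
    """Per-sample cross-entropy d_j = -log P(true class), all >= 0."""

    d: np.ndarray
    iteration: int = 0

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=float)
        object.__setattr__(self, "d", d)
        if d.ndim != 1 or len(d) == 0:
            raise ValueError("scores must be a non-empty 1-D vector")
        if (d < 0).any():
            raise ValueError("cross-entropy scores must be nonnegative")


def cross_entropy_scores(
    probs: np.ndarray,
    labels: np.ndarray,
    iteration: int = 0,
) -> CrossEntropyScores:
    """Per-sample cross-entropy from an n x C class-probability matrix.

    ``d_j = -log(P[j, labels[j]])`` with P clipped to [EPS, 1] (natural
    log).  Rows must sum to 1 within 1e-6; labels must index valid classes.
    """
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels, dtype=np.int64)
    if probs.ndim != 2 or probs.shape[1] < 2:
        raise ValueError("probs must be n x C with C >= 2")
    if len(labels) != probs.shape[0]:
        raise ValueError("labels length mismatch with probs")
    row_sums = probs.sum(axis=1)
    if np.abs(row_sums - 1.0).max() > 1e-6:
        bad = int(np.abs(row_sums - 1.0).argmax())
        raise ValueError(f"probability row {bad} sums to {row_sums[bad]:.6g}, not 1")
    if labels.min() < 0 or labels.max() >= probs.shape[1]:
        raise ValueError("label index out of range")
    p_true = probs[np.arange(len(labels)), labels]
    d = -np.log(np.clip(p_true, EPS, 1.0))
    return CrossEntropyScores(d, iteration=iteration)


def update_weights(
    w: SampleWeights,
    d_curr: CrossEntropyScores,
    d_prev: CrossEntropyScores | None = None,
) -> SampleWeights:
    """One multiplicative reweighting step.

    ``r_j = d_curr_j / max(d_prev_j, EPS)``; when ``d_prev`` is None (first
    update after a reset) the previous scores are taken as 1 so
    ``r_j = d_curr_j``.  The updated vector is renormalized to sum 1.  If
    every updated weight is zero (all samples perfectly classified) the
    update falls back to uniform weights with a warning.
    """
    if len(d_curr.d) != len(w):
        raise ValueError("score / weight length mismatch")
    if d_prev is not None and len(d_prev.d) != len(w):
        raise ValueError("previous-score / weight length mismatch")
    if d_prev is None:
        ratio = d_curr.d
    else:
        ratio = d_curr.d / np.maximum(d_prev.d, EPS)
    new = w.w * ratio
    total = new.sum()
    if total <= 0.0:
        _log.warning(
            "all updated sample weights are zero (every sample perfectly "
            "classified); falling back to uniform weights"
        )
        return SampleWeights(np.full(len(w), 1.0 / len(w)), iteration=w.iteration + 1)
    return SampleWeights(new / total, iteration=w.iteration + 1)


def reset_weights(n: int) -> SampleWeights:
    """Uniform 1/n weights, iteration counter 0."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return SampleWeights(np.full(n, 1.0 / n), iteration=0)
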