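"""Consensus labeling and conditional-probability confusion matrices.

A sample's consensus pattern is the pattern assigned by an absolute
majority of the scoring iterations (4 or more of 6 in the reference
protocol; generalized to ``floor(m/2) + 1`` of ``m``). Samples without a
consensus pattern are excluded from confusion analysis.

The confusion matrix ``P`` has entries ``P[i][j]``: the conditional
probability that a sample with consensus pattern ``i`` was scored as
pattern ``j``. For each consensus pattern the samples are identified, the
assignments of the evaluated iterations over those samples are counted, and
each row is normalized by its count — per-scorer matrices count that
scorer's iterations, a group matrix pools all iterations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .patterns import PATTERNS, PatternLabel
from .scoring import Annotation, expand_labels
from .util import as_rng

__all__ = [
    "ConfusionMatrix",
    "EmptyAnalysisError",
    "consensus_labels",
    "confusion_matrix",
    "confusion_by_length",
]

_NONE = int(PatternLabel.NONE)


class EmptyAnalysisError(ValueError):
    """Raised when no sample survives consensus/threshold filtering."""


def consensus_labels(iteration_labels, majority: int | None = None) -> np.ndarray:
    """Absolute-majority consensus over ``m`` equal-length label vectors.

    A sample receives pattern ``p`` iff at least ``majority`` iterations
    (default ``floor(m/2) + 1``) assigned it ``p``; otherwise NONE. NONE
    votes never form a consensus.
    """
    vecs = [np.asarray(v) for v in iteration_labels]
    if len(vecs) < 2:
        raise ValueError("need at least 2 iterations for a consensus")
    n = len(vecs[0])
    for v in vecs:
        if len(v) != n:
            raise ValueError("iteration label vectors must have equal length")
    m = len(vecs)
    need = majority if majority is not None else m // 2 + 1
    stack = np.stack(vecs)  # (m, n)
    out = np.full(n, _NONE, dtype=np.int8)
    best = np.zeros(n, dtype=np.int32)
    for pattern in PATTERNS:
        votes = (stack == int(pattern)).sum(axis=0)
        win = (votes >= need) & (votes > best)
        out[win] = int(pattern)
        best = np.maximum(best, votes)
    return out


@dataclass
class ConfusionMatrix:
    """6x6 conditional-probability matrix with counts and optional SDs.

    ``p[i, j]`` is the probability that a consensus-``i`` sample was scored
    ``j``; rows with no consensus samples are NaN and flagged undefined.
    ``n_consensus[i]`` counts consensus-``i`` samples; ``n_counted[i]``
    counts the sample-iteration assignments entering row ``i`` (consensus
    samples times iterations, minus unscored assignments).
    """

    p: np.ndarray
    n_ij: np.ndarray
    n_consensus: np.ndarray
    n_counted: np.ndarray
    sd: np.ndarray | None = None
    patterns: tuple[PatternLabel, ...] = field(default=PATTERNS)

    def row(self, pattern: PatternLabel) -> np.ndarray:
        return self.p[self.patterns.index(PatternLabel(pattern))]

    @property
    def defined_rows(self) -> np.ndarray:
        return self.n_counted > 0


def _count_matrix(consensus: np.ndarray, iteration_labels) -> ConfusionMatrix:
    k = len(PATTERNS)
    n_ij = np.zeros((k, k), dtype=np.int64)
    n_consensus = np.zeros(k, dtype=np.int64)
    for i, pat_i in enumerate(PATTERNS):
        mask = consensus == int(pat_i)
        n_consensus[i] = int(mask.sum())
        if not n_consensus[i]:
            continue
        for labels in iteration_labels:
            sel = labels[mask]
            for j, pat_j in enumerate(PATTERNS):
                n_ij[i, j] += int((sel == int(pat_j)).sum())
    n_counted = n_ij.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = n_ij / n_counted[:, None]
    return ConfusionMatrix(p=p, n_ij=n_ij, n_consensus=n_consensus,
                           n_counted=n_counted)


def confusion_matrix(
    consensus,
    iteration_labels,
    n_resamples: int = 0,
    seed=None,
) -> ConfusionMatrix:
    """Confusion matrix of one or more scoring iterations against a
    consensus label vector.

    Samples whose consensus is NONE are excluded; sample-iteration pairs
    the scorer left unscored are dropped from their row, so every defined
    row sums to 1. ``n_resamples > 0`` adds per-cell bootstrap SDs
    (resampling samples with replacement).
    """
    consensus = np.asarray(consensus)
    vecs = [np.asarray(v) for v in iteration_labels]
    for v in vecs:
        if len(v) != len(consensus):
            raise ValueError("iteration labels must match consensus length")
    if not (consensus != _NONE).any():
        raise EmptyAnalysisError("no sample has a consensus pattern")
    cm = _count_matrix(consensus, vecs)
    if cm.n_counted.sum() == 0:
        raise EmptyAnalysisError("no scored samples over the consensus set")
    if n_resamples > 0:
        rng = as_rng(seed)
        n = len(consensus)
        boots = np.full((n_resamples, len(PATTERNS), len(PATTERNS)), np.nan)
        stack = np.stack(vecs)
        for b in range(n_resamples):
            idx = rng.integers(0, n, size=n)
            boots[b] = _count_matrix(consensus[idx], list(stack[:, idx])).p
        cm.sd = np.nanstd(boots, axis=0, ddof=1)
    return cm


def _mask_short_segments(annotation: Annotation, sample_rate: float,
                         threshold_s: float) -> np.ndarray:
    """Label vector of an annotation with samples of events shorter than
    ``threshold_s`` set to NONE."""
    labels = expand_labels(annotation, sample_rate)
    for ev in annotation.events:
        if ev.length_s < threshold_s:
            a = int(round(ev.start_s * sample_rate))
            b = int(round(ev.end_s * sample_rate))
            labels[max(a, 0) : min(b, len(labels))] = _NONE
    return labels


def confusion_by_length(
    consensus,
    annotations: list[Annotation],
    sample_rate: float,
    thresholds=None,
) -> dict[float, ConfusionMatrix]:
    """Confusion matrices after excluding scored segments shorter than a
    threshold, for each threshold (default 0..20 s).

    Threshold 0 reproduces the unfiltered matrix exactly. Raises
    :class:`EmptyAnalysisError` for a threshold that excludes everything.
    """
    if thresholds is None:
        thresholds = np.arange(0.0, 21.0, 1.0)
    out: dict[float, ConfusionMatrix] = {}
    for thr in thresholds:
        thr = float(thr)
        if thr < 0:
            raise ValueError("thresholds must be >= 0")
        vecs = [
            _mask_short_segments(a, sample_rate, thr) for a in annotations
        ]
        out[thr] = confusion_matrix(consensus, vecs)
    return out
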