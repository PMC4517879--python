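"""Sample-wise multi-rater agreement statistics.

Agreement between scorers (or between a scorer and ground truth) is
quantified with Fleiss' kappa computed on a sample-by-sample basis: each
signal sample is an observation, each scoring iteration a rater, and the
six RIP patterns the categories. Fleiss' kappa generalizes Cohen's kappa to
any number of raters:

    P_i    per-sample agreement: fraction of rater pairs that agree on
           sample i,
    P-bar  mean observed agreement over samples,
    P_e    chance agreement: sum of squared pooled category proportions,
    kappa  = (P-bar - P_e) / (1 - P_e).

Bootstrap resampling of samples (100 resamples by default) estimates the
standard deviation of kappa, and values are banded with the conventional
interpretation intervals (poor / slight / fair / moderate / substantial /
almost perfect).

Samples labeled NONE (unscored) by any party to a comparison are excluded
from that comparison; agreement is always computed over jointly scored
content.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .patterns import PATTERNS, PatternLabel
from .records import EvaluationPairing
from .util import as_rng

__all__ = [
    "AgreementResult",
    "InterScorerResult",
    "UndefinedAgreementError",
    "fleiss_kappa",
    "accuracy_kappa",
    "consistency_kappa",
    "intra_scorer_kappa",
    "inter_scorer_kappa",
    "bootstrap_sd",
    "kappa_band",
]


class UndefinedAgreementError(ValueError):
    """Raised when no jointly scored samples exist for a comparison."""


_BANDS = (
    (0.0, "poor"),  # kappa < 0
    (0.2, "slight"),
    (0.4, "fair"),
    (0.6, "moderate"),
    (0.8, "substantial"),
    (1.0, "almost perfect"),
)


def kappa_band(kappa: float) -> str:
    """Interpretation band for a kappa value.

    Intervals have closed upper bounds: kappa < 0 is "poor",
    0 <= kappa <= 0.2 "slight", 0.2 < kappa <= 0.4 "fair", 0.4 < kappa <=
    0.6 "moderate", 0.6 < kappa <= 0.8 "substantial", 0.8 < kappa <= 1
    "almost perfect".
    """
    if not (-1.0 - 1e-9 <= kappa <= 1.0 + 1e-9):
        raise ValueError(f"kappa must lie in [-1, 1], got {kappa}")
    if kappa < 0.0:
        return "poor"
    for upper, name in _BANDS[1:]:
        if kappa <= upper:
            return name
    return "almost perfect"


@dataclass(frozen=True)
class AgreementResult:
    """A kappa value with its bootstrap SD, sample count and band."""

    kappa: float
    sd: float
    n_samples: int
    band: str

    @classmethod
    def from_matrix(
        cls,
        matrix: np.ndarray,
        n_resamples: int = 100,
        seed=None,
    ) -> "AgreementResult":
        k = fleiss_kappa(matrix)
        sd = bootstrap_sd(matrix, n_resamples=n_resamples, seed=seed)
        return cls(kappa=k, sd=sd, n_samples=len(matrix), band=kappa_band(k))


def fleiss_kappa(label_matrix, categories=None) -> float:
    """Fleiss' kappa for an (n_samples, n_raters) label matrix.

    Every cell must be a scoreable category (exclude NONE rows upstream).
    When pooled chance agreement is 1 (a single category everywhere) the
    observed agreement is necessarily perfect and kappa is returned as 1.
    """
    m = np.asarray(label_matrix)
    if m.ndim != 2:
        raise ValueError("label matrix must be 2-D (samples x raters)")
    n, r = m.shape
    if n < 1:
        raise UndefinedAgreementError("no samples to compare")
    if r < 2:
        raise ValueError("need at least 2 raters")
    if categories is None:
        categories = PATTERNS
    cats = np.asarray([int(c) for c in categories])
    counts = (m[:, :, None] == cats[None, None, :]).sum(axis=1)
    if counts.sum(axis=1).min() != r:
        raise ValueError("label matrix contains values outside the categories")
    p_j = counts.sum(axis=0) / (n * r)
    p_i = (np.square(counts).sum(axis=1) - r) / (r * (r - 1))
    p_bar = float(p_i.mean())
    p_e = float(np.square(p_j).sum())
    if 1.0 - p_e < 1e-14:
        return 1.0  # degenerate: one category everywhere, agreement perfect
    return (p_bar - p_e) / (1.0 - p_e)


def bootstrap_sd(
    label_matrix,
    statistic=None,
    n_resamples: int = 100,
    seed=None,
    max_redraws: int = 10,
) -> float:
    """Bootstrap SD of a statistic of a label matrix.

    Sample rows are resampled with replacement ``n_resamples`` times
    (default 100) and the statistic recomputed; the standard deviation over
    resamples is returned. A resample on which the statistic is undefined is
    redrawn (bounded), after which the error propagates.
    """
    if n_resamples < 2:
        raise ValueError("n_resamples must be >= 2")
    m = np.asarray(label_matrix)
    stat = statistic if statistic is not None else fleiss_kappa
    rng = as_rng(seed)
    n = len(m)
    values = np.empty(n_resamples)
    for i in range(n_resamples):
        for attempt in range(max_redraws):
            idx = rng.integers(0, n, size=n)
            try:
                values[i] = stat(m[idx])
                break
            except (UndefinedAgreementError, ValueError):
                if attempt == max_redraws - 1:
                    raise
    return float(values.std(ddof=1))


def _joint_matrix(*label_vectors) -> np.ndarray:
    cols = [np.asarray(v) for v in label_vectors]
    n = len(cols[0])
    for c in cols:
        if len(c) != n:
            raise ValueError("label vectors must have equal length")
    m = np.column_stack(cols)
    keep = (m != int(PatternLabel.NONE)).all(axis=1)
    m = m[keep]
    if len(m) == 0:
        raise UndefinedAgreementError("no jointly scored samples")
    return m


def accuracy_kappa(
    assigned, truth, n_resamples: int = 100, seed=None
) -> AgreementResult:
    """Accuracy: agreement between assigned labels and the actual pattern.

    A two-rater Fleiss kappa over samples where both the scorer and the
    truth track carry a scoreable label.
    """
    m = _joint_matrix(assigned, truth)
    return AgreementResult.from_matrix(m, n_resamples=n_resamples, seed=seed)


def consistency_kappa(
    labels,
    pairing: EvaluationPairing,
    n_resamples: int = 100,
    seed=None,
) -> AgreementResult:
    """Consistency: agreement between the labels a scorer assigned to the
    two copies of each segment in an evaluation record.

    Copies are aligned positionally over their core content spans (the
    copies are bit-identical there), and a two-rater kappa is computed over
    the aligned samples.
    """
    labels = np.asarray(labels)
    first_parts = []
    second_parts = []
    for (s1, e1), (s2, e2) in pairing.pairs:
        if e1 > len(labels) or e2 > len(labels):
            raise ValueError("pairing does not fit the supplied label vector")
        first_parts.append(labels[s1:e1])
        second_parts.append(labels[s2:e2])
    first = np.concatenate(first_parts)
    second = np.concatenate(second_parts)
    m = _joint_matrix(first, second)
    return AgreementResult.from_matrix(m, n_resamples=n_resamples, seed=seed)


def intra_scorer_kappa(
    iter1,
    iter2,
    n_resamples: int = 100,
    seed=None,
) -> tuple[AgreementResult, dict[PatternLabel, AgreementResult | None]]:
    """Intra-scorer repeatability: overall and per-pattern two-rater kappa
    between a scorer's two iterations over the same data.

    Per-pattern values use one-vs-rest binarization before the two-category
    kappa; a pattern absent from both iterations is reported as ``None``.
    """
    m = _joint_matrix(iter1, iter2)
    rng = as_rng(seed)
    overall = AgreementResult.from_matrix(m, n_resamples=n_resamples, seed=rng)
    per_pattern: dict[PatternLabel, AgreementResult | None] = {}
    for pattern in PATTERNS:
        binary = (m == int(pattern)).astype(np.int8)
        if binary.sum() == 0:
            per_pattern[pattern] = None
            continue
        k = fleiss_kappa(binary, categories=(0, 1))
        sd = bootstrap_sd(
            binary,
            statistic=lambda x: fleiss_kappa(x, categories=(0, 1)),
            n_resamples=n_resamples,
            seed=rng,
        )
        per_pattern[pattern] = AgreementResult(
            kappa=k, sd=sd, n_samples=len(binary), band=kappa_band(k)
        )
    return overall, per_pattern


@dataclass(frozen=True)
class InterScorerResult:
    """Mean and SD of kappa over all iteration combinations."""

    mean: float
    sd: float
    kappas: tuple[float, ...]

    @property
    def n_combinations(self) -> int:
        return len(self.kappas)


def inter_scorer_kappa(iterations: list[list]) -> InterScorerResult:
    """Inter-scorer repeatability over all iteration combinations.

    ``iterations[s]`` is the list of label vectors scorer ``s`` produced.
    Every combination of one iteration per scorer is enumerated (2 x 2 x 2 =
    8 for three scorers with two iterations each), a multi-rater kappa is
    computed per combination, and the mean and standard deviation over
    combinations are reported.
    """
    if len(iterations) < 2:
        raise ValueError("need at least 2 scorers")
    for its in iterations:
        if not its:
            raise ValueError("every scorer needs at least one iteration")
    kappas = []
    for combo in itertools.product(*iterations):
        m = _joint_matrix(*combo)
        kappas.append(fleiss_kappa(m))
    arr = np.asarray(kappas)
    sd = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
    return InterScorerResult(mean=float(arr.mean()), sd=sd,
                             kappas=tuple(float(k) for k in arr))
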