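"""Core domain types: pattern labels, signal records, labeled segments.

The six respiratory inductive plethysmography (RIP) patterns form a mutually
exclusive alphabet used throughout the package:

* ``SYB`` — synchronous breathing: quasi-sinusoidal ribcage (RCG) and abdomen
  (ABD) signals less than 90° out of phase.
* ``ASB`` — asynchronous breathing: phase difference of 90° or more.
* ``SIH`` — sigh: a single breath with at least twice the amplitude and
  duration of the surrounding breaths in both channels.
* ``PAU`` — respiratory pause: both channels' excursion below 10% of the
  preceding normal breath; scored regardless of duration.
* ``MVT`` — movement artifact: chaotic, non-sinusoidal, low-frequency motion
  in both channels.
* ``UNK`` — unknown: technical faults or discordant channel patterns.

``NONE`` is a sentinel for unscored samples (or no-consensus samples); it is
never a scoreable category.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "PatternLabel",
    "PATTERNS",
    "RipRecord",
    "LabeledSegment",
    "SegmentLibrary",
]


class PatternLabel(IntEnum):
    """The six scoreable RIP patterns plus the ``NONE`` sentinel."""

    NONE = 0
    SYB = 1
    ASB = 2
    SIH = 3
    PAU = 4
    MVT = 5
    UNK = 6

    @classmethod
    def from_code(cls, code: str) -> "PatternLabel":
        try:
            return cls[code.strip().upper()]
        except KeyError:
            raise ValueError(f"unknown pattern code: {code!r}") from None

    @property
    def is_scoreable(self) -> bool:
        return self is not PatternLabel.NONE


#: The scoreable categories, in canonical order.
PATTERNS: tuple[PatternLabel, ...] = (
    PatternLabel.SYB,
    PatternLabel.ASB,
    PatternLabel.SIH,
    PatternLabel.PAU,
    PatternLabel.MVT,
    PatternLabel.UNK,
)


def _as_float_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional, got shape {arr.shape}")
    return arr


@dataclass
class RipRecord:
    """A fixed-rate multi-channel cardiorespiratory record.

    RCG (ribcage) and ABD (abdomen) are mandatory; PPG and SAT are optional
    decorative channels that play no role in scoring.

    Parameters
    ----------
    sample_rate : float
        Samples per second (50 Hz in the intended acquisition setup).
    rcg, abd : array-like
        Band signals in arbitrary units; equal length.
    ppg, sat : array-like, optional
        Photoplethysmogram and oxygen-saturation channels.
    t0 : float
        Record start time in seconds (epoch-agnostic).
    """

    sample_rate: float
    rcg: np.ndarray
    abd: np.ndarray
    ppg: np.ndarray | None = None
    sat: np.ndarray | None = None
    t0: float = 0.0

    def __post_init__(self) -> None:
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        self.rcg = _as_float_array(self.rcg, "rcg")
        self.abd = _as_float_array(self.abd, "abd")
        if self.ppg is not None:
            self.ppg = _as_float_array(self.ppg, "ppg")
        if self.sat is not None:
            self.sat = _as_float_array(self.sat, "sat")
        n = len(self.rcg)
        if n < 1:
            raise ValueError("record must contain at least one sample")
        for name in ("abd", "ppg", "sat"):
            ch = getattr(self, name)
            if ch is not None and len(ch) != n:
                raise ValueError(
                    f"channel {name} has length {len(ch)}, expected {n}"
                )

    @property
    def n_samples(self) -> int:
        return len(self.rcg)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate

    def time(self) -> np.ndarray:
        """Per-sample time axis in seconds, starting at ``t0``."""
        return self.t0 + np.arange(self.n_samples) / self.sample_rate


@dataclass
class LabeledSegment:
    """A two-channel (RCG, ABD) signal excerpt with a known pattern."""

    pattern: PatternLabel
    rcg: np.ndarray
    abd: np.ndarray
    source_id: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pattern = PatternLabel(self.pattern)
        if not self.pattern.is_scoreable:
            raise ValueError("a labeled segment must carry a scoreable pattern")
        self.rcg = _as_float_array(self.rcg, "rcg")
        self.abd = _as_float_array(self.abd, "abd")
        if len(self.rcg) != len(self.abd):
            raise ValueError("RCG and ABD excerpts must have equal length")
        if len(self.rcg) == 0:
            raise ValueError("segment must contain at least one sample")

    @property
    def length_samples(self) -> int:
        return len(self.rcg)

    def signals(self) -> np.ndarray:
        """Stack the two channels as an (n, 2) array, RCG first."""
        return np.column_stack([self.rcg, self.abd])


@dataclass
class SegmentLibrary:
    """A collection of labeled segments, the currency of training and QC."""

    segments: list[LabeledSegment] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.segments)

    def __iter__(self):
        return iter(self.segments)

    def add(self, segment: LabeledSegment) -> None:
        self.segments.append(segment)

    @property
    def counts_by_pattern(self) -> Mapping[PatternLabel, int]:
        counts = {p: 0 for p in PATTERNS}
        for seg in self.segments:
            counts[seg.pattern] += 1
        return counts

    def by_pattern(self, pattern: PatternLabel) -> list[LabeledSegment]:
        return [s for s in self.segments if s.pattern == pattern]

    @classmethod
    def from_segments(cls, segments: Iterable[LabeledSegment]) -> "SegmentLibrary":
        return cls(segments=list(segments))
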