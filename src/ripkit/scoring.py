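"""Scorer output: timestamped annotations, label tracks, scoring rates.

An annotation is one scorer's pass over one record: an ordered list of
scored segments, each with a record-time span (half-open, seconds), an
assigned pattern, and the wall-clock timestamp at which the score was
committed. Scoring time is reconstructed from consecutive timestamp
differences; differences above 2 minutes are treated as interruptions and
excluded, and the scoring rate is reported as hours of data scored per hour
of scoring work.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace

import numpy as np

from .patterns import PatternLabel
from .splice import GroundTruthTrack

__all__ = [
    "ScoreEvent",
    "Annotation",
    "UndefinedRateError",
    "GAP_EXCLUSION_S",
    "expand_labels",
    "scoring_rate",
    "pattern_scoring_rate",
    "read_annotation",
    "write_annotation",
]

#: Wall-clock gaps strictly greater than this (2 min) are excluded from
#: scoring-time sums; a gap of exactly 120 s is kept.
GAP_EXCLUSION_S = 120.0


class UndefinedRateError(ValueError):
    """Raised when a scoring rate cannot be computed (too few events, no
    usable wall-clock time, or no events of the requested pattern)."""


@dataclass(frozen=True)
class ScoreEvent:
    """One scored segment: record-time span, pattern, wall-clock stamp."""

    start_s: float
    end_s: float
    pattern: PatternLabel
    wallclock_s: float
    comment: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "pattern", PatternLabel(self.pattern))
        if self.end_s <= self.start_s:
            raise ValueError("event must have end_s > start_s")
        if not self.pattern.is_scoreable:
            raise ValueError("a score event must carry a scoreable pattern")

    @property
    def length_s(self) -> float:
        return self.end_s - self.start_s


@dataclass
class Annotation:
    """An ordered, non-overlapping list of score events for one record."""

    events: list[ScoreEvent]
    record_length_s: float
    scorer_id: str = ""
    iteration: int = 1

    def __post_init__(self) -> None:
        if self.record_length_s <= 0:
            raise ValueError("record_length_s must be positive")
        self.events = sorted(self.events, key=lambda e: e.start_s)
        for ev in self.events:
            if ev.start_s < -1e-9 or ev.end_s > self.record_length_s + 1e-9:
                raise ValueError(
                    f"event [{ev.start_s}, {ev.end_s}) outside the record"
                )
        for a, b in zip(self.events[:-1], self.events[1:]):
            if b.start_s < a.end_s - 1e-9:
                raise ValueError(
                    f"events overlap at {b.start_s:.3f} s"
                )

    def __len__(self) -> int:
        return len(self.events)

    def shift_wallclock(self, offset_s: float) -> "Annotation":
        return Annotation(
            events=[replace(e, wallclock_s=e.wallclock_s + offset_s)
                    for e in self.events],
            record_length_s=self.record_length_s,
            scorer_id=self.scorer_id,
            iteration=self.iteration,
        )


def expand_labels(annotation: Annotation, sample_rate: float) -> np.ndarray:
    """Per-sample label vector for an annotation.

    The vector has ``round(record_length_s * sample_rate)`` entries;
    unscored samples are ``NONE``. Event spans follow the half-open
    convention, so abutting events share no sample.
    """
    n = int(round(annotation.record_length_s * sample_rate))
    labels = np.zeros(n, dtype=np.int8)
    for ev in annotation.events:
        a = int(round(ev.start_s * sample_rate))
        b = int(round(ev.end_s * sample_rate))
        labels[max(a, 0) : min(b, n)] = int(ev.pattern)
    return labels


def labels_from_track(track: GroundTruthTrack) -> np.ndarray:
    """The per-sample label vector of a ground-truth track (identity
    companion to :func:`expand_labels` for truth tracks)."""
    return track.labels.copy()


def _usable_gaps(annotation: Annotation) -> np.ndarray:
    stamps = np.array([e.wallclock_s for e in annotation.events], dtype=float)
    diffs = np.diff(np.sort(stamps))
    return diffs[diffs <= GAP_EXCLUSION_S]


def scoring_rate(annotation: Annotation) -> float:
    """Overall scoring rate: data-hours scored per hour of scoring time.

    Scoring time is the sum of consecutive wall-clock differences of at
    most 2 min; larger gaps are interruptions and do not count.
    """
    if len(annotation) < 2:
        raise UndefinedRateError("need at least two events to estimate a rate")
    scoring_time = float(_usable_gaps(annotation).sum())
    if scoring_time <= 0:
        raise UndefinedRateError("no usable wall-clock time between events")
    return annotation.record_length_s / scoring_time


def pattern_scoring_rate(annotation: Annotation, pattern: PatternLabel) -> float:
    """Pattern-specific scoring rate.

    Numerator: total record-time length of events assigned ``pattern``.
    Denominator: the wall-clock cost attributed to those events — the
    difference from the previous event's timestamp, when it is at most
    2 min (the first event of a session has no attributable cost).
    """
    pattern = PatternLabel(pattern)
    events = sorted(annotation.events, key=lambda e: e.wallclock_s)
    data_s = 0.0
    work_s = 0.0
    for prev, ev in zip(events[:-1], events[1:]):
        if ev.pattern != pattern:
            continue
        data_s += ev.length_s
        gap = ev.wallclock_s - prev.wallclock_s
        if 0 <= gap <= GAP_EXCLUSION_S:
            work_s += gap
    if data_s == 0.0:
        raise UndefinedRateError(f"no {pattern.name} events with a preceding "
                                 "timestamp")
    if work_s <= 0:
        raise UndefinedRateError("no usable wall-clock time for the pattern")
    return data_s / work_s


# ---------------------------------------------------------------------------
# file format: CSV start_s,end_s,pattern,wallclock_s,comment
# ---------------------------------------------------------------------------

_HEADER = ["start_s", "end_s", "pattern", "wallclock_s", "comment"]


def write_annotation(annotation: Annotation, path) -> None:
    """Write an annotation as delimited text (header mandatory)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(_HEADER + [f"# record_length_s={annotation.record_length_s!r}"])
        for ev in annotation.events:
            w.writerow([
                repr(ev.start_s), repr(ev.end_s), ev.pattern.name,
                repr(ev.wallclock_s), ev.comment,
            ])


def read_annotation(path, record_length_s: float | None = None,
                    scorer_id: str = "", iteration: int = 1) -> Annotation:
    """Read an annotation file, validating every row.

    Raises ``ValueError`` naming the offending line on malformed rows;
    overlapping or out-of-bounds events are rejected by the
    :class:`Annotation` constructor.
    """
    events: list[ScoreEvent] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ValueError(f"{path}: empty annotation file") from None
        if [h.strip() for h in header[:5]] != _HEADER:
            raise ValueError(f"{path}: line 1: unexpected header {header[:5]}")
        if record_length_s is None:
            for cell in header[5:]:
                if cell.strip().startswith("# record_length_s="):
                    record_length_s = float(cell.split("=", 1)[1])
        if record_length_s is None:
            raise ValueError(f"{path}: record_length_s neither given nor stored")
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            try:
                events.append(ScoreEvent(
                    start_s=float(row[0]),
                    end_s=float(row[1]),
                    pattern=PatternLabel.from_code(row[2]),
                    wallclock_s=float(row[3]),
                    comment=row[4] if len(row) > 4 else "",
                ))
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from None
    return Annotation(events=events, record_length_s=record_length_s,
                      scorer_id=scorer_id, iteration=iteration)
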