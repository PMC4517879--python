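"""Smooth concatenation of labeled segments into continuous records.

Two segments are joined by overlapping them over a transition window of
``n_t`` samples: the tail of the first segment is attenuated by a decaying
sigmoid factor (1 → 0) while the head of the second is amplified by the
complementary rising factor (0 → 1), and the two are summed. Outside the
window both inputs are reproduced bit-exactly, and the output length is
``len(a) + len(b) - n_t``. This avoids the sharp transients that plain
abutment would introduce, which do not resemble natural RIP signals.

Ground truth for a concatenated record is a per-sample label vector plus a
segment table; samples inside a transition window are attributed by a
midpoint split (first half to the preceding segment, second half to the
following one).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .patterns import LabeledSegment, PatternLabel, RipRecord

__all__ = [
    "CrossfadeSpec",
    "SegmentSpan",
    "GroundTruthTrack",
    "crossfade_weights",
    "concatenate_pair",
    "concatenate_list",
    "transition_mask",
]


@dataclass(frozen=True)
class CrossfadeSpec:
    """Transition-window length and the rising sigmoid ramp weights.

    ``ramp`` weights the incoming (second) segment; the outgoing segment is
    weighted by ``1 - ramp``, so the two factors sum to 1 at every sample.
    """

    n_t: int
    ramp: np.ndarray

    def __post_init__(self) -> None:
        if self.n_t < 0:
            raise ValueError("n_t must be >= 0")
        ramp = np.asarray(self.ramp, dtype=float)
        object.__setattr__(self, "ramp", ramp)
        if len(ramp) != self.n_t:
            raise ValueError("ramp length must equal n_t")
        if self.n_t >= 2:
            if abs(ramp[0]) > 1e-9 or abs(ramp[-1] - 1.0) > 1e-9:
                raise ValueError("ramp must run from 0 to 1")
            if np.any(np.diff(ramp) < -1e-12):
                raise ValueError("ramp must be non-decreasing")

    @property
    def falling(self) -> np.ndarray:
        return 1.0 - self.ramp


def crossfade_weights(n_t: int, shape: str = "raised_cosine") -> CrossfadeSpec:
    """Build the sigmoid transition-window weights.

    ``shape="raised_cosine"`` (default) uses the half-period raised cosine
    ``0.5 - 0.5*cos(pi*k/(n_t-1))``, which reaches 0 and 1 exactly at the
    window edges so the inputs are reproduced bit-exactly outside the
    window. ``shape="logistic"`` uses a rescaled logistic curve with the
    same endpoint property. ``n_t=0`` yields pure abutment; ``n_t=1`` has no
    two distinct endpoints and uses the single weight 0.5.
    """
    if n_t < 0:
        raise ValueError("n_t must be >= 0")
    if n_t == 0:
        ramp = np.empty(0)
    elif n_t == 1:
        ramp = np.array([0.5])
    elif shape == "raised_cosine":
        k = np.arange(n_t)
        ramp = 0.5 - 0.5 * np.cos(np.pi * k / (n_t - 1))
        ramp[0] = 0.0
        ramp[-1] = 1.0
    elif shape == "logistic":
        x = np.arange(n_t) / (n_t - 1)
        steep = 8.0
        f = 1.0 / (1.0 + np.exp(-steep * (x - 0.5)))
        ramp = (f - f[0]) / (f[-1] - f[0])
    else:
        raise ValueError(f"unknown ramp shape: {shape!r}")
    return CrossfadeSpec(n_t=n_t, ramp=ramp)


def _as_two_channel(seg) -> np.ndarray:
    if isinstance(seg, LabeledSegment):
        return seg.signals()
    arr = np.asarray(seg, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("expected an (n, 2) two-channel array")
    return arr


def concatenate_pair(a, b, spec: CrossfadeSpec) -> np.ndarray:
    """Concatenate two two-channel segments over the transition window.

    Returns an ``(len(a) + len(b) - n_t, 2)`` array: ``a`` bit-exact before
    the window, ``b`` bit-exact after it, and the complementary-weighted sum
    inside it.
    """
    a = _as_two_channel(a)
    b = _as_two_channel(b)
    n_t = spec.n_t
    if len(a) < n_t or len(b) < n_t:
        raise ValueError(
            f"both segments must be at least n_t={n_t} samples long"
        )
    la, lb = len(a), len(b)
    out = np.empty((la + lb - n_t, 2))
    out[: la - n_t] = a[: la - n_t]
    if n_t:
        w = spec.ramp[:, None]
        out[la - n_t : la] = a[la - n_t :] * (1.0 - w) + b[:n_t] * w
    out[la:] = b[n_t:]
    return out


@dataclass(frozen=True)
class SegmentSpan:
    """A half-open [start, end) sample span with its ground-truth pattern."""

    start: int
    end: int
    pattern: PatternLabel
    source_id: str = ""

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class GroundTruthTrack:
    """Per-sample ground-truth labels plus the tiling segment table."""

    labels: np.ndarray
    segment_table: list[SegmentSpan] = field(default_factory=list)
    sample_rate: float = 50.0

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int8)
        if self.segment_table:
            spans = sorted(self.segment_table, key=lambda s: s.start)
            if spans[0].start != 0 or spans[-1].end != len(self.labels):
                raise ValueError("segment table must tile the record")
            for u, v in zip(spans[:-1], spans[1:]):
                if u.end != v.start:
                    raise ValueError(
                        "segment table has a gap or overlap at sample "
                        f"{u.end}"
                    )
            self.segment_table = spans

    @property
    def n_samples(self) -> int:
        return len(self.labels)

    def patterns_present(self) -> set[PatternLabel]:
        return {s.pattern for s in self.segment_table}


def transition_mask(track: GroundTruthTrack, n_t: int) -> np.ndarray:
    """Boolean mask of the samples inside transition windows.

    Each internal segment boundary of the track sits at the midpoint of an
    ``n_t``-sample blend window; the mask marks those windows so an
    evaluation can optionally exclude blended samples (set the truth to
    NONE there) instead of attributing them by the midpoint convention.
    """
    if n_t < 0:
        raise ValueError("n_t must be >= 0")
    mask = np.zeros(track.n_samples, dtype=bool)
    half = (n_t + 1) // 2
    for sp in track.segment_table[:-1]:
        b = sp.end
        mask[max(b - half, 0) : min(b - half + n_t, track.n_samples)] = True
    return mask


def concatenate_list(
    segments: list[LabeledSegment],
    spec: CrossfadeSpec,
    sample_rate: float = 50.0,
) -> tuple[RipRecord, GroundTruthTrack]:
    """Concatenate a list of labeled segments into a record with ground
    truth.

    The record length is ``sum(lengths) - (k-1)*n_t`` for ``k`` segments.
    Each sample carries the label of its source segment; the ``n_t`` samples
    of each transition window are split at the window midpoint, the first
    half labeled with the preceding segment's pattern.
    """
    if not segments:
        raise ValueError("segment list must be non-empty")
    n_t = spec.n_t
    lengths = [s.length_samples for s in segments]
    if min(lengths) < n_t:
        raise ValueError("every segment must be at least n_t samples long")
    total = sum(lengths) - (len(segments) - 1) * n_t
    out = np.empty((total, 2))
    first = segments[0].signals()
    out[: lengths[0]] = first
    pos = lengths[0]
    boundaries: list[int] = []
    half = (n_t + 1) // 2  # first half of the window -> preceding segment
    for seg in segments[1:]:
        sig = seg.signals()
        if n_t:
            w = spec.ramp[:, None]
            out[pos - n_t : pos] = out[pos - n_t : pos] * (1.0 - w) + sig[:n_t] * w
        boundaries.append(pos - n_t + half)
        out[pos : pos + len(sig) - n_t] = sig[n_t:]
        pos += len(sig) - n_t
    assert pos == total

    table: list[SegmentSpan] = []
    starts = [0] + boundaries
    ends = boundaries + [total]
    for seg, s, e in zip(segments, starts, ends):
        if e <= s:
            warnings.warn(
                "transition windows swallowed an entire segment in the "
                "ground-truth table",
                stacklevel=2,
            )
            e = s  # zero-length span dropped below
        table.append(SegmentSpan(start=s, end=e, pattern=seg.pattern,
                                 source_id=seg.source_id))
    # drop degenerate spans while keeping the tiling contiguous
    table = [sp for sp in table if sp.length > 0]
    labels = np.zeros(total, dtype=np.int8)
    for sp in table:
        labels[sp.start : sp.end] = int(sp.pattern)
    record = RipRecord(sample_rate=sample_rate, rcg=out[:, 0], abd=out[:, 1])
    track = GroundTruthTrack(labels=labels, segment_table=table,
                             sample_rate=sample_rate)
    return record, track
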