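"""Builders for training, evaluation and quality-control records.

Three record types drive scorer training and monitoring:

* **Training records** (~1 h): segments of every pattern are accumulated
  past 1.5 h, randomly reordered so no two adjacent segments share a
  pattern, truncated to the shortest prefix giving at least 1 h of
  concatenated signal, and spliced into a continuous record with ground
  truth.
* **Evaluation records** (~1 h): a unique segment list totalling 30 min is
  duplicated; each half is independently reordered; every unique segment
  therefore appears exactly once per half, enabling a consistency measure
  (agreement of a scorer with itself across halves) on top of accuracy.
* **QC pre-processing**: known-label segments are inserted twice into a long
  host record — once at random times in an early region, once (re-ordered)
  in a late region — so ongoing scorer accuracy and consistency can be
  monitored on real workloads.

All randomness flows from explicit seeds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from .patterns import (
    PATTERNS,
    LabeledSegment,
    PatternLabel,
    RipRecord,
    SegmentLibrary,
)
from .splice import (
    CrossfadeSpec,
    GroundTruthTrack,
    SegmentSpan,
    concatenate_list,
    crossfade_weights,
)
from .synth import SynthParams, synth_segment
from .util import as_rng

__all__ = [
    "EvaluationPairing",
    "QcInsertion",
    "QcInsertionPlan",
    "default_segment_source",
    "reorder_no_adjacent",
    "build_training_record",
    "build_evaluation_record",
    "select_qc_segments",
    "insert_qc_segments",
    "training_termination",
]

#: Default per-segment duration range (s) for training/evaluation records.
SEGMENT_DURATION_RANGE = (15.0, 45.0)

#: Per-pattern QC insertion counts: 152 segments, each pattern
#: approximately equally represented.
QC_COUNTS: dict[PatternLabel, int] = {
    PatternLabel.SYB: 25,
    PatternLabel.ASB: 26,
    PatternLabel.SIH: 27,
    PatternLabel.PAU: 22,
    PatternLabel.MVT: 27,
    PatternLabel.UNK: 25,
}


SegmentSource = Callable[[PatternLabel, float, np.random.Generator], LabeledSegment]


def default_segment_source(
    params: SynthParams | None = None,
) -> SegmentSource:
    """A segment source backed by the synthetic pattern generators."""
    base = params or SynthParams()

    def make(pattern: PatternLabel, duration_s: float,
             rng: np.random.Generator) -> LabeledSegment:
        seed = int(rng.integers(0, 2**31 - 1))
        return synth_segment(pattern, duration_s, base.with_seed(seed))

    return make


def _library_source(library: SegmentLibrary) -> SegmentSource:
    by_pattern = {p: library.by_pattern(p) for p in PATTERNS}

    def make(pattern: PatternLabel, duration_s: float,
             rng: np.random.Generator) -> LabeledSegment:
        pool = by_pattern[pattern]
        if not pool:
            raise ValueError(f"library has no segments of pattern {pattern.name}")
        return pool[int(rng.integers(len(pool)))]

    return make


def _coerce_source(source) -> SegmentSource:
    if source is None:
        return default_segment_source()
    if isinstance(source, SegmentLibrary):
        return _library_source(source)
    if callable(source):
        return source
    raise TypeError("source must be a SegmentLibrary, callable, or None")


# ---------------------------------------------------------------------------
# ordering
# ---------------------------------------------------------------------------


def _conflicts(order: Sequence[LabeledSegment]) -> int:
    return sum(
        1 for a, b in zip(order[:-1], order[1:]) if a.pattern == b.pattern
    )


def reorder_no_adjacent(
    segments: Sequence[LabeledSegment],
    seed=None,
    max_passes: int = 3,
) -> list[LabeledSegment]:
    """Randomly permute segments so no two adjacent share a pattern.

    A random permutation is repaired by the push-to-end rule (a segment
    whose pattern matches its predecessor is moved to the end of the list),
    applied for up to ``max_passes`` full passes. Because push-to-end can
    cycle when duplicates pile up at the tail, remaining conflicts are then
    repaired by re-inserting the offending segments at non-conflicting
    slots. If no conflict-free ordering exists (one pattern holds more than
    half the list) the minimal-conflict arrangement is returned with a
    warning.
    """
    if not segments:
        raise ValueError("segment list must be non-empty")
    rng = as_rng(seed)
    order = [segments[i] for i in rng.permutation(len(segments))]
    for _ in range(max_passes):
        out: list[LabeledSegment] = []
        tail: list[LabeledSegment] = []
        for seg in order:
            if out and out[-1].pattern == seg.pattern:
                tail.append(seg)
            else:
                out.append(seg)
        order = out + tail
        if not tail:
            break
    if _conflicts(order):
        # greedy re-insertion of conflicting segments
        i = 1
        guard = 0
        while i < len(order) and guard < 10 * len(order):
            guard += 1
            if order[i].pattern != order[i - 1].pattern:
                i += 1
                continue
            seg = order.pop(i)
            placed = False
            for j in range(len(order) + 1):
                left_ok = j == 0 or order[j - 1].pattern != seg.pattern
                right_ok = j == len(order) or order[j].pattern != seg.pattern
                if left_ok and right_ok:
                    order.insert(j, seg)
                    placed = True
                    break
            if not placed:
                order.append(seg)
                i += 1
    if _conflicts(order):
        warnings.warn(
            "no conflict-free ordering exists; returning a minimal-conflict "
            "arrangement",
            stacklevel=2,
        )
    return order


# ---------------------------------------------------------------------------
# training records
# ---------------------------------------------------------------------------


def _accumulate_segments(
    source: SegmentSource,
    total_s: float,
    rng: np.random.Generator,
    sample_rate: float,
    duration_range: tuple[float, float],
    id_prefix: str,
) -> list[LabeledSegment]:
    """Cycle the six patterns, drawing segments until the total length
    exceeds ``total_s``."""
    segments: list[LabeledSegment] = []
    acc = 0.0
    i = 0
    while acc <= total_s:
        pattern = PATTERNS[i % len(PATTERNS)]
        dur = float(rng.uniform(*duration_range))
        seg = source(pattern, dur, rng)
        seg = LabeledSegment(
            pattern=seg.pattern, rcg=seg.rcg, abd=seg.abd,
            source_id=f"{id_prefix}{i:04d}", meta=dict(seg.meta),
        )
        segments.append(seg)
        acc += seg.length_samples / sample_rate
        i += 1
    return segments


def _truncate_to_duration(
    order: list[LabeledSegment], target_s: float, n_t: int, sample_rate: float
) -> list[LabeledSegment]:
    """Shortest prefix whose concatenated duration reaches ``target_s``."""
    acc_samples = 0
    for k, seg in enumerate(order):
        acc_samples += seg.length_samples - (n_t if k else 0)
        if acc_samples / sample_rate >= target_s:
            return order[: k + 1]
    return order


def build_training_record(
    source=None,
    spec: CrossfadeSpec | None = None,
    seed=None,
    *,
    accumulate_s: float = 1.5 * 3600.0,
    target_s: float = 3600.0,
    duration_range: tuple[float, float] = SEGMENT_DURATION_RANGE,
    sample_rate: float = 50.0,
    max_retries: int = 10,
) -> tuple[RipRecord, GroundTruthTrack]:
    """Build a Training-Mode record with ground truth.

    Segments of each pattern are accumulated past ``accumulate_s`` (default
    1.5 h), randomly reordered with the no-adjacent-duplicates repair, and
    truncated to the shortest prefix whose concatenated length reaches
    ``target_s`` (default 1 h). The permutation is redrawn (bounded) if
    truncation dropped a pattern category or the prefix violates adjacency.
    """
    rng = as_rng(seed)
    src = _coerce_source(source)
    spec = spec if spec is not None else crossfade_weights(int(round(sample_rate)))
    pool = _accumulate_segments(
        src, accumulate_s, rng, sample_rate, duration_range, "tr-"
    )
    for _ in range(max_retries):
        order = reorder_no_adjacent(pool, rng)
        prefix = _truncate_to_duration(order, target_s, spec.n_t, sample_rate)
        patterns = {s.pattern for s in prefix}
        if patterns == set(PATTERNS) and _conflicts(prefix) == 0:
            break
    else:
        raise RuntimeError(
            "could not build a training list covering all patterns without "
            "adjacent duplicates"
        )
    return concatenate_list(prefix, spec, sample_rate)


# ---------------------------------------------------------------------------
# evaluation records
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EvaluationPairing:
    """Links the two copies of each unique segment in an evaluation record.

    Each pair holds the half-open output sample spans of the *core* content
    of the two copies (trimmed by one transition window on each side, so the
    paired spans are equal-length and bit-identical in signal content).
    """

    pairs: list[tuple[tuple[int, int], tuple[int, int]]]
    source_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for (s1, e1), (s2, e2) in self.pairs:
            if e1 - s1 != e2 - s2:
                raise ValueError("paired spans must be equal length")
            if e1 <= s1:
                raise ValueError("paired spans must be non-empty")

    def __len__(self) -> int:
        return len(self.pairs)


def build_evaluation_record(
    source=None,
    seed=None,
    *,
    spec: CrossfadeSpec | None = None,
    half_s: float = 1800.0,
    duration_range: tuple[float, float] = SEGMENT_DURATION_RANGE,
    sample_rate: float = 50.0,
    max_retries: int = 10,
) -> tuple[RipRecord, GroundTruthTrack, EvaluationPairing]:
    """Build an Evaluation-Mode record: a 30-min unique segment list,
    duplicated, each half independently ordered, halves joined.

    Every unique segment appears exactly once per half; the returned
    :class:`EvaluationPairing` aligns the two copies for the consistency
    statistic.
    """
    rng = as_rng(seed)
    src = _coerce_source(source)
    spec = spec if spec is not None else crossfade_weights(int(round(sample_rate)))
    unique = _accumulate_segments(
        src, half_s, rng, sample_rate, duration_range, "ev-"
    )
    order1 = reorder_no_adjacent(unique, rng)
    for _ in range(max_retries):
        order2 = reorder_no_adjacent(unique, rng)
        if [s.source_id for s in order2] != [s.source_id for s in order1]:
            break
    else:  # pragma: no cover - probability ~ 1/n! per draw
        raise RuntimeError("could not draw a distinct second-half ordering")
    joined = order1 + order2
    record, track = concatenate_list(joined, spec, sample_rate)

    # output content start of list item j: S_0 = 0, S_j = S_{j-1} + l_{j-1} - n_t
    starts: list[int] = []
    pos = 0
    for seg in joined:
        starts.append(pos)
        pos += seg.length_samples - spec.n_t
    core: dict[tuple[str, int], tuple[int, int]] = {}
    counts: dict[str, int] = {}
    for seg, s in zip(joined, starts):
        k = counts.get(seg.source_id, 0)
        counts[seg.source_id] = k + 1
        core[(seg.source_id, k)] = (
            s + spec.n_t,
            s + seg.length_samples - spec.n_t,
        )
    pairs = []
    ids = []
    for seg in unique:
        pairs.append((core[(seg.source_id, 0)], core[(seg.source_id, 1)]))
        ids.append(seg.source_id)
    return record, track, EvaluationPairing(pairs=pairs, source_ids=ids)


# ---------------------------------------------------------------------------
# quality-control insertion
# ---------------------------------------------------------------------------


def select_qc_segments(
    library: SegmentLibrary,
    counts_by_pattern: Mapping[PatternLabel, int] | None = None,
    seed=None,
) -> list[LabeledSegment]:
    """Uniform selection without replacement of per-pattern QC segments."""
    counts = dict(counts_by_pattern) if counts_by_pattern is not None else dict(
        QC_COUNTS
    )
    rng = as_rng(seed)
    chosen: list[LabeledSegment] = []
    for pattern in PATTERNS:
        want = int(counts.get(pattern, 0))
        if want == 0:
            continue
        pool = library.by_pattern(pattern)
        if len(pool) < want:
            raise ValueError(
                f"library holds {len(pool)} {pattern.name} segments, "
                f"{want} requested"
            )
        idx = rng.choice(len(pool), size=want, replace=False)
        chosen.extend(pool[int(i)] for i in idx)
    return chosen


@dataclass(frozen=True)
class QcInsertion:
    """One QC segment placement."""

    pass_idx: int  # 1 or 2
    host_position_s: float  # split point in the original host record
    position_s: float  # content start in the output record
    source_id: str
    pattern: PatternLabel
    length_s: float


@dataclass
class QcInsertionPlan:
    insertions: list[QcInsertion] = field(default_factory=list)

    @property
    def counts_by_pattern(self) -> dict[PatternLabel, int]:
        counts: dict[PatternLabel, int] = {}
        for ins in self.insertions:
            counts[ins.pattern] = counts.get(ins.pattern, 0) + 1
        return counts

    def by_pass(self, pass_idx: int) -> list[QcInsertion]:
        return [i for i in self.insertions if i.pass_idx == pass_idx]


def _draw_positions(
    rng: np.random.Generator,
    k: int,
    region: tuple[float, float],
    sample_rate: float,
    min_gap_samples: int,
    taken: list[int],
    n_host: int,
    max_tries: int = 200,
) -> list[int]:
    lo = max(int(np.ceil(region[0] * sample_rate)), min_gap_samples)
    hi = min(int(region[1] * sample_rate), n_host - min_gap_samples)
    # uniform sorted draws spread by the minimum gap: equivalent to a
    # uniform draw over all admissible spaced position sets
    span = hi - lo - (k - 1) * min_gap_samples
    if span <= 0:
        raise ValueError("insertion region too small for the host record")
    taken_arr = np.asarray(taken, dtype=int)
    for _ in range(max_tries):
        base = np.sort(rng.integers(lo, lo + span, size=k))
        pos = base + np.arange(k) * min_gap_samples
        allpos = np.sort(np.concatenate([pos, taken_arr]))
        if (np.diff(allpos) >= min_gap_samples).all():
            return [int(p) for p in pos]
    raise RuntimeError(
        "could not place QC segments with the required spacing; "
        "enlarge the region or reduce the count"
    )


def insert_qc_segments(
    record: RipRecord,
    qc_segments: Sequence[LabeledSegment],
    region_1: tuple[float, float] | None = None,
    region_2: tuple[float, float] | None = None,
    spec: CrossfadeSpec | None = None,
    seed=None,
    min_spacing_s: float = 0.0,
) -> tuple[RipRecord, QcInsertionPlan, GroundTruthTrack]:
    """Insert each QC segment twice into a host record.

    Pass 1 inserts the randomly ordered segments at uniformly drawn split
    points inside ``region_1`` (default: the first 3 h); pass 2 re-orders
    them independently and inserts them inside ``region_2`` (default: the
    last 3 h). Each insertion splits the host at the drawn point and
    splices the segment in with two transition windows, so the record grows
    by ``len(segment) - 2*n_t`` samples per insertion.

    Returns the grown record, the insertion plan, and a ground-truth track
    in output coordinates whose labels are the inserted patterns (``NONE``
    over host samples).
    """
    qc_segments = list(qc_segments)
    if not qc_segments:
        raise ValueError("no QC segments to insert")
    rng = as_rng(seed)
    fs = record.sample_rate
    spec = spec if spec is not None else crossfade_weights(int(round(fs)))
    n_t = spec.n_t
    dur = record.duration_s
    if region_1 is None:
        region_1 = (0.0, min(3 * 3600.0, dur / 2.0))
    if region_2 is None:
        region_2 = (max(dur - 3 * 3600.0, dur / 2.0), dur)
    for name, reg in (("region_1", region_1), ("region_2", region_2)):
        if not (0.0 <= reg[0] < reg[1] <= dur + 1e-9):
            raise ValueError(f"{name} must lie inside the host record")

    min_gap = max(2 * n_t + 1, int(round(min_spacing_s * fs)))
    host = np.column_stack([record.rcg, record.abd])
    n_host = len(host)
    order1 = [qc_segments[i] for i in rng.permutation(len(qc_segments))]
    order2 = [qc_segments[i] for i in rng.permutation(len(qc_segments))]
    pos1 = _draw_positions(rng, len(order1), region_1, fs, min_gap, [], n_host)
    pos2 = _draw_positions(rng, len(order2), region_2, fs, min_gap, pos1, n_host)

    events = sorted(
        [(p, seg, 1) for p, seg in zip(pos1, order1)]
        + [(p, seg, 2) for p, seg in zip(pos2, order2)],
        key=lambda e: e[0],
    )
    for seg in qc_segments:
        if seg.length_samples < max(2 * n_t, 1):
            raise ValueError("QC segments must span at least two transition windows")

    chunks: list[np.ndarray] = []
    spans: list[SegmentSpan] = []
    insertions: list[QcInsertion] = []
    half = (n_t + 1) // 2
    out_len = 0
    prev = 0

    def append_blend(piece: np.ndarray) -> int:
        """Blend ``piece`` onto the output; return its content start."""
        nonlocal out_len
        if out_len == 0 or n_t == 0:
            chunks.append(piece.copy())
            start = out_len - (n_t if out_len else 0)
            out_len += len(piece) - (n_t if out_len and n_t else 0)
            return max(start, 0)
        tail = chunks[-1]
        w = spec.ramp[:, None]
        tail[-n_t:] = tail[-n_t:] * (1.0 - w) + piece[:n_t] * w
        start = out_len - n_t
        chunks.append(piece[n_t:].copy())
        out_len += len(piece) - n_t
        return start

    for host_pos, seg, pass_idx in events:
        append_blend(host[prev:host_pos])
        start = append_blend(seg.signals())
        prev = host_pos
        label_start = start + half
        label_end = start + seg.length_samples - n_t + half
        spans.append(
            SegmentSpan(
                start=label_start,
                end=label_end,
                pattern=seg.pattern,
                source_id=seg.source_id,
            )
        )
        insertions.append(
            QcInsertion(
                pass_idx=pass_idx,
                host_position_s=host_pos / fs,
                position_s=start / fs,
                source_id=seg.source_id,
                pattern=seg.pattern,
                length_s=seg.length_samples / fs,
            )
        )
    append_blend(host[prev:])

    out = np.concatenate(chunks, axis=0)
    assert len(out) == out_len
    expected = n_host + sum(s.length_samples for s in qc_segments) * 2 - (
        4 * len(qc_segments) * n_t if n_t else 0
    )
    assert out_len == expected, (out_len, expected)

    labels = np.zeros(out_len, dtype=np.int8)
    table: list[SegmentSpan] = []
    cursor = 0
    for sp in sorted(spans, key=lambda s: s.start):
        if sp.start > cursor:
            table.append(SegmentSpan(cursor, sp.start, PatternLabel.NONE))
        table.append(sp)
        labels[sp.start : sp.end] = int(sp.pattern)
        cursor = sp.end
    if cursor < out_len:
        table.append(SegmentSpan(cursor, out_len, PatternLabel.NONE))

    grown = RipRecord(sample_rate=fs, rcg=out[:, 0], abd=out[:, 1], t0=record.t0)
    plan = QcInsertionPlan(insertions=insertions)
    track = GroundTruthTrack(labels=labels, segment_table=table, sample_rate=fs)
    return grown, plan, track


# ---------------------------------------------------------------------------
# training termination
# ---------------------------------------------------------------------------


def training_termination(
    history: Sequence[tuple[PatternLabel, bool]], quota: int = 5
) -> bool:
    """Whether a training session's consecutive-correct quota has been met.

    Scans the scoring history in order, counting correct scores per pattern;
    any error resets *all* counters (a strict reading of "consecutively").
    Returns True as soon as every one of the six patterns has accumulated
    ``quota`` correct scores within the current unbroken run of correct
    answers.
    """
    counters = {p: 0 for p in PATTERNS}
    for pattern, correct in history:
        pattern = PatternLabel(pattern)
        if not correct:
            counters = {p: 0 for p in PATTERNS}
            continue
        if pattern in counters:
            counters[pattern] += 1
        if all(c >= quota for c in counters.values()):
            return True
    return False
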