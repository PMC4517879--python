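"""Record builders: ordering repair, training/evaluation structure, QC
insertion, training termination."""

import numpy as np
import pytest

from ripkit.patterns import (
    PATTERNS,
    LabeledSegment,
    PatternLabel,
    RipRecord,
    SegmentLibrary,
)
from ripkit.records import (
    QC_COUNTS,
    build_evaluation_record,
    build_training_record,
    insert_qc_segments,
    reorder_no_adjacent,
    select_qc_segments,
    training_termination,
)
from ripkit.splice import crossfade_weights


def make_segment(n, pattern, seed=0, source_id=""):
    rng = np.random.default_rng(seed)
    return LabeledSegment(pattern=pattern, rcg=rng.standard_normal(n),
                          abd=rng.standard_normal(n), source_id=source_id)


def conflicts(order):
    return sum(1 for a, b in zip(order[:-1], order[1:])
               if a.pattern == b.pattern)


class TestReorder:
    @pytest.mark.parametrize("seed", range(10))
    def test_resolvable_triple_always_separated(self, seed):
        segs = [make_segment(10, PatternLabel.SYB, seed=1),
                make_segment(10, PatternLabel.SYB, seed=2),
                make_segment(10, PatternLabel.PAU, seed=3)]
        out = reorder_no_adjacent(segs, seed=seed)
        assert conflicts(out) == 0
        assert sorted(id(s) for s in out) == sorted(id(s) for s in segs)

    def test_unresolvable_warns(self):
        segs = [make_segment(10, PatternLabel.MVT, seed=i) for i in range(4)]
        with pytest.warns(UserWarning):
            out = reorder_no_adjacent(segs, seed=0)
        assert len(out) == 4

    def test_deterministic_given_seed(self):
        segs = [make_segment(10, p, seed=i)
                for i, p in enumerate(PATTERNS * 3)]
        a = reorder_no_adjacent(segs, seed=5)
        b = reorder_no_adjacent(segs, seed=5)
        assert [s.source_id for s in a] == [s.source_id for s in b]

    @pytest.mark.parametrize("seed", range(20))
    def test_random_mixes_resolved(self, seed):
        rng = np.random.default_rng(seed)
        pats = [PATTERNS[i] for i in rng.integers(0, 6, size=30)]
        # ensure resolvable: no pattern majority
        if max(pats.count(p) for p in PATTERNS) > (len(pats) + 1) // 2:
            pats = list(PATTERNS) * 5
        segs = [make_segment(10, p, seed=i) for i, p in enumerate(pats)]
        assert conflicts(reorder_no_adjacent(segs, seed=seed)) == 0


class TestTrainingRecord:
    def test_structure(self):
        # scaled durations; the construction rule is scale-free
        record, track = build_training_record(
            seed=3, accumulate_s=900.0, target_s=600.0
        )
        longest = max(sp.length for sp in track.segment_table) / 50.0
        assert 600.0 <= record.duration_s < 600.0 + 45.0 + 1.0
        assert track.patterns_present() == set(PATTERNS)
        assert conflicts(track.segment_table) == 0
        assert record.n_samples == track.n_samples

    def test_deterministic(self):
        r1, _ = build_training_record(seed=4, accumulate_s=600, target_s=400)
        r2, _ = build_training_record(seed=4, accumulate_s=600, target_s=400)
        np.testing.assert_array_equal(r1.rcg, r2.rcg)


@pytest.fixture(scope="module")
def eval_record():
    return build_evaluation_record(seed=8, half_s=300.0)


class TestEvaluationRecord:
    def test_each_segment_twice_once_per_half(self, eval_record):
        record, track, pairing = eval_record
        ids = [sp.source_id for sp in track.segment_table]
        k = len(pairing)
        assert len(ids) == 2 * k
        first, second = ids[:k], ids[k:]
        assert sorted(first) == sorted(second)
        assert len(set(first)) == k

    def test_per_half_histograms_identical(self, eval_record):
        _, track, pairing = eval_record
        k = len(pairing)
        pats = [sp.pattern for sp in track.segment_table]
        hist1 = {p: pats[:k].count(p) for p in PATTERNS}
        hist2 = {p: pats[k:].count(p) for p in PATTERNS}
        assert hist1 == hist2

    def test_halves_ordered_differently(self, eval_record):
        _, track, pairing = eval_record
        ids = [sp.source_id for sp in track.segment_table]
        k = len(pairing)
        assert ids[:k] != ids[k:]

    def test_paired_copies_bit_identical(self, eval_record):
        record, _, pairing = eval_record
        sig = np.column_stack([record.rcg, record.abd])
        for (s1, e1), (s2, e2) in pairing.pairs:
            np.testing.assert_array_equal(sig[s1:e1], sig[s2:e2])


class TestSelectQc:
    def _library(self, depth=30, n=120):
        lib = SegmentLibrary()
        for i in range(n):
            p = PATTERNS[i % 6]
            lib.add(make_segment(100, p, seed=i, source_id=f"lib-{i}"))
        return lib

    def test_152_segment_scheme(self):
        lib = SegmentLibrary()
        i = 0
        for p, want in QC_COUNTS.items():
            for _ in range(want + 3):
                lib.add(make_segment(50, p, seed=i, source_id=f"l{i}"))
                i += 1
        chosen = select_qc_segments(lib, QC_COUNTS, seed=1)
        assert len(chosen) == 152
        counts = {p: sum(1 for s in chosen if s.pattern == p)
                  for p in PATTERNS}
        assert counts == dict(QC_COUNTS)
        assert len({s.source_id for s in chosen}) == 152  # no replacement

    def test_zero_counts_empty(self):
        assert select_qc_segments(self._library(), {p: 0 for p in PATTERNS},
                                  seed=0) == []

    def test_insufficient_depth_names_pattern(self):
        lib = self._library(n=12)
        with pytest.raises(ValueError, match="SIH"):
            select_qc_segments(lib, {PatternLabel.SIH: 10}, seed=0)


class TestInsertQc:
    def _host(self, n=30000):
        rng = np.random.default_rng(0)
        return RipRecord(sample_rate=50.0, rcg=rng.standard_normal(n),
                         abd=rng.standard_normal(n))

    def _qc(self, k=12, n=200):
        return [make_segment(n, PATTERNS[i % 6], seed=100 + i,
                             source_id=f"qc-{i}") for i in range(k)]

    def test_growth_with_zero_window(self):
        host = self._host()
        qc = self._qc()
        total = sum(s.length_samples for s in qc)
        grown, plan, track = insert_qc_segments(
            host, qc, region_1=(0, 300), region_2=(300, 600),
            spec=crossfade_weights(0), seed=1,
        )
        assert grown.n_samples == host.n_samples + 2 * total
        # removing inserted samples recovers the host bit-exactly
        keep = track.labels == int(PatternLabel.NONE)
        np.testing.assert_array_equal(grown.rcg[keep], host.rcg)

    def test_passes_confined_to_regions(self):
        host = self._host()
        grown, plan, _ = insert_qc_segments(
            host, self._qc(), region_1=(0, 300), region_2=(300, 600), seed=2,
        )
        assert len(plan.by_pass(1)) == 12 and len(plan.by_pass(2)) == 12
        assert all(0 <= i.host_position_s < 300 for i in plan.by_pass(1))
        assert all(300 <= i.host_position_s <= 600 for i in plan.by_pass(2))

    def test_host_bit_identical_outside_neighborhoods(self):
        host = self._host()
        qc = self._qc()
        n_t = 50
        grown, plan, _ = insert_qc_segments(
            host, qc, region_1=(0, 300), region_2=(300, 600),
            spec=crossfade_weights(n_t), seed=3,
        )
        by_host = sorted(plan.insertions, key=lambda i: i.host_position_s)
        added = 0
        prev_edge = 0  # first untouched host sample after the last insertion
        for ins in by_host:
            split = int(round(ins.host_position_s * 50.0))
            a, b = prev_edge, split - n_t  # untouched host range
            if b > a:
                np.testing.assert_array_equal(
                    grown.rcg[a + added : b + added], host.rcg[a:b]
                )
            added += int(round(ins.length_s * 50.0)) - 2 * n_t
            prev_edge = split + n_t
        np.testing.assert_array_equal(grown.rcg[prev_edge + added :],
                                      host.rcg[prev_edge:])

    def test_growth_algebra_with_window(self):
        host = self._host()
        qc = self._qc()
        n_t = 50
        total = sum(s.length_samples for s in qc)
        grown, _, _ = insert_qc_segments(
            host, qc, region_1=(0, 300), region_2=(300, 600),
            spec=crossfade_weights(n_t), seed=4,
        )
        assert grown.n_samples == host.n_samples + 2 * total - 4 * len(qc) * n_t

    def test_deterministic(self):
        host = self._host()
        g1, p1, _ = insert_qc_segments(host, self._qc(), region_1=(0, 300),
                                       region_2=(300, 600), seed=7)
        g2, p2, _ = insert_qc_segments(host, self._qc(), region_1=(0, 300),
                                       region_2=(300, 600), seed=7)
        np.testing.assert_array_equal(g1.rcg, g2.rcg)
        assert p1.insertions == p2.insertions


def termination_oracle(history, quota=5):
    """Brute force: for each prefix end, recount the unbroken correct
    suffix from scratch."""
    for t in range(len(history)):
        errors = [i for i in range(t + 1) if not history[i][1]]
        start = errors[-1] + 1 if errors else 0
        run = [history[i][0] for i in range(start, t + 1)]
        if all(run.count(p) >= quota for p in PATTERNS):
            return True
    return False


class TestTrainingTermination:
    def test_quota_met(self):
        history = [(p, True) for p in PATTERNS for _ in range(5)]
        assert training_termination(history) is True

    def test_one_pattern_short(self):
        history = [(p, True) for p in PATTERNS[:5] for _ in range(5)]
        history += [(PatternLabel.UNK, True)] * 4
        assert training_termination(history) is False

    def test_error_resets_all_counters(self):
        history = [(p, True) for p in PATTERNS for _ in range(5)][:-1]
        history.append((PatternLabel.SYB, False))  # error after 29 correct
        history.append((PatternLabel.UNK, True))
        assert training_termination(history) is False

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        history = [
            (PATTERNS[int(rng.integers(6))], bool(rng.random() < 0.93))
            for _ in range(int(rng.integers(20, 120)))
        ]
        assert training_termination(history) == termination_oracle(history)
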