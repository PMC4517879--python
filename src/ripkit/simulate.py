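"""Simulated scorers and the end-to-end validation experiment.

A simulated scorer walks the ground-truth segment table of a record,
perturbs each segment boundary with Gaussian jitter (modeling the dominant
human disagreement mode, edge placement), assigns each segment a pattern
drawn from the confusion row of its true pattern (modeling category
confusion), and stamps each score with an accumulated wall-clock time drawn
from a per-segment rate model. With an identity confusion matrix and zero
jitter the scorer reproduces the truth exactly, which closes the loop on
every evaluation statistic: accuracy, consistency, intra-/inter-scorer
repeatability, scoring rate, and the confusion analysis.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from .agreement import (
    accuracy_kappa,
    consistency_kappa,
    inter_scorer_kappa,
    intra_scorer_kappa,
)
from .confusion import confusion_matrix, consensus_labels
from .patterns import PATTERNS, LabeledSegment, PatternLabel, SegmentLibrary
from .records import (
    EvaluationPairing,
    insert_qc_segments,
    select_qc_segments,
)
from .scoring import Annotation, ScoreEvent, expand_labels, scoring_rate
from .splice import GroundTruthTrack, crossfade_weights
from .synth import SynthParams, synth_breathing, synth_segment
from .util import as_rng

__all__ = [
    "ScorerProfile",
    "simulate_scorer",
    "ExperimentConfig",
    "run_validation_experiment",
    "load_report",
]


def _identity_confusion() -> np.ndarray:
    return np.eye(len(PATTERNS))


@dataclass
class ScorerProfile:
    """Behavioral model of a simulated scorer.

    ``confusion[i, j]`` is the probability of assigning pattern ``j`` to a
    segment whose true pattern is ``i`` (rows in canonical pattern order,
    each summing to 1). ``boundary_jitter_sd`` (s) perturbs segment edges;
    ``rate_mean``/``rate_sd`` (s) model the wall-clock cost of scoring one
    segment.
    """

    confusion: np.ndarray = field(default_factory=_identity_confusion)
    boundary_jitter_sd: float = 0.0
    rate_mean: float = 4.0
    rate_sd: float = 1.0
    seed: int | None = None

    def __post_init__(self) -> None:
        self.confusion = np.asarray(self.confusion, dtype=float)
        k = len(PATTERNS)
        if self.confusion.shape != (k, k):
            raise ValueError(f"confusion must be {k}x{k}")
        if np.any(self.confusion < 0) or np.any(
            np.abs(self.confusion.sum(axis=1) - 1.0) > 1e-9
        ):
            raise ValueError("confusion rows must be non-negative and sum to 1")
        if self.boundary_jitter_sd < 0:
            raise ValueError("boundary_jitter_sd must be >= 0")
        if self.rate_mean <= 0:
            raise ValueError("rate_mean must be positive")


def simulate_scorer(
    truth: GroundTruthTrack,
    profile: ScorerProfile,
    seed=None,
    wallclock_start_s: float = 0.0,
) -> Annotation:
    """Produce one simulated scoring pass over a record's ground truth.

    Segment boundaries are jittered jointly (abutting segments stay
    abutting), each scoreable segment's label is drawn from the confusion
    row of its true pattern, and wall-clock stamps accumulate from the rate
    model. NONE spans of the truth (unmonitored host data in QC records)
    are left unscored. A segment whose jittered span collapses below one
    sample is dropped with a warning.
    """
    rng = as_rng(seed if seed is not None else profile.seed)
    fs = truth.sample_rate
    table = truth.segment_table
    if not table:
        raise ValueError("truth track has no segment table")
    # joint boundary jitter over the tiling [b_0 .. b_K]
    bounds = np.array([table[0].start] + [sp.end for sp in table], dtype=float)
    bounds = bounds / fs
    if profile.boundary_jitter_sd > 0:
        inner = bounds[1:-1] + rng.normal(
            0.0, profile.boundary_jitter_sd, size=len(bounds) - 2
        )
        bounds = np.concatenate([[bounds[0]], inner, [bounds[-1]]])
        bounds = np.maximum.accumulate(np.clip(bounds, bounds[0], bounds[-1]))
    events: list[ScoreEvent] = []
    clock = wallclock_start_s
    label_idx = {int(p): i for i, p in enumerate(PATTERNS)}
    dropped = 0
    for sp, a, b in zip(table, bounds[:-1], bounds[1:]):
        if sp.pattern == PatternLabel.NONE:
            continue
        if b - a < 1.0 / fs:
            dropped += 1
            continue
        row = profile.confusion[label_idx[int(sp.pattern)]]
        assigned = PATTERNS[int(rng.choice(len(PATTERNS), p=row))]
        clock += max(0.1, rng.normal(profile.rate_mean, profile.rate_sd))
        events.append(
            ScoreEvent(start_s=float(a), end_s=float(b), pattern=assigned,
                       wallclock_s=clock)
        )
    if dropped:
        warnings.warn(
            f"{dropped} segment(s) collapsed below one sample under boundary "
            "jitter and were dropped",
            stacklevel=2,
        )
    return Annotation(
        events=events, record_length_s=truth.n_samples / fs
    )


# ---------------------------------------------------------------------------
# end-to-end validation experiment
# ---------------------------------------------------------------------------


@dataclass
class ExperimentConfig:
    """Configuration of a closed-loop validation experiment.

    The defaults run a desk-scale version of the monitoring protocol: a few
    synthetic host records, per-pattern QC segment insertion in an early
    and a late region, and three simulated scorers each scoring every
    record twice with independent seeds.
    """

    seed: int = 0
    n_records: int = 2
    host_duration_s: float = 1200.0
    qc_counts: dict = field(default_factory=lambda: {p: 4 for p in PATTERNS})
    qc_duration_range: tuple[float, float] = (4.5, 8.6)
    n_t: int = 50
    sample_rate: float = 50.0
    n_iterations: int = 2
    scorers: dict = field(
        default_factory=lambda: {
            "SC1": ScorerProfile(),
            "SC2": ScorerProfile(),
            "SC3": ScorerProfile(),
        }
    )
    bootstrap_resamples: int = 100

    @classmethod
    def from_dict(cls, data: dict) -> "ExperimentConfig":
        data = dict(data)
        if "qc_counts" in data:
            data["qc_counts"] = {
                PatternLabel.from_code(k) if isinstance(k, str) else PatternLabel(k): int(v)
                for k, v in data["qc_counts"].items()
            }
        if "scorers" in data:
            scorers = {}
            for name, prof in data["scorers"].items():
                if isinstance(prof, ScorerProfile):
                    scorers[name] = prof
                else:
                    scorers[name] = ScorerProfile(**prof)
            data["scorers"] = scorers
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        return cls(**data)


def _build_qc_library(
    counts: dict, duration_range, params: SynthParams, rng
) -> SegmentLibrary:
    lib = SegmentLibrary()
    uid = 0
    for pattern in PATTERNS:
        lo, hi = duration_range
        if pattern == PatternLabel.SIH:
            # a sigh needs room for one breath, the stretched sigh, and
            # one breath after it
            lo = max(lo, (2.0 + 2.2) / params.breath_rate + 0.3)
            hi = max(hi, lo + 1.0)
        for _ in range(int(counts.get(pattern, 0))):
            dur = float(rng.uniform(lo, hi))
            seg = synth_segment(
                pattern, dur, params.with_seed(int(rng.integers(0, 2**31 - 1)))
            )
            lib.add(
                LabeledSegment(
                    pattern=seg.pattern, rcg=seg.rcg, abd=seg.abd,
                    source_id=f"qc-{uid:04d}", meta=dict(seg.meta),
                )
            )
            uid += 1
    return lib


def _result_dict(res) -> dict:
    return {
        "kappa": res.kappa, "sd": res.sd, "n": res.n_samples, "band": res.band
    }


def run_validation_experiment(config: ExperimentConfig | dict | None = None,
                              ) -> dict:
    """Run the closed-loop validation pipeline and return a report.

    Synthesizes host records, inserts QC segments in two passes, simulates
    every scorer scoring each record ``n_iterations`` times with
    independent seeds, and computes accuracy, consistency, scoring rate,
    intra-/inter-scorer repeatability, and consensus-based confusion
    matrices (per scorer and pooled). The report is a JSON-serializable
    dict.
    """
    if config is None:
        cfg = ExperimentConfig()
    elif isinstance(config, ExperimentConfig):
        cfg = config
    else:
        cfg = ExperimentConfig.from_dict(config)
    rng = as_rng(cfg.seed)
    fs = cfg.sample_rate
    spec = crossfade_weights(cfg.n_t)
    params = SynthParams(sample_rate=fs)

    scorer_names = list(cfg.scorers)
    # pooled per-sample labels: labels[name][iteration] -> list of vectors
    labels: dict[str, list[list[np.ndarray]]] = {
        name: [[] for _ in range(cfg.n_iterations)] for name in scorer_names
    }
    truth_parts: list[np.ndarray] = []
    pair_parts: list[tuple[tuple[int, int], tuple[int, int]]] = []
    rates: dict[str, list[float]] = {name: [] for name in scorer_names}
    offset = 0

    for _rec in range(cfg.n_records):
        host = synth_breathing(
            cfg.host_duration_s,
            params.with_seed(int(rng.integers(0, 2**31 - 1))),
        )
        from .patterns import RipRecord

        record = RipRecord(sample_rate=fs, rcg=host.rcg, abd=host.abd)
        lib = _build_qc_library(cfg.qc_counts, cfg.qc_duration_range, params, rng)
        qc = select_qc_segments(lib, cfg.qc_counts, rng)
        grown, plan, track = insert_qc_segments(
            record, qc,
            region_1=(0.0, record.duration_s / 2.0),
            region_2=(record.duration_s / 2.0, record.duration_s),
            spec=spec, seed=rng,
        )
        truth_parts.append(track.labels)
        spans_by_id: dict[str, list[tuple[int, int]]] = {}
        for sp in track.segment_table:
            if sp.pattern != PatternLabel.NONE:
                spans_by_id.setdefault(sp.source_id, []).append(
                    (sp.start + offset, sp.end + offset)
                )
        for sid, spans in spans_by_id.items():
            if len(spans) == 2:
                pair_parts.append((spans[0], spans[1]))
        for name in scorer_names:
            profile = cfg.scorers[name]
            for it in range(cfg.n_iterations):
                ann = simulate_scorer(
                    track, profile, seed=int(rng.integers(0, 2**31 - 1))
                )
                labels[name][it].append(expand_labels(ann, fs))
                try:
                    rates[name].append(scoring_rate(ann))
                except Exception:
                    pass
        offset += track.n_samples

    truth = np.concatenate(truth_parts)
    pooled = {
        name: [np.concatenate(parts) for parts in labels[name]]
        for name in scorer_names
    }
    pairing = EvaluationPairing(pairs=pair_parts)
    nres = cfg.bootstrap_resamples

    report: dict = {"scorers": {}, "group": {}}
    all_iterations: list[np.ndarray] = []
    for name in scorer_names:
        vecs = pooled[name]
        all_iterations.extend(vecs)
        acc = accuracy_kappa(vecs[0], truth, n_resamples=nres, seed=rng)
        cons = consistency_kappa(vecs[0], pairing, n_resamples=nres, seed=rng)
        entry: dict = {
            "accuracy": _result_dict(acc),
            "consistency": _result_dict(cons),
            "scoring_rate": float(np.mean(rates[name])) if rates[name] else None,
        }
        if len(vecs) >= 2:
            overall, per_pattern = intra_scorer_kappa(
                vecs[0], vecs[1], n_resamples=nres, seed=rng
            )
            entry["intra"] = {
                "overall": _result_dict(overall),
                "per_pattern": {
                    p.name: (_result_dict(r) if r is not None else None)
                    for p, r in per_pattern.items()
                },
            }
        report["scorers"][name] = entry

    if len(scorer_names) >= 2:
        inter = inter_scorer_kappa([pooled[n] for n in scorer_names])
        report["group"]["inter"] = {
            "mean": inter.mean, "sd": inter.sd, "kappas": list(inter.kappas)
        }
    consensus = consensus_labels(all_iterations)
    if (consensus != int(PatternLabel.NONE)).any():
        group_cm = confusion_matrix(consensus, all_iterations)
        report["group"]["confusion"] = {
            "patterns": [p.name for p in PATTERNS],
            "p": np.where(np.isnan(group_cm.p), None, group_cm.p).tolist(),
            "n_consensus": group_cm.n_consensus.tolist(),
        }
        for name in scorer_names:
            cm = confusion_matrix(consensus, pooled[name])
            report["scorers"][name]["confusion"] = {
                "patterns": [p.name for p in PATTERNS],
                "p": np.where(np.isnan(cm.p), None, cm.p).tolist(),
                "n_consensus": cm.n_consensus.tolist(),
            }
    report["n_samples_truth"] = int((truth != int(PatternLabel.NONE)).sum())
    return report


def load_report(path) -> dict:
    """Read a validation-experiment report written as JSON."""
    with open(path) as fh:
        return json.load(fh)
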