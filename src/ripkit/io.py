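"""Delimited-text readers and writers for records, label tracks and plans.

Signal files are CSV with header ``time_s,rcg,abd,ppg,sat``; absent optional
channels are written as empty columns. Label tracks are run-length CSV
``start_s,end_s,pattern``; QC insertion plans are CSV
``pass,position_s,source_id,pattern,length_s``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .patterns import PatternLabel, RipRecord
from .records import QcInsertion, QcInsertionPlan
from .splice import GroundTruthTrack, SegmentSpan

__all__ = [
    "write_record",
    "read_record",
    "write_track",
    "read_track",
    "write_plan",
    "read_plan",
]


def write_record(record: RipRecord, path) -> None:
    n = record.n_samples
    empty = np.full(n, np.nan)
    df = pd.DataFrame(
        {
            "time_s": record.time(),
            "rcg": record.rcg,
            "abd": record.abd,
            "ppg": record.ppg if record.ppg is not None else empty,
            "sat": record.sat if record.sat is not None else empty,
        }
    )
    df.to_csv(path, index=False)


def read_record(path) -> RipRecord:
    df = pd.read_csv(path)
    expected = ["time_s", "rcg", "abd", "ppg", "sat"]
    if list(df.columns[:5]) != expected:
        raise ValueError(f"{path}: expected header {expected}")
    t = df["time_s"].to_numpy(dtype=float)
    if len(t) < 2:
        raise ValueError(f"{path}: need at least two samples to infer the rate")
    dt = np.diff(t)
    if np.ptp(dt) > 1e-6:
        raise ValueError(f"{path}: sample times are not uniformly spaced")
    kwargs = {}
    for opt in ("ppg", "sat"):
        col = df[opt].to_numpy(dtype=float)
        if not np.isnan(col).all():
            kwargs[opt] = col
    return RipRecord(
        sample_rate=1.0 / float(dt.mean()),
        rcg=df["rcg"].to_numpy(dtype=float),
        abd=df["abd"].to_numpy(dtype=float),
        t0=float(t[0]),
        **kwargs,
    )


def write_track(track: GroundTruthTrack, path) -> None:
    fs = track.sample_rate
    rows = [
        {
            "start_s": sp.start / fs,
            "end_s": sp.end / fs,
            "pattern": sp.pattern.name,
        }
        for sp in track.segment_table
    ]
    pd.DataFrame(rows, columns=["start_s", "end_s", "pattern"]).to_csv(
        path, index=False
    )


def read_track(path, sample_rate: float = 50.0) -> GroundTruthTrack:
    df = pd.read_csv(path)
    spans = []
    for _, row in df.iterrows():
        spans.append(
            SegmentSpan(
                start=int(round(row["start_s"] * sample_rate)),
                end=int(round(row["end_s"] * sample_rate)),
                pattern=PatternLabel.from_code(str(row["pattern"])),
            )
        )
    n = spans[-1].end if spans else 0
    labels = np.zeros(n, dtype=np.int8)
    for sp in spans:
        labels[sp.start : sp.end] = int(sp.pattern)
    return GroundTruthTrack(labels=labels, segment_table=spans,
                            sample_rate=sample_rate)


def write_plan(plan: QcInsertionPlan, path) -> None:
    rows = [
        {
            "pass": ins.pass_idx,
            "position_s": ins.position_s,
            "source_id": ins.source_id,
            "pattern": ins.pattern.name,
            "length_s": ins.length_s,
            "host_position_s": ins.host_position_s,
        }
        for ins in plan.insertions
    ]
    pd.DataFrame(
        rows,
        columns=["pass", "position_s", "source_id", "pattern", "length_s",
                 "host_position_s"],
    ).to_csv(path, index=False)


def read_plan(path) -> QcInsertionPlan:
    df = pd.read_csv(path)
    insertions = [
        QcInsertion(
            pass_idx=int(row["pass"]),
            host_position_s=float(row["host_position_s"]),
            position_s=float(row["position_s"]),
            source_id=str(row["source_id"]),
            pattern=PatternLabel.from_code(str(row["pattern"])),
            length_s=float(row["length_s"]),
        )
        for _, row in df.iterrows()
    ]
    return QcInsertionPlan(insertions=insertions)
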