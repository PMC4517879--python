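"""Build a training record, an evaluation record, and a QC-inserted record.

Training records concatenate segments of all six patterns (no two adjacent
segments share a pattern) with smooth crossfade transitions. Evaluation
records duplicate a unique segment list across two independently ordered
halves. QC insertion splices known-label segments into a long host record
twice — once early, once late — to monitor scorer performance.
"""

import numpy as np

from ripkit import (
    PATTERNS,
    RipRecord,
    SynthParams,
    build_evaluation_record,
    build_training_record,
    insert_qc_segments,
    select_qc_segments,
    synth_breathing,
)
from ripkit.simulate import _build_qc_library

# scaled durations keep the example quick; the construction is scale-free
record, track = build_training_record(seed=1, accumulate_s=900, target_s=600)
print(f"training record: {record.duration_s:.0f} s, "
      f"{len(track.segment_table)} segments, "
      f"patterns: {sorted(p.name for p in track.patterns_present())}")

record, track, pairing = build_evaluation_record(seed=2, half_s=300)
print(f"evaluation record: {record.duration_s:.0f} s, "
      f"{len(pairing)} unique segments, each appearing in both halves")

rng = np.random.default_rng(3)
host_seg = synth_breathing(1200.0, SynthParams(seed=4))
host = RipRecord(sample_rate=50.0, rcg=host_seg.rcg, abd=host_seg.abd)
counts = {p: 4 for p in PATTERNS}
library = _build_qc_library(counts, (4.5, 8.6), SynthParams(), rng)
qc = select_qc_segments(library, counts, seed=rng)
grown, plan, qc_track = insert_qc_segments(
    host, qc, region_1=(0, 600), region_2=(600, 1200), seed=rng
)
print(f"QC insertion: host {host.duration_s:.0f} s grew to "
      f"{grown.duration_s:.0f} s with {len(plan.insertions)} insertions "
      f"({len(plan.by_pass(1))} per pass)")
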