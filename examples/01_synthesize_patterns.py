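"""Generate each of the six RIP patterns and verify its scoring rule.

Each generator is paired with an independent measurement oracle: the phase
at the dominant respiratory frequency for synchronous/asynchronous
breathing, breath amplitude/duration ratios for sighs, peak-to-trough
excursion for pauses, and spectral/autocorrelation tests for movement
artifact and unknown patterns.
"""

import numpy as np

from ripkit import (
    PATTERNS,
    SynthParams,
    low_frequency_power_ratio,
    measure_breaths,
    measure_phase,
    synth_breathing,
    synth_pause_segment,
    synth_segment,
    synth_sigh_segment,
)

FS = 50.0
params = SynthParams(sample_rate=FS, seed=1)

print("pattern  check")
for pattern in PATTERNS:
    seg = synth_segment(pattern, 30.0, params)
    print(f"{seg.pattern.name}: {seg.length_samples} samples")

syb = synth_breathing(30.0, SynthParams(phase_deg=30.0, seed=2))
asb = synth_breathing(30.0, SynthParams(phase_deg=140.0, seed=2))
print(f"\nSYB phase: {measure_phase(syb.rcg, syb.abd, FS):.1f} deg (<90)")
print(f"ASB phase: {measure_phase(asb.rcg, asb.abd, FS):.1f} deg (>=90)")

sih = synth_sigh_segment(30.0, SynthParams(seed=3))
breaths = measure_breaths(sih.rcg, FS)
amps = np.array([b.amplitude for b in breaths])
j = int(np.argmax(amps))
print(f"sigh amplitude ratio: {amps[j] / np.delete(amps, j).mean():.2f} (>=2)")

pau = synth_pause_segment(30.0, 4.0, SynthParams(seed=4))
s, e = pau.meta["pause_window"]
normal = np.mean([b.amplitude for b in measure_breaths(pau.rcg[:s], FS)[-3:]])
print(f"pause excursion ratio: {np.ptp(pau.rcg[s:e]) / normal:.3f} (<0.10)")

mvt = synth_segment(PATTERNS[4], 30.0, params)
print(f"movement low-frequency power ratio: "
      f"{low_frequency_power_ratio(mvt.rcg, FS):.0f} (>1)")
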