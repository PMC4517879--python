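# ripkit

Synthesis and scorer-evaluation statistics for infant respiratory
inductive plethysmography (RIP) records.

## The problem

Automated cardiorespiratory analysis of infants — for example, detecting
postoperative apnea in infants recovering from anesthesia — needs manually
scored reference data. Human scorers segment two-channel RIP recordings
(ribcage **RCG** and abdomen **ABD**, sampled at 50 Hz) and assign each
sample one of six mutually exclusive patterns:

| Code | Pattern | Scoring rule |
|------|---------|--------------|
| SYB | synchronous breathing | quasi-sinusoidal, RCG–ABD phase < 90° |
| ASB | asynchronous breathing | quasi-sinusoidal, phase ≥ 90° |
| SIH | sigh | one breath with ≥ 2× the amplitude **and** duration of the epoch's average breath, in both channels |
| PAU | respiratory pause | both channels' excursion < 10% of the preceding normal breath, scored regardless of duration |
| MVT | movement artifact | chaotic, non-sinusoidal, low-frequency motion in both channels |
| UNK | unknown | technical faults or discordant channels |

Manual scoring is only useful if scorers are trained, evaluated, and
continuously monitored. `ripkit` implements the computational machinery for
that workflow:

- **Pattern synthesis** (`ripkit.synth`): parameterized generators for all
  six patterns plus independent measurement oracles (cross-spectral phase,
  breath amplitude/duration detection, spectral and autocorrelation tests)
  that verify each generated segment satisfies its scoring rule.
- **Crossfade concatenation** (`ripkit.splice`): segments are joined over a
  transition window of `n_t` samples by complementary sigmoid weights, so
  records are continuous (no artificial transients) and carry an exact
  per-sample ground-truth track.
- **Record builders** (`ripkit.records`): 1-hour training records (all six
  patterns, no two adjacent segments alike), duplicated-half evaluation
  records (every unique segment appears once per half, enabling a
  *consistency* measure), and quality-control insertion (152 known-label
  segments spliced twice into long host records — once in the first 3 h,
  once re-ordered into the last 3 h).
- **Scoring model** (`ripkit.scoring`): timestamped annotations, per-sample
  label expansion, and scoring rates with the 2-minute interruption rule.
- **Agreement statistics** (`ripkit.agreement`): sample-wise Fleiss' kappa

  κ = (P̄ − P̄ₑ) / (1 − P̄ₑ),

  where P̄ is the mean per-sample agreement across raters and P̄ₑ the chance
  agreement from pooled category proportions; accuracy, consistency,
  intra-/inter-scorer repeatability, bootstrap SDs (100 resamples), and
  interpretation bands (poor/slight/fair/moderate/substantial/almost
  perfect).
- **Confusion analysis** (`ripkit.confusion`): absolute-majority consensus
  labels (≥ 4 of 6 iterations) and conditional-probability confusion
  matrices P(scored *j* | consensus *i*), with segment-length sensitivity.
- **Scorer simulation** (`ripkit.simulate`): configurable confusion
  channels, boundary jitter and wall-clock models, closing the loop on
  every statistic without human input.

## Worked example

```python
import numpy as np
from ripkit import (SynthParams, build_evaluation_record, simulate_scorer,
                    ScorerProfile, expand_labels, accuracy_kappa,
                    consistency_kappa)

record, truth, pairing = build_evaluation_record(seed=2, half_s=300)
profile = ScorerProfile()          # identity confusion, no jitter
ann = simulate_scorer(truth, profile, seed=5)
labels = expand_labels(ann, record.sample_rate)
acc = accuracy_kappa(labels, truth.labels, seed=0)
cons = consistency_kappa(labels, pairing, seed=0)
print(acc.kappa, acc.band, cons.kappa)
```

prints

```
1.0 almost perfect 1.0
```

— a perfect simulated scorer agrees with the ground truth on every sample
(accuracy κ = 1) and labels the two copies of every segment identically
(consistency κ = 1). Realistic profiles (see
`examples/04_validation_experiment.py`) degrade these numbers in
interpretable ways: a scorer who confuses PAU with UNK 30% of the time
drops to accuracy κ ≈ 0.94 with the PAU row of the group confusion matrix
splitting ≈ 0.9/0.1 between PAU and UNK.

The `examples/` directory holds one short narrative script per capability;
each builds its own input, runs the method and prints what the numbers
mean. A thin CLI mirrors the main operations
(`ripkit synth|train-record|eval-record|qc-insert|rate|agree|confusion|validate`).

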