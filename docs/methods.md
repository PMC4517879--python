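# Methods

This note documents the models, conventions and numerical choices behind
`ripkit`, and what its synthetic data does and does not emulate.

## Breathing model

Breathing is generated breath by breath. Breath *i* draws a period
*T<sub>i</sub>* and peak amplitude *A<sub>i</sub>* from mean-preserving
log-normal distributions around the nominal rate and amplitude, and is
rendered as one sinusoidal cycle *A<sub>i</sub>* sin(2π*u* − φ), with *u*
the within-breath fraction and φ the channel's phase offset. Anchoring the
cycle at the rising zero crossing (the inspiration onset) keeps the signal
continuous when amplitude changes between breaths — important for sighs
and pauses. The abdomen channel shares the ribcage's breath grid and is
offset by the configured phase; the folded phase magnitude (< 90° or
≥ 90°) decides the SYB/ASB label, with the 90° boundary assigned to ASB.

Defaults: 50 Hz sampling; breathing at 0.8 Hz (48 breaths/min, typical for
term infants); amplitude 1 a.u.; breath-to-breath coefficients of
variation 0.10 (amplitude) and 0.05 (period); additive white Gaussian
noise with SD 0.01 a.u. The noise default keeps the noise excursion well
below the 10% threshold of the pause rule; real RIP signals additionally
carry baseline drift and cardiogenic oscillations that this model omits.

Derived patterns:

- **Sigh**: one mid-segment breath is set to `sigh_gain` (default 2.2)
  times the *mean* of the other breaths in period and amplitude — tying
  the sigh to the mean rather than to its own jittered draw guarantees the
  ≥ 2× rule holds under breath-to-breath variability.
- **Pause**: residual breathing scaled by `pause_gain` (default 0.05)
  exactly tiles a window of the requested length; the window starts and
  ends at inspiration onsets, and its half-open sample span is reported in
  the segment metadata. Breath amplitude is peak-to-trough excursion,
  breath duration inspiration-onset to inspiration-onset.
- **Movement artifact**: an independent low-pass-filtered random walk per
  channel (4th-order Butterworth, cutoff 0.4 Hz, zero-phase) scaled to the
  RMS of nominal breathing — irregular low-frequency motion with no
  dominant periodicity.
- **Unknown**: discordant channels (movement on RCG, breathing on ABD) or
  a flat-line technical-fault motif with optional step artifacts.

The measurement oracles are independent of the generators: phase is the
cross-spectrum angle at the ribcage periodogram peak within 0.1–3 Hz
(raising an error when no ±1-bin neighbourhood holds ≥ 20% of band
power); breaths are detected at rising zero crossings of the low-passed,
mean-removed signal with ±30%-amplitude hysteresis; movement is verified
by a low-frequency/breathing-band power ratio and an autocorrelation
periodicity test (a ≥ 0.4 peak in the 0.3–3 s lag range *after* a dip
below 0.2).

## Concatenation

Two segments are joined over a transition window of `n_t` samples
(default 1 s, i.e. 50 samples — shorter than any scoreable segment): the
outgoing tail is weighted by a falling sigmoid, the incoming head by the
complementary rising sigmoid, and the two are summed. The ramp is a
half-period raised cosine, 0.5 − 0.5 cos(πk/(n_t−1)); it is sigmoid-shaped
and hits 0 and 1 *exactly* at the window edges, so inputs are reproduced
bit-exactly outside the window and the output length is
Σ lengths − (k−1)·n_t. A rescaled logistic ramp is available via
`crossfade_weights(n_t, shape="logistic")`. A one-sample window cannot
satisfy both endpoint constraints and uses the single weight 0.5.

Ground-truth labels inside a transition window are split at the window
midpoint — first half to the preceding segment, second half to the
following one. The boundary convention is symmetric; only segment
boundaries are stored, so some convention is required. Sample indexing is
0-based and all spans are half-open.

## Record construction

- **Training records**: segments of every pattern are accumulated
  round-robin (durations U(15, 45) s) past 1.5 h, randomly permuted,
  repaired by the push-to-end rule (a segment whose pattern matches its
  predecessor moves to the list tail; bounded to 3 passes since the rule
  can cycle, then a greedy re-insertion finishes the job, with a warning
  when no conflict-free ordering exists), and truncated to the shortest
  prefix whose *concatenated* length reaches 1 h — so the record is
  guaranteed at least the target duration and at most one segment longer.
  The permutation is redrawn (bounded) if truncation dropped a category.
- **Evaluation records**: a unique list totalling 30 min is built the same
  way, duplicated, and each copy independently ordered (re-drawn if the
  two orders collide); the halves are joined. The pairing aligns the two
  copies of each segment over their *core* content spans (trimmed by one
  transition window per side), which are bit-identical, so consistency can
  be computed positionally.
- **QC insertion**: the per-pattern selection (default 25/26/27/22/27/25 =
  152 segments, ≈ 1000 s with the default 4.5–8.6 s QC durations) is drawn
  uniformly without replacement, randomly ordered, and inserted at
  uniformly drawn split points in the first-3-h region; a second,
  independently re-ordered pass goes into the last-3-h region. Each
  insertion splits the host and splices with two transition windows
  (growth = length − 2·n_t per insertion). Split points keep a minimum
  spacing of 2·n_t + 1 samples (configurable upward) so every inserted
  span is attributable to exactly one truth label; positions are drawn by
  the ordered-uniform-plus-gap construction, which is uniform over
  admissible spaced sets.
- **Training termination**: the session ends once every pattern has
  accumulated 5 correct scores in the current unbroken run of correct
  answers; any error resets *all* per-pattern counters (the strict reading
  of "consecutively").

## Scoring and agreement

A score event's wall-clock cost is the difference from the previous
event's timestamp; the first event has no cost. Differences above 2 min
are treated as interruptions and excluded (a gap of exactly 120 s is
kept). The overall rate is data-hours per scoring-hour; pattern-specific
rates attribute each event's cost by the same previous-diff rule — how the
first event of a pattern burst should be attributed is genuinely open, and
the previous-diff rule is the package's choice.

Fleiss' kappa is computed sample-wise from the category-count matrix.
Degenerate input (one category everywhere) has chance agreement 1 and is
returned as κ = 1. Samples labeled NONE by any party to a comparison are
excluded from that comparison. Per-pattern repeatability uses one-vs-rest
binarization followed by the two-category kappa — a standard construction,
but one of several possible ones, so it is flagged here. Inter-scorer
repeatability enumerates the Cartesian product of one iteration per scorer
(8 combinations for 3 scorers × 2 iterations) and reports mean ± sample
SD. Bootstrap SDs resample sample rows with replacement (100 resamples by
default); the resampling unit is the sample, which understates SDs under
the strong serial correlation of per-sample labels — the SDs are
comparative, not inferential.

Consensus labels require an absolute majority (floor(m/2)+1, i.e. 4 of 6
iterations); NONE votes never form a consensus. Confusion rows count each
evaluated iteration's assignments over that row's consensus samples
(per-scorer matrices count that scorer's iterations; the group matrix
pools all); sample-iteration pairs left unscored are dropped from the
row, so defined rows always sum to 1. Whether consensus should include or
exclude the scorer under evaluation is ambiguous; both are possible by
passing different iteration sets to `consensus_labels` and
`confusion_matrix`.

## Simulated scorers

Boundary jitter is applied jointly to the segment-boundary list before
label assignment (abutting segments stay abutting; a collapsed segment is
dropped with a warning), modeling edge placement separately from category
confusion, which is drawn once per segment from the profile's confusion
row. Because labels are drawn per segment, recovery checks compute
binomial standard errors on segment draws, not raw samples. On isolated
QC spans, jitter mostly moves samples out of the NONE-excluded comparison
rather than mislabeling them; its degrading effect appears on contiguous
records.

## Problem sizes and limitations

The test suite and the acceptance script run the full-size protocol where
it is cheap (the 152-segment QC scheme over a 6.5 h host, 30-minute
evaluation halves, 10⁵-sample chance and recovery checks) and scaled-down
records (minutes instead of hours) where only the construction rule — not
its scale — is under test; the construction is scale-free.

Synthetic records emulate the *structure* real scoring infrastructure
needs (patterns obeying the scoring rules, smooth transitions, exact
ground truth) but not the variability of real infant data: no baseline
drift, no cardiogenic oscillations, no behavioral-state changes, no
gradual pattern transitions, and simulated scorers have no fatigue or
learning dynamics. Passing tests therefore validate the scoring *toolset*
— generators, record builders and statistics — not any claim about human
scorer performance on clinical recordings.
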