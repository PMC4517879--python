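"""Synthetic generators for the six RIP patterns, with measurement oracles.

Breathing is modeled breath-by-breath: each breath ``i`` draws a period
``T_i`` and a peak amplitude ``A_i`` from log-normal distributions around the
nominal rate and amplitude (coefficients of variation ``rate_cv`` and
``amplitude_cv``), and is rendered as one cycle of ``A_i * sin(2*pi*u)`` with
``u`` the within-breath fraction. The breath boundary (``u = 0``, rising zero
crossing) is the inspiration onset; a phase offset applied to the abdomen
channel shifts its cycle relative to the ribcage, producing thoraco-abdominal
asynchrony when the offset reaches 90° or more. Additive white Gaussian noise
models sensor noise.

Movement artifact is a low-pass-filtered random walk (default cutoff 0.4 Hz)
scaled to breathing-comparable amplitude — irregular, non-sinusoidal,
low-frequency motion with no dominant periodicity.

The measurement oracles (:func:`measure_phase`, :func:`measure_breaths`,
:func:`low_frequency_power_ratio`, :func:`is_quasi_periodic`) are independent
of the generators: they analyze the rendered samples and are used to verify
that every generated segment satisfies its scoring rule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import NamedTuple

import numpy as np
from scipy import signal as sps

from .patterns import LabeledSegment, PatternLabel

__all__ = [
    "SynthParams",
    "AperiodicSignalError",
    "Breath",
    "synth_breathing",
    "synth_sigh_segment",
    "synth_pause_segment",
    "synth_mvt_segment",
    "synth_unk_segment",
    "synth_segment",
    "decorate_record",
    "measure_phase",
    "measure_breaths",
    "low_frequency_power_ratio",
    "is_quasi_periodic",
]


class AperiodicSignalError(ValueError):
    """Raised when a phase measurement is requested on signals with no
    dominant periodicity in the breathing band."""


@dataclass(frozen=True)
class SynthParams:
    """Parameters of the quasi-sinusoidal breathing generator.

    Attributes
    ----------
    sample_rate : float
        Output sampling rate in Hz.
    breath_rate : float
        Nominal breathing frequency in Hz. The default 0.8 Hz (48
        breaths/min) sits in the typical range for term infants.
    breath_amplitude : float
        Nominal breath peak amplitude in arbitrary units; peak-to-trough
        excursion is twice this.
    phase_deg : float
        RCG-ABD phase offset in degrees, in [0, 360).
    amplitude_cv, rate_cv : float
        Breath-to-breath log-normal coefficients of variation for amplitude
        and period.
    noise_sd : float
        Standard deviation of additive white Gaussian sensor noise (a.u.).
        The default, 1% of the nominal breath amplitude, keeps the noise
        excursion well under the 10% threshold of the pause scoring rule.
    seed : int or None
        Seed for the generator; identical parameters and seed give
        bit-identical output.
    """

    sample_rate: float = 50.0
    breath_rate: float = 0.8
    breath_amplitude: float = 1.0
    phase_deg: float = 0.0
    amplitude_cv: float = 0.10
    rate_cv: float = 0.05
    noise_sd: float = 0.01
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.breath_rate <= 0:
            raise ValueError("breath_rate must be positive")
        if not (0.0 <= self.phase_deg < 360.0):
            raise ValueError("phase_deg must lie in [0, 360)")
        if self.amplitude_cv < 0 or self.rate_cv < 0:
            raise ValueError("coefficients of variation must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    def with_seed(self, seed: int | None) -> "SynthParams":
        return replace(self, seed=seed)

    def folded_phase_deg(self) -> float:
        """Phase magnitude folded to [0, 180]°."""
        phi = self.phase_deg % 360.0
        return min(phi, 360.0 - phi)


class Breath(NamedTuple):
    """One detected breath: peak-to-trough amplitude (a.u.) and
    inspiration-onset-to-inspiration-onset duration (s)."""

    amplitude: float
    duration: float


# ---------------------------------------------------------------------------
# breath-train rendering
# ---------------------------------------------------------------------------


def _lognormal_sigma(cv: float) -> float:
    return math.sqrt(math.log1p(cv * cv))


def _draw_breaths(
    duration_s: float, params: SynthParams, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Draw per-breath (periods, amplitudes) covering at least duration_s."""
    mean_t = 1.0 / params.breath_rate
    n_guess = int(math.ceil(duration_s / mean_t)) + 8
    periods = np.empty(0)
    amps = np.empty(0)
    sig_t = _lognormal_sigma(params.rate_cv)
    sig_a = _lognormal_sigma(params.amplitude_cv)
    while periods.sum() < duration_s:
        # mean-preserving log-normal jitter
        t_new = mean_t * np.exp(sig_t * rng.standard_normal(n_guess) - 0.5 * sig_t**2)
        a_new = params.breath_amplitude * np.exp(
            sig_a * rng.standard_normal(n_guess) - 0.5 * sig_a**2
        )
        periods = np.concatenate([periods, t_new])
        amps = np.concatenate([amps, a_new])
    k = int(np.searchsorted(np.cumsum(periods), duration_s)) + 1
    return periods[:k], amps[:k]


def _render(
    periods: np.ndarray,
    amps: np.ndarray,
    sample_rate: float,
    n_samples: int,
    phase_rad: float = 0.0,
) -> np.ndarray:
    """Render a breath train as one sinusoidal cycle per breath.

    The waveform within breath ``i`` is ``A_i * sin(2*pi*u - phase_rad)``;
    with zero phase it starts at the rising zero crossing (inspiration
    onset), so amplitude changes between breaths keep the signal continuous.
    """
    edges = np.concatenate([[0.0], np.cumsum(periods)])
    t = np.arange(n_samples) / sample_rate
    idx = np.clip(np.searchsorted(edges, t, side="right") - 1, 0, len(periods) - 1)
    u = (t - edges[idx]) / periods[idx]
    return amps[idx] * np.sin(2.0 * np.pi * u - phase_rad)


def _noise(n: int, sd: float, rng: np.random.Generator) -> np.ndarray:
    return rng.normal(0.0, sd, n) if sd > 0 else np.zeros(n)


def _check_breathing_duration(duration_s: float, params: SynthParams) -> None:
    if duration_s < 2.0 / params.breath_rate:
        raise ValueError(
            f"duration {duration_s} s is too short for 2 breath cycles at "
            f"{params.breath_rate} Hz"
        )


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------


def synth_breathing(duration_s: float, params: SynthParams) -> LabeledSegment:
    """Generate quasi-sinusoidal breathing on both channels.

    The label is SYB when the folded RCG-ABD phase is below 90° and ASB at
    90° or more.
    """
    _check_breathing_duration(duration_s, params)
    rng = np.random.default_rng(params.seed)
    periods, amps = _draw_breaths(duration_s, params, rng)
    n = int(round(duration_s * params.sample_rate))
    phase_rad = math.radians(params.phase_deg)
    rcg = _render(periods, amps, params.sample_rate, n)
    abd = _render(periods, amps, params.sample_rate, n, phase_rad)
    rcg += _noise(n, params.noise_sd, rng)
    abd += _noise(n, params.noise_sd, rng)
    label = (
        PatternLabel.SYB if params.folded_phase_deg() < 90.0 else PatternLabel.ASB
    )
    return LabeledSegment(
        pattern=label, rcg=rcg, abd=abd,
        meta={"phase_deg": params.folded_phase_deg()},
    )


def synth_sigh_segment(
    duration_s: float, params: SynthParams, sigh_gain: float = 2.2
) -> LabeledSegment:
    """Embed a single sigh — one breath with ``sigh_gain`` times the
    amplitude and duration of its neighbours — in baseline breathing.

    ``sigh_gain`` must be >= 2 so the segment satisfies the sigh scoring
    rule (amplitude and duration at least twice the epoch's average breath
    in both channels).
    """
    if sigh_gain < 1.0:
        raise ValueError("sigh_gain must be >= 1")
    # room for one breath before, the stretched sigh, and one breath after
    min_dur = (2.0 + sigh_gain) / params.breath_rate
    if duration_s < min_dur:
        raise ValueError(
            f"duration {duration_s} s is too short to embed a sigh "
            f"(need >= {min_dur:.1f} s at {params.breath_rate} Hz)"
        )
    rng = np.random.default_rng(params.seed)
    periods, amps = _draw_breaths(duration_s, params, rng)
    # the breath nearest the midpoint whose stretched copy still fits
    onsets = np.concatenate([[0.0], np.cumsum(periods)[:-1]])
    fits = np.flatnonzero(
        (onsets + sigh_gain * periods <= duration_s) & (onsets > 0.0)
    )
    if len(fits) == 0:
        raise ValueError("duration too short to embed a sigh between breaths")
    j = int(fits[np.argmin(np.abs(onsets[fits] - duration_s / 2.0))])
    j = min(j, len(periods) - 2)
    periods = periods.copy()
    amps = amps.copy()
    # the sigh is gain x the surrounding *mean* breath, so the ratio holds
    # regardless of the jitter drawn for breath j itself
    periods[j] = sigh_gain * float(np.delete(periods, j).mean())
    amps[j] = sigh_gain * float(np.delete(amps, j).mean())
    n = int(round(duration_s * params.sample_rate))
    phase_rad = math.radians(params.phase_deg)
    rcg = _render(periods, amps, params.sample_rate, n)
    abd = _render(periods, amps, params.sample_rate, n, phase_rad)
    rcg += _noise(n, params.noise_sd, rng)
    abd += _noise(n, params.noise_sd, rng)
    sigh_start = float(onsets[j])
    return LabeledSegment(
        pattern=PatternLabel.SIH, rcg=rcg, abd=abd,
        meta={"sigh_breath": j, "sigh_onset_s": sigh_start,
              "sigh_gain": sigh_gain},
    )


def synth_pause_segment(
    duration_s: float,
    pause_s: float,
    params: SynthParams,
    pause_gain: float = 0.05,
) -> LabeledSegment:
    """Breathing interrupted by a respiratory pause of length ``pause_s``.

    During the pause both channels carry residual motion scaled by
    ``pause_gain`` (< 0.1 satisfies the pause rule: excursion below 10% of
    the preceding normal breath). The pause starts and ends at an
    inspiration onset. ``meta["pause_window"]`` holds the half-open sample
    window of the pause.
    """
    _check_breathing_duration(duration_s, params)
    if not (0.0 < pause_s < duration_s - 2.0 / params.breath_rate):
        raise ValueError(
            "pause_s must satisfy 0 < pause_s < duration_s - 2 breath periods"
        )
    if not (0.0 <= pause_gain < 1.0):
        raise ValueError("pause_gain must lie in [0, 1)")
    rng = np.random.default_rng(params.seed)
    pre_target = (duration_s - pause_s) / 2.0
    pre_t, pre_a = _draw_breaths(max(pre_target, 1.25 / params.breath_rate),
                                 params, rng)
    # residual breaths exactly tiling the pause window
    n_pause_breaths = max(1, int(round(pause_s * params.breath_rate)))
    pau_t = np.full(n_pause_breaths, pause_s / n_pause_breaths)
    pau_a = np.full(n_pause_breaths, pause_gain * params.breath_amplitude)
    post_needed = duration_s - pre_t.sum() - pause_s
    post_t, post_a = _draw_breaths(max(post_needed, 1.25 / params.breath_rate),
                                   params, rng)
    periods = np.concatenate([pre_t, pau_t, post_t])
    amps = np.concatenate([pre_a, pau_a, post_a])
    n = int(round(duration_s * params.sample_rate))
    phase_rad = math.radians(params.phase_deg)
    rcg = _render(periods, amps, params.sample_rate, n)
    abd = _render(periods, amps, params.sample_rate, n, phase_rad)
    rcg += _noise(n, params.noise_sd, rng)
    abd += _noise(n, params.noise_sd, rng)
    start = int(round(pre_t.sum() * params.sample_rate))
    n_pause = int(round(pause_s * params.sample_rate))
    return LabeledSegment(
        pattern=PatternLabel.PAU, rcg=rcg, abd=abd,
        meta={"pause_window": (start, min(start + n_pause, n)),
              "pause_gain": pause_gain},
    )


def _mvt_channel(
    n: int,
    params: SynthParams,
    rng: np.random.Generator,
    cutoff_hz: float,
) -> np.ndarray:
    walk = np.cumsum(rng.standard_normal(n))
    sos = sps.butter(4, cutoff_hz / (params.sample_rate / 2.0), output="sos")
    y = sps.sosfiltfilt(sos, walk)
    y = y - y.mean()
    rms = float(np.sqrt(np.mean(y**2)))
    if rms > 0:
        # match the RMS of nominal breathing (A/sqrt(2))
        y *= (params.breath_amplitude / math.sqrt(2.0)) / rms
    return y


def synth_mvt_segment(
    duration_s: float, params: SynthParams, cutoff_hz: float = 0.4
) -> LabeledSegment:
    """Movement artifact: both channels are independent low-pass-filtered
    random walks (chaotic, non-sinusoidal, low-frequency motion)."""
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    rng = np.random.default_rng(params.seed)
    n = int(round(duration_s * params.sample_rate))
    n = max(n, 32)  # keep the zero-phase filter well-posed on tiny segments
    rcg = _mvt_channel(n, params, rng, cutoff_hz) + _noise(n, params.noise_sd, rng)
    abd = _mvt_channel(n, params, rng, cutoff_hz) + _noise(n, params.noise_sd, rng)
    return LabeledSegment(pattern=PatternLabel.MVT, rcg=rcg, abd=abd)


def synth_unk_segment(
    duration_s: float,
    params: SynthParams,
    mode: str = "discordant",
    n_steps: int = 0,
) -> LabeledSegment:
    """Unknown pattern: discordant channels or a technical-fault motif.

    ``mode="discordant"`` gives movement artifact on RCG and quasi-sinusoidal
    breathing on ABD (different patterns per channel). ``mode="flatline"``
    gives a flat RCG — optionally with ``n_steps`` abrupt baseline jumps,
    emulating a loose connector — over breathing on ABD.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    if mode not in ("discordant", "flatline"):
        raise ValueError(f"unknown UNK mode: {mode!r}")
    rng = np.random.default_rng(params.seed)
    n = int(round(duration_s * params.sample_rate))
    n = max(n, 32)
    breathing_params = replace(params, phase_deg=0.0)
    periods, amps = _draw_breaths(duration_s, breathing_params, rng)
    abd = _render(periods, amps, params.sample_rate, n) + _noise(
        n, params.noise_sd, rng
    )
    if mode == "discordant":
        rcg = _mvt_channel(n, params, rng, 0.4) + _noise(n, params.noise_sd, rng)
    else:
        rcg = np.zeros(n)
        for _ in range(n_steps):
            at = rng.integers(1, n)
            rcg[at:] += rng.uniform(0.5, 1.5) * params.breath_amplitude * (
                1 if rng.random() < 0.5 else -1
            )
        rcg += _noise(n, params.noise_sd, rng)
    return LabeledSegment(
        pattern=PatternLabel.UNK, rcg=rcg, abd=abd, meta={"mode": mode}
    )


def synth_segment(
    pattern: PatternLabel, duration_s: float, params: SynthParams
) -> LabeledSegment:
    """Dispatch to the generator for ``pattern`` with its default settings.

    SYB/ASB are produced by forcing the phase to a representative value
    (20° and 140°) unless ``params.phase_deg`` already falls on the correct
    side of the 90° boundary.
    """
    pattern = PatternLabel(pattern)
    if pattern == PatternLabel.SYB:
        p = params if params.folded_phase_deg() < 90.0 else replace(
            params, phase_deg=20.0
        )
        return synth_breathing(duration_s, p)
    if pattern == PatternLabel.ASB:
        p = params if params.folded_phase_deg() >= 90.0 else replace(
            params, phase_deg=140.0
        )
        return synth_breathing(duration_s, p)
    if pattern == PatternLabel.SIH:
        return synth_sigh_segment(duration_s, params)
    if pattern == PatternLabel.PAU:
        pause = min(4.0, 0.4 * duration_s)
        return synth_pause_segment(duration_s, pause, params)
    if pattern == PatternLabel.MVT:
        return synth_mvt_segment(duration_s, params)
    if pattern == PatternLabel.UNK:
        return synth_unk_segment(duration_s, params)
    raise ValueError(f"cannot synthesize pattern {pattern}")


def decorate_record(
    record,
    heart_rate_hz: float = 2.2,
    sat_percent: float = 97.0,
    noise_sd: float = 0.01,
    seed: int | None = None,
):
    """Return a copy of a record with decorative PPG and SAT channels.

    The photoplethysmogram is a sinusoid at the cardiac rate (default
    2.2 Hz, ~130 bpm) and the saturation channel a constant; neither plays
    any role in pattern scoring — they only complete the display layout of
    a multi-channel record.
    """
    from .patterns import RipRecord

    rng = np.random.default_rng(seed)
    n = record.n_samples
    t = np.arange(n) / record.sample_rate
    ppg = np.sin(2.0 * np.pi * heart_rate_hz * t) + _noise(n, noise_sd, rng)
    sat = np.full(n, float(sat_percent))
    return RipRecord(
        sample_rate=record.sample_rate, rcg=record.rcg.copy(),
        abd=record.abd.copy(), ppg=ppg, sat=sat, t0=record.t0,
    )


# ---------------------------------------------------------------------------
# measurement oracles
# ---------------------------------------------------------------------------


def measure_phase(rcg, abd, sample_rate: float) -> float:
    """RCG-ABD phase magnitude (degrees, folded to [0, 180]) at the dominant
    respiratory frequency.

    The dominant frequency is the RCG periodogram peak in the 0.1-3 Hz
    breathing band; the phase is the angle of the cross-spectrum at that
    bin. Raises :class:`AperiodicSignalError` when no single frequency
    dominates the band (e.g. movement artifact or noise).
    """
    x = np.asarray(rcg, dtype=float)
    y = np.asarray(abd, dtype=float)
    if len(x) != len(y):
        raise ValueError("rcg and abd must have equal length")
    n = len(x)
    if n < 8:
        raise ValueError("signals too short for phase estimation")
    x = sps.detrend(x)
    y = sps.detrend(y)
    win = np.hanning(n)
    fx = np.fft.rfft(x * win)
    fy = np.fft.rfft(y * win)
    freqs = np.fft.rfftfreq(n, 1.0 / sample_rate)
    band = (freqs >= 0.1) & (freqs <= 3.0)
    if not band.any():
        raise AperiodicSignalError("no spectral support in the breathing band")
    px = np.abs(fx) ** 2
    band_idx = np.flatnonzero(band)
    k_rel = int(np.argmax(px[band_idx]))
    k = band_idx[k_rel]
    # dominance: the peak (±1 bin) must hold a substantial share of band power
    lo = max(k_rel - 1, 0)
    frac = px[band_idx][lo : k_rel + 2].sum() / max(px[band_idx].sum(), 1e-300)
    if frac < 0.2:
        raise AperiodicSignalError(
            "no dominant periodicity in the breathing band"
        )
    ang = np.angle(fx[k] * np.conj(fy[k]))
    return float(abs(math.degrees(ang)))


def measure_breaths(sig, sample_rate: float) -> list[Breath]:
    """Detect breaths and return (peak-to-trough amplitude, duration) pairs.

    Inspiration onsets are taken at the rising zero crossings of the
    low-pass-smoothed, mean-removed signal (with amplitude hysteresis to
    reject noise crossings); the duration of breath *i* is onset-to-onset,
    its amplitude the peak-to-trough excursion between the onsets. A flat
    or onset-free signal yields an empty list.
    """
    x = np.asarray(sig, dtype=float)
    if x.ndim != 1:
        raise ValueError("signal must be one-dimensional")
    if len(x) < 16:
        return []
    cutoff = min(2.5, 0.45 * sample_rate)
    sos = sps.butter(3, cutoff / (sample_rate / 2.0), output="sos")
    xs = sps.sosfiltfilt(sos, x)
    xs = xs - xs.mean()
    amp = (np.percentile(xs, 95) - np.percentile(xs, 5)) / 2.0
    if amp <= 1e-12:
        return []
    cross = np.flatnonzero((xs[:-1] < 0.0) & (xs[1:] >= 0.0)) + 1
    if len(cross) < 2:
        return []
    # hysteresis: between kept onsets the signal must swing past +/-30% amp
    onsets = [int(cross[0])]
    for c in cross[1:]:
        seg = xs[onsets[-1] : c]
        if seg.max() >= 0.3 * amp and seg.min() <= -0.3 * amp:
            onsets.append(int(c))
    if len(onsets) < 2:
        return []
    breaths = []
    for a, b in zip(onsets[:-1], onsets[1:]):
        chunk = xs[a:b]
        breaths.append(
            Breath(
                amplitude=float(chunk.max() - chunk.min()),
                duration=float((b - a) / sample_rate),
            )
        )
    return breaths


def low_frequency_power_ratio(
    sig,
    sample_rate: float,
    split_hz: float = 0.4,
    breath_rate: float = 0.8,
    half_band_hz: float = 0.15,
) -> float:
    """Ratio of spectral power below ``split_hz`` to power in a band around
    the nominal breathing frequency. Movement artifact gives a ratio well
    above 1; quasi-sinusoidal breathing well below 1."""
    x = sps.detrend(np.asarray(sig, dtype=float))
    freqs, p = sps.periodogram(x, fs=sample_rate)
    low = p[freqs < split_hz].sum()
    breath_band = (freqs >= breath_rate - half_band_hz) & (
        freqs <= breath_rate + half_band_hz
    )
    breath = p[breath_band].sum()
    return float(low / max(breath, 1e-300))


def is_quasi_periodic(
    sig,
    sample_rate: float,
    min_period_s: float = 0.3,
    max_period_s: float = 3.0,
) -> bool:
    """Autocorrelation periodicity test in the plausible breath-period range.

    Returns True when the autocorrelation shows a local maximum of at least
    0.4 at some lag in [min_period_s, max_period_s] *after* having dipped
    below 0.2 — the signature of oscillation, as opposed to the slow
    monotone decay of drifting motion."""
    x = sps.detrend(np.asarray(sig, dtype=float))
    n = len(x)
    if n < int(2 * max_period_s * sample_rate):
        raise ValueError("signal too short for the periodicity test")
    ac = sps.correlate(x, x, mode="full")[n - 1 :]
    if ac[0] <= 0:
        return False
    ac = ac / ac[0]
    lo = int(min_period_s * sample_rate)
    hi = min(int(max_period_s * sample_rate), n - 1)
    peaks, props = sps.find_peaks(ac[: hi + 1], height=0.4)
    for p in peaks:
        if p >= lo and ac[:p].min() <= 0.2:
            return True
    return False
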