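"""Synthetic cohort generator for the three-emotion elicitation protocol.

Emulates a session in which each subject hears 3 minutes of relaxing music
before each of three 4-minute picture blocks (neutral, negative, positive)
while ECG (400 Hz), blood volume pulse (201 Hz) and skin conductance
(201 Hz) are recorded continuously.

The generative model is deliberately simple and fully parameterised so that
every planted parameter maps one-to-one onto a downstream feature:

* RR intervals: mean + 0.1 Hz (LF) sinusoid + 0.25 Hz (HF) sinusoid +
  Gaussian noise, floored at 0.3 s (an integral-pulse-frequency-modulation
  style tachogram).
* ECG: one template QRS complex centred at each beat time.
* BVP: one pulse per beat (cosine rise to a peak, cosine decay back to the
  onset level) with per-beat amplitude drawn from a Gaussian.
* Skin conductance: tonic level + linear drift + a Poisson train of
  Bateman-shaped sudomotor responses with exponentially distributed
  amplitudes + measurement noise.

Stress physiology is encoded per state: relative to neutral, the negative
(stress) state shortens RR intervals, lowers pulse-wave amplitude and
raises the skin-conductance response rate and tonic level.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace

import numpy as np

STATE_LABELS = ("relax", "neutral", "negative", "positive")

#: Bateman impulse-response time constants (seconds), conventional EDA values.
BATEMAN_TAU = (0.75, 2.0)


class SimulationError(ValueError):
    """Invalid simulation argument."""


@dataclass
class StateEffect:
    """Physiological parameters active while one emotional state is elicited.

    Units: seconds for RR-related fields, microsiemens for skin conductance,
    arbitrary units for pulse amplitude.
    """

    mean_rr_s: float = 0.787
    rr_sd_s: float = 0.010
    rr_lf_amp_s: float = 0.012  # 0.1 Hz modulation amplitude
    rr_hf_amp_s: float = 0.050  # 0.25 Hz modulation amplitude
    pulse_amp_mean: float = 0.72
    pulse_amp_sd: float = 0.09
    scr_rate_per_min: float = 4.0
    scr_amp_mean: float = 0.37
    tonic_level: float = 6.0
    tonic_drift_per_min: float = 0.02

    def __post_init__(self) -> None:
        if not (0.3 < self.mean_rr_s < 2.0):
            raise SimulationError(f"mean_rr_s must lie in (0.3, 2.0), got {self.mean_rr_s}")
        for name in ("rr_sd_s", "rr_lf_amp_s", "rr_hf_amp_s", "pulse_amp_sd",
                     "scr_rate_per_min", "scr_amp_mean"):
            if getattr(self, name) < 0:
                raise SimulationError(f"{name} must be >= 0, got {getattr(self, name)}")


def default_state_effects() -> dict[str, StateEffect]:
    """Per-state defaults.

    RR means/SDs and pulse amplitude statistics follow typical young-adult
    values with the stress state showing faster heart rate, reduced
    pulse-wave amplitude and elevated electrodermal activity; the relax
    flank defaults to the neutral physiology.
    """
    neutral = StateEffect()
    return {
        "neutral": neutral,
        "relax": replace(neutral),
        "negative": StateEffect(
            mean_rr_s=0.740, rr_sd_s=0.009, rr_lf_amp_s=0.016, rr_hf_amp_s=0.040,
            pulse_amp_mean=0.62, pulse_amp_sd=0.10,
            scr_rate_per_min=8.0, scr_amp_mean=0.91,
            tonic_level=7.0, tonic_drift_per_min=0.05,
        ),
        "positive": StateEffect(
            mean_rr_s=0.777, rr_sd_s=0.010, rr_lf_amp_s=0.012, rr_hf_amp_s=0.046,
            pulse_amp_mean=0.70, pulse_amp_sd=0.107,
            scr_rate_per_min=5.0, scr_amp_mean=0.42,
            tonic_level=6.3, tonic_drift_per_min=0.02,
        ),
    }


@dataclass
class SessionTimeline:
    """Ordered, contiguous labelled segments of one recording session."""

    segments: list[tuple[str, float, float]]

    def __post_init__(self) -> None:
        if not self.segments:
            raise SimulationError("timeline needs at least one segment")
        prev_end = None
        for label, start, end in self.segments:
            if label not in STATE_LABELS:
                raise SimulationError(f"unknown segment label {label!r}")
            if end <= start:
                raise SimulationError(f"segment {label} has end {end} <= start {start}")
            if prev_end is not None and abs(start - prev_end) > 1e-9:
                raise SimulationError("segments must be contiguous")
            prev_end = end

    @property
    def duration_s(self) -> float:
        return self.segments[-1][2] - self.segments[0][1]

    def label_at(self, t: float) -> str:
        for label, start, end in self.segments:
            if start <= t < end:
                return label
        return self.segments[-1][0]


def default_timeline() -> SessionTimeline:
    """3-min relax before each 4-min picture block (neutral, negative, positive)."""
    layout = [("relax", 180.0), ("neutral", 240.0), ("relax", 180.0),
              ("negative", 240.0), ("relax", 180.0), ("positive", 240.0)]
    segs, t = [], 0.0
    for label, dur in layout:
        segs.append((label, t, t + dur))
        t += dur
    return SessionTimeline(segs)


@dataclass
class RawRecording:
    """One channel's uniformly sampled amplitude series."""

    channel: str          # ecg | bvp | gsr
    rate_hz: float
    samples: np.ndarray
    t0_s: float = 0.0

    def __post_init__(self) -> None:
        if self.channel not in ("ecg", "bvp", "gsr"):
            raise SimulationError(f"unknown channel {self.channel!r}")
        if self.rate_hz <= 0:
            raise SimulationError("rate_hz must be positive")
        self.samples = np.asarray(self.samples, dtype=float)
        if not np.all(np.isfinite(self.samples)):
            raise SimulationError("recording contains non-finite samples")

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.rate_hz

    @property
    def times_s(self) -> np.ndarray:
        return self.t0_s + np.arange(len(self.samples)) / self.rate_hz


@dataclass
class CohortSimConfig:
    """Simulation conditions for one cohort."""

    n_subjects: int = 1
    seed: int = 0
    ecg_rate_hz: float = 400.0
    bvp_rate_hz: float = 201.0
    gsr_rate_hz: float = 201.0
    state_effects: dict[str, StateEffect] = field(default_factory=default_state_effects)
    timeline: SessionTimeline = field(default_factory=default_timeline)
    ecg_noise_sd: float = 0.01
    bvp_noise_sd: float = 0.005
    gsr_noise_sd: float = 0.01

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise SimulationError("n_subjects must be >= 1")
        for r in (self.ecg_rate_hz, self.bvp_rate_hz, self.gsr_rate_hz):
            if r <= 0:
                raise SimulationError("sampling rates must be positive")
        missing = set(STATE_LABELS) - set(self.state_effects)
        if missing:
            raise SimulationError(f"state_effects missing labels: {sorted(missing)}")


@dataclass
class SubjectRecord:
    """One simulated subject: timeline, three recordings and planted truth."""

    subject_id: int
    timeline: SessionTimeline
    recordings: dict[str, RawRecording]
    truth: dict


def simulate_rr_series(effect: StateEffect, duration_s: float,
                       rng: np.random.Generator, t_start_s: float = 0.0) -> np.ndarray:
    """Generate RR intervals covering at least ``duration_s`` seconds.

    RR_n = mean + LF sinusoid(0.1 Hz) + HF sinusoid(0.25 Hz) + N(0, sd),
    evaluated at the running beat time and floored at 0.3 s.
    """
    if duration_s <= 0:
        raise SimulationError("duration_s must be positive")
    rr, t = [], 0.0
    while t < duration_s - 1e-9:
        tt = t_start_s + t
        val = (effect.mean_rr_s
               + effect.rr_lf_amp_s * np.sin(2 * np.pi * 0.1 * tt)
               + effect.rr_hf_amp_s * np.sin(2 * np.pi * 0.25 * tt))
        if effect.rr_sd_s > 0:
            val += rng.normal(0.0, effect.rr_sd_s)
        val = max(val, 0.3)
        rr.append(val)
        t += val
    return np.asarray(rr)


def _qrs_template(rate_hz: float) -> np.ndarray:
    """Template QRS complex: dominant R spike flanked by small Q and S dips."""
    half = 0.06
    t = np.arange(-half, half + 0.5 / rate_hz, 1.0 / rate_hz)
    r = np.exp(-0.5 * (t / 0.008) ** 2)
    q = -0.15 * np.exp(-0.5 * ((t + 0.025) / 0.008) ** 2)
    s = -0.20 * np.exp(-0.5 * ((t - 0.025) / 0.008) ** 2)
    return r + q + s


def synthesize_ecg(rr: np.ndarray, rate_hz: float = 400.0,
                   duration_s: float | None = None,
                   noise_sd: float = 0.0,
                   rng: np.random.Generator | None = None) -> RawRecording:
    """Place one template QRS complex at each cumulative RR time.

    Beats fall at ``cumsum(rr)``; the recording spans ``duration_s`` (default:
    ``sum(rr)`` plus a short tail so the last complex is not clipped).
    """
    rr = np.asarray(rr, dtype=float)
    if rr.size == 0:
        raise SimulationError("empty RR list")
    if np.any(rr < 0.3):
        raise SimulationError("all RR intervals must be >= 0.3 s")
    beat_times = np.cumsum(rr)
    if duration_s is None:
        duration_s = float(beat_times[-1]) + 0.5
    n = int(round(duration_s * rate_hz))
    sig = np.zeros(n)
    tpl = _qrs_template(rate_hz)
    h = len(tpl) // 2
    for bt in beat_times:
        c = int(round(bt * rate_hz))
        lo, hi = c - h, c - h + len(tpl)
        if lo < 0 or hi > n:
            continue
        sig[lo:hi] += tpl
    if noise_sd > 0:
        if rng is None:
            raise SimulationError("noise requires an rng")
        sig += rng.normal(0.0, noise_sd, size=n)
    return RawRecording("ecg", rate_hz, sig)


def _pulse_shape(u: np.ndarray, peak_frac: float) -> np.ndarray:
    """Unit pulse on u in [0,1): cosine rise to 1 at ``peak_frac``, cosine decay to 0."""
    out = np.empty_like(u)
    rise = u < peak_frac
    out[rise] = 0.5 * (1.0 - np.cos(np.pi * u[rise] / peak_frac))
    out[~rise] = 0.5 * (1.0 + np.cos(np.pi * (u[~rise] - peak_frac) / (1.0 - peak_frac)))
    return out


def synthesize_bvp(rr: np.ndarray, effect: StateEffect, rate_hz: float = 201.0,
                   rng: np.random.Generator | None = None,
                   duration_s: float | None = None,
                   peak_frac: float = 0.3,
                   amplitudes: np.ndarray | None = None,
                   noise_sd: float = 0.0) -> tuple[RawRecording, np.ndarray]:
    """One pulse per beat, onset at the beat start, peak ``peak_frac`` into the beat.

    Pulse n occupies the beat interval so the peak-minus-onset amplitude
    equals the drawn amplitude exactly (up to sampling).  Returns the
    recording and the planted per-beat amplitudes.
    """
    rr = np.asarray(rr, dtype=float)
    if rr.size == 0:
        raise SimulationError("empty RR list")
    if np.any(rr < 0.3):
        raise SimulationError("all RR intervals must be >= 0.3 s")
    onsets = np.concatenate([[0.0], np.cumsum(rr)[:-1]])
    if amplitudes is None:
        if effect.pulse_amp_sd > 0:
            if rng is None:
                raise SimulationError("random amplitudes require an rng")
            amplitudes = rng.normal(effect.pulse_amp_mean, effect.pulse_amp_sd, size=rr.size)
        else:
            amplitudes = np.full(rr.size, effect.pulse_amp_mean)
        amplitudes = np.clip(amplitudes, 0.0, None)
    amplitudes = np.asarray(amplitudes, dtype=float)
    if duration_s is None:
        duration_s = float(np.sum(rr))
    n = int(round(duration_s * rate_hz))
    t = np.arange(n) / rate_hz
    sig = np.zeros(n)
    for onset, width, amp in zip(onsets, rr, amplitudes):
        lo = int(np.ceil(onset * rate_hz))
        hi = min(int(np.ceil((onset + width) * rate_hz)), n)
        if lo >= hi:
            continue
        u = (t[lo:hi] - onset) / width
        sig[lo:hi] += amp * _pulse_shape(u, peak_frac)
    if noise_sd > 0:
        if rng is None:
            raise SimulationError("noise requires an rng")
        sig += rng.normal(0.0, noise_sd, size=n)
    return RawRecording("bvp", rate_hz, sig), amplitudes


def bateman_kernel(rate_hz: float, tau: tuple[float, float] = BATEMAN_TAU,
                   length_s: float = 40.0) -> np.ndarray:
    """Bateman impulse response normalised to unit peak."""
    tau1, tau2 = tau
    t = np.arange(0.0, length_s, 1.0 / rate_hz)
    h = np.exp(-t / tau2) - np.exp(-t / tau1)
    return h / h.max()


def synthesize_gsr(effect: StateEffect, duration_s: float, rate_hz: float = 201.0,
                   rng: np.random.Generator | None = None,
                   noise_sd: float = 0.0,
                   t_start_s: float = 0.0) -> tuple[RawRecording, list[tuple[float, float]]]:
    """Tonic level + drift + Poisson train of Bateman-shaped responses.

    Event times follow a homogeneous Poisson process at ``scr_rate_per_min``;
    amplitudes are exponential with mean ``scr_amp_mean``.  Returns the
    recording and the planted ``(event_time_s, amplitude)`` list (times
    relative to the start of this recording).
    """
    if duration_s <= 0:
        raise SimulationError("duration_s must be positive")
    if effect.scr_rate_per_min < 0:
        raise SimulationError("scr_rate_per_min must be >= 0")
    n = int(round(duration_s * rate_hz))
    t = np.arange(n) / rate_hz
    sig = effect.tonic_level + effect.tonic_drift_per_min * (t_start_s + t) / 60.0
    events: list[tuple[float, float]] = []
    if effect.scr_rate_per_min > 0:
        if rng is None:
            raise SimulationError("events require an rng")
        rate_per_s = effect.scr_rate_per_min / 60.0
        tt = rng.exponential(1.0 / rate_per_s)
        while tt < duration_s:
            amp = rng.exponential(effect.scr_amp_mean)
            events.append((float(tt), float(amp)))
            tt += rng.exponential(1.0 / rate_per_s)
        if events:
            driver = np.zeros(n)
            for et, amp in events:
                driver[int(round(et * rate_hz))] += amp
            from scipy.signal import fftconvolve
            kern = bateman_kernel(rate_hz)
            sig = sig + fftconvolve(driver, kern)[:n]
    if noise_sd > 0:
        if rng is None:
            raise SimulationError("noise requires an rng")
        sig = sig + rng.normal(0.0, noise_sd, size=n)
    return RawRecording("gsr", rate_hz, sig), events


def simulate_subject(config: CohortSimConfig, subject_id: int,
                     rng: np.random.Generator) -> SubjectRecord:
    """Simulate one subject's full session (all three channels)."""
    tl = config.timeline
    duration = tl.duration_s

    # RR intervals: state effect switches at segment boundaries.
    rr_all: list[float] = []
    rr_by_segment: list[list[float]] = [[] for _ in tl.segments]
    t = 0.0
    seg_idx = 0
    while t < duration - 1e-9:
        while seg_idx + 1 < len(tl.segments) and t >= tl.segments[seg_idx][2]:
            seg_idx += 1
        effect = config.state_effects[tl.segments[seg_idx][0]]
        val = (effect.mean_rr_s
               + effect.rr_lf_amp_s * np.sin(2 * np.pi * 0.1 * t)
               + effect.rr_hf_amp_s * np.sin(2 * np.pi * 0.25 * t))
        if effect.rr_sd_s > 0:
            val += rng.normal(0.0, effect.rr_sd_s)
        val = max(val, 0.3)
        rr_all.append(val)
        rr_by_segment[seg_idx].append(val)
        t += val
    rr_arr = np.asarray(rr_all)
    beat_times = np.cumsum(rr_arr)

    ecg = synthesize_ecg(rr_arr, config.ecg_rate_hz, duration_s=duration,
                         noise_sd=config.ecg_noise_sd, rng=rng)

    # Per-beat pulse amplitudes follow the state active at the beat onset.
    onsets = np.concatenate([[0.0], beat_times[:-1]])
    amp_mean = np.array([config.state_effects[tl.label_at(o)].pulse_amp_mean for o in onsets])
    amp_sd = np.array([config.state_effects[tl.label_at(o)].pulse_amp_sd for o in onsets])
    amps = np.clip(amp_mean + amp_sd * rng.normal(size=len(onsets)), 0.0, None)
    bvp, _ = synthesize_bvp(rr_arr, config.state_effects["neutral"], config.bvp_rate_hz,
                            duration_s=duration, amplitudes=amps,
                            noise_sd=config.bvp_noise_sd, rng=rng)

    # Skin conductance: session-long tonic target (smoothed at segment joins)
    # plus a Poisson train of Bateman-shaped responses at per-state rates.
    n = int(round(duration * config.gsr_rate_hz))
    tg = np.arange(n) / config.gsr_rate_hz
    tonic = np.empty(n)
    for (label, start, end) in tl.segments:
        eff = config.state_effects[label]
        mask = (tg >= start) & (tg < end) if end < duration else (tg >= start)
        tonic[mask] = eff.tonic_level + eff.tonic_drift_per_min * (tg[mask] - start) / 60.0
    win = max(int(15 * config.gsr_rate_hz), 1)
    kernel = np.ones(win) / win
    pad = np.concatenate([np.full(win, tonic[0]), tonic, np.full(win, tonic[-1])])
    tonic = np.convolve(pad, kernel, mode="same")[win:-win]

    events_all: list[tuple[float, float]] = []
    driver = np.zeros(n)
    for (label, start, end) in tl.segments:
        eff = config.state_effects[label]
        if eff.scr_rate_per_min <= 0:
            continue
        rate_per_s = eff.scr_rate_per_min / 60.0
        tt = start + rng.exponential(1.0 / rate_per_s)
        while tt < end:
            amp = float(rng.exponential(eff.scr_amp_mean))
            events_all.append((float(tt), amp))
            idx = int(round(tt * config.gsr_rate_hz))
            if idx < n:
                driver[idx] += amp
            tt += rng.exponential(1.0 / rate_per_s)
    gsr_sig = tonic
    if events_all:
        from scipy.signal import fftconvolve
        gsr_sig = gsr_sig + fftconvolve(driver, bateman_kernel(config.gsr_rate_hz))[:n]
    if config.gsr_noise_sd > 0:
        gsr_sig = gsr_sig + rng.normal(0.0, config.gsr_noise_sd, size=n)
    gsr = RawRecording("gsr", config.gsr_rate_hz, gsr_sig)

    truth = {
        "rr_s": rr_arr,
        "beat_times_s": beat_times,
        "rr_by_segment": [np.asarray(x) for x in rr_by_segment],
        "pulse_amplitudes": amps,
        "scr_events": events_all,
        "state_effects": copy.deepcopy(config.state_effects),
    }
    return SubjectRecord(subject_id, tl, {"ecg": ecg, "bvp": bvp, "gsr": gsr}, truth)


def simulate_cohort(config: CohortSimConfig) -> list[SubjectRecord]:
    """Simulate the whole cohort; deterministic given ``config.seed``."""
    children = np.random.SeedSequence(config.seed).spawn(config.n_subjects)
    return [simulate_subject(config, i, np.random.default_rng(ss))
            for i, ss in enumerate(children)]


def synthetic_feature_matrix(n_subjects: int,
                             label_means: dict[str, float],
                             rng: np.random.Generator,
                             n_windows: int = 5,
                             between_sd: float = 1.0,
                             within_sd: float = 0.3,
                             feature: str = "HR_ECG",
                             timeline: SessionTimeline | None = None):
    """Feature matrix with planted per-state means, bypassing signal synthesis.

    Each subject's value in a segment is ``label mean + subject offset +
    segment noise``; windows add small within-segment noise.  Used for
    statistical power and type-I studies of the selection stage, where full
    signal synthesis would only add cost, not information.
    """
    import pandas as pd

    tl = timeline or default_timeline()
    rows = []
    for subj in range(n_subjects):
        offset = rng.normal(0.0, between_sd)
        for seg_idx, (label, _, _) in enumerate(tl.segments):
            seg_val = label_means.get(label, 0.0) + offset + rng.normal(0.0, between_sd)
            for w in range(n_windows):
                rows.append({
                    "subject": subj, "segment": seg_idx, "label": label,
                    "window": w,
                    feature: seg_val + rng.normal(0.0, within_sd),
                })
    return pd.DataFrame(rows)


def transition_shift_rate(n_subjects: int, shift_sd: float, n_reps: int,
                          seed: int, alpha: float = 0.05,
                          n_transitions: int = 3) -> float:
    """Fraction of replicates in which a feature passes the transition test.

    Each replicate draws paired before/after differences for every
    transition as N(shift_sd, 1) across subjects (the planted effect is
    ``shift_sd`` standard deviations of the paired difference); the feature
    counts as selected when every transition's Shapiro-gated paired test is
    significant at ``alpha``.  ``shift_sd = 0`` measures the type-I rate.
    """
    from .selection import _paired_test

    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_reps):
        ok = True
        for _ in range(n_transitions):
            diffs = rng.normal(shift_sd, 1.0, size=n_subjects)
            p, _test = _paired_test(diffs)
            if not p < alpha:
                ok = False
                break
        hits += ok
    return hits / n_reps
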