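"""Synthetic nasal-pressure recordings with labelled activity regimes.

Generates surrogate oxygen-circuit pressure traces for a telemonitoring
protocol in which inspiration appears as minima below a slowly drifting
baseline.  Two recording templates are provided:

* a 30-minute scripted "healthy protocol" (rest with everyday artifacts,
  a 3-minute exercise block, then recovery), whose 45-second windowing
  yields 40 windows labelled 23 reference / 4 exercise / 13 transition;
* an observational COPD-like recording of configurable length with
  absence gaps, a configurable number of exercise blocks and an
  approximate (blurred) annotation track.

Every generator is deterministic given the profile seed and emits a
ground-truth per-breath cycle log so that downstream breath detection
can be scored against truth.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "ProfileError",
    "ScheduleError",
    "SubjectProfile",
    "RegimeSegment",
    "RegimeSchedule",
    "BreathEvent",
    "Recording",
    "make_healthy_protocol",
    "make_copd_like",
    "synth_waveform",
    "sample_profile",
    "generate_cohort",
    "write_recording",
    "read_recording",
]

REGIMES = ("reference", "artifact", "exercise", "transition", "absent")
STRATEGIES = ("rate_dominant", "amplitude_dominant", "mixed")

#: hard physiological ceiling on instantaneous breathing frequency (Hz);
#: breath cycles are never generated shorter than 1 / this.
MAX_BREATH_FREQ_HZ = 2.0

#: fraction of a breath cycle spent in inspiration (trough below baseline)
INSPIRATION_FRACTION = 0.30
#: fraction spent in active expiration (shallow hump above baseline); the
#: remainder of the cycle is an end-expiratory pause at baseline
EXPIRATION_FRACTION = 0.35
#: expiration hump height relative to inspiratory depth
EXPIRATION_RATIO = 0.3
#: time constant (s) of the exponential recovery during transition regimes
TRANSITION_TAU_S = 120.0
#: period (s) of the slow sinusoidal baseline drift
DRIFT_PERIOD_S = 90.0


class ProfileError(ValueError):
    """Raised when a subject profile violates its physiological invariants."""


class ScheduleError(ValueError):
    """Raised when a regime schedule cannot be constructed as requested."""


@dataclass
class SubjectProfile:
    """Breathing phenotype of one simulated subject.

    Rates are in breaths/min, amplitudes in arbitrary pressure units.
    ``strategy`` captures how the subject adapts to respiratory load:
    mostly by breathing faster (``rate_dominant``), mostly by breathing
    deeper (``amplitude_dominant``), or both (``mixed``).
    """

    subject_id: str
    rest_rate: float = 15.0
    rest_amplitude: float = 1.0
    exercise_rate_multiplier: float = 1.5
    exercise_amplitude_multiplier: float = 1.5
    strategy: str = "mixed"
    breath_length_cv: float = 0.08
    amplitude_cv: float = 0.12
    noise_sd: float = 0.12
    baseline_drift_amplitude: float = 0.15
    #: sd (log scale) of the slow within-subject wander of the target
    #: breathing rate / amplitude; resting rate wanders far more than
    #: inspiratory depth does, relative to their exercise responses.
    rate_wander_sd: float = 0.18
    amplitude_wander_sd: float = 0.08
    wander_tau_s: float = 150.0
    seed: int = 0

    def validate(self) -> None:
        if self.strategy not in STRATEGIES:
            raise ProfileError(f"unknown strategy {self.strategy!r}")
        if not (6.0 <= self.rest_rate <= 40.0):
            raise ProfileError(
                f"rest_rate {self.rest_rate} outside physiological band 6-40 /min"
            )
        if self.rest_amplitude <= 0:
            raise ProfileError("rest_amplitude must be positive")
        if self.exercise_rate_multiplier < 1 or self.exercise_amplitude_multiplier < 1:
            raise ProfileError("exercise multipliers must be >= 1")
        if self.strategy == "rate_dominant" and not (
            self.exercise_rate_multiplier > self.exercise_amplitude_multiplier
        ):
            raise ProfileError("rate_dominant requires rate multiplier > amplitude multiplier")
        if self.strategy == "amplitude_dominant" and not (
            self.exercise_amplitude_multiplier > self.exercise_rate_multiplier
        ):
            raise ProfileError("amplitude_dominant requires amplitude multiplier > rate multiplier")
        for name in ("breath_length_cv", "amplitude_cv"):
            v = getattr(self, name)
            if not (0.0 <= v < 1.0):
                raise ProfileError(f"{name} must lie in [0, 1)")
        if self.noise_sd < 0 or self.baseline_drift_amplitude < 0:
            raise ProfileError("noise_sd and baseline_drift_amplitude must be >= 0")
        if self.rate_wander_sd < 0 or self.amplitude_wander_sd < 0:
            raise ProfileError("wander sds must be >= 0")
        if self.wander_tau_s <= 0:
            raise ProfileError("wander_tau_s must be positive")
        # exercising at the ceiling would have no physiological sense
        if self.rest_rate * self.exercise_rate_multiplier / 60.0 > MAX_BREATH_FREQ_HZ:
            raise ProfileError("exercise breathing rate exceeds the 2 Hz ceiling")


@dataclass(frozen=True)
class RegimeSegment:
    regime: str
    duration: float  # seconds

    def __post_init__(self):
        if self.regime not in REGIMES:
            raise ScheduleError(f"unknown regime {self.regime!r}")
        if self.duration <= 0:
            raise ScheduleError("segment durations must be positive")


@dataclass
class RegimeSchedule:
    """Ordered sequence of (regime, duration) segments covering a recording."""

    segments: list[RegimeSegment]

    @property
    def total_duration(self) -> float:
        return float(sum(s.duration for s in self.segments))

    def sample_regimes(self, sampling_rate: float) -> np.ndarray:
        """Regime name per sample, length = round(total_duration * fs)."""
        n_total = int(round(self.total_duration * sampling_rate))
        out = np.empty(n_total, dtype=object)
        pos = 0.0
        for seg in self.segments:
            i0 = int(round(pos * sampling_rate))
            i1 = int(round((pos + seg.duration) * sampling_rate))
            out[i0:i1] = seg.regime
            pos += seg.duration
        return out

    def spans(self) -> list[tuple[str, float, float]]:
        """(regime, start_s, end_s) triples."""
        out, pos = [], 0.0
        for seg in self.segments:
            out.append((seg.regime, pos, pos + seg.duration))
            pos += seg.duration
        return out

    def to_dict(self) -> list[dict]:
        return [{"regime": s.regime, "duration": s.duration} for s in self.segments]

    @classmethod
    def from_dict(cls, items: Iterable[dict]) -> "RegimeSchedule":
        return cls([RegimeSegment(d["regime"], d["duration"]) for d in items])


@dataclass(frozen=True)
class BreathEvent:
    """Ground-truth record of one generated breath cycle."""

    start_s: float
    length_s: float
    depth: float
    regime: str

    @property
    def minimum_s(self) -> float:
        """Time of the inspiratory pressure minimum within the cycle."""
        return self.start_s + 0.5 * INSPIRATION_FRACTION * self.length_s


@dataclass
class Recording:
    """A uniformly sampled pressure trace plus its regime annotation.

    ``schedule`` is the true regime sequence that generated the waveform;
    ``annotation`` is the regime track used for labelling windows.  They
    coincide except for COPD-like recordings, where the annotation may be
    deliberately approximate (recovery relabelled as reference, block
    edges blurred) to emulate an imprecise activity diary.
    """

    samples: np.ndarray
    sampling_rate: float
    schedule: RegimeSchedule
    profile: SubjectProfile
    annotation: RegimeSchedule | None = None
    cycle_log: list[BreathEvent] = field(default_factory=list)

    def __post_init__(self):
        if self.annotation is None:
            self.annotation = self.schedule
        expected = int(round(self.schedule.total_duration * self.sampling_rate))
        if len(self.samples) != expected:
            raise ScheduleError(
                f"sample count {len(self.samples)} != schedule duration x rate {expected}"
            )
        if not np.all(np.isfinite(self.samples)):
            raise ScheduleError("recording contains non-finite samples")

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.samples)) / self.sampling_rate


# ---------------------------------------------------------------------------
# waveform synthesis
# ---------------------------------------------------------------------------

def _breath_shape(phase: np.ndarray, depth: float) -> np.ndarray:
    """Pressure deviation from baseline over one cycle, phase in [0, 1).

    Inspiration is a half-sine trough (nasal pressure drops as the subject
    inhales through the cannula), expiration a shallower positive hump,
    followed by an end-expiratory pause at baseline.
    """
    y = np.zeros_like(phase)
    insp = phase < INSPIRATION_FRACTION
    y[insp] = -depth * np.sin(np.pi * phase[insp] / INSPIRATION_FRACTION)
    exp_end = INSPIRATION_FRACTION + EXPIRATION_FRACTION
    exp = (~insp) & (phase < exp_end)
    y[exp] = (EXPIRATION_RATIO * depth) * np.sin(
        np.pi * (phase[exp] - INSPIRATION_FRACTION) / EXPIRATION_FRACTION
    )
    return y


def _draw_positive(rng: np.random.Generator, mean: float, cv: float) -> float:
    """Gamma draw with given mean and CV (degenerates to the mean at cv=0)."""
    if cv <= 0:
        return mean
    shape = 1.0 / (cv * cv)
    return float(rng.gamma(shape, mean / shape))


def _regime_targets(profile: SubjectProfile, regime: str, t_in_regime: float,
                    prev_exercise: bool) -> tuple[float, float]:
    """(mean breath length s, mean inspiratory depth) for a regime at time t."""
    rest_len = 60.0 / profile.rest_rate
    rest_amp = profile.rest_amplitude
    if regime in ("reference", "artifact", "absent"):
        return rest_len, rest_amp
    ex_len = 60.0 / (profile.rest_rate * profile.exercise_rate_multiplier)
    ex_amp = rest_amp * profile.exercise_amplitude_multiplier
    if regime == "exercise":
        return ex_len, ex_amp
    # transition: exponential recovery from exercise back toward rest
    if not prev_exercise:
        return rest_len, rest_amp
    decay = math.exp(-t_in_regime / TRANSITION_TAU_S)
    rate = profile.rest_rate + (
        profile.rest_rate * profile.exercise_rate_multiplier - profile.rest_rate
    ) * decay
    amp = rest_amp + (ex_amp - rest_amp) * decay
    return 60.0 / rate, amp


def _render_breathing(profile: SubjectProfile, schedule: RegimeSchedule,
                      sampling_rate: float, rng: np.random.Generator,
                      ) -> tuple[np.ndarray, list[BreathEvent]]:
    """Concatenate breath cycles over all non-absent schedule spans."""
    n_total = int(round(schedule.total_duration * sampling_rate))
    x = np.zeros(n_total)
    log: list[BreathEvent] = []
    min_len = 1.0 / MAX_BREATH_FREQ_HZ

    spans = schedule.spans()
    # merge consecutive non-absent spans into breathing stretches, keeping
    # per-time regime lookup for target rate/amplitude
    i = 0
    while i < len(spans):
        if spans[i][0] == "absent":
            i += 1
            continue
        j = i
        while j + 1 < len(spans) and spans[j + 1][0] != "absent":
            j += 1
        stretch = spans[i:j + 1]
        t = stretch[0][1]
        end = stretch[-1][2]
        z_rate = (rng.normal(0.0, profile.rate_wander_sd)
                  if profile.rate_wander_sd > 0 else 0.0)
        z_amp = (rng.normal(0.0, profile.amplitude_wander_sd)
                 if profile.amplitude_wander_sd > 0 else 0.0)
        while t < end - 1e-9:
            regime, reg_start = next(
                (r, s) for r, s, e in stretch if s - 1e-9 <= t < e
            )
            prev_ex = any(r == "exercise" and e <= reg_start + 1e-9 for r, s, e in stretch)
            mean_len, mean_amp = _regime_targets(profile, regime, t - reg_start, prev_ex)
            # slow Ornstein-Uhlenbeck wander of the targets (stationary,
            # updated breath by breath)
            mean_len = mean_len * math.exp(-z_rate)
            mean_amp = mean_amp * math.exp(z_amp)
            length = _draw_positive(rng, mean_len, profile.breath_length_cv)
            length = float(np.clip(length, min_len, 3.0 * mean_len))
            depth = _draw_positive(rng, mean_amp, profile.amplitude_cv)
            depth = max(depth, 0.05 * mean_amp)
            i0 = int(round(t * sampling_rate))
            # never bleed a cycle into the following absent span
            i1 = min(int(round((t + length) * sampling_rate)),
                     int(round(end * sampling_rate)), n_total)
            if i1 > i0:
                tt = np.arange(i0, i1) / sampling_rate
                phase = np.clip((tt - t) / length, 0.0, 1.0 - 1e-12)
                x[i0:i1] += _breath_shape(phase, depth)
            ev = BreathEvent(t, length, depth, regime)
            if ev.minimum_s < end:
                log.append(ev)
            t += length
            if profile.rate_wander_sd > 0 or profile.amplitude_wander_sd > 0:
                rho = math.exp(-length / profile.wander_tau_s)
                innov = math.sqrt(max(1.0 - rho * rho, 0.0))
                z_rate = rho * z_rate + innov * (
                    rng.normal(0.0, profile.rate_wander_sd)
                    if profile.rate_wander_sd > 0 else 0.0
                )
                z_amp = rho * z_amp + innov * (
                    rng.normal(0.0, profile.amplitude_wander_sd)
                    if profile.amplitude_wander_sd > 0 else 0.0
                )
        i = j + 1
    return x, log


def _artifact_noise(schedule: RegimeSchedule, sampling_rate: float,
                    amplitude: float, rng: np.random.Generator) -> np.ndarray:
    """High-frequency, high-variance bursts over artifact spans.

    Stand-in for drinking/cough/speech/mouth-breathing disturbances; these
    spans remain labelled reference downstream.
    """
    n_total = int(round(schedule.total_duration * sampling_rate))
    out = np.zeros(n_total)
    for regime, s, e in schedule.spans():
        if regime != "artifact":
            continue
        i0, i1 = int(round(s * sampling_rate)), int(round(e * sampling_rate))
        burst = rng.normal(0.0, 0.8 * amplitude, size=i1 - i0)
        # sharpen toward high frequencies with a first difference
        burst = 0.6 * np.concatenate([[0.0], np.diff(burst)]) + 0.4 * burst
        out[i0:i1] = burst
    return out


def synth_waveform(profile: SubjectProfile, schedule: RegimeSchedule,
                   sampling_rate: float = 10.0,
                   rng: np.random.Generator | None = None,
                   ) -> tuple[np.ndarray, list[BreathEvent]]:
    """Render the pressure trace for a profile over a regime schedule.

    Returns the sample array and the ground-truth breath cycle log.
    Breathing oscillation is present in every non-absent regime; absent
    spans carry sensor noise only.  Additive components: white sensor
    noise (``noise_sd``), slow sinusoidal baseline drift, and burst noise
    over artifact spans.
    """
    profile.validate()
    if rng is None:
        rng = np.random.default_rng(profile.seed)
    x, log = _render_breathing(profile, schedule, sampling_rate, rng)
    x += _artifact_noise(schedule, sampling_rate, profile.rest_amplitude, rng)
    n = len(x)
    t = np.arange(n) / sampling_rate
    if profile.baseline_drift_amplitude > 0:
        phase = rng.uniform(0, 2 * np.pi)
        x += profile.baseline_drift_amplitude * np.sin(
            2 * np.pi * t / DRIFT_PERIOD_S + phase
        )
    if profile.noise_sd > 0:
        x += rng.normal(0.0, profile.noise_sd, size=n)
    return x, log


# ---------------------------------------------------------------------------
# protocol templates
# ---------------------------------------------------------------------------

#: window length (s) the downstream analysis assumes
WINDOW_S = 45.0

#: healthy protocol structure, in 45-s windows
HEALTHY_N_REFERENCE = 23
HEALTHY_N_EXERCISE = 4
HEALTHY_N_TRANSITION = 13

#: windows of the reference phase that contain an everyday-activity burst
#: (drinking, coughing, speaking, mouth breathing), and burst length
_ARTIFACT_WINDOWS = (6, 10, 14, 18)
_ARTIFACT_S = 10.0


def healthy_schedule() -> RegimeSchedule:
    """The scripted 30-minute protocol: 23 reference windows (four of them
    carrying artifact bursts), a 3-minute exercise block, 13 recovery
    windows."""
    segs: list[RegimeSegment] = []
    pos = 0.0
    ref_end = HEALTHY_N_REFERENCE * WINDOW_S
    for w in _ARTIFACT_WINDOWS:
        a_start = w * WINDOW_S + (WINDOW_S - _ARTIFACT_S) / 2.0
        segs.append(RegimeSegment("reference", a_start - pos))
        segs.append(RegimeSegment("artifact", _ARTIFACT_S))
        pos = a_start + _ARTIFACT_S
    segs.append(RegimeSegment("reference", ref_end - pos))
    segs.append(RegimeSegment("exercise", HEALTHY_N_EXERCISE * WINDOW_S))
    segs.append(RegimeSegment("transition", HEALTHY_N_TRANSITION * WINDOW_S))
    return RegimeSchedule(segs)


def make_healthy_protocol(profile: SubjectProfile) -> Recording:
    """30-minute scripted recording at 10 Hz; windowing it yields exactly
    40 windows labelled 23 reference / 4 exercise / 13 transition."""
    profile.validate()
    schedule = healthy_schedule()
    rng = np.random.default_rng(profile.seed)
    x, log = synth_waveform(profile, schedule, 10.0, rng)
    return Recording(x, 10.0, schedule, profile, cycle_log=log)


def _place_blocks(rng: np.random.Generator, total_windows: int,
                  block_lengths: list[int], margin: int) -> list[int]:
    """Non-overlapping start windows for blocks, in order, with margins."""
    needed = sum(block_lengths) + margin * (len(block_lengths) + 1)
    if needed > total_windows:
        raise ScheduleError(
            f"cannot fit {len(block_lengths)} blocks into {total_windows} windows"
        )
    free = total_windows - sum(block_lengths) - margin * (len(block_lengths) + 1)
    cuts = np.sort(rng.integers(0, free + 1, size=len(block_lengths)))
    gaps = np.diff(np.r_[0, cuts])  # extra reference windows before each block
    starts, pos = [], margin
    for k, L in enumerate(block_lengths):
        start = pos + int(gaps[k])
        starts.append(start)
        pos = start + L + margin
    return starts


def make_copd_like(profile: SubjectProfile, duration_hours: float = 8.0,
                   n_exercise_blocks: int = 2, exercise_minutes: float = 20.0,
                   recovery_minutes: float = 5.0, n_absent_gaps: int = 3,
                   absent_minutes: float = 15.0, label_noise: float = 1.0,
                   edge_jitter_windows: int = 2) -> Recording:
    """Observational COPD-like recording with absence gaps and an
    approximate annotation track.

    The true schedule contains ``n_exercise_blocks`` exercise periods each
    followed by a physiological recovery, plus absence gaps (oxygen off or
    patient away).  The annotation labels only exercise and reference:
    recovery is annotated as reference, and with probability
    ``label_noise`` each exercise-block edge is shifted by up to
    ``edge_jitter_windows`` windows, emulating an approximate diary.
    ``label_noise = 0`` leaves the annotation identical to the schedule
    (apart from the recovery-as-reference convention).
    """
    profile.validate()
    if duration_hours <= 0:
        raise ScheduleError("duration_hours must be positive")
    if n_exercise_blocks < 0:
        raise ScheduleError("n_exercise_blocks must be >= 0")
    rng = np.random.default_rng(profile.seed)
    total_windows = int(round(duration_hours * 3600.0 / WINDOW_S))
    ex_w = max(1, int(round(exercise_minutes * 60.0 / WINDOW_S)))
    rec_w = max(1, int(round(recovery_minutes * 60.0 / WINDOW_S)))
    gap_w = max(1, int(round(absent_minutes * 60.0 / WINDOW_S)))

    kinds = ["exercise"] * n_exercise_blocks + ["absent"] * n_absent_gaps
    kinds = [kinds[i] for i in rng.permutation(len(kinds))]
    block_lengths = [ex_w + rec_w if k == "exercise" else gap_w for k in kinds]
    starts = _place_blocks(rng, total_windows, block_lengths, margin=2)

    window_regime = np.array(["reference"] * total_windows, dtype=object)
    ex_spans: list[tuple[int, int]] = []
    for start, kind in zip(starts, kinds):
        if kind == "exercise":
            window_regime[start:start + ex_w] = "exercise"
            window_regime[start + ex_w:start + ex_w + rec_w] = "transition"
            ex_spans.append((start, start + ex_w))
        else:
            window_regime[start:start + gap_w] = "absent"

    segs: list[RegimeSegment] = []
    for regime in window_regime:
        if segs and segs[-1].regime == regime:
            segs[-1] = RegimeSegment(regime, segs[-1].duration + WINDOW_S)
        else:
            segs.append(RegimeSegment(regime, WINDOW_S))
    schedule = RegimeSchedule(segs)

    # annotation: recovery -> reference, exercise edges optionally blurred
    ann_regime = np.where(window_regime == "transition", "reference", window_regime)
    ann_regime = np.array(ann_regime, dtype=object)
    for (s, e) in ex_spans:
        ann_regime[s:e] = "reference"
    for (s, e) in ex_spans:
        if rng.uniform() < label_noise:
            s = int(np.clip(s + rng.integers(-edge_jitter_windows, edge_jitter_windows + 1),
                            0, total_windows - 1))
        if rng.uniform() < label_noise:
            e = int(np.clip(e + rng.integers(-edge_jitter_windows, edge_jitter_windows + 1),
                            s + 1, total_windows))
        ann_regime[s:e] = "exercise"
    ann_regime[window_regime == "absent"] = "absent"
    ann_segs: list[RegimeSegment] = []
    for regime in ann_regime:
        if ann_segs and ann_segs[-1].regime == regime:
            ann_segs[-1] = RegimeSegment(regime, ann_segs[-1].duration + WINDOW_S)
        else:
            ann_segs.append(RegimeSegment(regime, WINDOW_S))
    annotation = RegimeSchedule(ann_segs)

    x, log = synth_waveform(profile, schedule, 10.0, rng)
    return Recording(x, 10.0, schedule, profile, annotation=annotation, cycle_log=log)


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

def sample_profile(subject_id: str, strategy: str, seed: int,
                   rng: np.random.Generator) -> SubjectProfile:
    """Draw a physiologically plausible subject phenotype.

    Resting rate 12-18 breaths/min; the load-adaptation multipliers depend
    on the strategy: rate-dominant subjects speed up markedly (x~1.7) and
    deepen slightly, amplitude-dominant subjects deepen markedly (x~1.9)
    and speed up slightly, mixed subjects do both moderately.
    """
    rest_rate = float(rng.uniform(12.0, 18.0))
    rest_amp = float(rng.uniform(0.8, 1.2))
    if strategy == "rate_dominant":
        rate_m = float(np.clip(rng.normal(1.45, 0.10), 1.25, 1.8))
        amp_m = float(np.clip(rng.normal(1.2, 0.06), 1.05, rate_m - 0.05))
    elif strategy == "amplitude_dominant":
        amp_m = float(np.clip(rng.normal(1.9, 0.15), 1.5, 2.4))
        rate_m = float(np.clip(rng.normal(1.08, 0.04), 1.01, 1.25))
    else:
        rate_m = float(np.clip(rng.normal(1.3, 0.08), 1.15, 1.5))
        amp_m = float(np.clip(rng.normal(1.45, 0.10), 1.2, 1.8))
    rate_m = min(rate_m, (MAX_BREATH_FREQ_HZ * 60.0) / rest_rate * 0.9)
    if strategy == "rate_dominant":
        amp_m = min(amp_m, rate_m - 0.01)
    if strategy == "amplitude_dominant":
        rate_m = min(rate_m, amp_m - 0.01)
    return SubjectProfile(
        subject_id=subject_id,
        rest_rate=rest_rate,
        rest_amplitude=rest_amp,
        exercise_rate_multiplier=rate_m,
        exercise_amplitude_multiplier=amp_m,
        strategy=strategy,
        seed=seed,
    )


def generate_cohort(n_healthy: int = 20, n_copd: int = 8, seed: int = 0,
                    copd_duration_hours: float = 8.0,
                    copd_exercise_blocks: int = 2,
                    copd_label_noise: float = 1.0) -> dict[str, list[Recording]]:
    """Generate the study cohort: healthy protocol recordings with the two
    adaptation strategies alternating, plus observational COPD-like
    recordings.  Deterministic given ``seed``."""
    master = np.random.default_rng(seed)
    healthy: list[Recording] = []
    for i in range(n_healthy):
        strategy = "rate_dominant" if i % 2 == 0 else "amplitude_dominant"
        sub_seed = int(master.integers(0, 2**31 - 1))
        prof = sample_profile(f"H{i + 1:02d}", strategy, sub_seed, master)
        healthy.append(make_healthy_protocol(prof))
    copd: list[Recording] = []
    for i in range(n_copd):
        strategy = ("rate_dominant", "amplitude_dominant", "mixed")[i % 3]
        sub_seed = int(master.integers(0, 2**31 - 1))
        prof = sample_profile(f"P{i + 1:02d}", strategy, sub_seed, master)
        # patients breathe faster and shallower at rest, with noisier signal
        prof.rest_rate = float(np.clip(prof.rest_rate * 1.2, 6.0, 40.0))
        prof.rest_amplitude *= 0.8
        prof.noise_sd *= 1.5
        prof.exercise_rate_multiplier = min(
            prof.exercise_rate_multiplier,
            (MAX_BREATH_FREQ_HZ * 60.0) / prof.rest_rate * 0.9,
        )
        if prof.strategy == "amplitude_dominant":
            prof.exercise_rate_multiplier = min(
                prof.exercise_rate_multiplier, prof.exercise_amplitude_multiplier - 0.01
            )
        # scale block sizes down for short demo recordings so the
        # schedule always fits
        ex_min = min(20.0, copd_duration_hours * 60.0 / 6.0)
        gap_min = min(15.0, copd_duration_hours * 60.0 / 8.0)
        n_gaps = 3 if copd_duration_hours >= 4 else 2
        copd.append(make_copd_like(
            prof, duration_hours=copd_duration_hours,
            n_exercise_blocks=copd_exercise_blocks,
            exercise_minutes=ex_min,
            recovery_minutes=min(5.0, ex_min / 2.0),
            n_absent_gaps=n_gaps, absent_minutes=gap_min,
            label_noise=copd_label_noise,
        ))
    return {"healthy": healthy, "copd": copd}


# ---------------------------------------------------------------------------
# I/O: CSV trace + JSON sidecar
# ---------------------------------------------------------------------------

def write_recording(rec: Recording, out_dir: str | Path) -> Path:
    """Write ``<id>.csv`` (time_s, pressure) and ``<id>.json`` sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sid = rec.profile.subject_id
    pd.DataFrame({"time_s": rec.times, "pressure": rec.samples}).to_csv(
        out_dir / f"{sid}.csv", index=False
    )
    sidecar = {
        "subject_id": sid,
        "sampling_rate": rec.sampling_rate,
        "profile": asdict(rec.profile),
        "schedule": rec.schedule.to_dict(),
        "annotation": rec.annotation.to_dict(),
        "cycle_log": [
            {"start_s": e.start_s, "length_s": e.length_s,
             "depth": e.depth, "regime": e.regime}
            for e in rec.cycle_log
        ],
    }
    (out_dir / f"{sid}.json").write_text(json.dumps(sidecar))
    return out_dir / f"{sid}.csv"


def read_recording(csv_path: str | Path) -> Recording:
    csv_path = Path(csv_path)
    sidecar = json.loads(csv_path.with_suffix(".json").read_text())
    df = pd.read_csv(csv_path)
    profile = SubjectProfile(**sidecar["profile"])
    return Recording(
        samples=df["pressure"].to_numpy(),
        sampling_rate=sidecar["sampling_rate"],
        schedule=RegimeSchedule.from_dict(sidecar["schedule"]),
        profile=profile,
        annotation=RegimeSchedule.from_dict(sidecar["annotation"]),
        cycle_log=[BreathEvent(**e) for e in sidecar["cycle_log"]],
    )


def write_cohort(cohort: dict[str, list[Recording]], out_dir: str | Path) -> Path:
    """Write all recordings plus a manifest JSON listing subjects."""
    out_dir = Path(out_dir)
    manifest = {}
    for kind, recs in cohort.items():
        sub_dir = out_dir / kind
        entries = []
        for rec in recs:
            write_recording(rec, sub_dir)
            entries.append(rec.profile.subject_id)
        manifest[kind] = entries
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out_dir / "manifest.json"


def read_cohort(out_dir: str | Path) -> dict[str, list[Recording]]:
    out_dir = Path(out_dir)
    manifest = json.loads((out_dir / "manifest.json").read_text())
    return {
        kind: [read_recording(out_dir / kind / f"{sid}.csv") for sid in sids]
        for kind, sids in manifest.items()
    }
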