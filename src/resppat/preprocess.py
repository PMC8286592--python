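"""Windowing, presence detection, breath segmentation and quality control.

The analysis operates on non-overlapping 45-second windows of the
pressure trace.  Within each window, breaths are delimited by the
inspiratory minima of the signal; the cycle length is the time between
consecutive minima and the inspiratory depth is the distance from the
estimated baseline down to each minimum.  Windows with fewer than four
identified breaths, or with overly variable cycle lengths, are flagged
as poor quality and excluded from all classification data, as are
windows where no subject presence is detected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import median_filter
from scipy.signal import butter, filtfilt, find_peaks, periodogram

from .synth import Recording

__all__ = [
    "PreprocessConfig",
    "Window",
    "BreathSegmentation",
    "window_recording",
    "detect_presence",
    "segment_breaths",
    "quality_filter",
    "preprocess_recording",
    "windows_table",
]

WINDOW_S = 45.0

LABELS = ("reference", "exercise", "transition", "excluded")
QUALITIES = ("ok", "too_few_breaths", "too_variable", "absent")

#: regime -> window label; everyday-activity artifacts stay in the
#: reference class, recovery maps to transition, absence is excluded.
_REGIME_TO_LABEL = {
    "reference": "reference",
    "artifact": "reference",
    "exercise": "exercise",
    "transition": "transition",
    "absent": "excluded",
}


@dataclass
class PreprocessConfig:
    """Tunable thresholds of the preprocessing stage.

    min_breath_s
        Minimum separation between detected minima; 0.5 s corresponds to
        the 2 Hz ceiling above which breathing has no physiological sense.
    min_prominence
        Absolute prominence for minima detection; ``None`` selects an
        adaptive value of half the standard deviation of the
        baseline-corrected window.
    max_cycle_cv
        Windows whose cycle-length coefficient of variation exceeds this
        are flagged ``too_variable``.
    presence_band / presence_snr
        Subject presence requires at least ``presence_snr`` times more
        power in the respiratory band than the broadband noise floor
        extrapolated into that band.
    baseline_window_s
        Length of the rolling-median window used as the baseline estimate.
    lowpass_hz
        Zero-phase low-pass cutoff applied before minima detection;
        breathing above 2 Hz is non-physiological, so energy beyond this
        cutoff is sensor noise.  ``None`` disables smoothing.
    """

    min_breath_s: float = 0.5
    min_prominence: float | None = None
    max_cycle_cv: float = 0.5
    presence_band: tuple[float, float] = (0.1, 2.0)
    presence_snr: float = 3.0
    noise_band: tuple[float, float] = (2.5, 5.0)
    baseline_window_s: float = 5.0
    lowpass_hz: float | None = 2.0
    #: minima whose depth falls below this fraction of the window's median
    #: depth are rejected as noise dips rather than breaths
    min_relative_depth: float = 0.35


@dataclass
class Window:
    """One 45-s segment of a recording."""

    samples: np.ndarray
    index: int
    label: str
    sampling_rate: float
    subject_id: str = ""
    quality: str = "ok"

    @property
    def start_s(self) -> float:
        return self.index * WINDOW_S


@dataclass
class BreathSegmentation:
    """Detected breath cycles within one window."""

    minima_indices: np.ndarray
    cycle_lengths: np.ndarray  # seconds, between consecutive minima
    inspiratory_depths: np.ndarray  # baseline minus signal at each minimum
    baseline: np.ndarray = field(default_factory=lambda: np.array([]))

    @property
    def n_breaths(self) -> int:
        return len(self.minima_indices)

    @property
    def n_cycles(self) -> int:
        return len(self.cycle_lengths)


def window_recording(rec: Recording) -> list[Window]:
    """Cut a recording into floor(duration / 45 s) non-overlapping windows.

    Each window is labelled by the majority regime of the annotation track
    (ties broken toward the regime appearing earlier in the window);
    absent-majority windows get label ``excluded`` and quality ``absent``.
    Trailing partial segments are discarded, never zero-padded.
    """
    fs = rec.sampling_rate
    if fs <= 0:
        raise ValueError("sampling rate must be positive")
    wlen = int(round(WINDOW_S * fs))
    n_windows = len(rec.samples) // wlen
    regimes = rec.annotation.sample_regimes(fs)
    out: list[Window] = []
    for i in range(n_windows):
        seg = rec.samples[i * wlen:(i + 1) * wlen]
        reg = regimes[i * wlen:(i + 1) * wlen]
        names, first_pos = [], {}
        for pos, r in enumerate(reg):
            if r not in first_pos:
                first_pos[r] = pos
                names.append(r)
        counts = {r: int(np.sum(reg == r)) for r in names}
        best = max(counts.values())
        majority = min((r for r in names if counts[r] == best),
                       key=lambda r: first_pos[r])
        label = _REGIME_TO_LABEL[majority]
        w = Window(seg, i, label, fs, subject_id=rec.profile.subject_id)
        if majority == "absent":
            w.quality = "absent"
        out.append(w)
    return out


def detect_presence(w: Window, config: PreprocessConfig | None = None) -> bool:
    """True iff the window shows breathing-band oscillation above noise.

    Power in the respiratory band (default 0.1-2 Hz) must be at least
    ``presence_snr`` times the noise power expected in that band, where
    the noise level is the median spectral density above the band
    (white-noise extrapolation).  Signals at exactly the threshold count
    as present.
    """
    config = config or PreprocessConfig()
    x = np.asarray(w.samples, dtype=float)
    if len(x) < 16 or np.ptp(x) == 0:
        return False
    freqs, psd = periodogram(x - x.mean(), fs=w.sampling_rate)
    lo, hi = config.presence_band
    band = (freqs >= lo) & (freqs <= hi)
    nlo, nhi = config.noise_band
    noise = (freqs > nlo) & (freqs <= nhi)
    df = freqs[1] - freqs[0]
    band_power = float(np.sum(psd[band]) * df)
    noise_density = float(np.median(psd[noise])) if noise.any() else 0.0
    floor = noise_density * (hi - lo)
    eps = 1e-12 * max(1.0, float(np.var(x)))
    if band_power <= eps:
        return False
    return band_power >= config.presence_snr * floor


def _rolling_median_baseline(x: np.ndarray, fs: float, window_s: float) -> np.ndarray:
    size = max(3, int(round(window_s * fs)) | 1)  # odd length
    return median_filter(x, size=size, mode="nearest")


def segment_breaths(w: Window, config: PreprocessConfig | None = None
                    ) -> BreathSegmentation:
    """Locate inspiratory minima and derive cycle lengths and depths.

    Minima are prominence-filtered local extrema of the baseline-corrected
    signal with minimum separation ``min_breath_s``.  The baseline is a
    rolling median (default 5 s), which makes segmentation invariant to
    constant offsets and robust to slow drift.  An empty segmentation is
    returned when no minima are found.
    """
    config = config or PreprocessConfig()
    raw = np.asarray(w.samples, dtype=float)
    x = raw
    if config.lowpass_hz is not None and config.lowpass_hz < w.sampling_rate / 2:
        b, a = butter(4, config.lowpass_hz, fs=w.sampling_rate, btype="low")
        x = filtfilt(b, a, raw)
    baseline = _rolling_median_baseline(raw, w.sampling_rate, config.baseline_window_s)
    detrended = x - baseline
    prom = config.min_prominence
    if prom is None:
        sd = float(np.std(detrended))
        prom = max(0.5 * sd, 1e-9)
    distance = max(1, int(round(config.min_breath_s * w.sampling_rate)))
    minima, _ = find_peaks(-detrended, prominence=prom, distance=distance)
    if len(minima) == 0:
        return BreathSegmentation(
            np.array([], dtype=int), np.array([]), np.array([]), baseline
        )
    # depths from the raw trace (the low-pass attenuates narrow troughs),
    # with a parabolic vertex refinement around each sampled minimum
    depths = np.empty(len(minima))
    for k, mi in enumerate(minima):
        depths[k] = baseline[mi] - _refine_minimum(raw, mi)
    depths = np.clip(depths, 0.0, None)
    # reject dips much shallower than the typical breath of this window
    if len(minima) >= 3 and config.min_relative_depth > 0:
        keep = depths >= config.min_relative_depth * np.median(depths)
        minima, depths = minima[keep], depths[keep]
    cycle_lengths = np.diff(minima) / w.sampling_rate
    return BreathSegmentation(minima, cycle_lengths, depths, baseline)


def _refine_minimum(x: np.ndarray, i: int) -> float:
    """Sub-sample trough value by fitting a parabola through the sampled
    minimum and its neighbours; falls back to the sampled value when the
    local curvature is degenerate."""
    i = int(np.clip(i, 1, len(x) - 2))
    j = i - 1 + int(np.argmin(x[i - 1:i + 2]))
    j = int(np.clip(j, 1, len(x) - 2))
    y0, y1, y2 = x[j - 1], x[j], x[j + 1]
    curv = y0 - 2.0 * y1 + y2
    if curv <= 1e-12:
        return float(y1)
    return float(y1 - (y2 - y0) ** 2 / (8.0 * curv))


def quality_filter(seg: BreathSegmentation, config: PreprocessConfig | None = None
                   ) -> str:
    """Quality verdict for a segmented window.

    Fewer than 4 identified breath cycles -> ``too_few_breaths`` (hard
    rule); cycle-length CV above ``max_cycle_cv`` -> ``too_variable``;
    otherwise ``ok``.
    """
    config = config or PreprocessConfig()
    if seg.n_cycles < 4:
        return "too_few_breaths"
    lengths = np.asarray(seg.cycle_lengths, dtype=float)
    mean = lengths.mean()
    cv = float(lengths.std(ddof=1) / mean) if mean > 0 else np.inf
    if cv > config.max_cycle_cv:
        return "too_variable"
    return "ok"


def preprocess_recording(rec: Recording, config: PreprocessConfig | None = None
                         ) -> tuple[list[Window], dict[int, BreathSegmentation]]:
    """Window a recording and run presence, segmentation and quality checks.

    Returns the windows (with ``quality`` set) and a segmentation per
    window index for every window where presence was detected.
    """
    config = config or PreprocessConfig()
    windows = window_recording(rec)
    segs: dict[int, BreathSegmentation] = {}
    for w in windows:
        if w.quality == "absent":
            continue
        if not detect_presence(w, config):
            w.quality = "absent"
            continue
        seg = segment_breaths(w, config)
        w.quality = quality_filter(seg, config)
        segs[w.index] = seg
    return windows, segs


def windows_table(windows: list[Window],
                  segs: dict[int, BreathSegmentation]) -> pd.DataFrame:
    """Tidy one-row-per-window summary (subject, index, label, quality,
    breath counts and medians)."""
    rows = []
    for w in windows:
        seg = segs.get(w.index)
        rows.append({
            "subject": w.subject_id,
            "window": w.index,
            "label": w.label,
            "quality": w.quality,
            "n_breaths": seg.n_breaths if seg is not None else 0,
            "median_cycle_s": float(np.median(seg.cycle_lengths))
            if seg is not None and seg.n_cycles else np.nan,
            "median_depth": float(np.median(seg.inspiratory_depths))
            if seg is not None and seg.n_breaths else np.nan,
        })
    return pd.DataFrame(rows)
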