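"""Activation thresholds and contraction/activation event detection.

The activation threshold is learned from a resting baseline recording as
``mean + multiplier * SD`` (multiplier 3 for the ultrasound NPD signal,
2 for the EMG envelope and smoothed torque).  A contraction in the NPD
series shows as two transient peaks — one at contraction onset, one at
relaxation — separated by a quiet "tensed" interval, because coherent
fiber motion happens only during the transitions.  Detection therefore
verifies a candidate peak by requiring 70% of the samples in the following
0.25 s window to stay above threshold, and a full contraction requires two
such verified peaks after a cue, with a continuous sub-threshold interval
between them.

EMG and torque activations are simpler sustained-crossing events: the
signal must remain above its threshold for a 1 s hold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, sosfilt
from sklearn.base import BaseEstimator

from .npd import NPDSeries

__all__ = [
    "ActivationThreshold",
    "ContractionEvent",
    "SampledSignal",
    "ContractionDetector",
    "SustainedActivationDetector",
    "baseline_threshold",
    "verify_peak",
    "detect_contraction",
    "emg_preprocess",
    "torque_preprocess",
    "detect_sustained_activation",
    "moving_average",
]


@dataclass
class ActivationThreshold:
    """Baseline-derived activation threshold, value = mean + multiplier * SD."""

    baseline_mean: float
    baseline_sd: float
    multiplier: float
    value: float = field(init=False)

    def __post_init__(self) -> None:
        if self.baseline_sd < 0:
            raise ValueError("baseline SD cannot be negative")
        self.value = self.baseline_mean + self.multiplier * self.baseline_sd


@dataclass
class ContractionEvent:
    """A detected contraction: verified onset peak, optional verified offset peak."""

    onset_frame: int
    onset_time_s: float
    peak_npd: float
    offset_frame: int | None = None
    offset_time_s: float | None = None
    complete: bool = False

    def __post_init__(self) -> None:
        if self.offset_frame is not None and self.offset_frame <= self.onset_frame:
            raise ValueError("offset must come after onset")

    def to_dict(self) -> dict:
        return {
            "onset_frame": self.onset_frame,
            "onset_time_s": self.onset_time_s,
            "offset_frame": self.offset_frame,
            "offset_time_s": self.offset_time_s,
            "peak_npd": self.peak_npd,
            "complete": self.complete,
        }


@dataclass
class SampledSignal:
    """Uniformly sampled 1-D signal (EMG in volts, torque in N·m, ...)."""

    values: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 1:
            raise ValueError("signal must be 1-D")
        if not self.fs > 0:
            raise ValueError("sampling rate must be positive")
        if not np.isfinite(self.values).all():
            raise ValueError("signal contains non-finite values")

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.values)) / self.fs


def baseline_threshold(baseline, multiplier: float) -> ActivationThreshold:
    """Derive an activation threshold from a resting baseline recording.

    ``value = mean + multiplier * SD`` with the sample SD (n-1 denominator).
    Accepts an :class:`~usmuscle.npd.NPDSeries`, a :class:`SampledSignal`,
    or a bare array.
    """
    if multiplier <= 0:
        raise ValueError("multiplier must be positive")
    values = np.asarray(getattr(baseline, "values", baseline), dtype=np.float64)
    if values.size < 2:
        raise ValueError("baseline needs at least 2 samples")
    return ActivationThreshold(
        baseline_mean=float(values.mean()),
        baseline_sd=float(values.std(ddof=1)),
        multiplier=float(multiplier),
    )


def _window_samples(window_s: float, fps: float) -> int:
    return max(1, round(window_s * fps))


def verify_peak(
    npd: NPDSeries,
    i: int,
    threshold: ActivationThreshold,
    window_s: float = 0.25,
    fraction: float = 0.70,
) -> bool:
    """Check whether sample ``i`` starts a genuine activation peak.

    True iff ``npd[i]`` strictly exceeds the threshold and at least
    ``ceil(fraction * w)`` of the ``w`` samples ``i .. i+w-1`` do too, where
    ``w = round(window_s * fps)`` (10 samples for 0.25 s at 40 fps).  When
    fewer than ``w`` samples remain the rule is applied to those remaining.
    """
    if not 0 <= i < len(npd):
        raise IndexError(f"sample index {i} out of range")
    if npd.values[i] <= threshold.value:
        return False
    w = _window_samples(window_s, npd.fps)
    window = npd.values[i : i + w]
    needed = math.ceil(fraction * len(window))
    return int((window > threshold.value).sum()) >= needed


def detect_contraction(
    npd: NPDSeries,
    threshold: ActivationThreshold,
    cue_start: float,
    search_end: float | None = None,
    window_s: float = 0.25,
    fraction: float = 0.70,
    min_quiet_s: float = 0.25,
) -> ContractionEvent | None:
    """Detect one contraction (two verified peaks) after a cue.

    The onset is the first sample at/after ``cue_start`` passing
    :func:`verify_peak`.  The search then skips the onset peak's
    supra-threshold run, requires a continuous sub-threshold ("tensed")
    interval of at least ``min_quiet_s``, and takes the first verified peak
    after it as the relaxation offset.  Returns ``None`` when no onset is
    found, or an incomplete event when only the onset is.
    """
    if search_end is None:
        search_end = float(npd.times[-1]) + 1.0 / npd.fps
    if not cue_start < search_end:
        raise ValueError("empty search window: cue_start must precede search_end")
    start = npd.index_at(cue_start)
    end = npd.index_at(search_end)
    if start >= end:
        raise ValueError("search window contains no NPD samples")

    onset = next(
        (i for i in range(start, end) if verify_peak(npd, i, threshold, window_s, fraction)),
        None,
    )
    if onset is None:
        return None

    quiet_needed = _window_samples(min_quiet_s, npd.fps)
    below = npd.values <= threshold.value
    # Skip past the onset peak's supra-threshold run, then demand a continuous
    # quiet ("tensed") interval before admitting the relaxation peak.  Once a
    # long-enough quiet interval has been observed, isolated blips that fail
    # peak verification do not cancel it — they are the random baseline
    # excursions the verification window exists to reject.
    j = onset
    while j < end and not below[j]:
        j += 1
    offset = None
    quiet_run = 0
    quiet_seen = False
    while j < end:
        if below[j]:
            quiet_run += 1
            quiet_seen = quiet_seen or quiet_run >= quiet_needed
        else:
            if quiet_seen and verify_peak(npd, j, threshold, window_s, fraction):
                offset = j
                break
            quiet_run = 0
        j += 1

    w = _window_samples(window_s, npd.fps)
    span_end = min(end, (offset + w) if offset is not None else end)
    peak = float(npd.values[onset:span_end].max())
    times = npd.times
    return ContractionEvent(
        onset_frame=onset,
        onset_time_s=float(times[onset]),
        peak_npd=peak,
        offset_frame=offset,
        offset_time_s=float(times[offset]) if offset is not None else None,
        complete=offset is not None,
    )


def moving_average(values: np.ndarray, window: int) -> np.ndarray:
    """Centered symmetric moving average with symmetrically shrunken edges.

    ``window`` is forced to the nearest odd integer >= 1 so the filter stays
    symmetric and centered (zero phase distortion).  Near the edges the
    half-width shrinks so the window never leaves the record.
    """
    x = np.asarray(values, dtype=np.float64)
    window = max(1, int(window))
    if window % 2 == 0:
        window += 1
    half = window // 2
    if half == 0 or len(x) == 0:
        return x.copy()
    csum = np.concatenate(([0.0], np.cumsum(x)))
    n = len(x)
    idx = np.arange(n)
    h = np.minimum(half, np.minimum(idx, n - 1 - idx))
    lo, hi = idx - h, idx + h
    return (csum[hi + 1] - csum[lo]) / (2 * h + 1)


def _ma_window(duration_s: float, fs: float) -> int:
    w = round(duration_s * fs)
    w = max(1, w)
    return w + 1 if w % 2 == 0 else w


def emg_preprocess(
    raw: SampledSignal,
    band: tuple[float, float] = (5.0, 500.0),
    order: int = 5,
    smooth_s: float = 0.01,
) -> SampledSignal:
    """EMG envelope: band-pass, full-wave rectify, 0.01 s moving average.

    The band-pass (5th-order Butterworth, 5-500 Hz) runs forward-only,
    matching causal in-amplifier filtering; the rectified signal is then
    smoothed with a centered symmetric moving average.
    """
    if raw.fs <= 2 * band[1]:
        raise ValueError(
            f"sampling rate {raw.fs} Hz too low for a {band[1]} Hz band edge"
        )
    sos = butter(order, band, btype="bandpass", fs=raw.fs, output="sos")
    filtered = sosfilt(sos, raw.values)
    envelope = moving_average(np.abs(filtered), _ma_window(smooth_s, raw.fs))
    return SampledSignal(values=envelope, fs=raw.fs)


def torque_preprocess(raw: SampledSignal, smooth_s: float = 0.01) -> SampledSignal:
    """Smooth a torque trace with a 0.01 s centered symmetric moving average."""
    return SampledSignal(
        values=moving_average(raw.values, _ma_window(smooth_s, raw.fs)), fs=raw.fs
    )


def detect_sustained_activation(
    signal: SampledSignal,
    threshold: ActivationThreshold,
    hold_s: float = 1.0,
) -> float | None:
    """Time of the first threshold crossing sustained for ``hold_s`` seconds.

    Returns the timestamp of the first sample such that it and every sample
    in the following ``hold_s`` stay strictly above the threshold, or
    ``None`` if no crossing is held long enough.
    """
    n_hold = round(hold_s * signal.fs)
    if n_hold < 1:
        raise ValueError("hold_s * fs must be at least 1 sample")
    above = signal.values > threshold.value
    if len(above) < n_hold:
        return None
    # Run-length trick: position i qualifies iff the n_hold-window starting
    # there is all-true.
    csum = np.concatenate(([0], np.cumsum(above)))
    full = csum[n_hold:] - csum[:-n_hold] == n_hold
    hits = np.flatnonzero(full)
    if hits.size == 0:
        return None
    return float(hits[0] / signal.fs)


class ContractionDetector(BaseEstimator):
    """Detect ultrasound-visible contractions against a baseline-learned threshold.

    Parameters
    ----------
    multiplier : float, default 3.0
        Threshold multiplier; the NPD threshold is baseline mean + 3 SD.
    window_s : float, default 0.25
        Peak verification window (seconds).
    fraction : float, default 0.70
        Fraction of window samples that must exceed the threshold.
    min_quiet_s : float, default 0.25
        Minimum continuous sub-threshold ("tensed") interval between the
        contraction and relaxation peaks.

    Attributes
    ----------
    threshold_ : ActivationThreshold
        Learned from the baseline passed to :meth:`fit`.
    """

    def __init__(
        self,
        multiplier: float = 3.0,
        window_s: float = 0.25,
        fraction: float = 0.70,
        min_quiet_s: float = 0.25,
    ):
        self.multiplier = multiplier
        self.window_s = window_s
        self.fraction = fraction
        self.min_quiet_s = min_quiet_s

    def fit(self, X, y=None) -> "ContractionDetector":
        """Learn the activation threshold from a resting baseline NPD series."""
        self.threshold_ = baseline_threshold(X, self.multiplier)
        return self

    def predict(
        self, X: NPDSeries, cues: list[float] | None = None, search_ends=None
    ) -> list[ContractionEvent | None]:
        """Detect one contraction per cue (default: a single cue at t=0).

        ``search_ends`` defaults to the next cue onset (end of recording for
        the last cue).
        """
        if not hasattr(self, "threshold_"):
            raise RuntimeError("ContractionDetector must be fitted first")
        if cues is None:
            cues = [0.0]
        if search_ends is None:
            end_of_rec = float(X.times[-1]) + 1.0 / X.fps
            search_ends = list(cues[1:]) + [end_of_rec]
        return [
            detect_contraction(
                X,
                self.threshold_,
                cue,
                end,
                window_s=self.window_s,
                fraction=self.fraction,
                min_quiet_s=self.min_quiet_s,
            )
            for cue, end in zip(cues, search_ends)
        ]


class SustainedActivationDetector(BaseEstimator):
    """Detect sustained EMG/torque activations (mean + 2 SD, 1 s hold).

    ``fit`` expects the already-preprocessed baseline (EMG envelope or
    smoothed torque); :meth:`predict` returns the onset time per signal,
    or ``None``.
    """

    def __init__(self, multiplier: float = 2.0, hold_s: float = 1.0):
        self.multiplier = multiplier
        self.hold_s = hold_s

    def fit(self, X, y=None) -> "SustainedActivationDetector":
        self.threshold_ = baseline_threshold(X, self.multiplier)
        return self

    def predict(self, X: SampledSignal) -> float | None:
        if not hasattr(self, "threshold_"):
            raise RuntimeError("SustainedActivationDetector must be fitted first")
        return detect_sustained_activation(X, self.threshold_, self.hold_s)
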