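"""Seeded synthetic ultrasound video, EMG, and torque with known ground truth.

The video generator emulates what the frame-differencing statistic actually
sees in B-mode recordings of a contracting muscle: a persistent speckle-like
texture that shears and translates briefly at contraction onset and again at
relaxation (aponeurosis shear and pennation-angle change), stays almost
still while the muscle holds tension, and shows small sub-pixel jitter plus
per-pixel noise at rest.  It is deliberately not a physical beam/speckle
simulation — additive Gaussian noise on a band-limited texture is enough to
give the NPD series the statistical structure the detector assumes
(a stochastic resting baseline, two transient peaks per contraction).

All generators are pure functions of their parameters and a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates
from scipy.signal import lfilter

from .detection import SampledSignal
from .npd import FrameSequence, ROIPolygon

__all__ = [
    "ActivationProfile",
    "UsSimParams",
    "CueSchedule",
    "simulate_us_video",
    "simulate_emg",
    "simulate_torque",
    "generate_cue_schedule",
    "default_muscle_region",
]


@dataclass
class ActivationProfile:
    """Ground-truth activation: non-overlapping (onset_s, offset_s, intensity) events."""

    events: list[tuple[float, float, float]]
    duration_s: float

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration must be positive")
        prev_end = 0.0
        for onset, offset, intensity in self.events:
            if not 0.0 <= onset < offset <= self.duration_s:
                raise ValueError(
                    f"event ({onset}, {offset}) outside [0, {self.duration_s}] or empty"
                )
            if onset < prev_end:
                raise ValueError("events must be ordered and non-overlapping")
            if not 0.0 <= intensity <= 1.0:
                raise ValueError("intensity must lie in [0, 1]")
            prev_end = offset

    def activation(self, t: np.ndarray, rise_s: float = 0.1) -> np.ndarray:
        """Activation level over time with linear rise/decay edges of ``rise_s``."""
        act = np.zeros_like(t, dtype=np.float64)
        for onset, offset, intensity in self.events:
            up = np.clip((t - onset) / rise_s, 0.0, 1.0)
            down = np.clip((offset + rise_s - t) / rise_s, 0.0, 1.0)
            act = np.maximum(act, intensity * np.minimum(up, down))
        return act


def default_muscle_region(height: int = 128, width: int = 128) -> ROIPolygon:
    """Trapezoid over the simulated muscle belly (mirrors a manual ROI)."""
    return ROIPolygon(
        vertices=[
            (0.12 * width, 0.30 * height),
            (0.88 * width, 0.35 * height),
            (0.82 * width, 0.75 * height),
            (0.15 * width, 0.70 * height),
        ]
    )


@dataclass
class UsSimParams:
    """Knobs of the synthetic B-mode video generator.

    ``rest_jitter_px`` is the SD (pixels/frame) of the sub-pixel tissue
    jitter at rest; ``contraction_shift_px`` the per-frame directional shift
    during a transition at full intensity; ``transition_s`` the duration of
    the shear/translation burst at each contraction onset and offset.
    """

    height: int = 128
    width: int = 128
    fps: float = 40.0
    muscle_region: ROIPolygon | None = None
    speckle_sigma: float = 0.02
    rest_jitter_px: float = 0.05
    contraction_shift_px: float = 1.5
    texture_corr_len_px: float = 3.0
    transition_s: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.speckle_sigma < 0 or self.rest_jitter_px < 0 or self.contraction_shift_px < 0:
            raise ValueError("noise and shift magnitudes must be non-negative")
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if self.muscle_region is None:
            self.muscle_region = default_muscle_region(self.height, self.width)


@dataclass
class CueSchedule:
    """Cue onsets (seconds) with a fixed cue duration and total length."""

    onsets: np.ndarray
    cue_s: float
    duration_s: float

    def __post_init__(self) -> None:
        self.onsets = np.asarray(self.onsets, dtype=np.float64)

    def to_profile(self, intensity: float = 0.3, pad_s: float = 2.0) -> ActivationProfile:
        """Ground-truth profile with one contraction per cue.

        ``pad_s`` extends the recording past the last cue so the final
        relaxation transient is fully captured.
        """
        events = [(float(t), float(t + self.cue_s), intensity) for t in self.onsets]
        return ActivationProfile(events=events, duration_s=self.duration_s + pad_s)


def _displacement_trace(
    profile: ActivationProfile, n_frames: int, fps: float,
    shift_px: float, transition_s: float,
) -> np.ndarray:
    """Cumulative directional displacement (px) per frame.

    Ramps up by ``shift_px * intensity`` per frame over the transition window
    at each event onset, holds while the muscle is tensed, and ramps back
    down over the transition window at the offset.
    """
    cum = np.zeros(n_frames)
    n_trans = max(1, round(transition_s * fps))
    for onset_s, offset_s, intensity in profile.events:
        on_f = round(onset_s * fps)
        off_f = round(offset_s * fps)
        step = shift_px * intensity
        ramp = np.arange(1, n_trans + 1) * step
        plateau = ramp[-1]
        for f in range(on_f, min(off_f, n_frames)):
            k = f - on_f
            cum[f] += ramp[k] if k < n_trans else plateau
        for f in range(off_f, n_frames):
            k = f - off_f
            cum[f] += plateau - ramp[k] if k < n_trans else 0.0
    return cum


def simulate_us_video(
    profile: ActivationProfile, params: UsSimParams
) -> tuple[FrameSequence, list[dict]]:
    """Render a synthetic B-mode sequence for an activation profile.

    Returns the frame sequence and the ground-truth transition frames
    (``{"onset_frame", "offset_frame", "intensity"}`` per event).
    """
    rng = np.random.default_rng(params.seed)
    h, w, fps = params.height, params.width, params.fps
    n_frames = round(profile.duration_s * fps)
    if n_frames < 2:
        raise ValueError("profile too short for a video at this frame rate")

    # Static band-limited texture: smoothed white noise rescaled to mid-gray.
    texture = gaussian_filter(rng.standard_normal((h, w)), params.texture_corr_len_px)
    texture = 0.5 + 0.15 * texture / texture.std()
    texture = np.clip(texture, 0.05, 0.95)

    # Motion confined to the muscle region via a feathered weight field, with
    # a mild depth gradient so the region shears rather than translating rigidly.
    from .npd import rasterize_roi

    region = rasterize_roi(params.muscle_region, h, w)
    weight = gaussian_filter(region.mask.astype(np.float64), 2.0)
    rows = np.arange(h)[:, None] / max(h - 1, 1)
    shear = (0.6 + 0.8 * rows) * weight  # deeper tissue moves more
    ux, uy = 0.8, 0.6  # unit direction of the contraction shift

    cum = _displacement_trace(
        profile, n_frames, fps, params.contraction_shift_px, params.transition_s
    )
    jitter = rng.normal(0.0, params.rest_jitter_px, size=(n_frames, 2))
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)

    frames = np.empty((n_frames, h, w))
    for t in range(n_frames):
        dx = cum[t] * ux + jitter[t, 0]
        dy = cum[t] * uy + jitter[t, 1]
        if dx == 0.0 and dy == 0.0:
            warped = texture
        else:
            warped = map_coordinates(
                texture, [yy - dy * shear, xx - dx * shear], order=1, mode="reflect"
            )
        frames[t] = warped
    if params.speckle_sigma > 0:
        frames += rng.normal(0.0, params.speckle_sigma, size=frames.shape)
    np.clip(frames, 0.0, 1.0, out=frames)

    truth = [
        {
            "onset_frame": round(onset * fps),
            "offset_frame": round(offset * fps),
            "intensity": intensity,
        }
        for onset, offset, intensity in profile.events
    ]
    return FrameSequence(frames=frames, fps=fps), truth


def simulate_emg(
    profile: ActivationProfile,
    fs: float = 1200.0,
    gain: float = 0.2,
    noise_sd: float = 0.01,
    seed: int = 0,
) -> SampledSignal:
    """Amplitude-modulated Gaussian noise EMG (volts).

    The carrier is zero-mean broadband noise whose instantaneous amplitude is
    ``noise_sd + gain * activation(t)``; activation rises and decays over
    ~100 ms at event edges.
    """
    if fs <= 1000:
        raise ValueError("EMG sampling rate must exceed 1000 Hz (500 Hz band edge)")
    rng = np.random.default_rng(seed)
    t = np.arange(round(profile.duration_s * fs)) / fs
    amplitude = noise_sd + gain * profile.activation(t, rise_s=0.1)
    return SampledSignal(values=rng.standard_normal(len(t)) * amplitude, fs=fs)


def simulate_torque(
    profile: ActivationProfile,
    fs: float = 1000.0,
    mvc_torque: float = 100.0,
    noise_sd: float = 0.5,
    seed: int = 0,
    tau_s: float = 0.15,
) -> SampledSignal:
    """Plantarflexion torque (N·m): first-order lag of the activation plus noise."""
    rng = np.random.default_rng(seed)
    t = np.arange(round(profile.duration_s * fs)) / fs
    target = np.zeros_like(t)
    for onset, offset, intensity in profile.events:
        target[(t >= onset) & (t < offset)] = mvc_torque * intensity
    a = 1.0 - np.exp(-1.0 / (fs * tau_s))  # discrete first-order lag, tau ~ 150 ms
    lagged = lfilter([a], [1.0, a - 1.0], target)
    return SampledSignal(values=lagged + rng.normal(0.0, noise_sd, len(t)), fs=fs)


def generate_cue_schedule(
    n_trials: int,
    cue_s: float = 2.5,
    inter_trial_range_s: tuple[float, float] = (3.0, 5.5),
    seed: int = 0,
) -> CueSchedule:
    """Cue onsets with i.i.d. uniform inter-trial rest gaps before each cue."""
    if n_trials < 1:
        raise ValueError("need at least one trial")
    lo, hi = inter_trial_range_s
    if not 0 < lo <= hi:
        raise ValueError("inter-trial range must be positive and ordered")
    rng = np.random.default_rng(seed)
    gaps = rng.uniform(lo, hi, size=n_trials)
    onsets = np.cumsum(gaps + cue_s) - cue_s
    return CueSchedule(onsets=onsets, cue_s=cue_s, duration_s=float(onsets[-1] + cue_s))
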