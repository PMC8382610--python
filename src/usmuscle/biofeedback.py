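"""MVC-normalized trial feedback: peak NPD, target bands, session summaries.

After each cued trial the peak of the NPD series is taken over the recorded
window, normalized to the peak reached during the maximum voluntary
contraction (MVC) test, and compared with a target intensity.  A trial is
*successful* when the normalized peak lies within 10% of the target,
*acceptable* within 20%, and *unsuccessful* otherwise; by default the bands
are relative to the target value (a target of 0.60 is hit successfully
anywhere in [0.54, 0.66]), with an absolute-band mode available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from .npd import NPDSeries

__all__ = [
    "TrialProtocol",
    "TrialResult",
    "TrialClassifier",
    "peak_npd",
    "normalize_to_mvc",
    "classify_trial",
    "session_summary",
    "CLASSES",
]

CLASSES = ("successful", "acceptable", "unsuccessful")


@dataclass
class TrialProtocol:
    """Timing of one cued trial: rest, preparation, execution, rest (12 s total)."""

    rest_pre_s: float = 2.0
    prep_s: float = 1.0
    execute_s: float = 4.0
    rest_post_s: float = 5.0

    def __post_init__(self) -> None:
        for name in ("rest_pre_s", "prep_s", "execute_s", "rest_post_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def total_s(self) -> float:
        return self.rest_pre_s + self.prep_s + self.execute_s + self.rest_post_s

    @property
    def video_window_s(self) -> tuple[float, float]:
        """Recorded video window: preparation + execution (5 s by default)."""
        return (self.rest_pre_s, self.rest_pre_s + self.prep_s + self.execute_s)


@dataclass
class TrialResult:
    peak_npd: float
    normalized: float
    target: float
    abs_diff: float
    classification: str

    def to_dict(self) -> dict:
        return {
            "peak_npd": self.peak_npd,
            "normalized": self.normalized,
            "target": self.target,
            "abs_diff": self.abs_diff,
            "classification": self.classification,
        }


def peak_npd(npd: NPDSeries, window_start_s: float, window_end_s: float) -> float:
    """Maximum NPD value within ``[window_start_s, window_end_s)``."""
    times = npd.times
    sel = (times >= window_start_s) & (times < window_end_s)
    if not sel.any():
        raise ValueError("trial window contains no NPD samples")
    return float(npd.values[sel].max())


def normalize_to_mvc(peak: float, mvc_peak: float) -> float:
    """Express a trial peak as a fraction of the MVC-test peak (may exceed 1)."""
    if mvc_peak <= 0:
        raise ValueError("MVC peak must be positive; run MVC calibration first")
    return peak / mvc_peak


def classify_trial(normalized: float, target: float, inner: float = 0.10,
                   outer: float = 0.20, mode: str = "relative") -> str:
    """Assign a feedback band to an MVC-normalized trial peak.

    With the default relative bands, the deviation is
    ``r = |normalized - target| / target``; ``r <= inner`` is successful,
    ``inner < r <= outer`` acceptable, else unsuccessful.  In ``absolute``
    mode the deviation is not divided by the target.  Boundaries are
    inclusive toward the better class.
    """
    if target <= 0:
        raise ValueError("target must be positive")
    if not 0 < inner <= outer:
        raise ValueError("band widths must satisfy 0 < inner <= outer")
    if mode not in ("relative", "absolute"):
        raise ValueError(f"unknown band mode {mode!r}")
    r = abs(normalized - target)
    if mode == "relative":
        r /= target
    if r <= inner:
        return "successful"
    if r <= outer:
        return "acceptable"
    return "unsuccessful"


def session_summary(trials: list[TrialResult]) -> tuple[float, float, float]:
    """Quartiles (25%, median, 75%) of |normalized - target| across trials.

    Uses the linear-interpolation quantile definition.
    """
    if not trials:
        raise ValueError("session summary requires at least one trial")
    diffs = np.array([t.abs_diff for t in trials])
    q25, q50, q75 = np.quantile(diffs, [0.25, 0.50, 0.75])
    return float(q25), float(q50), float(q75)


class TrialClassifier(BaseEstimator):
    """Classify trial peaks into successful / acceptable / unsuccessful bands.

    Parameters
    ----------
    target : float
        Target intensity on the MVC-normalized scale.
    inner, outer : float, default 0.10 / 0.20
        Band half-widths (successful / acceptable).
    mode : {"relative", "absolute"}, default "relative"
        Whether band widths are fractions of the target or of the
        normalized scale itself.

    Attributes
    ----------
    mvc_peak_ : float
        Maximum peak NPD over the MVC attempts, set by :meth:`fit`.
    """

    def __init__(self, target: float | None = None, inner: float = 0.10,
                 outer: float = 0.20, mode: str = "relative"):
        self.target = target
        self.inner = inner
        self.outer = outer
        self.mode = mode

    def fit(self, X, y=None) -> "TrialClassifier":
        """Calibrate from the MVC test: ``X`` is the peak NPD of each attempt."""
        peaks = np.asarray(X, dtype=np.float64).ravel()
        if peaks.size < 1:
            raise ValueError("MVC calibration needs at least one attempt")
        self.mvc_peak_ = float(peaks.max())
        if self.mvc_peak_ <= 0:
            raise ValueError("MVC peak must be positive")
        return self

    def predict(self, X) -> list[str]:
        """Band labels for raw trial peak NPD values."""
        return [t.classification for t in self.evaluate(X)]

    def evaluate(self, X) -> list[TrialResult]:
        """Full :class:`TrialResult` records for raw trial peak NPD values."""
        if not hasattr(self, "mvc_peak_"):
            raise RuntimeError("TrialClassifier must be fitted on MVC peaks first")
        if self.target is None or self.target <= 0:
            raise ValueError("a positive target must be configured")
        results = []
        for peak in np.asarray(X, dtype=np.float64).ravel():
            norm = normalize_to_mvc(float(peak), self.mvc_peak_)
            results.append(
                TrialResult(
                    peak_npd=float(peak),
                    normalized=norm,
                    target=self.target,
                    abs_diff=abs(norm - self.target),
                    classification=classify_trial(
                        norm, self.target, self.inner, self.outer, self.mode
                    ),
                )
            )
        return results


def target_from_training(training_peaks, mvc_peak: float) -> float:
    """Target intensity: mean of training-trial peaks, MVC-normalized."""
    peaks = np.asarray(training_peaks, dtype=np.float64)
    if peaks.size < 1:
        raise ValueError("need at least one training trial")
    return float(np.mean([normalize_to_mvc(p, mvc_peak) for p in peaks]))
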