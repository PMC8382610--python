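"""Normalized pixel difference (NPD) extraction from B-mode ultrasound video.

The NPD of a frame transition is the mean absolute per-pixel intensity change
between two adjacent grayscale frames, restricted to a region of interest (ROI)
drawn over the muscle belly:

    NPD(i) = sum_{p in ROI} |A(i)_p - A(i-1)_p| / |ROI|

with intensities on [0, 1].  Because the statistic averages over the whole ROI,
uncorrelated speckle largely cancels and the series responds to coherent tissue
motion (fascicle shear at contraction onset and relaxation) rather than noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely
from shapely.geometry import Polygon as _ShapelyPolygon
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "FrameSequence",
    "ROIPolygon",
    "ROIMask",
    "NPDSeries",
    "NPDExtractor",
    "to_grayscale",
    "rasterize_roi",
    "frame_difference",
    "compute_npd",
]

# BT.601 luma weights, the de facto standard for video grayscale conversion.
_BT601 = np.array([0.299, 0.587, 0.114])


class EmptyROIError(ValueError):
    """The ROI polygon covers no pixel centers of the frame grid."""


@dataclass
class FrameSequence:
    """Ordered grayscale frames with a frame rate.

    Parameters
    ----------
    frames : ndarray, shape (n_frames, height, width)
        Intensities on [0, 1].
    fps : float
        Frame rate in frames per second (nominally 40 for the supported
        ultrasound recordings, but any positive rate is accepted; all
        duration parameters downstream are specified in seconds).
    """

    frames: np.ndarray
    fps: float

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float64)
        if self.frames.ndim != 3:
            raise ValueError(
                f"frames must be 3-D (n_frames, height, width), got ndim={self.frames.ndim}"
            )
        if not (self.frames.min(initial=0.0) >= 0.0 and self.frames.max(initial=0.0) <= 1.0):
            raise ValueError("frame intensities must lie in [0, 1]")
        if not self.fps > 0:
            raise ValueError(f"fps must be positive, got {self.fps}")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def height(self) -> int:
        return self.frames.shape[1]

    @property
    def width(self) -> int:
        return self.frames.shape[2]


@dataclass
class ROIPolygon:
    """Simple polygon in pixel coordinates (x = column, y = row, origin top-left)."""

    vertices: list[tuple[float, float]]

    def __post_init__(self) -> None:
        self.vertices = [(float(x), float(y)) for x, y in self.vertices]
        if len(self.vertices) < 3:
            raise ValueError("polygon needs at least 3 vertices")
        poly = _ShapelyPolygon(self.vertices)
        if not poly.is_valid:
            raise ValueError("polygon must be simple (non-self-intersecting)")
        if poly.area == 0:
            raise EmptyROIError("polygon has zero area")

    def as_shapely(self) -> _ShapelyPolygon:
        return _ShapelyPolygon(self.vertices)


@dataclass
class ROIMask:
    """Rasterized ROI: boolean grid plus the pixel count (the M×N of the NPD mean)."""

    mask: np.ndarray
    pixel_count: int = field(init=False)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2-D")
        self.pixel_count = int(self.mask.sum())
        if self.pixel_count < 1:
            raise EmptyROIError("ROI mask selects no pixels")


@dataclass
class NPDSeries:
    """Per-frame-transition NPD values.

    ``values[k]`` is the NPD of the transition into frame ``k + frame_offset``
    of the source video; with the default ``frame_offset = 1`` the series has
    ``n_frames - 1`` entries and sample k is timestamped at the later frame,
    ``t = (k + 1) / fps``.
    """

    values: np.ndarray
    fps: float
    frame_offset: int = 1

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 1:
            raise ValueError("NPD values must be 1-D")
        if not self.fps > 0:
            raise ValueError("fps must be positive")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def times(self) -> np.ndarray:
        """Timestamps in seconds (at the later frame of each transition)."""
        return (np.arange(len(self.values)) + self.frame_offset) / self.fps

    def index_at(self, t_s: float) -> int:
        """First sample index whose timestamp is >= ``t_s`` (clipped to range)."""
        idx = int(np.searchsorted(self.times, t_s, side="left"))
        return min(idx, len(self.values))


def to_grayscale(rgb_frame: np.ndarray) -> np.ndarray:
    """Convert an 8-bit RGB frame to grayscale on [0, 1] (BT.601 luma / 255)."""
    rgb = np.asarray(rgb_frame, dtype=np.float64)
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise ValueError(f"expected an (H, W, 3) RGB frame, got shape {rgb.shape}")
    if rgb.min() < 0 or rgb.max() > 255:
        raise ValueError("RGB channel values must lie in [0, 255]")
    return rgb @ _BT601 / 255.0


def rasterize_roi(polygon: ROIPolygon, height: int, width: int) -> ROIMask:
    """Rasterize a polygon over the frame grid by pixel-center inclusion.

    A pixel (row r, column c) is inside iff the point (c, r) lies inside the
    polygon or on its boundary (``covers`` predicate), so boundary ties are
    deterministically counted as inside.
    """
    if height < 1 or width < 1:
        raise ValueError("frame dimensions must be >= 1")
    poly = polygon.as_shapely()
    cols, rows = np.meshgrid(np.arange(width), np.arange(height))
    pts = shapely.points(cols.ravel(), rows.ravel())
    inside = shapely.covers(poly, pts).reshape(height, width)
    if not inside.any():
        raise EmptyROIError("polygon covers no pixel centers within the frame")
    return ROIMask(mask=inside)


def frame_difference(frame_b: np.ndarray, frame_a: np.ndarray, mask: ROIMask) -> np.ndarray:
    """Signed per-pixel difference ``frame_b - frame_a`` over the masked pixels."""
    a = np.asarray(frame_a, dtype=np.float64)
    b = np.asarray(frame_b, dtype=np.float64)
    if a.shape != b.shape or a.shape != mask.mask.shape:
        raise ValueError(
            f"shape mismatch: frames {a.shape}/{b.shape} vs mask {mask.mask.shape}"
        )
    return (b - a)[mask.mask]


def compute_npd(seq: FrameSequence, mask: ROIMask) -> NPDSeries:
    """Compute the NPD series of a video: mean |Δintensity| per masked pixel.

    Raises
    ------
    ValueError
        If the video has fewer than 2 frames.
    EmptyROIError
        If the mask selects no pixels or does not match the frame grid.
    """
    if seq.n_frames < 2:
        raise ValueError("need at least 2 frames to compute frame differences")
    if mask.mask.shape != (seq.height, seq.width):
        raise ValueError(
            f"mask shape {mask.mask.shape} does not match frames "
            f"({seq.height}, {seq.width})"
        )
    roi = seq.frames[:, mask.mask]  # (n_frames, pixel_count)
    values = np.abs(np.diff(roi, axis=0)).mean(axis=1)
    return NPDSeries(values=values, fps=seq.fps)


class NPDExtractor(TransformerMixin, BaseEstimator):
    """Transformer turning ultrasound videos into NPD series.

    Parameters
    ----------
    roi : ROIPolygon or list of (x, y) vertices
        Region of interest over the muscle belly, excluding aponeuroses.

    Attributes
    ----------
    mask_ : ROIMask
        Rasterized ROI, set by :meth:`fit` against a video's frame grid.
    n_pixels_ : int
        Number of ROI pixels (the normalization constant of the NPD mean).
    """

    def __init__(self, roi=None):
        self.roi = roi

    def _as_polygon(self) -> ROIPolygon:
        if isinstance(self.roi, ROIPolygon):
            return self.roi
        if self.roi is None:
            raise ValueError("roi must be set before fitting")
        return ROIPolygon(vertices=list(self.roi))

    def fit(self, X: FrameSequence, y=None) -> "NPDExtractor":
        """Rasterize the ROI against the frame grid of ``X``."""
        self.mask_ = rasterize_roi(self._as_polygon(), X.height, X.width)
        self.n_pixels_ = self.mask_.pixel_count
        return self

    def transform(self, X: FrameSequence) -> NPDSeries:
        """Compute the NPD series of ``X`` under the fitted ROI mask."""
        if not hasattr(self, "mask_"):
            raise RuntimeError("NPDExtractor must be fitted before transform")
        return compute_npd(X, self.mask_)
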