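"""File formats: raw-binary video stream, AVI, ROI JSON, signal CSV, results JSON.

The raw video stream ("USRW") is a minimal little-endian container for
per-frame grayscale rasters, mirroring the raw-binary path ultrasound
acquisition software exposes for semi-real-time processing:

    magic  4 bytes  b"USRW"
    height uint32   pixels
    width  uint32   pixels
    n      uint32   frame count
    fps    float32  frames/second
    data   n * height * width uint8 rasters, row-major, frame-contiguous
"""

from __future__ import annotations

import json
import struct
from pathlib import Path

import numpy as np
import pandas as pd

from .biofeedback import TrialResult
from .detection import ContractionEvent, SampledSignal
from .npd import FrameSequence, NPDSeries, ROIPolygon, to_grayscale

__all__ = [
    "write_raw_video",
    "read_raw_video",
    "read_avi",
    "read_roi_json",
    "write_roi_json",
    "write_npd_csv",
    "read_npd_csv",
    "write_signal_csv",
    "read_signal_csv",
    "write_events_json",
    "read_events_json",
    "write_results_json",
]

_MAGIC = b"USRW"
_HEADER = struct.Struct("<4sIIIf")


def write_raw_video(seq: FrameSequence, path) -> None:
    """Write a frame sequence as a USRW stream (intensities quantized to 8 bit)."""
    data = np.round(np.clip(seq.frames, 0.0, 1.0) * 255.0).astype(np.uint8)
    with open(path, "wb") as fh:
        fh.write(_HEADER.pack(_MAGIC, seq.height, seq.width, seq.n_frames, seq.fps))
        fh.write(data.tobytes())


def read_raw_video(path) -> FrameSequence:
    """Read a USRW stream back into a FrameSequence (intensities on [0, 1])."""
    with open(path, "rb") as fh:
        header = fh.read(_HEADER.size)
        if len(header) < _HEADER.size:
            raise IOError(f"{path}: truncated header")
        magic, height, width, n, fps = _HEADER.unpack(header)
        if magic != _MAGIC:
            raise IOError(f"{path}: not a USRW raw video stream")
        payload = fh.read(n * height * width)
    if len(payload) != n * height * width:
        raise IOError(f"{path}: truncated frame data")
    frames = (
        np.frombuffer(payload, dtype=np.uint8)
        .reshape(n, height, width)
        .astype(np.float64)
        / 255.0
    )
    return FrameSequence(frames=frames, fps=float(fps))


def read_avi(path, fps_override: float | None = None) -> FrameSequence:
    """Read an AVI through imageio (whatever codec the ambient decoder supports).

    RGB frames are converted with BT.601 luma; already-grayscale frames are
    scaled from [0, 255].
    """
    import imageio.v3 as iio

    try:
        stack = iio.imread(path, index=None)
        meta = iio.immeta(path)
    except Exception as exc:  # pragma: no cover - decoder availability varies
        raise IOError(f"{path}: cannot decode video ({exc})") from exc
    fps = fps_override or float(meta.get("fps", 40.0))
    frames = [
        to_grayscale(f) if f.ndim == 3 else np.asarray(f, dtype=np.float64) / 255.0
        for f in stack
    ]
    return FrameSequence(frames=np.stack(frames), fps=fps)


def read_roi_json(path) -> ROIPolygon:
    """ROI polygon file: ``{"vertices": [[x, y], ...]}``, 0-based pixel coords."""
    with open(path) as fh:
        obj = json.load(fh)
    if "vertices" not in obj:
        raise IOError(f"{path}: ROI JSON must contain a 'vertices' list")
    return ROIPolygon(vertices=[tuple(v) for v in obj["vertices"]])


def write_roi_json(roi: ROIPolygon, path) -> None:
    with open(path, "w") as fh:
        json.dump({"vertices": [list(v) for v in roi.vertices]}, fh)
        fh.write("\n")


def _fmt(x: float) -> str:
    return f"{x:.9g}"


def write_npd_csv(npd: NPDSeries, path) -> None:
    """NPD series CSV: frame_index, time_s, npd (9 significant digits)."""
    times = npd.times
    with open(path, "w") as fh:
        fh.write("frame_index,time_s,npd\n")
        for k, (t, v) in enumerate(zip(times, npd.values)):
            fh.write(f"{k + npd.frame_offset},{_fmt(t)},{_fmt(v)}\n")


def read_npd_csv(path) -> NPDSeries:
    df = pd.read_csv(path)
    for col in ("frame_index", "time_s", "npd"):
        if col not in df.columns:
            raise IOError(f"{path}: NPD CSV missing column {col!r}")
    if len(df) < 2:
        raise IOError(f"{path}: NPD CSV too short to infer the frame rate")
    dt = float(np.diff(df["time_s"]).mean())
    offset = int(df["frame_index"].iloc[0])
    return NPDSeries(values=df["npd"].to_numpy(), fps=1.0 / dt, frame_offset=offset)


def write_signal_csv(signal: SampledSignal, path) -> None:
    """Sampled signal CSV: ``time_s,value`` rows (fs recoverable from time_s)."""
    with open(path, "w") as fh:
        fh.write("time_s,value\n")
        for t, v in zip(signal.times, signal.values):
            fh.write(f"{_fmt(t)},{_fmt(v)}\n")


def read_signal_csv(path, fs: float | None = None) -> SampledSignal:
    df = pd.read_csv(path)
    for col in ("time_s", "value"):
        if col not in df.columns:
            raise IOError(f"{path}: signal CSV missing column {col!r}")
    if fs is None:
        if len(df) < 2:
            raise IOError(f"{path}: cannot infer sampling rate from one sample")
        fs = 1.0 / float(np.diff(df["time_s"]).mean())
    return SampledSignal(values=df["value"].to_numpy(), fs=fs)


def write_events_json(events, threshold, path) -> None:
    """Detected contraction events with the threshold that produced them."""
    payload = {
        "threshold": {
            "baseline_mean": threshold.baseline_mean,
            "baseline_sd": threshold.baseline_sd,
            "multiplier": threshold.multiplier,
            "value": threshold.value,
        },
        "events": [e.to_dict() if e is not None else None for e in events],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
        fh.write("\n")


def read_events_json(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def write_results_json(results: list[TrialResult], path) -> None:
    with open(path, "w") as fh:
        json.dump([r.to_dict() for r in results], fh, indent=1)
        fh.write("\n")


def write_ground_truth_json(truth: list[dict], schedule, path) -> None:
    """Ground-truth events and cue onsets of a simulated session."""
    payload = {
        "cue_onsets_s": [float(t) for t in schedule.onsets],
        "cue_s": schedule.cue_s,
        "duration_s": schedule.duration_s,
        "events": truth,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
        fh.write("\n")
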