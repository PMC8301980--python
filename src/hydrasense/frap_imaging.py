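"""Extraction and normalization of recovery traces from FRAP image stacks.

A FRAP acquisition is a single-channel time-lapse: a few pre-bleach frames,
an instantaneous bleach of a circular spot, then recovery frames at a fixed
interval.  The bleached-spot trace is normalized against the rest of the
field (which sees the same acquisition photobleaching but not the bleach
pulse) and against its own pre-bleach level, yielding a trace on which the
pre-bleach intensity is exactly 1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile
import yaml

from hydrasense.frap_model import NoBleachError, RecoveryTrace

__all__ = [
    "FrapStack",
    "detect_bleach_frame",
    "extract_trace",
    "extract_reference_trace",
    "normalize_trace",
    "stack_to_trace",
    "read_stack",
    "write_stack",
]


@dataclass(frozen=True)
class FrapStack:
    """Single-channel FRAP image time series with geometry metadata.

    frames: (time, rows, cols) non-negative intensities.
    pixel_size: um per pixel.  frame_interval: s.
    bleach_frame_index: index of the first post-bleach frame (>= 1).
    roi_center: (row, col) in pixels; roi_radius in pixels.
    """

    frames: np.ndarray
    pixel_size: float
    frame_interval: float
    bleach_frame_index: int
    roi_center: tuple[float, float]
    roi_radius: float

    def __post_init__(self):
        frames = np.asarray(self.frames, dtype=float)
        if frames.ndim != 3:
            raise ValueError("frames must be a (time, rows, cols) array")
        if np.any(frames < 0):
            raise ValueError("intensities must be non-negative")
        if not (self.pixel_size > 0 and self.frame_interval > 0):
            raise ValueError("pixel_size and frame_interval must be > 0")
        if not 1 <= self.bleach_frame_index < frames.shape[0]:
            raise ValueError("bleach_frame_index needs >= 1 pre-bleach frame")
        r, c = self.roi_center
        nr, nc = frames.shape[1:]
        if not (
            r - self.roi_radius >= -0.5
            and c - self.roi_radius >= -0.5
            and r + self.roi_radius <= nr - 0.5
            and c + self.roi_radius <= nc - 0.5
        ):
            raise ValueError("ROI disk must lie fully inside the frame")
        object.__setattr__(self, "frames", frames)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def roi_mask(self, guard: float = 0.0) -> np.ndarray:
        """Boolean mask of pixels whose centers lie within roi_radius
        (optionally inflated by ``guard`` pixels) of roi_center."""
        nr, nc = self.frames.shape[1:]
        rr, cc = np.ogrid[:nr, :nc]
        r0, c0 = self.roi_center
        return (rr - r0) ** 2 + (cc - c0) ** 2 <= (self.roi_radius + guard) ** 2


def detect_bleach_frame(stack: FrapStack) -> int:
    """Locate the first post-bleach frame as the largest single-step drop
    of the mean ROI intensity.

    The drop must exceed 3x the SD of the remaining inter-frame steps;
    otherwise a :class:`NoBleachError` is raised.  Ties break to the
    earliest frame.
    """
    if stack.n_frames < 3:
        raise ValueError("need at least 3 frames to detect a bleach")
    means = stack.frames[:, stack.roi_mask()].mean(axis=1)
    steps = np.diff(means)
    idx = int(np.argmin(steps))  # most negative step; argmin = earliest tie
    others = np.delete(steps, idx)
    noise_sd = float(np.std(others))
    if not steps[idx] < -3.0 * noise_sd or steps[idx] >= 0:
        raise NoBleachError("no inter-frame drop exceeding 3x the step noise SD")
    return idx + 1


def extract_trace(stack: FrapStack) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame arithmetic mean over the bleach-spot ROI.

    Returns ``(times, means)`` over all frames; post-bleach frames are
    timed mid-exposure, ``(k - bleach_frame_index + 0.5) * frame_interval``.
    """
    mask = stack.roi_mask()
    if not mask.any():
        raise ValueError("ROI contains no pixel centers")
    means = stack.frames[:, mask].mean(axis=1)
    k = np.arange(stack.n_frames)
    times = (k - stack.bleach_frame_index + 0.5) * stack.frame_interval
    return times, means


def extract_reference_trace(stack: FrapStack, guard: float = 0.0) -> np.ndarray:
    """Per-frame mean over the field outside the ROI disk.

    ``guard`` excludes an annulus of that many extra pixels around the ROI
    (default 0: the reference is everything except the bleached spot).
    """
    outside = ~stack.roi_mask(guard=guard)
    if not outside.any():
        raise ValueError("reference region is empty")
    return stack.frames[:, outside].mean(axis=1)


def normalize_trace(
    roi_trace: np.ndarray,
    reference_trace: np.ndarray,
    prebleach_frames: int,
    frame_interval: float,
) -> RecoveryTrace:
    """Double-normalize an ROI trace and return the post-bleach portion.

    (i) divide the ROI trace frame-wise by the reference trace, correcting
    global acquisition photobleaching; (ii) divide by the mean of the
    pre-bleach corrected values so the pre-bleach level is exactly 1.
    """
    roi = np.asarray(roi_trace, dtype=float)
    ref = np.asarray(reference_trace, dtype=float)
    if roi.shape != ref.shape:
        raise ValueError("ROI and reference traces must be equal length")
    if prebleach_frames < 1:
        raise ValueError("need at least one pre-bleach frame")
    if np.any(ref <= 0):
        raise ValueError("reference trace contains non-positive intensities")
    corrected = roi / ref
    pre = corrected[:prebleach_frames].mean()
    if pre <= 0:
        raise ValueError("pre-bleach level is non-positive")
    norm = corrected / pre
    post = norm[prebleach_frames:]
    times = (np.arange(post.size) + 0.5) * frame_interval
    return RecoveryTrace(times=times, intensities=np.clip(post, 0.0, None))


def stack_to_trace(stack: FrapStack, guard: float = 0.0) -> RecoveryTrace:
    """Full extraction pipeline: ROI mean, reference mean, double
    normalization; returns the normalized post-bleach RecoveryTrace."""
    _, roi = extract_trace(stack)
    ref = extract_reference_trace(stack, guard=guard)
    return normalize_trace(roi, ref, stack.bleach_frame_index, stack.frame_interval)


def _load_sidecar(path: Path) -> dict:
    text = path.read_text()
    if path.suffix in {".yaml", ".yml"}:
        return yaml.safe_load(text)
    return json.loads(text)


def read_stack(tiff_path: str | Path, sidecar_path: str | Path) -> FrapStack:
    """Read a multi-page single-channel TIFF plus its metadata sidecar.

    The sidecar (JSON or YAML) supplies pixel_size_um, frame_interval_s,
    bleach_frame_index, roi_center_row_px, roi_center_col_px and
    roi_radius_um; embedded TIFF tags are not trusted.
    """
    frames = tifffile.imread(str(tiff_path))
    meta = _load_sidecar(Path(sidecar_path))
    pixel_size = float(meta["pixel_size_um"])
    return FrapStack(
        frames=np.asarray(frames, dtype=float),
        pixel_size=pixel_size,
        frame_interval=float(meta["frame_interval_s"]),
        bleach_frame_index=int(meta["bleach_frame_index"]),
        roi_center=(float(meta["roi_center_row_px"]), float(meta["roi_center_col_px"])),
        roi_radius=float(meta["roi_radius_um"]) / pixel_size,
    )


def write_stack(stack: FrapStack, tiff_path: str | Path, sidecar_path: str | Path,
                extra_meta: dict | None = None) -> None:
    """Write a stack as 16-bit multi-page TIFF plus a JSON sidecar."""
    frames = stack.frames
    peak = frames.max()
    scale = 60000.0 / peak if peak > 0 else 1.0
    tifffile.imwrite(str(tiff_path), (frames * scale).astype(np.uint16))
    meta = {
        "pixel_size_um": stack.pixel_size,
        "frame_interval_s": stack.frame_interval,
        "bleach_frame_index": stack.bleach_frame_index,
        "roi_center_row_px": stack.roi_center[0],
        "roi_center_col_px": stack.roi_center[1],
        "roi_radius_um": stack.roi_radius * stack.pixel_size,
        "intensity_scale": scale,
    }
    if extra_meta:
        meta.update(extra_meta)
    Path(sidecar_path).write_text(json.dumps(meta, indent=2) + "\n")
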