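"""Real-time colour-threshold tracking pipeline.

The pipeline mirrors a typical closed-loop rig: each camera frame is cropped
to the tank interior, converted to HSV, thresholded with a per-subject HSV
range to isolate the fish body against the light tank floor, median-smoothed,
and reduced to a centroid.  Per-ROI binarized pixel sums drive zone-entry
detection, and the mean grey level of the screen-probe ROI records the task
epoch alongside the position data.

Hue uses the 0-179 half-degree convention; saturation and value are 0-255.
Hue ranges may wrap around the red point (``h_min > h_max``), which matters
for goldfish whose body hue sits near the wrap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import ndimage

from .arena import ArenaModel, roi_pixel_rect

__all__ = [
    "HsvRange",
    "TrackerConfig",
    "TrackSample",
    "crop_frame",
    "rgb_to_hsv",
    "binarize",
    "smooth_mask",
    "centroid",
    "roi_occupancy",
    "roi_pixel_count",
    "probe_luminance",
    "track_frame",
    "calibrate_entry_threshold",
]


@dataclass(frozen=True)
class HsvRange:
    """Inclusive HSV bounds; the hue interval is circular."""

    h_min: int
    h_max: int
    s_min: int = 0
    s_max: int = 255
    v_min: int = 0
    v_max: int = 255

    def __post_init__(self) -> None:
        if self.s_min > self.s_max or self.v_min > self.v_max:
            raise ValueError("min must be <= max for saturation and value")
        for v in (self.h_min, self.h_max):
            if not 0 <= v <= 179:
                raise ValueError("hue bounds must lie in [0, 179]")


# default matches an orange-bodied fish against a light floor
DEFAULT_HSV = HsvRange(h_min=170, h_max=25, s_min=80, s_max=255,
                       v_min=60, v_max=255)


@dataclass(frozen=True)
class TrackerConfig:
    hsv: HsvRange = DEFAULT_HSV
    smooth_radius_px: int = 3
    min_blob_px: int = 25
    roi_entry_threshold: Mapping[str, int] = field(
        default_factory=lambda: {"start": 30, "choice_left": 30,
                                 "choice_right": 30})

    def __post_init__(self) -> None:
        if self.smooth_radius_px < 1 or self.smooth_radius_px % 2 == 0:
            raise ValueError("smooth_radius_px must be an odd integer >= 1")
        if self.min_blob_px < 0:
            raise ValueError("min_blob_px must be >= 0")
        if any(t < 0 for t in self.roi_entry_threshold.values()):
            raise ValueError("ROI entry thresholds must be >= 0")


@dataclass(frozen=True)
class TrackSample:
    """Per-frame tracking output.

    ``centroid`` is in cropped-frame pixel coordinates ``(col, row)`` or
    ``None`` when no blob of at least ``min_blob_px`` pixels was found.
    ``roi_counts`` carries the raw binarized pixel sums used for occupancy,
    which the task engine uses to break (rare) simultaneous-entry ties.
    """

    frame_index: int
    t: float
    centroid: tuple[float, float] | None
    luminance: float
    roi_occupancy: Mapping[str, bool]
    roi_counts: Mapping[str, int] = field(default_factory=dict)


def crop_frame(frame: np.ndarray, arena: ArenaModel) -> np.ndarray:
    cam = arena.camera
    return frame[cam.crop_y:cam.crop_y + cam.crop_h,
                 cam.crop_x:cam.crop_x + cam.crop_w]


def rgb_to_hsv(frame: np.ndarray) -> np.ndarray:
    """Convert an 8-bit RGB frame to HSV with H in 0-179 and S, V in 0-255.

    Standard hexcone conversion, vectorised in float32 so it is cheap enough
    to run inside the per-frame tracking loop (the general-purpose library
    converters cost more than the rest of the pipeline combined).  Hue is in
    half-degrees (0-179); pixels with zero chroma get hue 0 by convention.

    Raises ``ValueError`` for anything other than a 3-channel image.
    """
    frame = np.asarray(frame)
    if frame.ndim != 3 or frame.shape[-1] != 3:
        raise ValueError(f"expected an RGB image (H, W, 3); got {frame.shape}")
    r = frame[..., 0].astype(np.float32)
    g = frame[..., 1].astype(np.float32)
    b = frame[..., 2].astype(np.float32)
    v = np.maximum(np.maximum(r, g), b)
    c = v - np.minimum(np.minimum(r, g), b)
    inv_c = 1.0 / np.where(c > 0, c, 1.0)
    # hue in units of 60 degrees, then scaled to half-degrees
    h6 = np.where(v == r, (g - b) * inv_c,
                  np.where(v == g, (b - r) * inv_c + 2.0,
                           (r - g) * inv_c + 4.0))
    h6 = np.where(h6 < 0, h6 + 6.0, h6)
    h6 = np.where(c > 0, h6, 0.0)
    s = 255.0 * c / np.where(v > 0, v, 1.0)
    out = np.empty(frame.shape, dtype=np.uint8)
    out[..., 0] = np.round(h6 * 30.0).astype(np.uint16) % 180
    out[..., 1] = np.round(s).astype(np.uint8)
    out[..., 2] = np.round(v).astype(np.uint8)
    return out


def binarize(hsv: np.ndarray, rng: HsvRange) -> np.ndarray:
    """Boolean mask of pixels inside the HSV range (hue circularly)."""
    h, s, v = hsv[..., 0], hsv[..., 1], hsv[..., 2]
    if rng.h_min <= rng.h_max:
        h_ok = (h >= rng.h_min) & (h <= rng.h_max)
    else:  # wrapping interval, e.g. (170, 10) covers 170..179 and 0..10
        h_ok = (h >= rng.h_min) | (h <= rng.h_max)
    return (h_ok
            & (s >= rng.s_min) & (s <= rng.s_max)
            & (v >= rng.v_min) & (v <= rng.v_max))


def smooth_mask(mask: np.ndarray, radius: int = 3) -> np.ndarray:
    """Median-filter a binary mask with a square window of side ``radius``.

    Removes isolated speckle from the threshold step without biasing large
    blobs; a blob whose diameter is several times the radius keeps its area
    to within a thin boundary ring.
    """
    if radius < 1 or radius % 2 == 0:
        raise ValueError("radius must be an odd integer >= 1")
    if radius == 1:
        return mask.astype(bool)
    return ndimage.median_filter(mask.astype(np.uint8), size=radius) > 0


def centroid(mask: np.ndarray,
             min_blob_px: int = 0) -> tuple[float, float] | None:
    """Arithmetic mean ``(col, row)`` of true pixels, or ``None``.

    Returns ``None`` when fewer than ``min_blob_px`` pixels are set, which
    suppresses phantom positions when the subject is occluded or the
    threshold picks up only noise.
    """
    rows, cols = np.nonzero(mask)
    if rows.size < max(min_blob_px, 1):
        return None
    return (float(cols.mean()), float(rows.mean()))


def roi_pixel_count(mask: np.ndarray,
                    roi_px: tuple[int, int, int, int]) -> int:
    col0, row0, col1, row1 = roi_px
    h, w = mask.shape
    if col0 < 0 or row0 < 0 or col1 > w or row1 > h:
        raise ValueError(f"ROI {roi_px} outside mask bounds {(w, h)}")
    return int(mask[row0:row1, col0:col1].sum())


def roi_occupancy(mask: np.ndarray, roi_px: tuple[int, int, int, int],
                  threshold: int) -> bool:
    """True iff the binarized pixel sum inside the ROI *exceeds* threshold.

    The comparison is strict: a sum exactly at threshold does not count as
    entry.
    """
    return roi_pixel_count(mask, roi_px) > threshold


def probe_luminance(frame: np.ndarray,
                    roi_px: tuple[int, int, int, int]) -> float:
    """Mean grey level (unweighted RGB mean) over the ROI, in 0-255."""
    col0, row0, col1, row1 = roi_px
    h, w = frame.shape[:2]
    if col0 < 0 or row0 < 0 or col1 > w or row1 > h or col0 >= col1 or row0 >= row1:
        raise ValueError(f"ROI {(col0, row0, col1, row1)} invalid for frame {(w, h)}")
    patch = frame[row0:row1, col0:col1]
    return float(np.asarray(patch, dtype=np.float64).mean())


def track_frame(frame: np.ndarray, arena: ArenaModel, config: TrackerConfig,
                frame_index: int, t: float) -> TrackSample:
    """Run the full per-frame pipeline on one RGB camera frame.

    crop -> HSV -> threshold -> median smooth -> centroid, plus occupancy of
    the detection ROIs (on the smoothed mask) and the screen-probe luminance.
    Deterministic: identical frame and config give an identical sample.
    """
    cropped = crop_frame(frame, arena)
    hsv = rgb_to_hsv(cropped)
    mask = smooth_mask(binarize(hsv, config.hsv), config.smooth_radius_px)
    c = centroid(mask, config.min_blob_px)

    occupancy: dict[str, bool] = {}
    counts: dict[str, int] = {}
    for name, roi in arena.rois.items():
        if roi.purpose != "detection":
            continue
        roi_px = roi_pixel_rect(roi, arena.camera, arena.tank)
        n = roi_pixel_count(mask, roi_px)
        counts[name] = n
        occupancy[name] = n > config.roi_entry_threshold.get(name, 0)

    probe_px = roi_pixel_rect(arena.rois["screen_probe"], arena.camera,
                              arena.tank)
    lum = probe_luminance(cropped, probe_px)
    return TrackSample(frame_index=frame_index, t=t, centroid=c,
                       luminance=lum, roi_occupancy=occupancy,
                       roi_counts=counts)


def calibrate_entry_threshold(sample_masks: list[np.ndarray],
                              roi_px: tuple[int, int, int, int],
                              fraction: float = 0.25) -> int:
    """Per-subject entry threshold from masks with the subject inside the ROI.

    Returns ``fraction`` of the median in-ROI pixel count over the sample
    masks, rounded to an integer.  Mirrors the per-subject threshold
    adjustment done on a real rig before a session.
    """
    if not sample_masks:
        raise ValueError("need at least one sample mask")
    counts = [roi_pixel_count(m, roi_px) for m in sample_masks]
    med = float(np.median(counts))
    if med <= 0:
        raise ValueError("no subject pixels inside the ROI in any sample")
    return int(round(fraction * med))
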