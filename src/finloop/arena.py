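"""Physical tank geometry, regions of interest, camera and screen layout.

Coordinate conventions used throughout the package:

* **Tank-floor frame** (cm): origin at the corner where the stimulus screen
  meets the left wall, ``x`` running along the screen (0..width), ``y``
  increasing away from the screen (0..length).  The opaque divider runs from
  the screen into the tank along ``x = width/2``.
* **Pixel frame**: origin at the image top-left, ``y`` down.  The screen wall
  maps to the top edge of the crop rectangle, so tank ``(0, 0)`` maps to the
  crop origin and tank ``y`` maps to pixel rows.

All regions of interest are *closed* rectangles: boundary pixels count as
inside.  That convention is fixed so that ROI entry detection is reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from typing import Literal

import yaml

__all__ = [
    "TankGeometry",
    "Rect",
    "RegionOfInterest",
    "CameraModel",
    "ScreenLayout",
    "ArenaModel",
    "cm_to_px",
    "px_to_cm",
    "roi_pixel_rect",
    "default_arena",
    "save_arena",
    "load_arena",
]


@dataclass(frozen=True)
class TankGeometry:
    """Experimental tank dimensions in cm.

    The divider is an opaque partition running perpendicular to the screen
    down the middle of the tank, splitting the screen end into two arms of a
    Y-maze.
    """

    length_cm: float = 60.0
    width_cm: float = 30.0
    height_cm: float = 36.0
    water_level_cm: float = 15.0
    divider_length_cm: float = 25.0

    def __post_init__(self) -> None:
        for name in ("length_cm", "width_cm", "height_cm", "water_level_cm",
                     "divider_length_cm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.divider_length_cm >= self.length_cm:
            raise ValueError("divider_length_cm must be < length_cm")


@dataclass(frozen=True)
class Rect:
    """Axis-aligned rectangle, closed on all sides."""

    x_min: float
    y_min: float
    x_max: float
    y_max: float

    def __post_init__(self) -> None:
        if self.x_max < self.x_min or self.y_max < self.y_min:
            raise ValueError("degenerate rectangle: max < min")

    @property
    def width(self) -> float:
        return self.x_max - self.x_min

    @property
    def height(self) -> float:
        return self.y_max - self.y_min

    @property
    def area(self) -> float:
        return self.width * self.height

    @property
    def centre(self) -> tuple[float, float]:
        return ((self.x_min + self.x_max) / 2.0, (self.y_min + self.y_max) / 2.0)

    def contains(self, x: float, y: float) -> bool:
        return self.x_min <= x <= self.x_max and self.y_min <= y <= self.y_max

    def intersects(self, other: "Rect") -> bool:
        return not (self.x_max < other.x_min or other.x_max < self.x_min
                    or self.y_max < other.y_min or other.y_max < self.y_min)


ROI_NAMES = ("start", "choice_left", "choice_right", "screen_probe")


@dataclass(frozen=True)
class RegionOfInterest:
    """Named rectangular ROI on the tank floor (cm coordinates)."""

    name: str
    rect: Rect
    purpose: Literal["detection", "luminance"] = "detection"

    def __post_init__(self) -> None:
        if self.name not in ROI_NAMES:
            raise ValueError(f"unknown ROI name {self.name!r}; one of {ROI_NAMES}")


@dataclass(frozen=True)
class CameraModel:
    """Overhead camera: full image size, tank-interior crop, and scale.

    ``cm_per_px`` is a single isotropic scale factor; the camera is top-down
    over a flat tank floor, so no lens-distortion model is used.
    """

    image_width_px: int = 1280
    image_height_px: int = 720
    fps: float = 33.0
    crop_x: int = 490
    crop_y: int = 60
    crop_w: int = 300
    crop_h: int = 600
    cm_per_px: float = 0.1

    def __post_init__(self) -> None:
        if self.cm_per_px <= 0:
            raise ValueError("cm_per_px must be > 0")
        if self.fps <= 0:
            raise ValueError("fps must be > 0")
        if (self.crop_x < 0 or self.crop_y < 0
                or self.crop_x + self.crop_w > self.image_width_px
                or self.crop_y + self.crop_h > self.image_height_px):
            raise ValueError("crop rectangle outside image bounds")


@dataclass(frozen=True)
class ScreenLayout:
    """Stimulus screen geometry and the epoch-indicator grey levels.

    Stimuli are coloured circles on a grey background; during pre-training a
    white-noise rectangle (Gaussian noise, mean 0, variance 10, around mid
    grey) is used instead.  A strip at the top of the screen (imaged by the
    ``screen_probe`` ROI) encodes the task epoch as a grey level: low during
    the inter-trial interval, intermediate while a trial is available or
    stimuli are on (stimuli sit on the same grey background), high after a
    choice.
    """

    screen_width_px: int = 1920
    screen_height_px: int = 1080
    circle_diameter_cm: float = 3.5
    circle_bottom_offset_cm: float = 5.0
    circle_side_offset_cm: float = 7.0
    noise_rect_w_cm: float = 13.5
    noise_rect_h_cm: float = 12.0
    noise_mean: float = 0.0
    noise_variance: float = 10.0
    background_level: int = 128
    epoch_levels: dict[str, int] = field(default_factory=lambda: {
        "ITI": 0,
        "TRIAL_AVAILABLE": 128,
        "STIMULUS_ON": 128,
        "OUTCOME_DELAY": 255,
    })

    def __post_init__(self) -> None:
        if self.circle_diameter_cm <= 0:
            raise ValueError("circle_diameter_cm must be > 0")
        lv = self.epoch_levels
        if not (lv["ITI"] < lv["TRIAL_AVAILABLE"] <= lv["STIMULUS_ON"]
                < lv["OUTCOME_DELAY"]):
            raise ValueError("epoch levels must be ordered "
                             "ITI < TRIAL_AVAILABLE <= STIMULUS_ON < OUTCOME_DELAY")


@dataclass(frozen=True)
class ArenaModel:
    """Complete rig description: tank, ROIs, camera, and screen layout."""

    tank: TankGeometry
    rois: dict[str, RegionOfInterest]
    camera: CameraModel
    screen: ScreenLayout

    def __post_init__(self) -> None:
        for roi in self.rois.values():
            r = roi.rect
            if (r.x_min < 0 or r.y_min < 0 or r.x_max > self.tank.width_cm
                    or r.y_max > self.tank.length_cm):
                raise ValueError(f"ROI {roi.name!r} outside tank footprint")
        if "choice_left" in self.rois and "choice_right" in self.rois:
            left = self.rois["choice_left"].rect
            right = self.rois["choice_right"].rect
            # interiors must be disjoint (the shared divider line may touch)
            if (left.x_max > right.x_min and right.x_max > left.x_min
                    and left.y_max > right.y_min and right.y_max > left.y_min):
                raise ValueError("choice zones overlap")

    @property
    def divider_x_cm(self) -> float:
        return self.tank.width_cm / 2.0

    def roi(self, name: str) -> RegionOfInterest:
        return self.rois[name]


def cm_to_px(point: tuple[float, float], camera: CameraModel,
             tank: TankGeometry) -> tuple[float, float]:
    """Map a tank-floor point (cm) to pixel coordinates (column, row).

    Tank ``x`` (along the screen) maps to pixel columns and tank ``y`` (away
    from the screen) to pixel rows, with the screen-left corner at the crop
    origin.

    Raises ``ValueError`` if the point lies outside the tank footprint.
    """
    x, y = point
    if not (0 <= x <= tank.width_cm and 0 <= y <= tank.length_cm):
        raise ValueError(f"point {point} outside tank footprint")
    col = camera.crop_x + x / camera.cm_per_px
    row = camera.crop_y + y / camera.cm_per_px
    return (col, row)


def px_to_cm(point_px: tuple[float, float], camera: CameraModel,
             tank: TankGeometry) -> tuple[float, float]:
    """Inverse of :func:`cm_to_px` (no bounds check on the result)."""
    col, row = point_px
    x = (col - camera.crop_x) * camera.cm_per_px
    y = (row - camera.crop_y) * camera.cm_per_px
    return (x, y)


def roi_pixel_rect(roi: RegionOfInterest, camera: CameraModel,
                   tank: TankGeometry,
                   relative_to_crop: bool = True) -> tuple[int, int, int, int]:
    """ROI rectangle as integer pixel bounds ``(col0, row0, col1, row1)``.

    Bounds are inclusive-exclusive half-open so the rectangle can index numpy
    arrays directly.  With ``relative_to_crop`` the bounds are in cropped-frame
    coordinates (the frame produced by :func:`finloop.tracking.crop_frame`).
    """
    c0, r0 = cm_to_px((roi.rect.x_min, roi.rect.y_min), camera, tank)
    c1, r1 = cm_to_px((roi.rect.x_max, roi.rect.y_max), camera, tank)
    if relative_to_crop:
        c0, c1 = c0 - camera.crop_x, c1 - camera.crop_x
        r0, r1 = r0 - camera.crop_y, r1 - camera.crop_y
    col0, row0 = int(round(c0)), int(round(r0))
    col1, row1 = int(round(c1)), int(round(r1))
    return (col0, row0, max(col1, col0 + 1), max(row1, row0 + 1))


def _default_rois(tank: TankGeometry) -> dict[str, RegionOfInterest]:
    w = tank.width_cm
    length = tank.length_cm
    half = w / 2.0
    start_half = 5.0  # 10 x 10 cm start square
    rois = {
        "start": RegionOfInterest(
            "start",
            Rect(half - start_half, length - 10.0, half + start_half, length)),
        "choice_left": RegionOfInterest(
            "choice_left", Rect(0.0, 0.0, 15.0, 15.0)),
        "choice_right": RegionOfInterest(
            "choice_right", Rect(w - 15.0, 0.0, w, 15.0)),
        "screen_probe": RegionOfInterest(
            "screen_probe", Rect(half - 1.5, 0.0, half + 1.5, 1.0),
            purpose="luminance"),
    }
    return rois


def default_arena(camera: CameraModel | None = None) -> ArenaModel:
    """The standard rig: 60x30 cm tank, 25 cm divider, Y-maze ROIs.

    The start zone is a 10x10 cm square centred on the tank's long axis at the
    far (non-screen) end, equidistant from the two 15x15 cm choice zones that
    abut the screen wall on either side of the divider.  The screen-probe ROI
    is a small strip at the top-centre of the screen edge.
    """
    tank = TankGeometry()
    if camera is None:
        camera = CameraModel()
    return ArenaModel(tank=tank, rois=_default_rois(tank), camera=camera,
                      screen=ScreenLayout())


def pretraining_start_roi(tank: TankGeometry,
                          variant: Literal["back_half", "back_quarter",
                                           "square"]) -> RegionOfInterest:
    """Start-zone variants used while shaping self-initiated trials.

    ``back_half``: the rear half of the tank (y beyond length/2, i.e. > 30 cm
    from the screen); ``back_quarter``: the rear quarter; ``square``: the
    final 10x10 cm centred square used in the main experiments.
    """
    length, w = tank.length_cm, tank.width_cm
    if variant == "back_half":
        rect = Rect(0.0, length / 2.0, w, length)
    elif variant == "back_quarter":
        rect = Rect(0.0, 3.0 * length / 4.0, w, length)
    elif variant == "square":
        rect = Rect(w / 2.0 - 5.0, length - 10.0, w / 2.0 + 5.0, length)
    else:
        raise ValueError(f"unknown start-zone variant {variant!r}")
    return RegionOfInterest("start", rect)


# ---------------------------------------------------------------------------
# serialisation — one human-editable YAML document per rig

def _arena_to_dict(arena: ArenaModel) -> dict:
    return {
        "tank": asdict(arena.tank),
        "camera": asdict(arena.camera),
        "screen": asdict(arena.screen),
        "rois": {
            name: {"rect": asdict(roi.rect), "purpose": roi.purpose}
            for name, roi in arena.rois.items()
        },
    }


def _arena_from_dict(d: dict) -> ArenaModel:
    rois = {
        name: RegionOfInterest(name, Rect(**spec["rect"]), spec["purpose"])
        for name, spec in d["rois"].items()
    }
    return ArenaModel(
        tank=TankGeometry(**d["tank"]),
        rois=rois,
        camera=CameraModel(**d["camera"]),
        screen=ScreenLayout(**d["screen"]),
    )


def save_arena(arena: ArenaModel, path) -> None:
    """Write the arena configuration as a YAML document."""
    with open(path, "w") as fh:
        yaml.safe_dump(_arena_to_dict(arena), fh, sort_keys=True)


def load_arena(path) -> ArenaModel:
    """Load an arena configuration; ``load(save(a)) == a`` exactly."""
    with open(path) as fh:
        return _arena_from_dict(yaml.safe_load(fh))


def with_camera(arena: ArenaModel, camera: CameraModel) -> ArenaModel:
    return replace(arena, camera=camera)
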