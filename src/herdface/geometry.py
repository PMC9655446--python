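"""Image-coordinate geometry between detection and encoding.

All coordinates are 0-based with the origin at the top-left corner, x
rightward, y downward, and boxes as half-open intervals. Angles are measured
in that frame, so a positive eye angle means the right eye sits lower than
the left eye on screen.

The chain implemented here is the deterministic part of a face-recognition
front end: resize a frame for the detector, keep the best confident
detection, squarify its box, measure the eye-line angle from landmarks, and
rotate/crop into a fixed-size aligned "chip face" (eyes horizontal, muzzle
below the eye line).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from PIL import Image
from scipy import ndimage

from .exceptions import InvalidInputError

__all__ = [
    "BoundingBox",
    "Landmarks",
    "ImageFrame",
    "ChipFace",
    "resize_for_detection",
    "map_box_to_source",
    "filter_detections",
    "squarify",
    "eye_angle",
    "align_chip",
]

DEFAULT_CHIP_SIDE = 224


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned half-open box in pixel coordinates with a detector score."""

    x_min: float
    y_min: float
    x_max: float
    y_max: float
    confidence: float = 1.0

    def __post_init__(self) -> None:
        if not (self.x_min < self.x_max and self.y_min < self.y_max):
            raise InvalidInputError(
                f"degenerate bounding box ({self.x_min},{self.y_min},"
                f"{self.x_max},{self.y_max})"
            )
        if not 0.0 <= self.confidence <= 1.0:
            raise InvalidInputError(f"confidence {self.confidence} outside [0,1]")

    @property
    def width(self) -> float:
        return self.x_max - self.x_min

    @property
    def height(self) -> float:
        return self.y_max - self.y_min

    @property
    def center(self) -> tuple[float, float]:
        return (0.5 * (self.x_min + self.x_max), 0.5 * (self.y_min + self.y_max))

    @property
    def is_square(self) -> bool:
        return math.isclose(self.width, self.height, rel_tol=0.0, abs_tol=1e-6)

    def contains_point(self, x: float, y: float) -> bool:
        return self.x_min <= x <= self.x_max and self.y_min <= y <= self.y_max


@dataclass(frozen=True)
class Landmarks:
    """Facial key points: the two eyes and the muzzle tip.

    "left"/"right" are as seen in the image: in an upright face the left eye
    is the one with the smaller x coordinate.
    """

    left_eye: tuple[float, float]
    right_eye: tuple[float, float]
    muzzle: tuple[float, float]

    def __post_init__(self) -> None:
        if tuple(self.left_eye) == tuple(self.right_eye):
            raise InvalidInputError("left and right eye coincide")

    def as_array(self) -> np.ndarray:
        return np.array([self.left_eye, self.right_eye, self.muzzle], dtype=float)


@dataclass
class ImageFrame:
    """One 8-bit video frame (or still) with stream provenance."""

    pixels: np.ndarray
    frame_index: int = 0
    timestamp_ms: float = 0.0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.uint8)
        if self.pixels.ndim not in (2, 3) or min(self.pixels.shape[:2]) < 1:
            raise InvalidInputError("frame must be a non-empty HxW[xC] pixel grid")
        if self.frame_index < 0 or self.timestamp_ms < 0:
            raise InvalidInputError("frame_index and timestamp_ms must be >= 0")

    @property
    def height(self) -> int:
        return int(self.pixels.shape[0])

    @property
    def width(self) -> int:
        return int(self.pixels.shape[1])


@dataclass
class ChipFace:
    """A square, rotation-aligned face crop — the unit input to an encoder."""

    pixels: np.ndarray
    chip_side: int = DEFAULT_CHIP_SIDE
    frame_index: int = 0
    identity: str | None = None
    rotation_deg: float = 0.0
    landmarks: Landmarks | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.uint8)
        h, w = self.pixels.shape[:2]
        if h != self.chip_side or w != self.chip_side:
            raise InvalidInputError(
                f"chip must be {self.chip_side}x{self.chip_side}, got {w}x{h}"
            )


def resize_for_detection(
    frame: ImageFrame, target_w: int, target_h: int
) -> tuple[ImageFrame, tuple[float, float]]:
    """Resize a frame for the detector and record the scale factors.

    The resize is direct (anisotropic, no letterboxing). The returned
    ``(scale_x, scale_y)`` maps source coordinates to resized coordinates, so
    boxes detected on the output can be mapped back with
    :func:`map_box_to_source`.
    """
    if target_w < 1 or target_h < 1:
        raise InvalidInputError("target dimensions must be >= 1")
    scale = (target_w / frame.width, target_h / frame.height)
    if (target_w, target_h) == (frame.width, frame.height):
        return ImageFrame(frame.pixels.copy(), frame.frame_index, frame.timestamp_ms), scale
    img = Image.fromarray(frame.pixels)
    resized = np.asarray(img.resize((target_w, target_h), Image.BILINEAR))
    return ImageFrame(resized, frame.frame_index, frame.timestamp_ms), scale


def map_box_to_source(box: BoundingBox, scale: tuple[float, float]) -> BoundingBox:
    """Map a box detected on a resized frame back to source coordinates."""
    sx, sy = scale
    return BoundingBox(
        box.x_min / sx, box.y_min / sy, box.x_max / sx, box.y_max / sy, box.confidence
    )


def filter_detections(
    boxes: list[BoundingBox], min_conf: float = 0.7
) -> BoundingBox | None:
    """Keep the single best detection with confidence strictly above ``min_conf``.

    Returns ``None`` when no detection survives, which callers treat as
    "skip this frame". Strict ``>`` mirrors the acceptance rule used at the
    similarity threshold.
    """
    if not 0.0 <= min_conf <= 1.0:
        raise InvalidInputError(f"min_conf {min_conf} outside [0,1]")
    survivors = [b for b in boxes if b.confidence > min_conf]
    if not survivors:
        return None
    return max(survivors, key=lambda b: b.confidence)


def squarify(bbox: BoundingBox, frame_w: int, frame_h: int) -> BoundingBox:
    """Expand a box into a square of side ``max(w, h)`` that fits the frame.

    The square is centered on the input box's center and translated (never
    shrunk) to fit inside the frame; if the side exceeds the smaller frame
    dimension it is clamped to that value first. Idempotent.
    """
    if bbox.x_max <= 0 or bbox.y_max <= 0 or bbox.x_min >= frame_w or bbox.y_min >= frame_h:
        raise InvalidInputError("box does not intersect the frame")
    side = max(bbox.width, bbox.height)
    side = min(side, float(min(frame_w, frame_h)))
    cx, cy = bbox.center
    x0 = cx - side / 2.0
    y0 = cy - side / 2.0
    # translate-to-fit: shift the square, preserving its side
    x0 = min(max(x0, 0.0), frame_w - side)
    y0 = min(max(y0, 0.0), frame_h - side)
    return BoundingBox(x0, y0, x0 + side, y0 + side, bbox.confidence)


def eye_angle(lm: Landmarks) -> float:
    """Signed angle in degrees of the left->right eye line vs the +x axis.

    Returned in (-90, 90] (y-down frame); 0 when both eyes share a y
    coordinate. Angles outside that half-turn (an upside-down face) fold back
    by 180 degrees — the portrait flip is resolved later using the muzzle.
    """
    (lx, ly), (rx, ry) = lm.left_eye, lm.right_eye
    angle = math.degrees(math.atan2(ry - ly, rx - lx))
    if angle > 90.0:
        angle -= 180.0
    elif angle <= -90.0:
        angle += 180.0
    return angle


def _rotation_matrix(deg: float) -> np.ndarray:
    a = math.radians(deg)
    return np.array([[math.cos(a), -math.sin(a)], [math.sin(a), math.cos(a)]])


def _rotate_points(points: np.ndarray, deg: float, center: np.ndarray) -> np.ndarray:
    return (points - center) @ _rotation_matrix(deg).T + center


def align_chip(
    frame: ImageFrame,
    sq_box: BoundingBox,
    lm: Landmarks,
    chip_side: int = DEFAULT_CHIP_SIDE,
) -> ChipFace:
    """Rotate the face upright about the eye midpoint and crop a chip.

    The image is rotated by the negative eye angle so the eye line becomes
    horizontal; if the muzzle then lies above the eye line, a further 180°
    turn restores portrait orientation (muzzle below eyes). The square region
    is re-cropped around the rotated box center and resampled (bilinear,
    black fill outside the canvas) to ``chip_side`` pixels. The transformed
    landmarks ride along on the returned chip.
    """
    if not sq_box.is_square:
        raise InvalidInputError("align_chip requires a square box; call squarify first")
    for x, y in lm.as_array():
        if not sq_box.contains_point(x, y):
            raise InvalidInputError("landmarks must lie inside the box")

    mid = 0.5 * (np.asarray(lm.left_eye, float) + np.asarray(lm.right_eye, float))
    rotation = -eye_angle(lm)
    pts = _rotate_points(lm.as_array(), rotation, mid)
    if pts[2, 1] < pts[0, 1]:  # muzzle above eye line: upside-down face
        rotation += 180.0
        pts = _rotate_points(lm.as_array(), rotation, mid)

    side = sq_box.width
    center = _rotate_points(np.array([sq_box.center]), rotation, mid)[0]
    origin = center - side / 2.0

    # output pixel centers -> rotated-frame coords -> source coords
    u = (np.arange(chip_side) + 0.5) * side / chip_side
    xs = origin[0] + u
    ys = origin[1] + u
    gx, gy = np.meshgrid(xs, ys)
    grid = np.stack([gx.ravel(), gy.ravel()], axis=1)
    src = _rotate_points(grid, -rotation, mid)
    # sample in array index space (pixel centers at i + 0.5)
    coords = np.stack([src[:, 1] - 0.5, src[:, 0] - 0.5])

    pix = frame.pixels
    if pix.ndim == 2:
        pix = pix[:, :, None]
    out = np.empty((chip_side, chip_side, pix.shape[2]), dtype=np.uint8)
    for c in range(pix.shape[2]):
        sampled = ndimage.map_coordinates(
            pix[:, :, c].astype(float), coords, order=1, mode="constant", cval=0.0
        )
        out[:, :, c] = (
            np.clip(np.rint(sampled), 0, 255).astype(np.uint8).reshape(chip_side, chip_side)
        )
    if frame.pixels.ndim == 2:
        out = out[:, :, 0]

    chip_scale = chip_side / side
    chip_pts = (pts - origin) * chip_scale
    chip_lm = Landmarks(tuple(chip_pts[0]), tuple(chip_pts[1]), tuple(chip_pts[2]))
    return ChipFace(
        out,
        chip_side=chip_side,
        frame_index=frame.frame_index,
        rotation_deg=rotation,
        landmarks=chip_lm,
    )
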