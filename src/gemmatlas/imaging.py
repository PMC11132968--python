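"""From a gemma image plus notch landmarks to a raw 1D intensity profile.

The pipeline stage implemented here mirrors standard confocal practice:
maximum-intensity projection, rolling-ball background subtraction, rotation
of the image so the two apical notches lie on the horizontal axis, and a
rectangular plot-profile (per-column mean) of the reporter channel over a
region of interest covering the gemma.

Landmarks (start, notch1, notch2, end) are supplied, either from synthetic
ground truth or from a sidecar CSV produced during manual annotation;
automatic notch detection is out of scope.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage
from skimage import measure, transform
from skimage.filters import threshold_otsu

__all__ = [
    "GemmaImage",
    "LandmarkSet",
    "IntensityProfile",
    "Rect",
    "max_project",
    "subtract_background",
    "rotate_to_axis",
    "extract_profile",
    "membrane_roi",
    "read_image",
    "write_image",
    "read_landmark_csv",
]


@dataclass
class GemmaImage:
    """A multi-channel 2D gemma image with channel roles.

    ``channels`` maps a role name (``reporter``, ``membrane``, optionally
    ``chlorophyll``) to a 2D nonnegative float array; all channels share one
    shape.  ``pixel_size`` is in micrometres per pixel when known.
    """

    channels: dict[str, np.ndarray]
    pixel_size: float | None = None

    def __post_init__(self) -> None:
        shapes = {role: ch.shape for role, ch in self.channels.items()}
        if len(set(shapes.values())) > 1:
            raise ValueError(f"channel shapes differ: {shapes}")
        for role, ch in self.channels.items():
            if ch.ndim != 2:
                raise ValueError(f"channel {role!r} is not 2D")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    @property
    def reporter(self) -> np.ndarray:
        return self.channels["reporter"]

    @property
    def membrane(self) -> np.ndarray:
        return self.channels["membrane"]


@dataclass(frozen=True)
class LandmarkSet:
    """The four profiling landmarks: start, notch1, notch2, end.

    Before rotation each landmark is an (x, y) pixel coordinate (x = column,
    y = row).  After :func:`rotate_to_axis` the landmarks are scalar x-axis
    positions (`scalar` is True) with start < notch1 < notch2 < end.
    """

    start: tuple[float, float] | float
    notch1: tuple[float, float] | float
    notch2: tuple[float, float] | float
    end: tuple[float, float] | float
    scalar: bool = False

    def as_array(self) -> np.ndarray:
        return np.asarray([self.start, self.notch1, self.notch2, self.end], dtype=float)

    def positions(self) -> np.ndarray:
        """Scalar axis positions (requires ``scalar=True``)."""
        if not self.scalar:
            raise ValueError("landmarks are 2D coordinates; rotate the image first")
        return self.as_array()


@dataclass
class IntensityProfile:
    """A 1D intensity trace along the notch axis.

    ``positions`` are strictly increasing (pixels before normalization),
    ``intensities`` are nonnegative fluorescence values, and ``landmarks``
    are the four landmark positions on the same axis.
    """

    positions: np.ndarray
    intensities: np.ndarray
    landmarks: np.ndarray
    background_subtracted: bool = False
    smoothed: bool = False

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.landmarks = np.asarray(self.landmarks, dtype=float)
        if self.positions.shape != self.intensities.shape:
            raise ValueError("positions and intensities differ in length")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("intensities must be finite")


@dataclass(frozen=True)
class Rect:
    """A rectangle in pixel coordinates, half-open: cols [x0, x1), rows [y0, y1)."""

    x0: int
    x1: int
    y0: int
    y1: int

    def __post_init__(self) -> None:
        if self.x1 <= self.x0 or self.y1 <= self.y0:
            raise ValueError("empty rectangle")


def max_project(stack: np.ndarray) -> np.ndarray:
    """Maximum-intensity projection of a Z-stack along its first axis."""
    stack = np.asarray(stack)
    if stack.ndim != 3 or stack.shape[0] == 0:
        raise ValueError("stack must be a nonempty 3D array (planes, rows, cols)")
    return stack.max(axis=0)


def subtract_background(image: np.ndarray, radius: int = 50) -> np.ndarray:
    """Remove a slowly varying background with a rolling-ball estimate.

    The background is the grayscale opening of the image with a disc
    structuring element of the given ``radius``; the result is the image
    minus that background, elementwise nonnegative and never exceeding the
    input.  ``radius`` should be well above the feature scale (nuclei) so
    that foreground spots survive essentially unchanged.
    """
    image = np.asarray(image, dtype=float)
    if radius < 1:
        raise ValueError("radius must be >= 1")
    if 2 * radius + 1 > max(image.shape):
        raise ValueError("radius larger than image")
    yy, xx = np.mgrid[-radius : radius + 1, -radius : radius + 1]
    footprint = (xx * xx + yy * yy) <= radius * radius
    background = ndimage.grey_opening(image, footprint=footprint, mode="nearest")
    return np.clip(image - background, 0.0, None)


def _rotation_angle(landmarks: LandmarkSet) -> float:
    (x1, y1), (x2, y2) = landmarks.notch1, landmarks.notch2
    if x1 == x2 and y1 == y2:
        raise ValueError("coincident notch landmarks")
    return math.atan2(y2 - y1, x2 - x1)


def rotate_to_axis(
    image: GemmaImage, landmarks: LandmarkSet
) -> tuple[GemmaImage, LandmarkSet]:
    """Rotate so that the notch-to-notch vector is horizontal.

    The image is rotated by ``-atan2(dy, dx)`` about the notch midpoint with
    bilinear interpolation and zero padding; landmark coordinates are mapped
    through the same rotation and returned as scalar x positions.  If the
    rotation would put notch2 left of notch1, a further half-turn is applied
    so the returned landmarks are ordered start < notch1 < notch2 < end.
    """
    theta = _rotation_angle(landmarks)
    pts = landmarks.as_array()  # (4, 2) as (x, y)
    mid = (pts[1] + pts[2]) / 2.0

    def rot_pts(angle: float) -> np.ndarray:
        c, s = math.cos(angle), math.sin(angle)
        rot = np.array([[c, -s], [s, c]])
        return (pts - mid) @ rot.T + mid

    angle = -theta
    new_pts = rot_pts(angle)
    if new_pts[1, 0] > new_pts[2, 0]:
        angle += math.pi
        new_pts = rot_pts(angle)

    # warp() takes the *inverse* map: output (x, y) -> input (x, y)
    c, s = math.cos(-angle), math.sin(-angle)
    rot = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
    rot[:2, 2] = mid - rot[:2, :2] @ mid
    tform = transform.AffineTransform(matrix=rot)
    rotated = {
        role: transform.warp(
            ch, tform, order=1, cval=0.0, preserve_range=True
        ).astype(float)
        for role, ch in image.channels.items()
    }
    ys = new_pts[[1, 2], 1]
    if abs(ys[0] - ys[1]) > 0.5:
        raise AssertionError("rotated notches not horizontal")
    scalar = LandmarkSet(*new_pts[:, 0].tolist(), scalar=True)
    order = scalar.as_array()
    if np.any(np.diff(order) <= 0):
        raise ValueError("rotated landmarks are not ordered along the axis")
    return GemmaImage(rotated, pixel_size=image.pixel_size), scalar


def membrane_roi(image: GemmaImage, pad: int = 2) -> Rect:
    """Default ROI: bounding box of the membrane-channel foreground.

    Otsu threshold on the membrane channel, largest connected component,
    bounding box padded by ``pad`` pixels (clipped to the image).
    """
    mem = image.membrane
    mask = mem > threshold_otsu(mem)
    labels = measure.label(mask)
    if labels.max() == 0:
        raise ValueError("no membrane foreground found")
    largest = max(measure.regionprops(labels), key=lambda r: r.area)
    r0, c0, r1, c1 = largest.bbox
    h, w = mem.shape
    return Rect(max(c0 - pad, 0), min(c1 + pad, w), max(r0 - pad, 0), min(r1 + pad, h))


def extract_profile(
    image: GemmaImage,
    landmarks: LandmarkSet,
    roi: Rect | None = None,
    channel: str = "reporter",
) -> IntensityProfile:
    """Per-column mean intensity over the ROI (the plot-profile convention).

    ``positions`` are absolute image x coordinates of the ROI columns (pixel
    centers), so the scalar landmark positions carry through unchanged.
    """
    if roi is None:
        roi = membrane_roi(image)
    h, w = image.shape
    if not (0 <= roi.x0 < roi.x1 <= w and 0 <= roi.y0 < roi.y1 <= h):
        raise ValueError("roi outside image bounds")
    marks = landmarks.positions()
    if marks[0] < roi.x0 - 0.5 or marks[-1] > roi.x1 - 0.5:
        raise ValueError("landmarks outside roi x-range")
    block = image.channels[channel][roi.y0 : roi.y1, roi.x0 : roi.x1]
    profile = block.mean(axis=0)
    positions = np.arange(roi.x0, roi.x1, dtype=float)
    return IntensityProfile(positions, np.clip(profile, 0.0, None), marks)


def read_image(path, roles: tuple[str, ...] = ("reporter", "membrane")) -> GemmaImage:
    """Read a multi-channel TIFF (channels on the first axis) or a 2D image."""
    arr = tifffile.imread(path)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.shape[0] != len(roles):
        raise ValueError(f"expected {len(roles)} channels, found {arr.shape[0]}")
    return GemmaImage({role: arr[i].astype(float) for i, role in enumerate(roles)})


def write_image(path, image: GemmaImage, roles: tuple[str, ...] | None = None) -> None:
    roles = roles or tuple(image.channels)
    stack = np.stack([image.channels[r] for r in roles]).astype(np.float32)
    tifffile.imwrite(path, stack)


def read_landmark_csv(path) -> dict[str, LandmarkSet]:
    """Load landmark sidecar CSV (image_id, start_x, start_y, ... end_y)."""
    df = pd.read_csv(path)
    out: dict[str, LandmarkSet] = {}
    for _, row in df.iterrows():
        out[str(row["image_id"])] = LandmarkSet(
            (row["start_x"], row["start_y"]),
            (row["notch1_x"], row["notch1_y"]),
            (row["notch2_x"], row["notch2_y"]),
            (row["end_x"], row["end_y"]),
        )
    return out
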