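"""Preparation of raw aortic-root ultrasound volumes and leaflet photographs.

The pipeline mirrors an ex-vivo acquisition protocol: a TEE-like 3D
ultrasound image of the aortic root is cropped to a 32x128x128 subvolume
anchored at the manually identified commissure plane, denoised by gray-value
thresholding and scaled to [0, 1]; high-resolution leaflet photographs are
converted to grayscale, inverted, background-suppressed, centered on their
center of mass, rotated so the two commissure points share an image column,
and downsampled to a 128x64 planar shape image.

All manual inputs (commissure plane index, in-plane crop center, commissure
landmarks, per-image background threshold) are explicit arguments.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

#: mm per pixel of the preprocessed leaflet images.
LEAFLET_RESOLUTION_MM = 0.34
#: mm per pixel of the raw leaflet photographs.
RAW_PHOTO_RESOLUTION_MM = 0.037
#: (slice, row, col) voxel spacing in mm of the cropped root subvolume.
VOLUME_SPACING_MM = (0.71, 0.49, 0.49)
#: Gray-value threshold applied to the root volumes (0..255 scale).
VOLUME_GRAY_THRESHOLD = 80
#: Midpoint of the manually selected background-threshold range (158..168).
DEFAULT_BACKGROUND_THRESHOLD = 163
#: Range of plausible per-image background thresholds on the inverted scale.
BACKGROUND_THRESHOLD_RANGE = (158, 168)

LEAFLET_SHAPE = (128, 64)
VOLUME_SHAPE = (32, 128, 128)
LEAFLET_TYPES = ("rc", "lc", "nc")


@dataclass
class LeafletImage:
    """A preprocessed planar leaflet shape image.

    ``pixels`` is a 128x64 float array with intensities in [0, 1]; rows run
    along the commissure axis (the two commissure points share a column
    after alignment).  Background pixels are exactly zero.
    """

    pixels: np.ndarray
    leaflet_type: str | None = None
    valve_id: str | None = None
    resolution: float = LEAFLET_RESOLUTION_MM

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float32)
        if self.pixels.shape != LEAFLET_SHAPE:
            raise ValueError(
                f"leaflet image must be {LEAFLET_SHAPE} (rows, cols), got {self.pixels.shape}")
        if self.pixels.min() < 0 or self.pixels.max() > 1:
            raise ValueError("leaflet intensities must lie in [0, 1]")
        if self.leaflet_type is not None and self.leaflet_type not in LEAFLET_TYPES:
            raise ValueError(f"leaflet_type must be one of {LEAFLET_TYPES}")


@dataclass
class RootVolume:
    """A cropped, thresholded and rescaled aortic-root subvolume.

    ``voxels`` is a (slice, row, col) = 32x128x128 float array in [0, 1];
    slice 0 is the commissure plane, deeper slices lie below it.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float] = VOLUME_SPACING_MM
    valve_id: str | None = None

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float32)
        if self.voxels.shape != VOLUME_SHAPE:
            raise ValueError(
                f"root volume must be {VOLUME_SHAPE} (slice, row, col), got {self.voxels.shape}")
        if self.voxels.min() < 0 or self.voxels.max() > 1:
            raise ValueError("volume intensities must lie in [0, 1]")

    @property
    def axial_extent_mm(self) -> float:
        """Height of the subvolume along the slice axis in mm."""
        return self.voxels.shape[0] * self.spacing[0]


@dataclass
class CommissureAnnotation:
    """Manual annotations anchoring the preprocessing.

    ``plane_index``/``center`` locate the commissure plane and the in-plane
    root center in the raw volume; ``commissure_points`` are two (row, col)
    landmarks in the raw leaflet photograph.
    """

    plane_index: int
    center: tuple[float, float]
    commissure_points: tuple[tuple[float, float], tuple[float, float]] | None = None

    def __post_init__(self) -> None:
        if self.commissure_points is not None:
            p1, p2 = self.commissure_points
            if tuple(p1) == tuple(p2):
                raise ValueError("commissure points must be distinct")


def crop_commissure_subvolume(raw_volume: np.ndarray,
                              annotation: CommissureAnnotation,
                              n_slices: int = 32,
                              in_plane: tuple[int, int] = (128, 128)) -> np.ndarray:
    """Crop the commissure-anchored subvolume out of a raw 3D image.

    Slice 0 of the output is the commissure plane, slices 1..n_slices-1 the
    layers below it; the in-plane window is centered on ``annotation.center``
    and zero-padded where it leaves the raw extent.
    """
    raw = np.asarray(raw_volume)
    if raw.ndim != 3:
        raise ValueError(f"raw volume must be 3D (slice, row, col), got ndim={raw.ndim}")
    z0 = int(annotation.plane_index)
    if z0 < 0 or z0 + n_slices > raw.shape[0]:
        raise ValueError(
            f"plane index {z0} needs {n_slices - 1} slices below it; "
            f"raw volume has {raw.shape[0]} slices")
    out = np.zeros((n_slices,) + tuple(in_plane), dtype=raw.dtype)
    r0 = int(round(annotation.center[0])) - in_plane[0] // 2
    c0 = int(round(annotation.center[1])) - in_plane[1] // 2
    rs, re = max(r0, 0), min(r0 + in_plane[0], raw.shape[1])
    cs, ce = max(c0, 0), min(c0 + in_plane[1], raw.shape[2])
    if rs < re and cs < ce:
        out[:, rs - r0:re - r0, cs - c0:ce - c0] = raw[z0:z0 + n_slices, rs:re, cs:ce]
    return out


def threshold_volume(volume: np.ndarray, t: float = VOLUME_GRAY_THRESHOLD) -> np.ndarray:
    """Suppress speckle background: gray values <= t are set to 0 (0..255 scale)."""
    if not 0 <= t <= 255:
        warnings.warn(f"threshold {t} outside the 0..255 gray range", stacklevel=2)
    vol = np.asarray(volume)
    return np.where(vol > t, vol, 0)


def scale_to_unit(volume: np.ndarray) -> np.ndarray:
    """Scale 0..255 gray values by 1/255 into [0, 1]."""
    return np.asarray(volume, dtype=np.float32) / 255.0


def preprocess_volume(raw_volume: np.ndarray, annotation: CommissureAnnotation,
                      t: float = VOLUME_GRAY_THRESHOLD,
                      valve_id: str | None = None) -> RootVolume:
    """Full raw-volume pipeline: crop, threshold, scale to [0, 1]."""
    sub = crop_commissure_subvolume(raw_volume, annotation)
    sub = threshold_volume(sub, t=t)
    return RootVolume(scale_to_unit(sub), valve_id=valve_id)


def commissure_rotation_angle(p1: tuple[float, float], p2: tuple[float, float]) -> float:
    """Minimal-magnitude rotation (degrees) aligning the p1-p2 line with a column.

    Points are (row, col).  The returned angle is the one to rotate the image
    by (counterclockwise in (row, col) pixel coordinates, see
    :func:`rotate_image`) so that both points end up in the same column.
    Ties between +90 and -90 degrees resolve to +90.
    """
    dr = float(p2[0]) - float(p1[0])
    dc = float(p2[1]) - float(p1[1])
    if dr == 0.0 and dc == 0.0:
        raise ValueError("commissure points must be distinct")
    angle = math.degrees(math.atan2(dc, dr))
    # fold into (-90, 90]: the line is undirected
    if angle > 90.0:
        angle -= 180.0
    elif angle <= -90.0:
        angle += 180.0
    if angle == -90.0:
        angle = 90.0
    return angle


def rotate_image(image: np.ndarray, angle_deg: float, order: int = 1) -> np.ndarray:
    """Rotate about the image center so that ``commissure_rotation_angle``'s
    output verticalizes the landmark line; bilinear by default."""
    return ndimage.rotate(image, -angle_deg, reshape=False, order=order, mode="constant")


def rotate_points(points: np.ndarray, angle_deg: float, center: tuple[float, float]) -> np.ndarray:
    """Apply the same rotation as :func:`rotate_image` to (row, col) points.

    A line whose direction makes ``commissure_rotation_angle`` return
    ``angle_deg`` maps onto a constant-column line under this transform.
    """
    a = math.radians(-angle_deg)
    rot = np.array([[math.cos(a), -math.sin(a)], [math.sin(a), math.cos(a)]])
    pts = np.asarray(points, dtype=float) - np.asarray(center, dtype=float)
    return pts @ rot.T + np.asarray(center, dtype=float)


def center_of_mass(image: np.ndarray) -> tuple[float, float]:
    """Intensity-weighted center of mass of the foreground."""
    total = float(image.sum())
    if total <= 0:
        raise ValueError("empty foreground: no positive pixels")
    return tuple(ndimage.center_of_mass(image))  # type: ignore[return-value]


def _working_frame_shape(out_shape: tuple[int, int],
                         raw_resolution: float,
                         out_resolution: float) -> tuple[int, int]:
    scale = out_resolution / raw_resolution
    return (int(round(out_shape[0] * scale)), int(round(out_shape[1] * scale)))


def preprocess_leaflet(raw_photo: np.ndarray,
                       commissure_points: tuple[tuple[float, float], tuple[float, float]],
                       background_threshold: float = DEFAULT_BACKGROUND_THRESHOLD,
                       raw_resolution: float = RAW_PHOTO_RESOLUTION_MM,
                       out_resolution: float = LEAFLET_RESOLUTION_MM,
                       leaflet_type: str | None = None,
                       valve_id: str | None = None) -> LeafletImage:
    """Turn a raw RGB leaflet photograph into a 128x64 planar shape image.

    Pipeline order: grayscale -> invert (255 - g) -> background-to-zero by
    ``background_threshold`` -> translate the intensity-weighted center of
    mass to the frame midpoint -> rotate about the center so the commissure
    points share a column -> area-weighted downsample to 128x64 -> / 255.

    The working frame between centering and downsampling spans
    ``out_shape * out_resolution`` mm at raw resolution so that the final
    image has the requested mm-per-pixel.
    """
    photo = np.asarray(raw_photo)
    if photo.ndim == 3 and photo.shape[2] in (3, 4):
        gray = photo[..., :3].astype(np.float64) @ np.array([0.299, 0.587, 0.114])
    elif photo.ndim == 2:
        gray = photo.astype(np.float64)
    else:
        raise ValueError(f"expected an RGB or grayscale photo, got shape {photo.shape}")
    inverted = 255.0 - gray
    fg = np.where(inverted > background_threshold, inverted, 0.0)
    if not np.any(fg > 0):
        raise ValueError("empty foreground after background thresholding")

    com = center_of_mass(fg)
    frame_shape = _working_frame_shape(LEAFLET_SHAPE, raw_resolution, out_resolution)
    frame_mid = ((frame_shape[0] - 1) / 2.0, (frame_shape[1] - 1) / 2.0)
    # whole-pixel placement into the frame plus subpixel shift by interpolation
    shift = (frame_mid[0] - com[0], frame_mid[1] - com[1])
    int_shift = (int(math.floor(shift[0])), int(math.floor(shift[1])))
    sub_shift = (shift[0] - int_shift[0], shift[1] - int_shift[1])
    frame = np.zeros(frame_shape, dtype=np.float64)
    rs = max(0, int_shift[0]); re = min(frame_shape[0], fg.shape[0] + int_shift[0])
    cs = max(0, int_shift[1]); ce = min(frame_shape[1], fg.shape[1] + int_shift[1])
    if rs < re and cs < ce:
        frame[rs:re, cs:ce] = fg[rs - int_shift[0]:re - int_shift[0],
                                 cs - int_shift[1]:ce - int_shift[1]]
    if any(abs(s) > 1e-9 for s in sub_shift):
        frame = ndimage.shift(frame, sub_shift, order=1, mode="constant")

    angle = commissure_rotation_angle(*commissure_points)
    if angle != 0.0:
        frame = rotate_image(frame, angle)

    from skimage.transform import resize  # local import: skimage is heavy

    small = resize(frame, LEAFLET_SHAPE, order=1, anti_aliasing=True,
                   mode="constant", preserve_range=True)
    small = np.clip(small / 255.0, 0.0, 1.0)
    small[small < 1e-3] = 0.0  # interpolation residue far from the leaflet
    return LeafletImage(small.astype(np.float32), leaflet_type=leaflet_type,
                        valve_id=valve_id, resolution=out_resolution)
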