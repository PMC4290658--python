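"""Spatial and temporal registration.

Every pupa is mapped into a common reference frame before measurements are
compared: spatially, the stack is rotated so the anterior→posterior midline
runs horizontally, anterior at the left; temporally, frame indices are
expressed in hours relative to the onset of head eversion (hours AHE), the
prepupal→pupal transition that aligns different animals.  The midline and
head-eversion frame are annotations supplied by the experimenter, not
auto-detected.

Images are resampled bilinearly; geometry (polygons, the midline itself) is
transformed with the exact affine so measurements carry no resampling bias.
Frames recorded before head eversion get negative hours AHE.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from skimage.transform import AffineTransform, warp

from .errors import ValidationError
from .imaging import TimeSeriesStack


@dataclass
class ReferenceFrame:
    """Spatial/temporal annotations registering one stack.

    ``rotation_deg`` is counter-clockwise positive in the (x, y) coordinate
    convention used throughout the package (x right, y down).
    """

    midline: np.ndarray  # (2, 2) array of (x, y) endpoints
    anterior_point: np.ndarray  # (x, y) marking the anterior end of the midline
    thorax_abdomen_boundary: np.ndarray  # (2, 2) segment
    he_frame: int
    frame_interval_min: float
    rotation_deg: float | None = None

    def __post_init__(self) -> None:
        self.midline = np.asarray(self.midline, dtype=float).reshape(2, 2)
        self.anterior_point = np.asarray(self.anterior_point, dtype=float).reshape(2)
        self.thorax_abdomen_boundary = np.asarray(
            self.thorax_abdomen_boundary, dtype=float
        ).reshape(2, 2)
        if self.frame_interval_min <= 0:
            raise ValidationError("frame_interval_min must be positive")
        if self.rotation_deg is None:
            self.rotation_deg = rotation_from_midline(self.midline, self.anterior_point)


def rotation_from_midline(midline: np.ndarray, anterior_point: np.ndarray) -> float:
    """Rotation (degrees, CCW positive) mapping the anterior→posterior axis onto +x.

    The returned angle is normalised to (-180, 180].
    """
    midline = np.asarray(midline, dtype=float).reshape(2, 2)
    anterior_point = np.asarray(anterior_point, dtype=float).reshape(2)
    a, b = midline
    if np.allclose(a, b):
        raise ValueError("midline endpoints coincide")
    # orient the segment anterior -> posterior
    if np.linalg.norm(a - anterior_point) <= np.linalg.norm(b - anterior_point):
        ap = b - a
    else:
        ap = a - b
    angle = -math.degrees(math.atan2(ap[1], ap[0]))
    # normalise to (-180, 180]
    angle = angle % 360.0
    if angle > 180.0:
        angle -= 360.0
    return angle


def _rotation_transform(
    shape: tuple[int, int], rotation_deg: float
) -> tuple[AffineTransform, tuple[int, int]]:
    """Affine rotating (x, y) points about the image centre, with the canvas
    enlarged so nothing is cropped; returns (transform, output (H, W))."""
    h, w = shape
    cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
    theta = math.radians(rotation_deg)
    base = (
        AffineTransform(translation=(-cx, -cy))
        + AffineTransform(rotation=theta)
        + AffineTransform(translation=(cx, cy))
    )
    corners = np.array([[0, 0], [w - 1, 0], [0, h - 1], [w - 1, h - 1]], dtype=float)
    mapped = base(corners)
    lo = mapped.min(axis=0)
    hi = mapped.max(axis=0)
    # snap the offset so right-angle rotations keep the pixel grid exact
    off = np.round(lo * 1e9) / 1e9
    tf = base + AffineTransform(translation=(-off[0], -off[1]))
    out_w = int(np.ceil(hi[0] - lo[0])) + 1
    out_h = int(np.ceil(hi[1] - lo[1])) + 1
    return tf, (out_h, out_w)


def apply_rotation(
    stack: TimeSeriesStack, frame: ReferenceFrame
) -> tuple[TimeSeriesStack, AffineTransform]:
    """Rotate every frame so the midline runs horizontally.

    Pixels are resampled with bilinear interpolation on an enlarged canvas;
    the returned :class:`~skimage.transform.AffineTransform` maps original
    (x, y) coordinates to rotated coordinates exactly, for transforming
    polygons and annotation geometry without interpolation.
    """
    rot = float(frame.rotation_deg)
    if not math.isfinite(rot):
        raise ValueError("rotation_deg must be finite")
    tf, (out_h, out_w) = _rotation_transform(stack.frame_shape, rot)
    t, c, _, _ = stack.frames.shape
    out = np.zeros((t, c, out_h, out_w), dtype=stack.frames.dtype)
    is_int = np.issubdtype(stack.frames.dtype, np.integer)
    for i in range(t):
        for ch in range(c):
            img = warp(
                stack.frames[i, ch].astype(float),
                inverse_map=tf.inverse,
                output_shape=(out_h, out_w),
                order=1,
                preserve_range=True,
                cval=0.0,
            )
            out[i, ch] = np.rint(img) if is_int else img
    return TimeSeriesStack(frames=out, metadata=stack.metadata), tf


def transform_points(points: np.ndarray, tf: AffineTransform) -> np.ndarray:
    """Apply a registration transform to an (N, 2) array of (x, y) points."""
    return tf(np.asarray(points, dtype=float).reshape(-1, 2))


def frame_to_hours_ahe(frame_idx: int, frame: ReferenceFrame) -> float:
    """Time of a frame in hours after head eversion (negative = prepupal)."""
    return (frame_idx - frame.he_frame) * frame.frame_interval_min / 60.0


def hours_ahe_to_frame(hours: float, frame: ReferenceFrame, n_frames: int | None = None) -> int:
    """Nearest frame index to a time in hours AHE; ties round toward the later frame."""
    exact = frame.he_frame + hours * 60.0 / frame.frame_interval_min
    idx = int(math.floor(exact + 0.5))
    if idx < 0 or (n_frames is not None and idx >= n_frames):
        raise IndexError(f"hours {hours} maps to frame {idx}, outside the stack")
    return idx
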