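"""Joint-angle tracking from high-speed leg videos.

The tibia carries a dark pin on a bright background. Each frame is
thresholded to isolate the pin, the pin's orientation is taken as the
long axis of the ellipse with the same normalized second central
moments as the thresholded region, and the femur–tibia joint angle is
the unsigned angle between that axis and a configured femur reference
axis. Angle traces sampled at the camera rate are linearly resampled
onto the imaging timebase for comparison with calcium signals.

Coordinate convention: pixel rows increase downward; orientations are
reported in degrees in [0, 180), measured from the +column axis and
increasing toward decreasing row (right-handed with y = −row). The
synthetic leg-video generator renders with the same convention, so
rendered and recovered angles compare directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from skimage.measure import label as cc_label

from .exceptions import (
    DataError,
    InvalidParameterError,
    NoPinDetectedError,
    OrientationUndefinedError,
)

__all__ = [
    "EllipseFit",
    "AngleTrace",
    "binarize_pin",
    "ellipse_orientation",
    "angle_from_orientation",
    "track_video",
    "resample_to_frames",
]


@dataclass(frozen=True)
class EllipseFit:
    """Equivalent-ellipse description of a binary region.

    ``mu20``/``mu02``/``mu11`` are the normalized second central
    moments (pixel²) of the region, with the 1/12 per-pixel variance of
    a unit square included on the diagonal terms; ``orientation`` is the
    long-axis direction in [0, 180) under the module's angular
    convention; ``axis_ratio`` = major/minor axis length (≥ 1).
    """

    centroid: tuple[float, float]  # (row, col)
    mu20: float
    mu02: float
    mu11: float
    orientation: float  # degrees in [0, 180)
    axis_ratio: float
    n_pixels: int


@dataclass
class AngleTrace:
    """A femur–tibia joint-angle time series."""

    times: np.ndarray  # s, strictly increasing
    angles: np.ndarray  # degrees in [0, 180]
    source_rate: float  # frames/s of the source sampling
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.angles = np.asarray(self.angles, dtype=float)
        if self.times.shape != self.angles.shape or self.times.ndim != 1:
            raise InvalidParameterError("times and angles must be equal-length 1-D")
        if len(self.times) == 0:
            raise DataError("angle trace is empty")
        if np.any(np.diff(self.times) <= 0):
            raise InvalidParameterError("times must be strictly increasing")
        if np.any(self.angles < 0) or np.any(self.angles > 180):
            raise InvalidParameterError("angles must lie in [0, 180] degrees")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_s": self.times, "angle_deg": self.angles})


def binarize_pin(
    frame: np.ndarray,
    threshold: float | None = None,
    dark_pin: bool = True,
    keep_largest: bool = True,
) -> np.ndarray:
    """Isolate the pin by intensity thresholding.

    With ``dark_pin`` (the default — pins are ink-blackened on a bright
    background) the mask is pixels strictly darker than ``threshold``;
    set ``dark_pin=False`` for inverted contrast. ``threshold`` defaults
    to the midpoint of the frame's min and max, which separates the
    strongly bimodal pin/background distribution. ``keep_largest``
    retains only the largest connected component, discarding isolated
    noise pixels.
    """
    f = np.asarray(frame, dtype=float)
    if f.ndim != 2:
        raise InvalidParameterError("frame must be 2-D")
    if not np.all(np.isfinite(f)):
        raise DataError("frame must be finite")
    if threshold is None:
        threshold = 0.5 * (f.min() + f.max())
    mask = f < threshold if dark_pin else f > threshold
    if not mask.any():
        raise NoPinDetectedError(
            f"thresholding at {threshold} produced an empty mask"
        )
    if keep_largest:
        labels = cc_label(mask, connectivity=2)
        counts = np.bincount(labels.ravel())
        counts[0] = 0
        mask = labels == int(np.argmax(counts))
    return mask


def ellipse_orientation(mask: np.ndarray) -> EllipseFit:
    """Long-axis orientation of the equivalent ellipse of a binary mask.

    The normalized second central moments of the pixel set are computed
    (each pixel treated as a unit square, adding 1/12 to the diagonal
    terms), and the orientation is ``½·atan2(2·mu11, mu20 − mu02)`` in
    the y = −row convention, mapped to [0, 180). A mask whose moment
    matrix is isotropic (a disk or a point) has no defined long axis and
    raises :class:`OrientationUndefinedError`.
    """
    mask = np.asarray(mask, dtype=bool)
    rows, cols = np.nonzero(mask)
    n = len(rows)
    if n == 0:
        raise NoPinDetectedError("mask is empty")
    if n == 1:
        raise OrientationUndefinedError("single-pixel mask has no orientation")
    x = cols.astype(float)
    y = -rows.astype(float)  # y increases toward decreasing row
    xc, yc = x.mean(), y.mean()
    dx, dy = x - xc, y - yc
    mu20 = float(np.mean(dx * dx)) + 1.0 / 12.0
    mu02 = float(np.mean(dy * dy)) + 1.0 / 12.0
    mu11 = float(np.mean(dx * dy))
    aniso = float(np.hypot(mu20 - mu02, 2.0 * mu11))
    trace = mu20 + mu02
    if aniso <= 1e-9 * trace:
        raise OrientationUndefinedError(
            "moment matrix is isotropic; long axis undefined"
        )
    theta = 0.5 * np.arctan2(2.0 * mu11, mu20 - mu02)
    orientation = float(np.rad2deg(theta) % 180.0)
    common = np.sqrt(((mu20 - mu02) / 2.0) ** 2 + mu11**2)
    lam_major = trace / 2.0 + common
    lam_minor = trace / 2.0 - common
    ratio = float(np.sqrt(lam_major / max(lam_minor, 1e-12)))
    return EllipseFit(
        centroid=(float(-yc), float(xc)),
        mu20=mu20,
        mu02=mu02,
        mu11=mu11,
        orientation=orientation,
        axis_ratio=ratio,
        n_pixels=n,
    )


def angle_from_orientation(
    fit: EllipseFit | float,
    femur_axis_angle: float,
    hinge_side: str = "ccw",
    extended_when_parallel: bool = True,
    min_angle: float = 10.0,
) -> float:
    """Femur–tibia joint angle from the tibia's image-plane orientation.

    The ellipse long axis is undirected, so the tibia direction is known
    only modulo 180°; because a physical joint cannot flip across the
    femur, the configured ``hinge_side`` (the rotation sense from the
    femur axis toward the tibia: "ccw" or "cw") resolves the ambiguity.

    A tibia parallel to the femur axis could be full flexion (0°) or
    full extension (180°). Real joints never reach 0° — passive flexion
    bottoms out near 18° — so with ``extended_when_parallel`` (the
    default) raw angles below ``min_angle`` are folded to ``180 − raw``,
    which is continuous through full extension (a measured orientation a
    hair past parallel maps to just under 180° instead of jumping to
    ~0°). Set ``extended_when_parallel=False`` for joints that genuinely
    operate near 0°.
    """
    if hinge_side not in ("ccw", "cw"):
        raise InvalidParameterError("hinge_side must be 'ccw' or 'cw'")
    orientation = fit.orientation if isinstance(fit, EllipseFit) else float(fit)
    s = 1.0 if hinge_side == "ccw" else -1.0
    theta = (s * (orientation - femur_axis_angle)) % 180.0
    if extended_when_parallel and theta < min_angle:
        theta = 180.0 - theta
    return float(theta)


def track_video(
    frames: np.ndarray | Sequence[np.ndarray],
    frame_interval: float,
    femur_axis_angle: float,
    hinge_side: str = "ccw",
    threshold: float | None = None,
    dark_pin: bool = True,
    start_time: float = 0.0,
) -> AngleTrace:
    """Per-frame joint angle of a pin video: threshold → moments → angle."""
    angles = []
    for frame in frames:
        mask = binarize_pin(frame, threshold=threshold, dark_pin=dark_pin)
        fit = ellipse_orientation(mask)
        angles.append(
            angle_from_orientation(fit, femur_axis_angle, hinge_side=hinge_side)
        )
    times = start_time + np.arange(len(angles)) * frame_interval
    return AngleTrace(
        times=times,
        angles=np.asarray(angles),
        source_rate=1.0 / frame_interval,
        metadata={"femur_axis_angle": femur_axis_angle, "hinge_side": hinge_side},
    )


def resample_to_frames(angle: AngleTrace, frame_times: np.ndarray) -> AngleTrace:
    """Linearly interpolate the angle trace onto an imaging timebase.

    Frame times outside the trace span are clamped to the first/last
    angle; the number of clamped frames is recorded in the returned
    trace's metadata.
    """
    ft = np.asarray(frame_times, dtype=float)
    if ft.ndim != 1 or len(ft) == 0:
        raise DataError("frame_times must be a nonempty 1-D array")
    resampled = np.interp(ft, angle.times, angle.angles)
    clamped = int(np.sum((ft < angle.times[0]) | (ft > angle.times[-1])))
    rate = 1.0 / float(np.median(np.diff(ft))) if len(ft) > 1 else angle.source_rate
    meta = dict(angle.metadata)
    meta["clamped_frames"] = clamped
    return AngleTrace(times=ft, angles=resampled, source_rate=rate, metadata=meta)
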