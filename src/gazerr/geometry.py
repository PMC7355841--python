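"""Screen geometry and angular gaze-error computation.

Raw eye-tracker output is a stream of on-screen pixel coordinates for the
left and right eye together with the ground-truth stimulus (AOI) position.
Accuracy is conventionally reported in degrees of visual angle, so every
analysis in this package starts by converting pixel traces into gaze
angles.  With the origin at the screen centre, x rightward and y downward,
a point at pixel offset (GazeX, GazeY) viewed from distance ``Z`` mm
subtends

    OSD    = mu * sqrt(GazeX^2 + GazeY^2)          (on-screen distance, mm)
    theta  = atan(OSD / Z)                          (frontal gaze angle)
    yaw    = atan(mu * GazeX / Z)
    pitch  = atan(mu * GazeY / Z)

where ``mu`` is the pixel pitch of the display (mm per pixel).  Signed
angular errors are the per-sample differences between estimated and
ground-truth angles, for the frontal, yaw and pitch components.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "ScreenGeometry",
    "RawGazeSession",
    "AngularTrace",
    "ErrorTrace",
    "DESKTOP_SCREEN",
    "TABLET_SCREEN",
    "pixel_pitch",
    "combine_eyes",
    "to_angles",
    "compute_errors",
    "angles_to_pixels",
]


class InvalidGeometryError(ValueError):
    """Raised for nonpositive screen dimensions or distances."""


@dataclass(frozen=True)
class ScreenGeometry:
    """Physical display description.

    The coordinate convention throughout the package is: origin at the
    screen centre, x positive rightward, y positive downward, units of
    pixels for raw data and millimetres for physical distances.
    """

    width_px: int
    height_px: int
    diagonal_mm: float

    def __post_init__(self) -> None:
        if self.width_px <= 0 or self.height_px <= 0 or self.diagonal_mm <= 0:
            raise InvalidGeometryError(
                f"screen dimensions must be positive, got "
                f"{self.width_px}x{self.height_px}, diagonal {self.diagonal_mm}"
            )

    @property
    def diagonal_px(self) -> float:
        return float(np.hypot(self.width_px, self.height_px))

    @property
    def pixel_pitch_mm(self) -> float:
        return self.diagonal_mm / self.diagonal_px


#: 22-inch desktop monitor, 1680x1050 (22 in = 558.8 mm diagonal).
DESKTOP_SCREEN = ScreenGeometry(width_px=1680, height_px=1050, diagonal_mm=558.8)
#: 10.1-inch tablet, 1920x800 (10.1 in = 256.54 mm diagonal).
TABLET_SCREEN = ScreenGeometry(width_px=1920, height_px=800, diagonal_mm=256.54)


def pixel_pitch(geom: ScreenGeometry) -> float:
    """Pixel pitch mu in mm/pixel: physical diagonal over pixel diagonal."""
    return geom.pixel_pitch_mm


@dataclass
class RawGazeSession:
    """One recording: binocular pixel gaze plus ground-truth AOI trace.

    All coordinate arrays are pixels relative to the screen centre and have
    equal length; missing tracker samples are NaN.
    """

    timestamps_ms: np.ndarray
    x_left: np.ndarray
    y_left: np.ndarray
    x_right: np.ndarray
    y_right: np.ndarray
    aoi_x: np.ndarray
    aoi_y: np.ndarray
    z_mm: float
    platform: str = "desktop"
    condition: str = ""
    participant: str = ""
    screen: ScreenGeometry = field(default=DESKTOP_SCREEN)

    def __post_init__(self) -> None:
        arrays = [
            self.timestamps_ms, self.x_left, self.y_left,
            self.x_right, self.y_right, self.aoi_x, self.aoi_y,
        ]
        n = len(arrays[0])
        if any(len(a) != n for a in arrays):
            raise ValueError("all session arrays must have equal length")
        if np.any(np.diff(np.asarray(self.timestamps_ms, dtype=float)) < 0):
            raise ValueError("timestamps must be nondecreasing")

    def __len__(self) -> int:
        return len(self.timestamps_ms)


@dataclass
class AngularTrace:
    """Gaze and ground-truth angles in degrees, one entry per sample."""

    theta_gaze: np.ndarray
    theta_gt: np.ndarray
    theta_yaw: np.ndarray
    theta_pitch: np.ndarray
    aoi_yaw: np.ndarray
    aoi_pitch: np.ndarray
    osd_mm: np.ndarray
    osd_gt_mm: np.ndarray

    def __len__(self) -> int:
        return len(self.theta_gaze)


@dataclass
class ErrorTrace:
    """Signed angular errors (degrees) per sample, with session metadata.

    ``aoi_index`` assigns each sample to its ground-truth AOI (1..15,
    row-major) when known; it drives per-AOI feature aggregation and the
    flip augmentations.
    """

    err_frontal: np.ndarray
    err_yaw: np.ndarray
    err_pitch: np.ndarray
    condition: str = ""
    participant: str = ""
    platform: str = "desktop"
    aoi_index: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if not (len(self.err_frontal) == len(self.err_yaw) == len(self.err_pitch)):
            raise ValueError("error arrays must have equal length")

    def __len__(self) -> int:
        return len(self.err_frontal)

    def category(self, name: str) -> np.ndarray:
        """Return the error series for one of {frontal, yaw, pitch}."""
        try:
            return {"frontal": self.err_frontal,
                    "yaw": self.err_yaw,
                    "pitch": self.err_pitch}[name]
        except KeyError:
            raise KeyError(f"unknown error category {name!r}") from None


def combine_eyes(session: RawGazeSession) -> tuple[np.ndarray, np.ndarray]:
    """Binocular average per sample: the cyclopean gaze point in pixels.

    GazeX = (X_left + X_right)/2 and likewise for y.  NaN in either eye
    propagates, so dropouts remain visible to the imputation step.
    """
    gx = (np.asarray(session.x_left, float) + np.asarray(session.x_right, float)) / 2.0
    gy = (np.asarray(session.y_left, float) + np.asarray(session.y_right, float)) / 2.0
    return gx, gy


def to_angles(
    gaze_px: tuple[np.ndarray, np.ndarray],
    aoi_px: tuple[np.ndarray, np.ndarray],
    geom: ScreenGeometry,
    z_mm: float,
) -> AngularTrace:
    """Convert pixel gaze and ground-truth traces to angles in degrees.

    Pixel offsets are scaled to millimetres with the pixel pitch before the
    arctangent so that yaw/pitch are dimensionally consistent with the
    frontal angle.
    """
    if z_mm <= 0:
        raise InvalidGeometryError(f"viewing distance must be positive, got {z_mm}")
    mu = geom.pixel_pitch_mm
    gx = np.asarray(gaze_px[0], float)
    gy = np.asarray(gaze_px[1], float)
    ax = np.asarray(aoi_px[0], float)
    ay = np.asarray(aoi_px[1], float)

    osd = mu * np.hypot(gx, gy)
    osd_gt = mu * np.hypot(ax, ay)
    return AngularTrace(
        theta_gaze=np.degrees(np.arctan(osd / z_mm)),
        theta_gt=np.degrees(np.arctan(osd_gt / z_mm)),
        theta_yaw=np.degrees(np.arctan(mu * gx / z_mm)),
        theta_pitch=np.degrees(np.arctan(mu * gy / z_mm)),
        aoi_yaw=np.degrees(np.arctan(mu * ax / z_mm)),
        aoi_pitch=np.degrees(np.arctan(mu * ay / z_mm)),
        osd_mm=osd,
        osd_gt_mm=osd_gt,
    )


def angles_to_pixels(
    yaw_deg: np.ndarray, pitch_deg: np.ndarray, geom: ScreenGeometry, z_mm: float
) -> tuple[np.ndarray, np.ndarray]:
    """Inverse of the yaw/pitch conversion: angles back to centre-origin pixels."""
    if z_mm <= 0:
        raise InvalidGeometryError(f"viewing distance must be positive, got {z_mm}")
    mu = geom.pixel_pitch_mm
    x = z_mm * np.tan(np.radians(np.asarray(yaw_deg, float))) / mu
    y = z_mm * np.tan(np.radians(np.asarray(pitch_deg, float))) / mu
    return x, y


def compute_errors(
    ang: AngularTrace,
    *,
    condition: str = "",
    participant: str = "",
    platform: str = "desktop",
    aoi_index: Optional[np.ndarray] = None,
) -> ErrorTrace:
    """Signed angular errors: estimated minus ground-truth, per component."""
    n = len(ang.theta_gaze)
    for name in ("theta_gt", "theta_yaw", "theta_pitch", "aoi_yaw", "aoi_pitch"):
        if len(getattr(ang, name)) != n:
            raise ValueError("angular trace arrays are misaligned")
    return ErrorTrace(
        err_frontal=ang.theta_gaze - ang.theta_gt,
        err_yaw=ang.theta_yaw - ang.aoi_yaw,
        err_pitch=ang.theta_pitch - ang.aoi_pitch,
        condition=condition,
        participant=participant,
        platform=platform,
        aoi_index=aoi_index,
    )
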