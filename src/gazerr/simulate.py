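"""Synthetic gaze-session simulator.

Emulates a fixation-accuracy study: 20 participants look at a dot stepping
through a 5x3 grid of AOI locations (3-s dwell each) on a desktop monitor
or a tablet, while one operating condition at a time perturbs the tracker
output — user distance 50/60/70/80 cm, or a 20-degree head pose (desktop)
/ platform pose (tablet) in roll, pitch or yaw.

Each condition is described by an :class:`ErrorProfile`:

* ``bias_mean`` — the target mean absolute frontal angular error of the
  condition, in degrees.  A per-participant radial bias is drawn as
  N(bias_mean, (participant_cv * bias_mean)^2) once per session.
* ``dispersion`` — per-sample angular scatter (degrees) around the bias.
* ``anisotropy`` — (yaw_gain, pitch_gain) weighting of tangential jitter,
  shaping how the error splits into yaw/pitch components (head yaw mostly
  produces horizontal error, head pitch vertical error).
* ``outlier_rate`` / ``outlier_scale`` — heavy-tailed spike contamination.
* ``missing_rate`` — tracker dropouts, emitted as NaN samples.

Gaze points are placed radially: a sample's frontal angle is the ground
truth angle plus the drawn angular offset, so after outlier removal the
pooled mean absolute frontal error of a condition converges to
``bias_mean`` by construction.  The default profiles encode the observed
per-condition error magnitudes of a 20-participant desktop/tablet study
(e.g. desktop 50 cm: 3.37 deg; tablet platform roll 20 deg: 7.74 deg).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import (
    DESKTOP_SCREEN,
    TABLET_SCREEN,
    RawGazeSession,
    ScreenGeometry,
    angles_to_pixels,
)

__all__ = [
    "AoiGrid",
    "ErrorProfile",
    "SimulationSpec",
    "make_aoi_grid",
    "default_profiles",
    "condition_z_mm",
    "simulate_session",
    "simulate_study",
    "DESKTOP_CONDITIONS",
    "TABLET_CONDITIONS",
]

DESKTOP_CONDITIONS = ("UD50", "UD60", "UD70", "UD80", "roll20", "pitch20", "yaw20")
TABLET_CONDITIONS = DESKTOP_CONDITIONS  # pose conditions are platform poses


@dataclass(frozen=True)
class AoiGrid:
    """5x3 lattice of stimulus dot centres, row-major AOI-1..AOI-15."""

    centers_x: np.ndarray           # pixels, centre origin
    centers_y: np.ndarray
    rows: int = 3
    cols: int = 5
    dwell_s: float = 3.0

    @property
    def n_aoi(self) -> int:
        return self.rows * self.cols


def make_aoi_grid(geom: ScreenGeometry, rows: int = 3, cols: int = 5) -> AoiGrid:
    """Equal-margin lattice; the middle AOI sits at the screen centre."""
    xs = (np.arange(cols) + 0.5) / cols * geom.width_px - geom.width_px / 2.0
    ys = (np.arange(rows) + 0.5) / rows * geom.height_px - geom.height_px / 2.0
    gx, gy = np.meshgrid(xs, ys)                   # row-major: rows outer
    return AoiGrid(centers_x=gx.ravel(), centers_y=gy.ravel(), rows=rows, cols=cols)


@dataclass(frozen=True)
class ErrorProfile:
    condition: str
    bias_mean: float                 # degrees, target mean |frontal error|
    dispersion: float                # degrees, per-sample scatter
    participant_cv: float = 0.12     # between-participant CV of the bias
    anisotropy: tuple[float, float] = (1.0, 1.0)   # (yaw_gain, pitch_gain)
    tangential_sigma: float = 0.2    # degrees, direction-shaping jitter
    outlier_rate: float = 0.0
    outlier_scale: float = 8.0       # spike size in units of dispersion
    missing_rate: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.outlier_rate < 1.0 and 0.0 <= self.missing_rate < 1.0):
            raise ValueError("rates must lie in [0, 1)")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")


# Per-condition targets: (mean |error| deg, dispersion deg, anisotropy,
# outlier rate).  Dispersion is IQR/1.349 of the observed error spread.
_DESKTOP_TABLE = {
    "UD50":    (3.37, 0.84, (1.0, 1.0), 0.05),
    "UD60":    (2.04, 0.57, (1.0, 1.0), 0.05),
    "UD70":    (1.21, 0.56, (1.0, 1.0), 0.05),
    "UD80":    (1.02, 0.59, (1.0, 1.0), 0.05),
    "roll20":  (3.70, 0.90, (1.2, 1.2), 0.05),
    "yaw20":   (8.51, 1.10, (1.7, 0.6), 0.05),
    "pitch20": (3.15, 1.18, (0.6, 1.7), 0.05),
}
_TABLET_TABLE = {
    "UD50":    (2.68, 0.29, (1.0, 1.0), 0.02),
    "UD60":    (2.46, 0.40, (1.0, 1.0), 0.02),
    "UD70":    (0.59, 0.24, (1.0, 1.0), 0.02),
    "UD80":    (1.55, 0.16, (1.0, 1.0), 0.02),
    "roll20":  (7.74, 0.56, (1.3, 1.3), 0.02),
    "yaw20":   (4.25, 0.39, (1.7, 0.6), 0.02),
    "pitch20": (2.45, 0.17, (0.6, 1.7), 0.02),
}


def default_profiles(platform: str) -> dict[str, ErrorProfile]:
    """Per-condition error profiles for the desktop or tablet platform."""
    try:
        table = {"desktop": _DESKTOP_TABLE, "tablet": _TABLET_TABLE}[platform]
    except KeyError:
        raise ValueError(f"unknown platform {platform!r}") from None
    return {
        cond: ErrorProfile(
            condition=cond, bias_mean=mean, dispersion=disp,
            anisotropy=aniso, outlier_rate=orate, missing_rate=0.02,
        )
        for cond, (mean, disp, aniso, orate) in table.items()
    }


def condition_z_mm(condition: str) -> float:
    """Viewing distance of a condition; pose conditions run at 60 cm."""
    if condition.startswith("UD"):
        return float(condition[2:]) * 10.0
    return 600.0


@dataclass(frozen=True)
class SimulationSpec:
    platform: str = "desktop"
    participants: int = 20
    samples_per_aoi: int = 41
    seed: int = 0
    screen: ScreenGeometry | None = None

    def __post_init__(self) -> None:
        if self.participants < 1 or self.samples_per_aoi < 5:
            raise ValueError("need >=1 participant and >=5 samples per AOI")
        if self.platform not in ("desktop", "tablet"):
            raise ValueError(f"unknown platform {self.platform!r}")

    @property
    def geometry(self) -> ScreenGeometry:
        if self.screen is not None:
            return self.screen
        return DESKTOP_SCREEN if self.platform == "desktop" else TABLET_SCREEN


def simulate_session(
    spec: SimulationSpec,
    profile: ErrorProfile,
    participant: int,
    seed: int,
) -> RawGazeSession:
    """Simulate one participant-condition recording.

    For each of the 15 AOIs in sequence, ``samples_per_aoi`` gaze samples
    are produced at the ground-truth angle plus a radial angular offset
    (participant bias + per-sample dispersion + occasional outlier spikes)
    and anisotropic tangential jitter, then converted back to on-screen
    pixels.  Binocular output is two copies with small independent pixel
    noise; dropouts are NaN in all four eye coordinates.
    """
    rng = np.random.default_rng(seed)
    geom = spec.geometry
    grid = make_aoi_grid(geom)
    z = condition_z_mm(profile.condition)
    mu = geom.pixel_pitch_mm

    n_aoi = grid.n_aoi
    spa = spec.samples_per_aoi
    n = n_aoi * spa

    # ground-truth pixel trace and per-sample AOI ids (row-major 1..15)
    aoi_x = np.repeat(grid.centers_x, spa)
    aoi_y = np.repeat(grid.centers_y, spa)

    # ground-truth frontal angle of each sample
    theta_gt = np.degrees(np.arctan(mu * np.hypot(aoi_x, aoi_y) / z))

    # radial unit direction of each AOI in pixel space; the centre AOI
    # gets a per-participant random direction
    norm = np.hypot(aoi_x, aoi_y)
    centre = norm == 0
    safe = np.where(centre, 1.0, norm)
    ux = np.where(centre, 0.0, aoi_x / safe)
    uy = np.where(centre, 0.0, aoi_y / safe)
    if centre.any():
        phi = rng.uniform(0, 2 * np.pi)
        ux = np.where(centre, np.cos(phi), ux)
        uy = np.where(centre, np.sin(phi), uy)

    # radial angular offset: participant bias + per-sample scatter + spikes
    bias = rng.normal(profile.bias_mean,
                      profile.participant_cv * profile.bias_mean)
    delta = bias + rng.normal(0.0, profile.dispersion, size=n)
    spikes = rng.random(n) < profile.outlier_rate
    spike_mag = profile.outlier_scale * profile.dispersion \
        * (1.0 + np.abs(rng.standard_normal(n)))
    delta = delta + spikes * rng.choice([-1.0, 1.0], size=n) * spike_mag

    # place the gaze point at the radius whose frontal angle is exactly
    # theta_gt + delta, so the frontal angular error equals delta
    theta = np.clip(theta_gt + delta, 0.0, 89.0)
    radius_px = z * np.tan(np.radians(theta)) / mu
    gx = radius_px * ux
    gy = radius_px * uy

    # anisotropic tangential jitter (degrees -> pixels) shapes how the
    # error splits into yaw/pitch components; zero-mean, so it perturbs
    # the frontal error only at second order
    gy_gain, gp_gain = profile.anisotropy
    jx, jy = angles_to_pixels(
        rng.normal(0, profile.tangential_sigma * gy_gain, n),
        rng.normal(0, profile.tangential_sigma * gp_gain, n),
        geom, z,
    )
    gx = gx + jx
    gy = gy + jy

    # binocular: two noisy copies (1 px of per-eye sensor noise)
    eye_sd = 1.0
    x_left = gx + rng.normal(0, eye_sd, n)
    y_left = gy + rng.normal(0, eye_sd, n)
    x_right = gx + rng.normal(0, eye_sd, n)
    y_right = gy + rng.normal(0, eye_sd, n)

    missing = rng.random(n) < profile.missing_rate
    for arr in (x_left, y_left, x_right, y_right):
        arr[missing] = np.nan

    dt = grid.dwell_s * 1000.0 / spa
    timestamps = np.arange(n) * dt
    return RawGazeSession(
        timestamps_ms=timestamps,
        x_left=x_left, y_left=y_left, x_right=x_right, y_right=y_right,
        aoi_x=aoi_x, aoi_y=aoi_y,
        z_mm=z, platform=spec.platform, condition=profile.condition,
        participant=f"P{participant:02d}", screen=geom,
    )


def aoi_schedule(spec: SimulationSpec) -> np.ndarray:
    """Per-sample AOI ids (1..15) of a simulated session."""
    grid = make_aoi_grid(spec.geometry)
    return np.repeat(np.arange(1, grid.n_aoi + 1), spec.samples_per_aoi)


def simulate_study(
    spec: SimulationSpec,
    profiles: dict[str, ErrorProfile] | None = None,
) -> list[RawGazeSession]:
    """All participants x conditions for one platform (neutral == UD60).

    Session seeds are derived from ``spec.seed`` via a SeedSequence so the
    study is reproducible as a whole and per session.
    """
    if profiles is None:
        profiles = default_profiles(spec.platform)
    conditions = list(profiles)
    sessions = []
    ss = np.random.SeedSequence(spec.seed)
    seeds = ss.generate_state(spec.participants * len(conditions)) & 0x7FFFFFFF
    i = 0
    for p in range(1, spec.participants + 1):
        for cond in conditions:
            sessions.append(
                simulate_session(spec, profiles[cond], p, int(seeds[i]))
            )
            i += 1
    return sessions
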