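"""CSV I/O for raw gaze sessions and feature datasets.

Session dialect: one file per participant-condition with header
``timestamp_ms,x_left,y_left,x_right,y_right,aoi_x,aoi_y``; coordinates
are pixels relative to the screen centre (a ``top_left_origin`` flag
shifts display-coordinate files at load); missing samples are empty
fields.  Metadata travels in the filename pattern
``<platform>_<condition>_P<participant>.csv`` or a sidecar YAML manifest.
A column-name map adapts files with foreign headers.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .geometry import DESKTOP_SCREEN, TABLET_SCREEN, RawGazeSession, ScreenGeometry

__all__ = [
    "SESSION_COLUMNS",
    "session_filename",
    "write_session_csv",
    "read_session_csv",
    "write_study",
    "read_study",
    "write_features_csv",
    "read_features_csv",
]

SESSION_COLUMNS = (
    "timestamp_ms", "x_left", "y_left", "x_right", "y_right", "aoi_x", "aoi_y",
)

_FILENAME_RE = re.compile(r"(?P<platform>[a-z]+)_(?P<condition>[A-Za-z0-9]+)_P(?P<participant>\d+)\.csv$")


def session_filename(session: RawGazeSession) -> str:
    pid = session.participant.lstrip("P") or "0"
    return f"{session.platform}_{session.condition}_P{int(pid):02d}.csv"


def write_session_csv(session: RawGazeSession, path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame({
        "timestamp_ms": session.timestamps_ms,
        "x_left": session.x_left, "y_left": session.y_left,
        "x_right": session.x_right, "y_right": session.y_right,
        "aoi_x": session.aoi_x, "aoi_y": session.aoi_y,
    })
    df.to_csv(path, index=False, float_format="%.6f", na_rep="")
    return path


def read_session_csv(
    path: str | Path,
    z_mm: float | None = None,
    platform: str | None = None,
    condition: str | None = None,
    participant: str | None = None,
    screen: ScreenGeometry | None = None,
    column_map: dict[str, str] | None = None,
    top_left_origin: bool = False,
) -> RawGazeSession:
    """Load one session CSV; metadata defaults from the filename pattern."""
    path = Path(path)
    m = _FILENAME_RE.search(path.name)
    if m:
        platform = platform or m["platform"]
        condition = condition or m["condition"]
        participant = participant or f"P{int(m['participant']):02d}"
    platform = platform or "desktop"
    if screen is None:
        screen = TABLET_SCREEN if platform == "tablet" else DESKTOP_SCREEN
    if z_mm is None:
        from .simulate import condition_z_mm
        z_mm = condition_z_mm(condition or "UD60")

    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=column_map)
    missing_cols = set(SESSION_COLUMNS) - set(df.columns)
    if missing_cols:
        raise ValueError(f"{path.name}: missing columns {sorted(missing_cols)}")
    coords = {c: df[c].to_numpy(float) for c in SESSION_COLUMNS}
    if top_left_origin:
        for c in ("x_left", "x_right", "aoi_x"):
            coords[c] = coords[c] - screen.width_px / 2.0
        for c in ("y_left", "y_right", "aoi_y"):
            coords[c] = coords[c] - screen.height_px / 2.0
    return RawGazeSession(
        timestamps_ms=coords["timestamp_ms"],
        x_left=coords["x_left"], y_left=coords["y_left"],
        x_right=coords["x_right"], y_right=coords["y_right"],
        aoi_x=coords["aoi_x"], aoi_y=coords["aoi_y"],
        z_mm=float(z_mm), platform=platform,
        condition=condition or "", participant=participant or "",
        screen=screen,
    )


def write_study(sessions, outdir: str | Path, manifest_extra: dict | None = None) -> Path:
    """Write session CSVs plus a study.yaml manifest; returns the manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    entries = []
    for s in sessions:
        fname = session_filename(s)
        write_session_csv(s, outdir / fname)
        entries.append({
            "file": fname, "platform": s.platform, "condition": s.condition,
            "participant": s.participant, "z_mm": float(s.z_mm),
        })
    manifest = {
        "sessions": entries,
        "screen": {
            s.platform: {
                "width_px": s.screen.width_px,
                "height_px": s.screen.height_px,
                "diagonal_mm": s.screen.diagonal_mm,
            } for s in sessions
        },
        # the condition mean is pooled over samples, not a mean of
        # per-participant means
        "mean_definition": "pooled_samples",
    }
    if manifest_extra:
        manifest.update(manifest_extra)
    mpath = outdir / "study.yaml"
    mpath.write_text(yaml.safe_dump(manifest, sort_keys=True))
    return mpath


def read_study(outdir: str | Path) -> list[RawGazeSession]:
    """Load every session listed in a study.yaml manifest."""
    outdir = Path(outdir)
    manifest = yaml.safe_load((outdir / "study.yaml").read_text())
    sessions = []
    for entry in manifest["sessions"]:
        scr = manifest["screen"][entry["platform"]]
        sessions.append(read_session_csv(
            outdir / entry["file"],
            z_mm=entry["z_mm"], platform=entry["platform"],
            condition=entry["condition"], participant=entry["participant"],
            screen=ScreenGeometry(scr["width_px"], scr["height_px"],
                                  scr["diagonal_mm"]),
        ))
    return sessions


def write_features_csv(dataset, path: str | Path) -> Path:
    """One row per sample: 20 feature columns + label and provenance."""
    path = Path(path)
    dataset.to_frame().to_csv(path, index=False)
    return path


def read_features_csv(path: str | Path):
    from .features import FEATURE_NAMES, LabeledDataset

    df = pd.read_csv(path, float_precision="round_trip")
    feat = [c for c in FEATURE_NAMES if c in df.columns]
    prov_cols = [c for c in ("participant", "category", "variant") if c in df.columns]
    return LabeledDataset(
        matrix=df[feat].to_numpy(float),
        labels=df["label"].to_numpy(str),
        feature_names=tuple(feat),
        provenance=df[prov_cols] if prov_cols else None,
    )
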