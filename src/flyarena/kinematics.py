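"""Per-frame kinematic features of arena trajectories.

All metrics are defined over pairs of consecutive frames within a fly;
wherever the tracker dropped a frame the derived value is missing (NaN)
rather than bridged.  Features:

``speed``
    centroid displacement x fps, mm/s;
``dtheta_abs``
    absolute wrapped heading change per frame, rad, in [0, pi];
``cos_upwind``
    cosine of the angle between the heading and the radially outward
    direction — air is withdrawn through the centre hole, so outward is
    upwind; +1 facing away from the centre, -1 facing it;
``dist_center``
    distance from the arena centre, mm;
``cum_turn_5``
    trailing sum of ``dtheta_abs`` over five inter-frame changes
    (~167 ms at 30 fps).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .arena import ArenaGeometry, FlyTrackTable

__all__ = [
    "wrap_angle",
    "compute_heading",
    "compute_speed",
    "compute_angular_change",
    "compute_cos_upwind",
    "compute_cumulative_turning",
    "compute_distance_from_center",
    "frame_metrics",
]

#: displacements below this are treated as jitter: heading is held (mm)
DEFAULT_MIN_STEP = 0.1
#: radial direction is undefined closer to the suction hole than this (mm)
CENTER_EXCLUSION_MM = 0.5


def wrap_angle(angle):
    """Wrap to (-pi, pi]; absolute value is at most pi."""
    return -((np.pi - np.asarray(angle)) % (2.0 * np.pi) - np.pi)


def _consecutive(df: pd.DataFrame) -> pd.Series:
    return df.groupby("fly_id", sort=False)["frame"].diff() == 1


def compute_heading(tracks: FlyTrackTable, min_step: float = DEFAULT_MIN_STEP) -> pd.Series:
    """Heading (rad) per frame, aligned to ``tracks.data``.

    Uses the tracker-supplied body orientation where a ``heading`` column is
    present and non-missing; otherwise the direction of the frame-to-frame
    displacement, held unchanged while the fly moves less than ``min_step``
    mm per frame.  The first frame of a fly (and frames before the fly ever
    moved) have undefined heading (NaN).
    """
    df = tracks.data
    g = df.groupby("fly_id", sort=False)
    consec = _consecutive(df)
    dx = g["x"].diff()
    dy = g["y"].diff()
    step = np.hypot(dx, dy)
    raw = pd.Series(np.arctan2(dy, dx), index=df.index)
    raw[~(consec & (step >= min_step))] = np.nan
    displacement = raw.groupby(df["fly_id"], sort=False).ffill()
    if "heading" in df.columns:
        return df["heading"].astype(float).combine_first(displacement).rename("heading")
    return displacement.rename("heading")


def compute_speed(tracks: FlyTrackTable) -> pd.Series:
    """Walking speed (mm/s): centroid displacement x fps, NaN at gaps."""
    df = tracks.data
    g = df.groupby("fly_id", sort=False)
    speed = np.hypot(g["x"].diff(), g["y"].diff()) * tracks.fps
    speed[~_consecutive(df)] = np.nan
    return pd.Series(speed, index=df.index, name="speed")


def compute_angular_change(tracks: FlyTrackTable, heading: pd.Series, signed: bool = False) -> pd.Series:
    """Heading change per frame (rad), wrapped to (-pi, pi].

    ``signed=False`` (default) returns the absolute change — the "angular"
    metric; ``signed=True`` keeps the turn direction.
    """
    df = tracks.data
    dh = heading.groupby(df["fly_id"], sort=False).diff()
    dh[~_consecutive(df)] = np.nan
    out = wrap_angle(dh)
    out = pd.Series(out, index=df.index)
    if not signed:
        out = out.abs()
    return out.rename("dtheta" if signed else "dtheta_abs")


def compute_cos_upwind(
    tracks: FlyTrackTable,
    geometry: ArenaGeometry,
    heading: pd.Series,
    center_exclusion_mm: float = CENTER_EXCLUSION_MM,
) -> pd.Series:
    """Cosine of heading relative to the radially outward (upwind) direction.

    Missing where the heading is undefined or the fly is within
    ``center_exclusion_mm`` of the centre, where the radial direction is
    undefined (the suction hole).
    """
    df = tracks.data
    rx = df["x"] - geometry.center_x
    ry = df["y"] - geometry.center_y
    r = np.hypot(rx, ry)
    with np.errstate(invalid="ignore", divide="ignore"):
        cosu = (np.cos(heading) * rx + np.sin(heading) * ry) / r
    cosu = pd.Series(cosu, index=df.index)
    cosu[r < center_exclusion_mm] = np.nan
    return cosu.clip(-1.0, 1.0).rename("cos_upwind")


def compute_cumulative_turning(
    tracks: FlyTrackTable, dtheta: pd.Series, window_frames: int = 5
) -> pd.Series:
    """Trailing sum of per-frame turning over ``window_frames`` changes.

    Missing wherever any change inside the window is missing (i.e. the
    window crosses a tracking gap or the start of the track).
    """
    if window_frames < 2:
        raise ValueError(f"window_frames must be >= 2, got {window_frames}")
    df = tracks.data
    out = (
        dtheta.groupby(df["fly_id"], sort=False)
        .rolling(window_frames, min_periods=window_frames)
        .sum()
        .reset_index(level=0, drop=True)
    )
    # rolling skips NaNs only with min_periods < window; enforce missing-on-gap
    gap = dtheta.isna().astype(float)
    bad = (
        gap.groupby(df["fly_id"], sort=False)
        .rolling(window_frames, min_periods=1)
        .max()
        .reset_index(level=0, drop=True)
    )
    out[bad > 0] = np.nan
    return out.rename(f"cum_turn_{window_frames}")


def compute_distance_from_center(tracks: FlyTrackTable, geometry: ArenaGeometry) -> pd.Series:
    df = tracks.data
    return pd.Series(
        np.hypot(df["x"] - geometry.center_x, df["y"] - geometry.center_y),
        index=df.index,
        name="dist_center",
    )


def frame_metrics(
    tracks: FlyTrackTable,
    geometry: ArenaGeometry,
    window_frames: int = 5,
    min_step: float = DEFAULT_MIN_STEP,
) -> pd.DataFrame:
    """All per-frame kinematic features in one table.

    Returns a DataFrame with columns ``fly_id, frame, t, speed, dtheta_abs,
    cos_upwind, dist_center, cum_turn_5`` (the last named after
    ``window_frames``).
    """
    heading = compute_heading(tracks, min_step=min_step)
    dtheta_abs = compute_angular_change(tracks, heading)
    out = tracks.data[["fly_id", "frame", "t"]].copy()
    out["speed"] = compute_speed(tracks)
    out["dtheta_abs"] = dtheta_abs
    out["cos_upwind"] = compute_cos_upwind(tracks, geometry, heading)
    out["dist_center"] = compute_distance_from_center(tracks, geometry)
    out[f"cum_turn_{window_frames}"] = compute_cumulative_turning(tracks, dtheta_abs, window_frames)
    return out
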