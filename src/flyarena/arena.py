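"""Arena geometry, trajectory tables, and stimulus schedules.

Conventions used throughout the package:

* positions are in millimetres in arena-centred coordinates (x rightward,
  y upward); angles are in radians, counter-clockwise from +x;
* time intervals are half-open ``[t_start, t_end)``; frame ``n`` covers
  ``[n/fps, (n+1)/fps)``, so a frame belongs to exactly one epoch per
  channel;
* missing frames (tracking dropouts) are kept as gaps and never
  interpolated — downstream metrics are computed only over pairs of
  consecutive frames.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ArenaGeometry",
    "FlyTrackTable",
    "Epoch",
    "ProtocolSchedule",
    "TrackFormatError",
    "CalibrationError",
    "TrackDataError",
    "ProtocolError",
    "load_tracks",
    "write_tracks",
    "load_geometry",
    "save_geometry",
    "build_schedule",
    "read_schedule",
    "write_schedule",
    "slice_epoch",
    "swap_odor_labels",
]

REQUIRED_COLUMNS = ("frame", "fly_id", "x", "y")

#: quadrant labels used by the odor-conditioning assay
PAIRED, UNPAIRED = "paired", "unpaired"
#: quadrant labels used by the light-preference assay
LIT, UNLIT = "lit", "unlit"


class TrackFormatError(ValueError):
    """Tracker file does not have the expected columns / layout."""


class CalibrationError(ValueError):
    """Calibrated coordinates fall outside the arena."""


class TrackDataError(ValueError):
    """Track table violates an invariant (e.g. non-monotone frames)."""


class ProtocolError(ValueError):
    """Unknown or malformed stimulus protocol."""


def _default_odor_assignment() -> dict[int, str]:
    return {0: PAIRED, 1: UNPAIRED, 2: PAIRED, 3: UNPAIRED}


@dataclass(frozen=True)
class ArenaGeometry:
    """Circular four-quadrant arena.

    The arena is a 10 cm diameter, 3 mm high circular chamber with air drawn
    out through a central hole, so "upwind" is radially outward.  Diagonal
    quadrants carry the same odor (or light) and form a two-and-two
    assignment.

    Parameters
    ----------
    center_x, center_y
        Arena centre in the coordinates of the raw tracker file (mm).
    radius
        Arena radius in mm (default 50 for the 10 cm arena).
    px_per_mm
        Calibration factor for tracker files recorded in pixels.
    quadrant_phase
        Angle (rad) of the first quadrant boundary; quadrant ``q`` spans
        ``[phase + q*pi/2, phase + (q+1)*pi/2)``.
    odor_assignment
        Mapping quadrant index -> label; diagonal quadrants must share a
        label and exactly two labels must be used.
    """

    center_x: float = 0.0
    center_y: float = 0.0
    radius: float = 50.0
    px_per_mm: float = 1.0
    quadrant_phase: float = 0.0
    odor_assignment: Mapping[int, str] = field(default_factory=_default_odor_assignment)

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError(f"radius must be > 0, got {self.radius}")
        if self.px_per_mm <= 0:
            raise ValueError(f"px_per_mm must be > 0, got {self.px_per_mm}")
        if set(self.odor_assignment) != {0, 1, 2, 3}:
            raise ValueError("odor_assignment must label exactly quadrants 0-3")
        a = self.odor_assignment
        if a[0] != a[2] or a[1] != a[3] or a[0] == a[1]:
            raise ValueError(
                "diagonal quadrants must share a label and the two diagonals "
                f"must differ, got {dict(a)}"
            )

    @property
    def labels(self) -> tuple[str, str]:
        """The two quadrant labels as (label of quadrant 0, label of quadrant 1)."""
        return (self.odor_assignment[0], self.odor_assignment[1])

    def quadrants_with(self, label: str) -> tuple[int, ...]:
        return tuple(q for q, v in self.odor_assignment.items() if v == label)


def swap_odor_labels(assignment: Mapping[int, str]) -> dict[int, str]:
    """Swap the two labels of a quadrant assignment (reciprocal run)."""
    labels = sorted(set(assignment.values()))
    if len(labels) != 2:
        raise ValueError("assignment must use exactly two labels")
    other = {labels[0]: labels[1], labels[1]: labels[0]}
    return {q: other[v] for q, v in assignment.items()}


@dataclass
class FlyTrackTable:
    """Calibrated per-frame, per-fly trajectory table.

    ``data`` holds columns ``fly_id, frame, t, x, y`` (plus optional
    ``heading``), sorted by (fly_id, frame), in mm, arena-centred.
    """

    data: pd.DataFrame
    fps: float = 30.0

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ValueError(f"fps must be > 0, got {self.fps}")
        missing = [c for c in ("fly_id", "frame", "x", "y") if c not in self.data.columns]
        if missing:
            raise TrackFormatError(f"missing required column(s): {', '.join(missing)}")
        if "t" not in self.data.columns:
            self.data = self.data.assign(t=self.data["frame"] / self.fps)
        if len(self.data):
            dframe = self.data.groupby("fly_id", sort=False)["frame"].diff()
            if (dframe <= 0).any():
                bad = self.data.loc[dframe <= 0, "fly_id"].iloc[0]
                raise TrackDataError(f"frames not strictly increasing for fly {bad!r}")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def fly_ids(self) -> list:
        return list(self.data["fly_id"].unique())

    @property
    def n_flies(self) -> int:
        return self.data["fly_id"].nunique()

    @property
    def t_end(self) -> float:
        """End of the recording: the closing edge of the last frame."""
        if not len(self.data):
            return 0.0
        return (float(self.data["frame"].max()) + 1.0) / self.fps

    def for_fly(self, fly_id) -> "FlyTrackTable":
        return FlyTrackTable(self.data[self.data["fly_id"] == fly_id].copy(), self.fps)


def load_tracks(
    path,
    geometry: ArenaGeometry,
    fps: float = 30.0,
    units: str = "mm",
    bounds_tol: float = 1.05,
) -> FlyTrackTable:
    """Read a tracker-output CSV and return a calibrated :class:`FlyTrackTable`.

    The file must have a header row with columns ``frame, fly_id, x, y``
    (``heading`` optional).  ``units`` declares whether coordinates are in
    pixels (converted via ``geometry.px_per_mm``) or already in mm.  Output
    coordinates are arena-centred mm; gaps are preserved, not interpolated.

    Raises
    ------
    TrackFormatError
        A required column is absent.
    CalibrationError
        Any point lies farther than ``radius * bounds_tol`` from the centre.
    TrackDataError
        Frames are not strictly increasing within a fly.
    """
    if units not in ("mm", "px"):
        raise ValueError(f"units must be 'mm' or 'px', got {units!r}")
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise TrackFormatError(
            f"{path}: missing required column(s): {', '.join(missing)}"
        )
    cols = list(REQUIRED_COLUMNS) + (["heading"] if "heading" in df.columns else [])
    df = df[cols].copy()
    if units == "px":
        df["x"] = df["x"] / geometry.px_per_mm
        df["y"] = df["y"] / geometry.px_per_mm
    df["x"] = df["x"] - geometry.center_x
    df["y"] = df["y"] - geometry.center_y
    r = np.hypot(df["x"], df["y"])
    limit = geometry.radius * bounds_tol
    if (r > limit).any():
        worst = float(r.max())
        raise CalibrationError(
            f"{path}: point {worst:.2f} mm from centre exceeds "
            f"radius x {bounds_tol} = {limit:.2f} mm — check px_per_mm / center"
        )
    df = df.sort_values(["fly_id", "frame"], kind="mergesort").reset_index(drop=True)
    df["frame"] = df["frame"].astype(np.int64)
    if (df["frame"] < 0).any():
        raise TrackDataError(f"{path}: negative frame index")
    df["t"] = df["frame"] / fps
    return FlyTrackTable(df[["fly_id", "frame", "t", "x", "y"] + cols[4:]], fps=fps)


def write_tracks(tracks: FlyTrackTable, path) -> None:
    """Write a calibrated track table back to CSV (full float precision)."""
    cols = [c for c in ("fly_id", "frame", "x", "y", "heading") if c in tracks.data.columns]
    tracks.data[cols].to_csv(path, index=False)


def load_geometry(path) -> ArenaGeometry:
    """Read an arena-geometry config (YAML key-value; lengths in mm, angles rad)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if "odor_assignment" in raw:
        raw["odor_assignment"] = {int(k): str(v) for k, v in raw["odor_assignment"].items()}
    return ArenaGeometry(**raw)


def save_geometry(geometry: ArenaGeometry, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(
            {
                "center_x": float(geometry.center_x),
                "center_y": float(geometry.center_y),
                "radius": float(geometry.radius),
                "px_per_mm": float(geometry.px_per_mm),
                "quadrant_phase": float(geometry.quadrant_phase),
                "odor_assignment": {int(k): str(v) for k, v in geometry.odor_assignment.items()},
            },
            fh,
            sort_keys=True,
        )


# --------------------------------------------------------------------------
# stimulus schedules


EPOCH_LABELS = frozenset(
    {
        "train_paired",
        "train_unpaired",
        "test",
        "led_on",
        "led_off",
        "recovery",
        "light_quadrant_test",
    }
)


@dataclass(frozen=True)
class Epoch:
    """A labelled half-open time interval ``[t_start, t_end)``.

    ``channel`` separates concurrent stimulus streams: LED pulses overlap the
    odor epoch that contains them by design, so non-overlap is enforced only
    within a channel.
    """

    label: str
    t_start: float
    t_end: float
    trial_index: int = 0
    channel: str = "led"
    metadata: Mapping = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.label not in EPOCH_LABELS:
            raise ProtocolError(f"unknown epoch label {self.label!r}")
        if self.t_end < self.t_start:
            raise ProtocolError(
                f"epoch {self.label}: t_end ({self.t_end}) precedes t_start ({self.t_start})"
            )

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start

    def contains(self, t) -> np.ndarray:
        t = np.asarray(t)
        return (t >= self.t_start) & (t < self.t_end)


@dataclass
class ProtocolSchedule:
    """Ordered list of labelled epochs for a named assay protocol."""

    protocol_name: str
    epochs: Sequence[Epoch]

    def __post_init__(self) -> None:
        by_channel: dict[str, list[Epoch]] = {}
        for e in self.epochs:
            by_channel.setdefault(e.channel, []).append(e)
        for channel, eps in by_channel.items():
            eps = sorted(eps, key=lambda e: e.t_start)
            for a, b in zip(eps, eps[1:]):
                if b.t_start < a.t_end - 1e-9:
                    raise ProtocolError(
                        f"overlapping {channel!r} epochs: {a.label} [{a.t_start}, {a.t_end}) "
                        f"and {b.label} [{b.t_start}, {b.t_end})"
                    )

    def __iter__(self):
        return iter(self.epochs)

    def with_label(self, label: str) -> list[Epoch]:
        return [e for e in self.epochs if e.label == label]

    @property
    def led_on(self) -> list[Epoch]:
        return self.with_label("led_on")

    @property
    def duration(self) -> float:
        return max(e.t_end for e in self.epochs)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "label": [e.label for e in self.epochs],
                "t_start": [e.t_start for e in self.epochs],
                "t_end": [e.t_end for e in self.epochs],
                "trial_index": [e.trial_index for e in self.epochs],
                "channel": [e.channel for e in self.epochs],
                "metadata": [json.dumps(dict(e.metadata)) for e in self.epochs],
            }
        )


def _training_block(t: float, trial: int) -> list[Epoch]:
    # 60 s odor A with 30 x (1 s LED on, 1 s off), then 60 s odor B unlit
    eps = [Epoch("train_paired", t, t + 60.0, trial, "odor", {"odor": "A"})]
    for j in range(30):
        eps.append(Epoch("led_on", t + 2.0 * j, t + 2.0 * j + 1.0, trial, "led"))
    eps.append(Epoch("train_unpaired", t + 60.0, t + 120.0, trial, "odor", {"odor": "B"}))
    return eps


def build_schedule(protocol_name: str, t0: float = 0.0) -> ProtocolSchedule:
    """Build the labelled epoch list of a named protocol starting at ``t0``.

    ``conditioning_v1``
        train(A+LED / B), test, train, train, test; each training block is
        60 s odor A with 30 one-second LED pulses separated by 1 s, then
        60 s odor B without light; each test is 60 s.
    ``activation_v1``
        six cycles of 10 s LED on, spaced by 100 s off (no odor).
    ``light_preference_v1``
        two 30 s tests with light in two quadrants, the second with the
        opposite quadrants lit, separated by 150 s of recovery.
    """
    if protocol_name == "activation_v1":
        epochs: list[Epoch] = []
        t = t0
        for i in range(6):
            epochs.append(Epoch("led_on", t, t + 10.0, i, "led"))
            epochs.append(Epoch("led_off", t + 10.0, t + 110.0, i, "led"))
            t += 110.0
        return ProtocolSchedule(protocol_name, epochs)

    if protocol_name == "conditioning_v1":
        epochs = []
        t = t0
        test_index = 0
        for item in ("train", "test", "train", "train", "test"):
            if item == "train":
                trial = sum(1 for e in epochs if e.label == "train_paired")
                epochs.extend(_training_block(t, trial))
                t += 120.0
            else:
                epochs.append(Epoch("test", t, t + 60.0, test_index, "odor"))
                test_index += 1
                t += 60.0
        return ProtocolSchedule(protocol_name, epochs)

    if protocol_name == "light_preference_v1":
        first, second = (0, 2), (1, 3)
        epochs = [
            Epoch("light_quadrant_test", t0, t0 + 30.0, 0, "assay", {"lit_quadrants": first}),
            Epoch("led_on", t0, t0 + 30.0, 0, "led", {"lit_quadrants": first}),
            Epoch("recovery", t0 + 30.0, t0 + 180.0, 0, "assay"),
            Epoch("light_quadrant_test", t0 + 180.0, t0 + 210.0, 1, "assay", {"lit_quadrants": second}),
            Epoch("led_on", t0 + 180.0, t0 + 210.0, 1, "led", {"lit_quadrants": second}),
        ]
        return ProtocolSchedule(protocol_name, epochs)

    raise ProtocolError(
        f"unknown protocol {protocol_name!r}; expected one of "
        "conditioning_v1, activation_v1, light_preference_v1"
    )


def write_schedule(schedule: ProtocolSchedule, path) -> None:
    schedule.to_frame().to_csv(path, index=False)


def read_schedule(path, protocol_name: str = "custom") -> ProtocolSchedule:
    df = pd.read_csv(path)
    epochs = []
    for row in df.itertuples(index=False):
        meta = json.loads(row.metadata) if isinstance(getattr(row, "metadata", None), str) else {}
        if "lit_quadrants" in meta:
            meta["lit_quadrants"] = tuple(meta["lit_quadrants"])
        epochs.append(
            Epoch(row.label, float(row.t_start), float(row.t_end), int(row.trial_index),
                  str(getattr(row, "channel", "led")), meta)
        )
    return ProtocolSchedule(protocol_name, epochs)


def slice_epoch(tracks: FlyTrackTable, epoch: Epoch) -> FlyTrackTable:
    """Rows with ``t`` in ``[t_start, t_end)``; frame indices untouched.

    An empty result or an epoch extending past the end of the recording
    produces a warning, not an error.
    """
    if epoch.t_end > tracks.t_end + 1e-9:
        warnings.warn(
            f"epoch [{epoch.t_start}, {epoch.t_end}) extends past the recording "
            f"end ({tracks.t_end:.3f} s); slice truncated",
            stacklevel=2,
        )
    mask = (tracks.data["t"] >= epoch.t_start) & (tracks.data["t"] < epoch.t_end)
    out = tracks.data[mask].copy()
    if not len(out):
        warnings.warn(
            f"epoch [{epoch.t_start}, {epoch.t_end}) contains no tracked frames",
            stacklevel=2,
        )
    return FlyTrackTable(out.reset_index(drop=True), tracks.fps)
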