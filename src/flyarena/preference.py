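"""Quadrant-occupancy preference indices.

The preference index (PI) in a frame is

    PI = (N_positive - N_negative) / N_total

where the positive quadrants are the two diagonal quadrants carrying the
conditioned (paired) odor — or the red light in the light-preference assay —
and N_total counts the flies tracked in that frame.  The memory score is the
PI averaged over the last 30 s of the 60 s post-training test, averaged over
a pair of reciprocal runs (odor-reinforcement assignment swapped) so innate
odor bias cancels.  The light-preference score averages the last 5 s of two
30 s lit-quadrant tests with opposite quadrants illuminated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .arena import (
    LIT,
    PAIRED,
    UNLIT,
    UNPAIRED,
    ArenaGeometry,
    FlyTrackTable,
    ProtocolError,
    ProtocolSchedule,
    slice_epoch,
)

__all__ = [
    "AssayRun",
    "MemoryScore",
    "LightPreference",
    "assign_quadrant",
    "preference_index",
    "window_mean_pi",
    "memory_score",
    "light_preference_index",
    "screening_filter",
]

#: within this distance (mm) of a quadrant boundary the previous quadrant is kept
HYSTERESIS_MM = 0.5


def assign_quadrant(
    tracks: FlyTrackTable,
    geometry: ArenaGeometry,
    hysteresis_mm: float = HYSTERESIS_MM,
) -> pd.DataFrame:
    """Quadrant index (0-3) per frame, by angular sector of the position.

    Quadrant ``q`` spans angles ``[phase + q*pi/2, phase + (q+1)*pi/2)``
    around the centre.  Within ``hysteresis_mm`` of a boundary (which
    includes a small disc around the centre) the fly keeps its previous
    quadrant, so boundary jitter does not flicker the assignment; a fly
    first seen in the ambiguous zone takes the raw sector.
    """
    df = tracks.data
    rx = (df["x"] - geometry.center_x).to_numpy()
    ry = (df["y"] - geometry.center_y).to_numpy()
    r = np.hypot(rx, ry)
    ang = np.arctan2(ry, rx) - geometry.quadrant_phase
    q_raw = np.floor(ang / (np.pi / 2.0)).astype(np.int64) % 4
    # perpendicular distance to the nearest boundary ray
    frac = np.mod(ang, np.pi / 2.0)
    d_boundary = r * np.sin(np.minimum(frac, np.pi / 2.0 - frac))
    ambiguous = d_boundary < hysteresis_mm
    q = pd.Series(q_raw.astype(float), index=df.index)
    q[ambiguous] = np.nan
    q = q.groupby(df["fly_id"], sort=False).ffill()
    q = q.fillna(pd.Series(q_raw.astype(float), index=df.index))
    out = df[["fly_id", "frame", "t"]].copy()
    out["quadrant"] = q.astype(np.int64)
    return out


def preference_index(
    quadrants: pd.DataFrame,
    labels: Mapping[int, str],
    positive: str = PAIRED,
) -> pd.DataFrame:
    """Per-frame preference index for the quadrants labelled ``positive``.

    ``quadrants`` is the output of :func:`assign_quadrant`; ``labels`` maps
    every quadrant index to one of two labels.  Frames with no tracked fly
    are absent from the result.  Returns columns ``frame, t, pi, n_flies``.
    """
    if set(labels) != {0, 1, 2, 3}:
        raise ValueError("labels must cover exactly quadrants 0-3")
    values = set(labels.values())
    if len(values) != 2 or positive not in values:
        raise ValueError(f"labels must use two values including {positive!r}, got {values}")
    sign = quadrants["quadrant"].map(lambda q: 1.0 if labels[int(q)] == positive else -1.0)
    grouped = sign.groupby(quadrants["frame"])
    pi = grouped.mean()
    n = grouped.size()
    t = quadrants.groupby("frame")["t"].first()
    return pd.DataFrame({"frame": pi.index, "t": t.values, "pi": pi.values, "n_flies": n.values})


def window_mean_pi(pi: pd.DataFrame, t_start: float, t_end: float) -> float:
    """Mean of the frame-wise PI over ``[t_start, t_end)``."""
    sel = pi[(pi["t"] >= t_start) & (pi["t"] < t_end)]
    if not len(sel):
        warnings.warn(f"no PI frames in [{t_start}, {t_end})", stacklevel=2)
        return float("nan")
    return float(sel["pi"].mean())


@dataclass
class AssayRun:
    """One conditioning run: tracks, its schedule, and that run's quadrant
    labels (already swapped for the reciprocal partner)."""

    tracks: FlyTrackTable
    schedule: ProtocolSchedule
    labels: Mapping[int, str]


@dataclass(frozen=True)
class MemoryScore:
    score: float
    run_scores: tuple
    single_run: bool


def memory_score(
    runs: Sequence[AssayRun],
    geometry: ArenaGeometry,
    window_s: float = 30.0,
    test_index: int = -1,
) -> MemoryScore:
    """Memory score of one biological replicate (a reciprocal run pair).

    Per run the PI toward the paired-odor quadrants is averaged over the
    last ``window_s`` of the final test epoch (``test_index`` selects a
    different test); the score is the unweighted mean of the two runs.  With
    a single run the score is computed anyway and flagged.
    """
    if not runs:
        raise ValueError("at least one run required")
    per_run = []
    for run in runs:
        tests = run.schedule.with_label("test")
        if not tests:
            raise ProtocolError("run schedule has no test epoch")
        test = tests[test_index]
        sliced = slice_epoch(run.tracks, test)
        quad = assign_quadrant(sliced, geometry)
        pi = preference_index(quad, run.labels, positive=PAIRED)
        per_run.append(window_mean_pi(pi, test.t_end - window_s, test.t_end))
    return MemoryScore(
        score=float(np.mean(per_run)),
        run_scores=tuple(per_run),
        single_run=len(per_run) == 1,
    )


@dataclass(frozen=True)
class LightPreference:
    score: float
    test_scores: tuple
    n_tests: int


def light_preference_index(
    tracks: FlyTrackTable,
    schedule: ProtocolSchedule,
    geometry: ArenaGeometry,
    window_s: float = 5.0,
) -> LightPreference:
    """Preference for the lit quadrants: mean PI over the last ``window_s``
    of each 30 s lit-quadrant test, averaged over the two tests (which have
    opposite quadrants illuminated)."""
    tests = schedule.with_label("light_quadrant_test")
    if len(tests) != 2:
        raise ProtocolError(f"expected 2 light_quadrant_test epochs, found {len(tests)}")
    lit_sets = [frozenset(e.metadata["lit_quadrants"]) for e in tests]
    if lit_sets[0] & lit_sets[1]:
        raise ProtocolError("the two tests must illuminate opposite quadrant sets")
    per_test = []
    for e, lit in zip(tests, lit_sets):
        labels = {q: (LIT if q in lit else UNLIT) for q in range(4)}
        sliced = slice_epoch(tracks, e)
        quad = assign_quadrant(sliced, geometry)
        pi = preference_index(quad, labels, positive=LIT)
        per_test.append(window_mean_pi(pi, e.t_end - window_s, e.t_end))
    return LightPreference(score=float(np.mean(per_test)), test_scores=tuple(per_test), n_tests=2)


def screening_filter(scores, threshold: float = 0.1):
    """Flag lines whose mean memory score exceeds the screening band.

    Strict comparison: ``|score| > threshold``; a line exactly at the
    threshold is not flagged.
    """
    arr = pd.Series(scores, dtype=float)
    flags = arr.abs() > threshold
    return flags.to_numpy() if not isinstance(scores, pd.Series) else flags
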