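"""Synthetic arena cohorts: a correlated random walk with stimulus coupling.

Each fly is a discrete-time correlated random walk inside the circular
arena: per frame the heading receives wrapped-normal noise with standard
deviation ``1/sqrt(turn_concentration)`` and the fly advances by a step of
length ``max(0, Normal(base_speed, speed_sd))/fps``; a step that would
cross the wall is converted into a tangential slide along it, which keeps
trajectories inside the arena without distorting the measured speed or
turning.  Four stimulus-coupled effect channels mirror the phenotype
classes the assay screens for, each neutral by default:

``led_speed_multiplier``
    multiplies the step length while the LED is on (speed suppression or
    elevation);
``onset_turn_boost``
    scales the heading-noise SD by ``1 + boost`` during the first 2 s of
    each LED period (startle turning);
``offset_upwind_bias``
    pulls the heading toward the radially outward (upwind) direction during
    the 2 s after LED offset, by that fraction of the angular error per
    frame;
``quadrant_bias``
    dwell bias during test epochs, implemented as an asymmetric crossing
    probability at quadrant boundaries: a step that would leave a favoured
    quadrant is rejected with probability ``|bias|`` (position held, heading
    kept).  Positive bias favours the paired/lit quadrants, negative the
    others.

Tracking dropouts are emulated by masking frames independently at
``track_dropout_rate``.  Per-fly random streams are split from the cohort
seed with a splitmix64 mix so cohorts are reproducible and flies
independent.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .arena import (
    ArenaGeometry,
    Epoch,
    FlyTrackTable,
    ProtocolSchedule,
    save_geometry,
    write_schedule,
    write_tracks,
)

try:  # pragma: no cover - exercised implicitly
    from numba import njit
except ImportError:  # pragma: no cover
    def njit(*args, **kwargs):
        def wrap(f):
            return f
        return wrap(args[0]) if args and callable(args[0]) else wrap

__all__ = ["SimConfig", "simulate_fly", "simulate_cohort", "write_fixture", "fly_seed"]

_MASK64 = (1 << 64) - 1


def _splitmix64(z: int) -> int:
    z = (z + 0x9E3779B97F4A7C15) & _MASK64
    z = ((z ^ (z >> 30)) * 0xBF58476D1CE4E5B9) & _MASK64
    z = ((z ^ (z >> 27)) * 0x94D049BB133111EB) & _MASK64
    return (z ^ (z >> 31)) & _MASK64


def fly_seed(cohort_seed: int, fly_index: int) -> int:
    """Per-fly seed: splitmix64 of the cohort seed advanced by the index."""
    return _splitmix64(_splitmix64(cohort_seed & _MASK64) + fly_index)


@dataclass(frozen=True)
class SimConfig:
    """Generative parameters of a synthetic cohort.

    Defaults describe the assay conditions: ~20 flies in a 10 cm (50 mm
    radius) arena filmed at 30 fps, walking ~10 mm/s with moderate heading
    persistence, ~2% of frames lost by the tracker, and all four stimulus
    channels neutral.
    """

    n_flies: int = 20
    fps: float = 30.0
    radius_mm: float = 50.0
    duration_s: Optional[float] = None  # None: use the schedule's duration
    seed: int = 0
    base_speed_mm_s: float = 10.0
    speed_sd: float = 3.0
    turn_concentration: float = 8.0  # heading-noise variance = 1/concentration
    led_speed_multiplier: float = 1.0
    onset_turn_boost: float = 0.0
    offset_upwind_bias: float = 0.0
    quadrant_bias: float = 0.0
    track_dropout_rate: float = 0.02
    onset_window_s: float = 2.0
    offset_window_s: float = 2.0

    def __post_init__(self) -> None:
        if self.n_flies < 0 or self.fps <= 0 or self.radius_mm <= 0:
            raise ValueError("n_flies >= 0, fps > 0 and radius_mm > 0 required")
        for name in ("base_speed_mm_s", "speed_sd", "turn_concentration",
                     "led_speed_multiplier", "track_dropout_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not -1.0 < self.quadrant_bias < 1.0:
            raise ValueError("quadrant_bias must lie in (-1, 1)")


@njit(cache=True)
def _quadrant(x: float, y: float, phase: float) -> int:
    ang = math.atan2(y, x) - phase
    return int(math.floor(ang / (0.5 * math.pi))) % 4


@njit(cache=True)
def _walk(x0, y0, th0, steps, dth, pull, favmask, reject_u, bias_prob, radius, phase):
    n = steps.size
    xs = np.empty(n)
    ys = np.empty(n)
    ths = np.empty(n)
    x, y, th = x0, y0, th0
    xs[0], ys[0], ths[0] = x, y, th
    two_pi = 2.0 * math.pi
    for i in range(1, n):
        th = th + dth[i]
        if pull[i] > 0.0:
            err = math.atan2(y, x) - th
            err = (err + math.pi) % two_pi - math.pi
            th = th + pull[i] * err
        th = (th + math.pi) % two_pi - math.pi
        nx = x + steps[i] * math.cos(th)
        ny = y + steps[i] * math.sin(th)
        rn2 = nx * nx + ny * ny
        if rn2 > radius * radius and steps[i] > 0.0:
            # wall crossing resolved by sliding: the step is converted into
            # an arc at the current radius, in the tangential direction that
            # matches the heading, and the heading aligns with the slide.
            # This preserves the step length and injects only noise-scale
            # heading changes, so wall encounters do not distort the
            # measured speed or turning.
            r = math.sqrt(x * x + y * y)
            phi = math.atan2(y, x)
            s = 1.0 if (-math.sin(phi) * math.cos(th) + math.cos(phi) * math.sin(th)) >= 0.0 else -1.0
            dphi = s * steps[i] / r
            phi += dphi
            nx = r * math.cos(phi)
            ny = r * math.sin(phi)
            th = phi + s * 0.5 * math.pi
        if favmask[i] != 0:
            qo = _quadrant(x, y, phase)
            qn = _quadrant(nx, ny, phase)
            if qo != qn and (favmask[i] >> qo) & 1 == 1 and (favmask[i] >> qn) & 1 == 0:
                if reject_u[i] < bias_prob:
                    # boundary acts as a semi-permeable wall: hold position
                    # and reflect the heading off the crossed boundary ray
                    nx = x
                    ny = y
                    if qn == (qo + 1) % 4:
                        beta = phase + 0.5 * math.pi * (qo + 1)
                    elif qn == (qo + 3) % 4:
                        beta = phase + 0.5 * math.pi * qo
                    else:  # diagonal hop through the centre: turn around
                        beta = th + 0.5 * math.pi
                    th = (2.0 * beta - th + math.pi) % two_pi - math.pi
        x, y = nx, ny
        xs[i], ys[i], ths[i] = x, y, th
    return xs, ys, ths


def _frame_modulation(config: SimConfig, schedule: ProtocolSchedule,
                      geometry: ArenaGeometry, n_frames: int):
    """Per-frame stimulus-coupling arrays derived from the schedule."""
    t = np.arange(n_frames) / config.fps
    speed_mult = np.ones(n_frames)
    turn_sd = np.full(n_frames, 1.0 / math.sqrt(config.turn_concentration)
                      if config.turn_concentration > 0 else 0.0)
    pull = np.zeros(n_frames)
    favmask = np.zeros(n_frames, dtype=np.int8)

    for e in schedule.with_label("led_on"):
        on = (t >= e.t_start) & (t < e.t_end)
        speed_mult[on] = config.led_speed_multiplier
        onset = (t >= e.t_start) & (t < min(e.t_start + config.onset_window_s, e.t_end))
        turn_sd[onset] *= 1.0 + config.onset_turn_boost
        offset = (t >= e.t_end) & (t < e.t_end + config.offset_window_s)
        pull[offset] = config.offset_upwind_bias

    if config.quadrant_bias != 0.0:
        want = "paired" if config.quadrant_bias > 0 else "unpaired"
        odor_bits = sum(1 << q for q in geometry.quadrants_with(want))
        for e in schedule.with_label("test"):
            favmask[(t >= e.t_start) & (t < e.t_end)] = odor_bits
        for e in schedule.with_label("light_quadrant_test"):
            lit = frozenset(e.metadata.get("lit_quadrants", ()))
            fav = lit if config.quadrant_bias > 0 else frozenset(range(4)) - lit
            favmask[(t >= e.t_start) & (t < e.t_end)] = sum(1 << q for q in fav)
    return speed_mult, turn_sd, pull, favmask


def simulate_fly(
    config: SimConfig,
    schedule: ProtocolSchedule,
    fly_seed_value: int,
    geometry: Optional[ArenaGeometry] = None,
    fly_id: str = "fly000",
) -> FlyTrackTable:
    """Simulate one fly; the returned table may have gaps (dropout)."""
    if geometry is None:
        geometry = ArenaGeometry(radius=config.radius_mm)
    duration = config.duration_s if config.duration_s is not None else schedule.duration
    n_frames = int(round(duration * config.fps))
    rng = np.random.default_rng(fly_seed_value)

    speed_mult, turn_sd, pull, favmask = _frame_modulation(config, schedule, geometry, n_frames)

    r0 = config.radius_mm * 0.9 * math.sqrt(rng.random())
    a0 = rng.uniform(-math.pi, math.pi)
    th0 = rng.uniform(-math.pi, math.pi)
    steps = np.maximum(rng.normal(config.base_speed_mm_s, config.speed_sd, n_frames), 0.0)
    steps = steps / config.fps * speed_mult
    dth = rng.normal(0.0, 1.0, n_frames) * turn_sd
    reject_u = rng.random(n_frames)
    keep = rng.random(n_frames) >= config.track_dropout_rate

    xs, ys, ths = _walk(
        r0 * math.cos(a0), r0 * math.sin(a0), th0,
        steps, dth, pull, favmask.astype(np.int8), reject_u,
        abs(config.quadrant_bias), config.radius_mm, geometry.quadrant_phase,
    )
    frames = np.arange(n_frames, dtype=np.int64)[keep]
    df = pd.DataFrame(
        {
            "fly_id": fly_id,
            "frame": frames,
            "t": frames / config.fps,
            "x": xs[keep],
            "y": ys[keep],
            "heading": ths[keep],
        }
    )
    return FlyTrackTable(df, fps=config.fps)


def simulate_cohort(
    config: SimConfig,
    schedule: ProtocolSchedule,
    geometry: Optional[ArenaGeometry] = None,
) -> tuple[FlyTrackTable, dict]:
    """Simulate ``config.n_flies`` independent flies under one schedule.

    Returns the pooled track table and a ground-truth record of every
    imposed effect size and per-fly seed.
    """
    if geometry is None:
        geometry = ArenaGeometry(radius=config.radius_mm)
    parts = []
    seeds = []
    for i in range(config.n_flies):
        s = fly_seed(config.seed, i)
        seeds.append(s)
        parts.append(simulate_fly(config, schedule, s, geometry, fly_id=f"fly{i:03d}").data)
    if parts:
        data = pd.concat(parts, ignore_index=True)
    else:
        data = pd.DataFrame(columns=["fly_id", "frame", "t", "x", "y", "heading"])
    truth = {
        "config": dataclasses.asdict(config),
        "protocol": schedule.protocol_name,
        "fly_seeds": [str(s) for s in seeds],
        "effects": {
            "led_speed_multiplier": config.led_speed_multiplier,
            "onset_turn_boost": config.onset_turn_boost,
            "offset_upwind_bias": config.offset_upwind_bias,
            "quadrant_bias": config.quadrant_bias,
        },
    }
    return FlyTrackTable(data, fps=config.fps), truth


def write_fixture(
    cohort: FlyTrackTable,
    truth: dict,
    schedule: ProtocolSchedule,
    geometry: ArenaGeometry,
    outdir,
) -> dict[str, Path]:
    """Write a cohort as tracker-format CSV plus config/schedule sidecars.

    Produces ``tracks.csv`` (readable by :func:`flyarena.arena.load_tracks`),
    ``schedule.csv``, ``geometry.yaml`` and ``ground_truth.json``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "tracks": outdir / "tracks.csv",
        "schedule": outdir / "schedule.csv",
        "geometry": outdir / "geometry.yaml",
        "ground_truth": outdir / "ground_truth.json",
    }
    write_tracks(cohort, paths["tracks"])
    write_schedule(schedule, paths["schedule"])
    save_geometry(geometry, paths["geometry"])
    with open(paths["ground_truth"], "w") as fh:
        json.dump(truth, fh, indent=2)
    return paths
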