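"""Epoch-locked summaries around LED stimuli.

The activation assay applies six 10 s optogenetic stimuli separated by
100 s.  For screening, each genotype is collapsed to nine numbers:

* mean walking speed, angular change and cos(upwind) over the ON windows
  (first 2 s of each LED period) and the OFF windows (2 s immediately after
  LED offset);
* ``delta_dist_center`` — change of the mean distance from the arena centre
  during the stimulus relative to the distance at stimulus onset;
* ``return_prob`` — probability that a fly wanders at least 10 mm from the
  position it held at LED offset and then comes back to within 3 mm of it
  within 15 s;
* ``cum_turn_first2s`` — mean five-frame cumulative turning during the first
  2 s of the stimulus.

A screen over genotypes standardizes each parameter to z-scores across the
line-level means (control line included).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .arena import ArenaGeometry, FlyTrackTable, ProtocolError, ProtocolSchedule
from . import kinematics

__all__ = [
    "PARAMETERS",
    "ReturnParams",
    "ReturnOutcome",
    "ReturnStats",
    "ScreenMatrix",
    "summarize_on_off",
    "delta_distance_from_center",
    "detect_return",
    "return_probability",
    "zscore_screen",
    "screen_matrix",
    "activation_summary",
]

PARAMETERS = (
    "speed_ON",
    "speed_OFF",
    "angular_ON",
    "angular_OFF",
    "cos_upwind_ON",
    "cos_upwind_OFF",
    "delta_dist_center",
    "return_prob",
    "cum_turn_first2s",
)


@dataclass(frozen=True)
class ReturnParams:
    """Thresholds of the return detector (mm, mm, s)."""

    excursion_mm: float = 10.0
    return_mm: float = 3.0
    horizon_s: float = 15.0

    def __post_init__(self) -> None:
        if not (self.excursion_mm > self.return_mm > 0):
            raise ValueError(
                f"need excursion_mm > return_mm > 0, got {self.excursion_mm}, {self.return_mm}"
            )
        if self.horizon_s <= 0:
            raise ValueError(f"horizon_s must be > 0, got {self.horizon_s}")


@dataclass(frozen=True)
class ReturnOutcome:
    returned: bool
    excluded: bool
    coverage: float


@dataclass(frozen=True)
class ReturnStats:
    probability: float
    n_returned: int
    n_valid: int
    n_excluded: int


@dataclass
class ScreenMatrix:
    """Lines x parameters matrix of line-level means with its z-scores."""

    values: pd.DataFrame
    zscores: pd.DataFrame


def _on_off_masks(t: pd.Series, schedule: ProtocolSchedule, on_window_s: float, off_window_s: float):
    led_on = schedule.led_on
    if not led_on:
        raise ProtocolError("schedule contains no led_on epochs")
    on_mask = np.zeros(len(t), dtype=bool)
    off_mask = np.zeros(len(t), dtype=bool)
    tv = t.to_numpy()
    for e in led_on:
        on_end = min(e.t_start + on_window_s, e.t_end)
        on_mask |= (tv >= e.t_start) & (tv < on_end)
        off_mask |= (tv >= e.t_end) & (tv < e.t_end + off_window_s)
    return on_mask, off_mask, led_on


def _window_mean(series: pd.Series, mask: np.ndarray, what: str) -> float:
    vals = series.to_numpy()[mask]
    vals = vals[~np.isnan(vals)]
    if not len(vals):
        warnings.warn(f"no frames available for {what}; value missing", stacklevel=3)
        return float("nan")
    return float(np.mean(vals))


def summarize_on_off(
    metrics: pd.DataFrame,
    schedule: ProtocolSchedule,
    on_window_s: float = 2.0,
    off_window_s: float = 2.0,
) -> pd.DataFrame:
    """Pooled ON/OFF-window means of the per-frame kinematic features.

    ON windows are the first ``on_window_s`` of each LED period, OFF windows
    the ``off_window_s`` immediately after offset; means pool all flies,
    frames and trials.  Returns a tidy table (parameter, value, n_flies,
    n_trials) including ``cum_turn_first2s``.
    """
    on_mask, off_mask, led_on = _on_off_masks(metrics["t"], schedule, on_window_s, off_window_s)
    cum_col = next(c for c in metrics.columns if c.startswith("cum_turn"))
    rows = []
    for param, col, mask in (
        ("speed_ON", "speed", on_mask),
        ("speed_OFF", "speed", off_mask),
        ("angular_ON", "dtheta_abs", on_mask),
        ("angular_OFF", "dtheta_abs", off_mask),
        ("cos_upwind_ON", "cos_upwind", on_mask),
        ("cos_upwind_OFF", "cos_upwind", off_mask),
        ("cum_turn_first2s", cum_col, on_mask),
    ):
        rows.append(
            {
                "parameter": param,
                "value": _window_mean(metrics[col], mask, param),
                "n_flies": int(metrics.loc[mask, "fly_id"].nunique()),
                "n_trials": len(led_on),
            }
        )
    return pd.DataFrame(rows)


def delta_distance_from_center(
    metrics: pd.DataFrame,
    schedule: ProtocolSchedule,
    fps: float,
    window: str = "on_full",
) -> tuple[float, pd.DataFrame, int]:
    """Change in mean distance from centre relative to the LED-onset position.

    Per fly and trial: ``mean(dist_center over the window) - dist_center at
    the onset frame``; fly-trials untracked at onset are excluded and
    counted.  ``window`` is ``on_full`` (whole LED period, default) or
    ``on_first2s``.  Returns (grand mean, per-fly-trial detail, n_excluded).
    """
    if window not in ("on_full", "on_first2s"):
        raise ValueError(f"window must be 'on_full' or 'on_first2s', got {window!r}")
    led_on = schedule.led_on
    if not led_on:
        raise ProtocolError("schedule contains no led_on epochs")
    tv = metrics["t"].to_numpy()
    onset = metrics.set_index(["fly_id", "frame"])["dist_center"]
    records = []
    n_excluded = 0
    for e in led_on:
        onset_frame = int(np.floor(e.t_start * fps + 1e-9))
        w_end = e.t_end if window == "on_full" else min(e.t_start + 2.0, e.t_end)
        in_window = (tv >= e.t_start) & (tv < w_end)
        sub = metrics.loc[in_window, ["fly_id", "dist_center"]]
        for fly_id, grp in sub.groupby("fly_id", sort=False):
            key = (fly_id, onset_frame)
            if key not in onset.index or np.isnan(onset.loc[key]):
                n_excluded += 1
                continue
            vals = grp["dist_center"].dropna()
            if not len(vals):
                n_excluded += 1
                continue
            records.append(
                {
                    "fly_id": fly_id,
                    "trial_index": e.trial_index,
                    "delta": float(vals.mean() - onset.loc[key]),
                }
            )
    detail = pd.DataFrame(records, columns=["fly_id", "trial_index", "delta"])
    value = float(detail["delta"].mean()) if len(detail) else float("nan")
    return value, detail, n_excluded


def detect_return(
    track: FlyTrackTable,
    t_ref: float,
    params: ReturnParams = ReturnParams(),
    coverage_fraction: float = 0.9,
) -> ReturnOutcome:
    """Did a single fly leave and come back after the stimulus ended?

    The origin is the position the fly held at ``t_ref`` (an LED-offset
    time).  ``returned`` is true iff there are times t1 < t2 within
    ``(t_ref, t_ref + horizon_s]`` at which the fly is at least
    ``excursion_mm`` from the origin and later within ``return_mm`` of it.
    ``excluded`` is true when the track covers less than
    ``coverage_fraction`` of the horizon or the fly is untracked at the
    reference frame.
    """
    df = track.data
    if track.n_flies > 1:
        raise ValueError("detect_return expects a single-fly track")
    fps = track.fps
    if t_ref < 0 or t_ref > track.t_end:
        raise ValueError(f"t_ref = {t_ref} s outside the recording [0, {track.t_end:.3f}]")
    ref_frame = int(np.floor(t_ref * fps + 1e-9))
    last_frame = int(np.floor((t_ref + params.horizon_s) * fps + 1e-9))
    frames = df["frame"].to_numpy()
    sel = (frames >= ref_frame) & (frames <= last_frame)
    expected = last_frame - ref_frame + 1
    coverage = float(sel.sum()) / expected
    at_ref = frames == ref_frame
    if not at_ref.any():
        return ReturnOutcome(returned=False, excluded=True, coverage=coverage)
    x0 = float(df.loc[at_ref, "x"].iloc[0])
    y0 = float(df.loc[at_ref, "y"].iloc[0])
    after = sel & (frames > ref_frame)
    d = np.hypot(df.loc[after, "x"] - x0, df.loc[after, "y"] - y0).to_numpy()
    # an excursion must precede the return: running max vs the return radius
    returned = bool(
        np.any((d <= params.return_mm) & (np.maximum.accumulate(d) >= params.excursion_mm))
    ) if len(d) else False
    excluded = coverage < coverage_fraction
    return ReturnOutcome(returned=returned, excluded=excluded, coverage=coverage)


def return_probability(
    tracks: FlyTrackTable,
    schedule: ProtocolSchedule,
    params: ReturnParams = ReturnParams(),
    coverage_fraction: float = 0.9,
) -> ReturnStats:
    """Fraction of non-excluded (fly, trial) pairs that returned, pooled
    over the LED offsets of the schedule."""
    led_on = schedule.led_on
    if not led_on:
        raise ProtocolError("schedule contains no led_on epochs")
    n_ret = n_valid = n_excl = 0
    for fly_id, grp in tracks.data.groupby("fly_id", sort=False):
        fly = FlyTrackTable(grp.reset_index(drop=True), tracks.fps)
        for e in led_on:
            out = detect_return(fly, e.t_end, params, coverage_fraction)
            if out.excluded:
                n_excl += 1
            else:
                n_valid += 1
                n_ret += int(out.returned)
    if n_valid == 0:
        warnings.warn("all fly-trials excluded; return probability undefined", stacklevel=2)
        return ReturnStats(float("nan"), 0, 0, n_excl)
    return ReturnStats(n_ret / n_valid, n_ret, n_valid, n_excl)


def zscore_screen(values: pd.DataFrame) -> pd.DataFrame:
    """Standardize each parameter column across lines: (v - mean) / sd.

    Sample standard deviation (ddof=1), computed over the line-level means
    including the control line.  A column with fewer than two non-missing
    values or zero variance is set missing with a warning.
    """
    z = pd.DataFrame(index=values.index, columns=values.columns, dtype=float)
    for col in values.columns:
        v = values[col].astype(float)
        n = v.notna().sum()
        sd = v.std(ddof=1)
        if n < 2 or not np.isfinite(sd) or sd == 0.0:
            warnings.warn(
                f"parameter {col!r}: degenerate column (n={n}, sd={sd}); z-scores missing",
                stacklevel=2,
            )
            z[col] = np.nan
        else:
            z[col] = (v - v.mean()) / sd
    return z


def screen_matrix(values: pd.DataFrame) -> ScreenMatrix:
    return ScreenMatrix(values=values.copy(), zscores=zscore_screen(values))


def activation_summary(
    tracks: FlyTrackTable,
    geometry: ArenaGeometry,
    schedule: ProtocolSchedule,
    return_params: ReturnParams = ReturnParams(),
    delta_window: str = "on_full",
) -> pd.DataFrame:
    """All nine screen parameters of one cohort as a tidy table."""
    metrics = kinematics.frame_metrics(tracks, geometry)
    rows = summarize_on_off(metrics, schedule)
    delta, detail, n_excl = delta_distance_from_center(metrics, schedule, tracks.fps, delta_window)
    rows = pd.concat(
        [
            rows,
            pd.DataFrame(
                [
                    {
                        "parameter": "delta_dist_center",
                        "value": delta,
                        "n_flies": detail["fly_id"].nunique() if len(detail) else 0,
                        "n_trials": len(schedule.led_on),
                    }
                ]
            ),
        ],
        ignore_index=True,
    )
    ret = return_probability(tracks, schedule, return_params)
    rows = pd.concat(
        [
            rows,
            pd.DataFrame(
                [
                    {
                        "parameter": "return_prob",
                        "value": ret.probability,
                        "n_flies": tracks.n_flies,
                        "n_trials": len(schedule.led_on),
                    }
                ]
            ),
        ],
        ignore_index=True,
    )
    return rows.reset_index(drop=True)
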