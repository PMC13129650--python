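"""Velocity-threshold microsaccade detection and size-density curves.

Eye-position traces are differentiated to velocity; samples whose speed
exceeds five times the trial's median speed mark saccades.  "Toward"
saccades move gaze away from fixation and in the cued item's direction.
Their density as a function of amplitude is computed over 0–2° with a
sliding window (step 0.05°, width 0.5°), expressed as saccades per trial.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Optional

import numpy as np
import pandas as pd

from .io import cue_sign
from .preprocess import EpochSet


@dataclass
class SaccadeEvent:
    trial_id: object
    onset: float  # ms, relative to cue
    offset: float
    dx: float
    dy: float
    amplitude: float
    direction: float  # polar angle, degrees
    peak_velocity: float  # deg/s
    is_toward: Optional[bool] = None


@dataclass
class SizeDensityCurve:
    size_centers: np.ndarray
    density: np.ndarray  # saccades per trial per size window
    condition: Optional[str] = None
    n_trials: int = 0
    n_saccades: int = 0


def gaze_velocity(x: np.ndarray, y: np.ndarray, sampling_rate: float = 1000.0,
                  estimator: str = "central") -> np.ndarray:
    """Speed trace in deg/s from position traces.

    ``central`` is the 3-point central difference; ``engbert`` is the 5-sample
    moving-window estimator common in microsaccade work.  Endpoints and any
    sample whose stencil touches missing data are NaN.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if np.isfinite(x).sum() < 3:
        raise ValueError("need at least 3 valid samples for velocity")
    vx = np.full_like(x, np.nan)
    vy = np.full_like(y, np.nan)
    if estimator == "central":
        vx[1:-1] = (x[2:] - x[:-2]) * (sampling_rate / 2.0)
        vy[1:-1] = (y[2:] - y[:-2]) * (sampling_rate / 2.0)
    elif estimator == "engbert":
        vx[2:-2] = (x[4:] + x[3:-1] - x[1:-3] - x[:-4]) * (sampling_rate / 6.0)
        vy[2:-2] = (y[4:] + y[3:-1] - y[1:-3] - y[:-4]) * (sampling_rate / 6.0)
    else:
        raise ValueError(f"unknown estimator {estimator!r}")
    return np.hypot(vx, vy)


def _runs(mask: np.ndarray):
    """Maximal runs of True as (start, stop) index pairs, stop exclusive."""
    d = np.diff(np.concatenate(([0], mask.astype(int), [0])))
    return list(zip(np.flatnonzero(d == 1), np.flatnonzero(d == -1)))


def detect_saccades(x: np.ndarray, y: np.ndarray, time: np.ndarray,
                    trial_id=None, *, sampling_rate: float = 1000.0,
                    k: float = 5.0, min_duration: float = 6.0,
                    merge_gap: float = 20.0,
                    estimator: str = "central") -> List[SaccadeEvent]:
    """Detect saccades where speed exceeds ``k`` × the trial-median speed.

    Suprathreshold runs closer than ``merge_gap`` ms are merged, runs shorter
    than ``min_duration`` ms are dropped.  Displacement is measured from the
    last sample before onset to the first sample after offset (clamped to the
    trace), so a step's full amplitude is recovered.
    """
    if k <= 0:
        raise ValueError("k must be > 0")
    speed = gaze_velocity(x, y, sampling_rate, estimator)
    finite = np.isfinite(speed)
    if not finite.any():
        return []
    median = float(np.median(speed[finite]))
    thr = k * median
    above = np.zeros_like(finite)
    above[finite] = speed[finite] > thr
    runs = _runs(above)
    if not runs:
        return []
    dt = 1000.0 / sampling_rate
    gap_n = int(round(merge_gap / dt))
    merged = [list(runs[0])]
    for s, e in runs[1:]:
        if s - merged[-1][1] <= gap_n:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    min_n = max(int(round(min_duration / dt)), 1)
    events: List[SaccadeEvent] = []
    for s, e in merged:
        if e - s < min_n:
            continue
        i0 = max(s - 1, 0)
        i1 = min(e, len(x) - 1)
        if not (np.isfinite(x[i0]) and np.isfinite(x[i1])
                and np.isfinite(y[i0]) and np.isfinite(y[i1])):
            continue
        dx = float(x[i1] - x[i0])
        dy = float(y[i1] - y[i0])
        events.append(SaccadeEvent(
            trial_id=trial_id, onset=float(time[s]), offset=float(time[e - 1]),
            dx=dx, dy=dy, amplitude=float(np.hypot(dx, dy)),
            direction=float(np.degrees(np.arctan2(dy, dx))),
            peak_velocity=float(np.nanmax(speed[s:e])),
            ))
    return events


_DIR_ANGLE = {"right": 0.0, "top": 90.0, "left": 180.0, "bottom": -90.0}


def classify_toward(events: Iterable[SaccadeEvent], cued_direction: str,
                    onset_position=(0.0, 0.0), *,
                    criterion: str = "axis_sign",
                    cone_halfwidth: float = 45.0) -> List[SaccadeEvent]:
    """Set ``is_toward`` on each event for a trial's cued direction.

    A toward saccade (1) moves gaze away from fixation — its endpoint is
    radially farther than its start — and (2) is directed at the cued item:
    either the signed displacement on the cued axis has the cued sign
    (``axis_sign``, the default) or the displacement angle lies within
    ``cone_halfwidth`` degrees of the cued direction (``cone``).

    ``onset_position`` maps event-relative geometry to fixation-relative
    radii when events were detected on uncentred traces (unused default).
    """
    out = []
    sgn = cue_sign(cued_direction)
    horizontal = cued_direction in ("left", "right")
    for ev in events:
        # radial-away test: reconstruct start/end relative to fixation
        sx, sy = onset_position
        ex, ey = sx + ev.dx, sy + ev.dy
        away = np.hypot(ex, ey) > np.hypot(sx, sy)
        if criterion == "axis_sign":
            along = ev.dx if horizontal else ev.dy
            aimed = np.sign(along) == sgn
        elif criterion == "cone":
            diff = (ev.direction - _DIR_ANGLE[cued_direction] + 180.0) % 360.0 - 180.0
            aimed = abs(diff) <= cone_halfwidth
        else:
            raise ValueError(f"unknown criterion {criterion!r}")
        ev.is_toward = bool(away and aimed)
        out.append(ev)
    return out


def detect_epoch_saccades(ep: EpochSet, config) -> List[SaccadeEvent]:
    """Detect and toward-classify saccades on every included epoch trial.

    Toward-classification uses each event's onset gaze position within the
    (baseline-corrected) trial so the radial-away test is meaningful.
    """
    events: List[SaccadeEvent] = []
    dt = 1000.0 / ep.sampling_rate
    for row in range(ep.n_trials):
        if not ep.included[row]:
            continue
        tr = ep.trials.iloc[row]
        x, y = ep.x[row], ep.y[row]
        if np.isfinite(x).sum() < 3:
            continue
        evs = detect_saccades(
            x, y, ep.time, trial_id=tr["trial_id"],
            sampling_rate=ep.sampling_rate, k=config.velocity_threshold,
            min_duration=config.saccade_min_duration,
            merge_gap=config.saccade_merge_gap,
            estimator=config.velocity_estimator)
        for ev in evs:
            i0 = max(int(round((ev.onset - ep.time[0]) / dt)) - 1, 0)
            pos = (x[i0], y[i0]) if np.isfinite(x[i0]) else (0.0, 0.0)
            classify_toward([ev], tr["cued_direction"], onset_position=pos,
                            criterion=config.toward_criterion,
                            cone_halfwidth=config.toward_cone_halfwidth)
        events.extend(evs)
    return events


def size_density(events: Iterable[SaccadeEvent], n_trials: int, *,
                 window=(200.0, 600.0), size_max: float = 2.0,
                 size_step: float = 0.05, size_width: float = 0.5,
                 toward_only: bool = True,
                 condition: Optional[str] = None) -> SizeDensityCurve:
    """Saccade rate per trial as a function of amplitude (sliding window).

    For each size centre c the density is the number of (toward) saccades
    with onset in ``window`` and amplitude within [c − width/2, c + width/2]
    (inclusive), divided by ``n_trials``.
    """
    if n_trials <= 0:
        raise ValueError("n_trials must be > 0")
    amps = np.array([
        ev.amplitude for ev in events
        if window[0] <= ev.onset < window[1]
        and (not toward_only or ev.is_toward)])
    centers = np.arange(0.0, size_max + size_step / 2, size_step)
    half = size_width / 2.0
    counts = np.array([np.count_nonzero((amps >= c - half) & (amps <= c + half))
                       for c in centers], float)
    return SizeDensityCurve(size_centers=centers, density=counts / n_trials,
                            condition=condition, n_trials=n_trials,
                            n_saccades=len(amps))


def events_table(events: Iterable[SaccadeEvent]) -> pd.DataFrame:
    return pd.DataFrame([vars(ev) for ev in events])
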