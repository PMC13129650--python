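"""Blink masking, epoching, baseline correction and fixational trial selection.

The preprocessing chain mirrors the standard cue-locked gaze protocol:
blink clusters (padded by 100 ms on both sides) are replaced by NaN, data
are epoched from −1,000 to +2,000 ms around the retro-cue, each trial is
baseline-corrected to its −200..0 ms mean, and trials in which gaze strays
more than 2° from fixation within 0–1,000 ms post-cue are excluded so the
remaining biases are fixational in nature.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace


import numpy as np
import pandas as pd

from .io import GazeRecording

logger = logging.getLogger("gazescaffold")


@dataclass
class EpochSet:
    """Cue-locked trials × time matrices of gaze position.

    ``time`` is relative to cue onset (ms); missing (blink) samples are NaN;
    ``included`` tracks trials surviving baseline/exclusion checks.
    """

    time: np.ndarray
    x: np.ndarray  # (n_trials, n_time)
    y: np.ndarray
    trials: pd.DataFrame
    included: np.ndarray
    sampling_rate: float = 1000.0
    baseline_applied: bool = False

    def __post_init__(self) -> None:
        if self.x.shape != self.y.shape:
            raise ValueError("x and y shapes differ")
        if self.x.shape[0] != len(self.trials):
            raise ValueError("row count != trial count")
        if self.x.shape[1] != len(self.time):
            raise ValueError("column count != time length")
        self.included = np.asarray(self.included, bool)

    @property
    def n_trials(self) -> int:
        return self.x.shape[0]

    def copy(self) -> "EpochSet":
        return replace(self, time=self.time.copy(), x=self.x.copy(),
                       y=self.y.copy(), trials=self.trials.copy(),
                       included=self.included.copy())

    def window_slice(self, window) -> slice:
        """Column slice for a half-open [start, end) window in ms."""
        lo = int(np.searchsorted(self.time, window[0] - 1e-9))
        hi = int(np.searchsorted(self.time, window[1] - 1e-9))
        return slice(lo, hi)


@dataclass
class ExclusionReport:
    n_trials: int
    n_excluded: int
    excluded_ids: np.ndarray
    usable_fraction: float


def mask_blinks(rec: GazeRecording, pad: float = 100.0) -> GazeRecording:
    """Replace blink clusters, padded by ``pad`` ms on each side, with NaN.

    Blink seeds are samples the tracker flagged invalid or whose pupil
    signal is missing/non-positive (the EyeLink convention).  Contiguous
    runs merge naturally under dilation.  Idempotent: a recording already
    blink-masked is returned unchanged.
    """
    if rec.blink_masked:
        return rec.copy()
    seeds = ~rec.valid
    if rec.pupil is not None:
        seeds |= ~np.isfinite(rec.pupil) | (rec.pupil <= 0)
    if seeds.all():
        raise ValueError("recording has zero valid samples")
    pad_n = int(round(pad / rec.dt))
    bad = seeds.copy()
    if pad_n > 0 and seeds.any():
        idx = np.flatnonzero(seeds)
        starts = np.clip(idx - pad_n, 0, None)
        stops = np.clip(idx + pad_n + 1, None, len(seeds))
        grow = np.zeros(len(seeds) + 1, dtype=int)
        np.add.at(grow, starts, 1)
        np.add.at(grow, stops, -1)
        bad = np.cumsum(grow[:-1]) > 0
    out = rec.copy()
    out.valid = ~bad
    out.x[bad] = np.nan
    out.y[bad] = np.nan
    out.blink_masked = True
    return out


def epoch(rec: GazeRecording, trials: pd.DataFrame, window=(-1000.0, 2000.0)) -> EpochSet:
    """Cut cue-locked epochs over a half-open [start, end) ms window."""
    n_time = int(round((window[1] - window[0]) / rec.dt))
    t0 = rec.time[0]
    time = window[0] + np.arange(n_time) * rec.dt
    onsets = trials["cue_onset_ms"].to_numpy(float)
    i0 = np.round((onsets + window[0] - t0) / rec.dt).astype(int)
    bad = (i0 < 0) | (i0 + n_time > len(rec))
    if bad.any():
        tid = trials["trial_id"].iloc[int(np.flatnonzero(bad)[0])]
        onset = onsets[np.flatnonzero(bad)[0]]
        raise ValueError(
            f"trial {tid}: window {window} around cue at {onset} ms "
            f"exceeds recording span [{t0}, {rec.time[-1]}]")
    idx = i0[:, None] + np.arange(n_time)[None, :]
    x = rec.x[idx]
    y = rec.y[idx]
    return EpochSet(time=time, x=x, y=y, trials=trials.reset_index(drop=True),
                    included=np.ones(len(trials), bool),
                    sampling_rate=rec.sampling_rate)


def baseline_correct(ep: EpochSet, window=(-200.0, 0.0)) -> EpochSet:
    """Subtract each trial's mean over the baseline window, per channel.

    Missing samples are ignored in the mean; trials whose baseline is fully
    missing on either channel are marked excluded with a warning.
    """
    out = ep.copy()
    sl = out.window_slice(window)
    if sl.stop <= sl.start:
        raise ValueError(f"baseline window {window} outside epoch time range")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN slices
        bx = np.nanmean(out.x[:, sl], axis=1)
        by = np.nanmean(out.y[:, sl], axis=1)
    dead = ~np.isfinite(bx) | ~np.isfinite(by)
    if dead.any():
        # routine with real blink rates; logged rather than raised to the user
        logger.warning("%d trial(s) with fully missing baseline excluded",
                       int(dead.sum()))
        out.included &= ~dead
    bx = np.where(np.isfinite(bx), bx, 0.0)
    by = np.where(np.isfinite(by), by, 0.0)
    out.x -= bx[:, None]
    out.y -= by[:, None]
    out.baseline_applied = True
    return out


def exclude_deviant_trials(ep: EpochSet, radius: float = 2.0,
                           window=(0.0, 1000.0),
                           metric: str = "euclidean"):
    """Drop trials with gaze farther than ``radius`` from fixation in-window.

    The default distance is Euclidean √(x²+y²); ``metric="per_axis"`` instead
    tests max(|x|, |y|).  Missing samples never count toward exclusion.
    Returns ``(EpochSet, ExclusionReport)`` where the report carries the
    usable-trial fraction (relative to trials entering this step).
    """
    if not ep.baseline_applied:
        raise ValueError("exclude_deviant_trials requires baseline-corrected epochs")
    out = ep.copy()
    sl = out.window_slice(window)
    x = out.x[:, sl]
    y = out.y[:, sl]
    if metric == "euclidean":
        dist = np.hypot(x, y)
    elif metric == "per_axis":
        dist = np.fmax(np.abs(x), np.abs(y))
    else:
        raise ValueError(f"unknown metric {metric!r}")
    with np.errstate(invalid="ignore"):
        deviant = np.nanmax(np.where(np.isfinite(dist), dist, -np.inf), axis=1) > radius
    n_before = int(out.included.sum())
    newly = deviant & out.included
    out.included &= ~deviant
    report = ExclusionReport(
        n_trials=n_before,
        n_excluded=int(newly.sum()),
        excluded_ids=out.trials.loc[newly, "trial_id"].to_numpy(),
        usable_fraction=float(out.included.sum()) / max(n_before, 1),
    )
    return out, report


def preprocess(rec: GazeRecording, trials: pd.DataFrame, config) -> tuple:
    """Run the full chain: blink mask → epoch → baseline → 2° exclusion."""
    rec = mask_blinks(rec, pad=config.blink_pad)
    ep = epoch(rec, trials, window=config.epoch_window)
    ep = baseline_correct(ep, window=config.baseline_window)
    return exclude_deviant_trials(ep, radius=config.exclusion_radius,
                                  window=config.exclusion_window,
                                  metric=config.exclusion_metric)
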