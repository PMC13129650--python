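"""Signed gaze bias ("towardness") toward the cued memory item.

Left/right trials are read out on the x axis and top/bottom trials on the
y axis; the sign is flipped so positive always means gaze drifted toward
the cued item's encoded direction.  Trials are then averaged within
participant × condition, and a scalar bias is the mean of the course over
the predefined 400–1,000 ms window.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, Tuple

import numpy as np
import pandas as pd

from .io import cue_sign
from .preprocess import EpochSet

ConditionKey = Tuple[str, str]  # (scaffold, cued_distance)


@dataclass
class TowardnessCourse:
    participant: object
    condition: ConditionKey
    time: np.ndarray
    towardness: np.ndarray
    n_trials: int


def trial_towardness(ep: EpochSet) -> np.ndarray:
    """Per-trial towardness matrix (trials × time).

    Rows of excluded trials are returned as NaN so downstream averages can
    never pick them up by accident.
    """
    if not ep.baseline_applied:
        raise ValueError("trial_towardness requires baseline-corrected epochs")
    dirs = ep.trials["cued_direction"].to_numpy()
    unknown = set(dirs) - {"left", "right", "top", "bottom"}
    if unknown:
        raise ValueError(f"unknown cued_direction value(s) {sorted(unknown)}")
    horiz = np.isin(dirs, ("left", "right"))
    signs = np.array([cue_sign(d) for d in dirs], float)
    tw = np.where(horiz[:, None], ep.x, ep.y) * signs[:, None]
    tw[~ep.included] = np.nan
    return tw


def average_towardness(tw: np.ndarray, ep: EpochSet,
                       participant=None,
                       grouping: Iterable[str] = ("scaffold", "cued_distance"),
                       ) -> Dict[ConditionKey, TowardnessCourse]:
    """Missing-aware mean towardness per condition group.

    Groups with no included trials are omitted with a warning.
    """
    grouping = list(grouping)
    courses: Dict[ConditionKey, TowardnessCourse] = {}
    keys = ep.trials[grouping].apply(tuple, axis=1)
    for key in sorted(keys.unique()):
        rows = (keys == key).to_numpy() & ep.included
        if not rows.any():
            warnings.warn(f"group {key}: no included trials, course omitted")
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            mean = np.nanmean(tw[rows], axis=0)
        courses[key] = TowardnessCourse(
            participant=participant, condition=key, time=ep.time,
            towardness=mean, n_trials=int(rows.sum()))
    return courses


def window_bias(course: TowardnessCourse, window=(400.0, 1000.0)) -> float:
    """Mean towardness over a half-open [start, end) ms window."""
    sel = (course.time >= window[0] - 1e-9) & (course.time < window[1] - 1e-9)
    if not sel.any():
        raise ValueError(f"window {window} outside course time range")
    vals = course.towardness[sel]
    if not np.isfinite(vals).any():
        warnings.warn("all-missing bias window; returning NaN")
        return float("nan")
    return float(np.nanmean(vals))


def bias_table(courses_by_participant: Dict[object, Dict[ConditionKey, TowardnessCourse]],
               window=(400.0, 1000.0)) -> pd.DataFrame:
    """Long-format table of window biases: participant, scaffold, distance, bias."""
    rows = []
    for pid, courses in courses_by_participant.items():
        for (scaffold, distance), course in courses.items():
            rows.append({"participant": pid, "scaffold": scaffold,
                         "cued_distance": distance,
                         "bias": window_bias(course, window),
                         "n_trials": course.n_trials})
    return pd.DataFrame(rows)


def interaction_index(biases: Dict[ConditionKey, float]) -> float:
    """(far − near) bias when direction is insufficient minus when sufficient.

    Positive values mean distance modulated the gaze bias more when distance
    was a useful scaffolding feature.
    """
    needed = [("direction_insufficient", "far"), ("direction_insufficient", "near"),
              ("direction_sufficient", "far"), ("direction_sufficient", "near")]
    missing = [k for k in needed if k not in biases or not np.isfinite(biases[k])]
    if missing:
        raise KeyError(f"missing condition bias(es): {missing}")
    ins = biases[needed[0]] - biases[needed[1]]
    suf = biases[needed[2]] - biases[needed[3]]
    return float(ins - suf)


def interaction_index_table(bias_df: pd.DataFrame) -> pd.DataFrame:
    """Per-participant interaction indices from a long bias table.

    Participants missing any of the four cells are dropped with a warning.
    """
    rows = []
    for pid, sub in bias_df.groupby("participant"):
        biases = {(r.scaffold, r.cued_distance): r.bias for r in sub.itertuples()}
        try:
            idx = interaction_index(biases)
        except KeyError as exc:
            warnings.warn(f"participant {pid} dropped: {exc}")
            continue
        rows.append({"participant": pid, "interaction_index": idx})
    return pd.DataFrame(rows)
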