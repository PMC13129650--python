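"""Data model and readers/writers.

Gaze is represented in degrees of visual angle relative to the fixation
point, with +x rightward and +y upward (screen-native y-down coordinates are
flipped at read time so that "toward the top item" is positive y).  Two
on-disk dialects are supported: a plain samples table (TSV/CSV with a
``# units: deg|px`` comment line) and a minimal EyeLink-ASC subset
(SAMPLE / EBLINK / MSG lines only).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd

logger = logging.getLogger("gazescaffold")

DIRECTIONS = ("left", "right", "top", "bottom")
#: accepted aliases for cued-direction tokens
DIRECTION_ALIASES = {
    "left": "left", "l": "left",
    "right": "right", "r": "right",
    "top": "top", "up": "top", "u": "top", "t": "top",
    "bottom": "bottom", "down": "bottom", "d": "bottom", "b": "bottom",
}
DISTANCES = ("near", "far")
DISTANCE_ALIASES = {"near": "near", "3": "near", "3.0": "near",
                    "far": "far", "6": "far", "6.0": "far"}
SCAFFOLDS = ("direction_insufficient", "direction_sufficient")
SCAFFOLD_ALIASES = {
    "direction_insufficient": "direction_insufficient",
    "insufficient": "direction_insufficient",
    "direction_sufficient": "direction_sufficient",
    "sufficient": "direction_sufficient",
}
AXES = ("horizontal", "vertical")

#: eccentricity of the near/far item positions, degrees
DISTANCE_DEG = {"near": 3.0, "far": 6.0}

TRIAL_COLUMNS = ["trial_id", "cue_onset_ms", "cued_direction", "cued_distance",
                 "scaffold", "config_axis", "correct"]


@dataclass
class ScreenGeometry:
    """Monitor geometry needed to convert pixel gaze to degrees.

    The conversion uses a per-axis arctangent with the viewing distance
    (~65 cm in the recordings this package targets); fixation is assumed at
    the screen centre unless ``center_px`` says otherwise.  ``y_down`` marks
    screens whose pixel y axis grows downward (the usual convention); such
    y values are negated so the analysis space has +y upward.
    """

    width_px: float
    height_px: float
    width_cm: float
    height_cm: float
    distance_cm: float = 65.0
    center_px: Optional[tuple] = None
    y_down: bool = True

    def center(self) -> tuple:
        if self.center_px is not None:
            return tuple(self.center_px)
        return ((self.width_px - 1) / 2.0, (self.height_px - 1) / 2.0)

    def to_degrees(self, px: np.ndarray, axis: str) -> np.ndarray:
        cx, cy = self.center()
        if axis == "x":
            cm_per_px = self.width_cm / self.width_px
            rel = (np.asarray(px, float) - cx) * cm_per_px
            return np.degrees(np.arctan2(rel, self.distance_cm))
        cm_per_px = self.height_cm / self.height_px
        rel = (np.asarray(px, float) - cy) * cm_per_px
        deg = np.degrees(np.arctan2(rel, self.distance_cm))
        return -deg if self.y_down else deg


@dataclass
class GazeRecording:
    """A continuous gaze trace at a fixed sampling rate.

    ``time`` is in milliseconds and must be uniform at 1/sampling_rate
    spacing; ``x``/``y`` are degrees relative to fixation; ``valid`` is False
    for blink/missing samples (whose x/y are NaN).
    """

    time: np.ndarray
    x: np.ndarray
    y: np.ndarray
    valid: np.ndarray
    pupil: Optional[np.ndarray] = None
    sampling_rate: float = 1000.0
    blink_masked: bool = False

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, float)
        self.x = np.asarray(self.x, float)
        self.y = np.asarray(self.y, float)
        self.valid = np.asarray(self.valid, bool)
        n = len(self.time)
        for name in ("x", "y", "valid"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"channel {name!r} length != time length")
        if self.pupil is not None:
            self.pupil = np.asarray(self.pupil, float)
            if len(self.pupil) != n:
                raise ValueError("pupil length != time length")
        if n >= 2:
            dt = np.diff(self.time)
            expected = 1000.0 / self.sampling_rate
            bad = np.nonzero(~np.isclose(dt, expected, rtol=0, atol=1e-6))[0]
            if bad.size:
                i = bad[0]
                raise ValueError(
                    f"non-uniform timestamps: gap of {dt[i]:g} ms after "
                    f"t={self.time[i]:g} ms (expected {expected:g} ms)")
        if np.any(~np.isfinite(self.x[self.valid])) or np.any(~np.isfinite(self.y[self.valid])):
            raise ValueError("x/y must be finite wherever valid is true")

    def __len__(self) -> int:
        return len(self.time)

    @property
    def dt(self) -> float:
        return 1000.0 / self.sampling_rate

    def copy(self) -> "GazeRecording":
        return replace(
            self, time=self.time.copy(), x=self.x.copy(), y=self.y.copy(),
            valid=self.valid.copy(),
            pupil=None if self.pupil is None else self.pupil.copy())


def _sniff_sep(header_line: str) -> str:
    return "\t" if "\t" in header_line else ","


def read_gaze(path, format: str = "samples_table",
              screen: Optional[ScreenGeometry] = None,
              sampling_rate: float = 1000.0) -> GazeRecording:
    """Read a gaze recording into degrees relative to fixation.

    ``format`` is ``"samples_table"`` (TSV/CSV with a ``# units:`` comment)
    or ``"asc_subset"`` (minimal EyeLink ASC).  If the source is in pixels a
    :class:`ScreenGeometry` must be supplied.
    """
    path = Path(path)
    if format == "samples_table":
        return _read_samples_table(path, screen, sampling_rate)
    if format == "asc_subset":
        return _read_asc_subset(path, screen, sampling_rate)
    raise ValueError(f"unknown gaze format {format!r}")


def _read_samples_table(path: Path, screen, sampling_rate) -> GazeRecording:
    units = "deg"
    header = None
    with open(path) as fh:
        for line in fh:
            s = line.strip()
            if not s:
                continue
            if s.startswith("#"):
                body = s.lstrip("#").strip()
                if body.lower().startswith("units:"):
                    units = body.split(":", 1)[1].strip().lower()
                continue
            header = s
            break
    if header is None:
        raise ValueError(f"{path}: empty samples table")
    sep = _sniff_sep(header)
    try:
        df = pd.read_csv(path, sep=sep, comment="#")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ValueError(f"{path}: unparseable samples table ({exc})") from exc
    required = {"time_ms", "x", "y"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    x = df["x"].to_numpy(float)
    y = df["y"].to_numpy(float)
    if units == "px":
        if screen is None:
            raise ValueError(f"{path}: pixel units require screen geometry")
        x = screen.to_degrees(x, "x")
        y = screen.to_degrees(y, "y")
    elif units != "deg":
        raise ValueError(f"{path}: unknown units {units!r}")
    if "valid" in df.columns:
        valid = df["valid"].to_numpy().astype(bool)
    else:
        valid = np.isfinite(x) & np.isfinite(y)
    pupil = df["pupil"].to_numpy(float) if "pupil" in df.columns else None
    x = np.where(valid, x, np.nan)
    y = np.where(valid, y, np.nan)
    return GazeRecording(time=df["time_ms"].to_numpy(float), x=x, y=y,
                         valid=valid, pupil=pupil, sampling_rate=sampling_rate)


def _read_asc_subset(path: Path, screen, sampling_rate) -> GazeRecording:
    """Parse a minimal EyeLink-ASC subset: sample lines, EBLINK, MSG.

    Sample lines are ``<time> <x> <y> <pupil> ...`` with ``.`` for missing
    data; ``EBLINK <eye> <start> <end>`` intervals are marked invalid.
    Anything else (MSG, SBLINK, SSACC, ESACC, comments) is ignored.
    """
    times, xs, ys, pupils = [], [], [], []
    blink_ivals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            s = line.strip()
            if not s or s.startswith(("#", "*", ";", "//")):
                continue
            tok = s.split()
            if tok[0].replace(".", "", 1).isdigit():
                if len(tok) < 3:
                    raise ValueError(f"{path}:{lineno}: unparseable sample line")
                try:
                    t = float(tok[0])
                    x = np.nan if tok[1] == "." else float(tok[1])
                    y = np.nan if tok[2] == "." else float(tok[2])
                    p = np.nan
                    if len(tok) > 3 and tok[3] != ".":
                        p = float(tok[3])
                except ValueError as exc:
                    raise ValueError(f"{path}:{lineno}: unparseable sample line") from exc
                times.append(t); xs.append(x); ys.append(y); pupils.append(p)
            elif tok[0] == "EBLINK":
                if len(tok) < 4:
                    raise ValueError(f"{path}:{lineno}: malformed EBLINK line")
                blink_ivals.append((float(tok[2]), float(tok[3])))
            elif tok[0] in ("MSG", "SBLINK", "SSACC", "ESACC", "SFIX", "EFIX",
                            "START", "END", "INPUT", "SAMPLES", "EVENTS"):
                continue
            else:
                raise ValueError(f"{path}:{lineno}: unrecognised line {tok[0]!r}")
    if not times:
        raise ValueError(f"{path}: no sample lines found")
    time = np.asarray(times, float)
    x = np.asarray(xs, float)
    y = np.asarray(ys, float)
    pupil = np.asarray(pupils, float)
    if screen is not None:
        x = screen.to_degrees(x, "x")
        y = screen.to_degrees(y, "y")
    valid = np.isfinite(x) & np.isfinite(y)
    for lo, hi in blink_ivals:
        valid &= ~((time >= lo) & (time <= hi))
    x = np.where(valid, x, np.nan)
    y = np.where(valid, y, np.nan)
    pupil = np.where(np.isfinite(pupil), pupil, 0.0)
    return GazeRecording(time=time, x=x, y=y, valid=valid, pupil=pupil,
                         sampling_rate=sampling_rate)


def write_gaze(rec: GazeRecording, path, units: str = "deg") -> None:
    """Write a recording in the samples_table dialect (degrees only)."""
    if units != "deg":
        raise ValueError("write_gaze only emits degree units")
    df = pd.DataFrame({"time_ms": rec.time, "x": rec.x, "y": rec.y})
    if rec.pupil is not None:
        df["pupil"] = rec.pupil
    df["valid"] = rec.valid.astype(int)
    with open(path, "w") as fh:
        fh.write("# units: deg\n")
        df.to_csv(fh, sep="\t", index=False, na_rep="nan")


def read_trials(path) -> pd.DataFrame:
    """Read and validate a trial table.

    Returns a DataFrame with the canonical columns ``trial_id, cue_onset_ms,
    cued_direction, cued_distance, scaffold, config_axis, correct[, rt_ms]``.
    Direction/distance/scaffold tokens are normalised through documented
    alias tables (e.g. ``up`` -> ``top``, ``3`` -> ``near``).
    """
    path = Path(path)
    with open(path) as fh:
        first = ""
        for line in fh:
            if line.strip() and not line.startswith("#"):
                first = line
                break
    if not first:
        warnings.warn(f"{path}: empty trial table")
        return pd.DataFrame(columns=TRIAL_COLUMNS)
    df = pd.read_csv(path, sep=_sniff_sep(first), comment="#")
    required = {"cue_onset_ms", "cued_direction", "cued_distance", "scaffold", "correct"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if "trial_id" not in df.columns:
        df.insert(0, "trial_id", np.arange(len(df)))

    def _map(col, aliases, what):
        vals = df[col].astype(str).str.strip().str.lower()
        unknown = sorted(set(vals) - set(aliases))
        if unknown:
            raise ValueError(f"{path}: unknown {what} token(s) {unknown}")
        return vals.map(aliases)

    df["cued_direction"] = _map("cued_direction", DIRECTION_ALIASES, "direction")
    df["cued_distance"] = _map("cued_distance", DISTANCE_ALIASES, "distance")
    df["scaffold"] = _map("scaffold", SCAFFOLD_ALIASES, "scaffold")
    if "config_axis" not in df.columns:
        df["config_axis"] = np.where(
            df["cued_direction"].isin(["left", "right"]), "horizontal", "vertical")
    df["correct"] = df["correct"].astype(int).astype(bool)
    return df.reset_index(drop=True)


def cue_axis(direction: str) -> str:
    return "horizontal" if direction in ("left", "right") else "vertical"


def cue_sign(direction: str) -> int:
    """Sign of the cued direction on its axis (+ for right/top)."""
    return {"right": 1, "top": 1, "left": -1, "bottom": -1}[direction]


def write_results(tables: Dict[str, pd.DataFrame], out_dir, *,
                  config=None, seed=None, overwrite: bool = False) -> dict:
    """Write named result tables as TSV plus a JSON provenance sidecar.

    Returns a manifest mapping table names to file paths.  Refuses to
    overwrite existing files unless ``overwrite`` is set.
    """
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {}
    for name, df in tables.items():
        p = out_dir / f"{name}.tsv"
        if p.exists() and not overwrite:
            raise FileExistsError(f"{p} exists (pass overwrite=True)")
        df.to_csv(p, sep="\t", index=False, na_rep="nan", float_format="%.10g")
        manifest[name] = str(p)
    meta = {
        "package": "gazescaffold",
        "version": __version__,
        "seed": seed,
        "config": None if config is None else config.to_dict(),
        "tables": manifest,
    }
    meta_path = out_dir / "meta.json"
    if meta_path.exists() and not overwrite:
        raise FileExistsError(f"{meta_path} exists (pass overwrite=True)")
    with open(meta_path, "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
    manifest["meta"] = str(meta_path)
    return manifest
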