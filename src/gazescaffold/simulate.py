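"""Synthetic gaze generator with the statistical structure the analysis assumes.

Each participant is a continuous 1,000 Hz recording of fixational drift
(an Ornstein–Uhlenbeck process around fixation), Poisson blinks, Poisson
microsaccades (lognormal amplitudes capped at 2°, biased toward the cued
item after cue onset), and — on each trial's cued axis — an additive
towardness ramp whose amplitude depends on the scaffold × distance cell.
Designs mirror the three experiments: 640 trials on the horizontal axis
only (exp1), or 800 trials over both axes and two scaffold conditions
(exp2/exp3).  Everything is deterministic under a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .io import GazeRecording, cue_sign

CellKey = Tuple[str, str]  # (scaffold, cued_distance)

#: group-mean window biases (deg) used as default injected amplitudes
DEFAULT_AMPLITUDES: Dict[CellKey, float] = {
    ("direction_insufficient", "near"): 0.065,
    ("direction_insufficient", "far"): 0.125,
    ("direction_sufficient", "near"): 0.093,
    ("direction_sufficient", "far"): 0.097,
}

DESIGNS = {
    "exp1": dict(n_trials=640, scaffolds=("direction_insufficient",),
                 directions=("left", "right"),
                 accuracy={"direction_insufficient": 0.75,
                           "direction_sufficient": 0.75}),
    "exp2": dict(n_trials=800,
                 scaffolds=("direction_insufficient", "direction_sufficient"),
                 directions=("left", "right", "top", "bottom"),
                 accuracy={"direction_insufficient": 0.74,
                           "direction_sufficient": 0.77}),
    "exp3": dict(n_trials=800,
                 scaffolds=("direction_insufficient", "direction_sufficient"),
                 directions=("left", "right", "top", "bottom"),
                 accuracy={"direction_insufficient": 0.79,
                           "direction_sufficient": 0.82}),
}

#: default trial segment layout of the continuous recording
TRIAL_LEN_MS = 3500.0
PRE_CUE_MS = 1200.0

_DIR_ANGLE = {"right": 0.0, "top": 90.0, "left": 180.0, "bottom": -90.0}


@dataclass
class GeneratorConfig:
    """Study-condition parameters of the synthetic generator.

    Amplitude defaults are the published group-mean window biases; the
    participant-level spread (a distance-effect trait shared across scaffold
    conditions plus condition-specific jitter) is calibrated so that at the
    full design size the far-vs-near contrast has Cohen's d ≈ 0.57 and the
    2 × 2 interaction is detected in ≈ 90% of replications at n = 25.
    """

    n_participants: int = 25
    design: str = "exp2"
    n_trials: Optional[int] = None  # None -> the design's trial count
    sampling_rate: float = 1000.0
    trial_len_ms: float = TRIAL_LEN_MS  # recording segment per trial
    pre_cue_ms: float = PRE_CUE_MS  # cue onset within the segment
    bias_amplitude: Dict[CellKey, float] = field(
        default_factory=lambda: dict(DEFAULT_AMPLITUDES))
    participant_distance_sd: float = 0.085  # deg, shared far-near trait
    participant_condition_sd: float = 0.05  # deg, per-scaffold jitter
    bias_onset: float = 250.0  # ms, ramp start
    bias_full: float = 400.0  # ms, ramp plateau
    ou_sd: float = 0.25  # deg, stationary SD of fixational drift
    ou_tau: float = 100.0  # ms, drift time constant
    drift_smooth_ms: float = 50.0  # moving-average window; keeps drift
    # velocity at the few-deg/s scale of real fixation so saccades stand out
    blink_rate: float = 0.15  # Hz
    blink_duration: Tuple[float, float] = (100.0, 300.0)  # ms, uniform
    saccade_rate: float = 0.8  # Hz
    saccade_amp_median: float = 0.3  # deg, lognormal median
    saccade_amp_sigma: float = 0.7  # lognormal shape
    saccade_amp_max: float = 2.0  # deg cap
    saccade_rise: float = 15.0  # ms
    saccade_decay_tau: float = 200.0  # ms, drift back to fixation
    toward_prob: float = 0.3  # post-cue saccades aimed at the cued item
    toward_jitter: float = 15.0  # deg SD around the cued direction
    accuracy: Optional[Dict[str, float]] = None  # None -> design default
    seed: int = 0

    def __post_init__(self) -> None:
        if self.design not in DESIGNS:
            raise ValueError(f"unknown design {self.design!r}")
        design = DESIGNS[self.design]
        if self.n_trials is None:
            self.n_trials = design["n_trials"]
        n_cells = len(design["scaffolds"]) * 2 * len(design["directions"])
        if self.n_trials % n_cells:
            raise ValueError(
                f"n_trials={self.n_trials} not divisible by the "
                f"{n_cells} design cells of {self.design}")
        if self.accuracy is None:
            self.accuracy = dict(design["accuracy"])

    def scaled_down(self, n_trials: int) -> "GeneratorConfig":
        """A smaller design preserving the effect-size calibration.

        Every stochastic contribution to the per-trial towardness (the OU
        drift and the saccade displacements) is shrunk by
        sqrt(n_trials / full) so the per-participant bias-estimate noise —
        and hence Cohen's d — matches the full-size design.  Not meant for
        saccade-size analyses, whose amplitude scale it deliberately alters.
        """
        full = DESIGNS[self.design]["n_trials"]
        factor = float(np.sqrt(n_trials / full))
        return replace(self, n_trials=n_trials, ou_sd=self.ou_sd * factor,
                       saccade_amp_median=self.saccade_amp_median * factor,
                       saccade_amp_max=self.saccade_amp_max * factor)

    def with_segment(self, trial_len_ms: float, pre_cue_ms: float) -> "GeneratorConfig":
        """Shorter trial segments (the epoch window must still fit)."""
        return replace(self, trial_len_ms=trial_len_ms, pre_cue_ms=pre_cue_ms)


@dataclass
class ParticipantData:
    participant: int
    recording: GazeRecording
    trials: pd.DataFrame
    truth: dict


def _trial_table(cfg: GeneratorConfig, rng: np.random.Generator) -> pd.DataFrame:
    design = DESIGNS[cfg.design]
    cells = [(s, dist, d)
             for s in design["scaffolds"]
             for dist in ("near", "far")
             for d in design["directions"]]
    reps = cfg.n_trials // len(cells)
    rows = cells * reps
    order = rng.permutation(len(rows))
    table = []
    for i, j in enumerate(order):
        s, dist, d = rows[j]
        table.append({
            "trial_id": i,
            "cue_onset_ms": i * cfg.trial_len_ms + cfg.pre_cue_ms,
            "cued_direction": d,
            "cued_distance": dist,
            "scaffold": s,
            "config_axis": "horizontal" if d in ("left", "right") else "vertical",
        })
    return pd.DataFrame(table)


def _ou_trace(n: int, sd: float, tau: float, dt: float,
              rng: np.random.Generator) -> np.ndarray:
    """Exact AR(1) discretisation of an OU process with stationary SD."""
    if sd == 0:
        return np.zeros(n)
    a = np.exp(-dt / tau)
    e = rng.normal(0.0, sd * np.sqrt(1 - a * a), n)
    x0 = rng.normal(0.0, sd)
    out, _ = lfilter([1.0], [1.0, -a], e, zi=np.array([a * x0]))
    return out


def _logistic_ramp(t: np.ndarray, onset: float, full: float) -> np.ndarray:
    center = (onset + full) / 2.0
    scale = max((full - onset) / 10.0, 1e-6)
    return 1.0 / (1.0 + np.exp(-(t - center) / scale))


def _saccade_kernel(cfg: GeneratorConfig, dt: float) -> np.ndarray:
    """Unit saccade waveform: raised-cosine rise, exponential drift back.

    The sigmoidal rise gives the bell-shaped velocity profile of real
    saccades (peak velocity pi/2 times the mean), followed by a slow drift
    back toward fixation.
    """
    rise_n = max(int(round(cfg.saccade_rise / dt)), 1)
    rise = 0.5 * (1 - np.cos(np.pi * np.arange(1, rise_n + 1) / rise_n))
    decay_n = int(round(5 * cfg.saccade_decay_tau / dt))
    return np.concatenate([
        rise, np.exp(-np.arange(1, decay_n + 1) * dt / cfg.saccade_decay_tau)])


def _capped_lognormal_mean(median: float, sigma: float, cap: float) -> float:
    from scipy.stats import norm
    mu = np.log(median)
    return (np.exp(mu + sigma ** 2 / 2) * norm.cdf((np.log(cap) - mu - sigma ** 2) / sigma)
            + cap * norm.sf((np.log(cap) - mu) / sigma))


def _expected_saccade_course(cfg: GeneratorConfig, post_len: int, dt: float) -> np.ndarray:
    """Expected toward-axis displacement from toward-biased microsaccades.

    Post-cue saccades aim at the cued item with probability ``toward_prob``
    (uniform otherwise, mean zero).  For a Poisson stream from cue onset the
    mean displacement at time t is λp · E[amp∥] · ∫₀ᵗ kernel, which is
    subtracted from the additive bias so the configured cell amplitude is
    exactly the expected towardness plateau.
    """
    if cfg.toward_prob == 0 or cfg.saccade_rate == 0:
        return np.zeros(post_len)
    lam = cfg.saccade_rate * cfg.toward_prob / 1000.0  # toward events per ms
    amp_along = (_capped_lognormal_mean(cfg.saccade_amp_median, cfg.saccade_amp_sigma,
                                        cfg.saccade_amp_max)
                 * np.exp(-np.radians(cfg.toward_jitter) ** 2 / 2))
    cum = np.concatenate(([0.0], np.cumsum(_saccade_kernel(cfg, dt)) * dt))
    idx = np.minimum(np.arange(post_len), len(cum) - 1)
    return lam * amp_along * cum[idx]


def expected_cell_bias(cfg: GeneratorConfig, window=(400.0, 1000.0)) -> Dict[CellKey, float]:
    """Ground-truth expected window bias per condition cell (group mean)."""
    dt = 1000.0 / cfg.sampling_rate
    post_len = int(round((cfg.trial_len_ms - cfg.pre_cue_ms) / dt))
    t = np.arange(post_len) * dt
    ramp = _logistic_ramp(t, cfg.bias_onset, cfg.bias_full)
    sel = (t >= window[0]) & (t < window[1])
    mean_ramp = float(ramp[sel].mean())
    return {cell: amp * mean_ramp for cell, amp in cfg.bias_amplitude.items()}


def generate_participant(cfg: GeneratorConfig, participant: int,
                         rng: np.random.Generator) -> ParticipantData:
    dt = 1000.0 / cfg.sampling_rate
    trials = _trial_table(cfg, rng)
    trial_len_n = int(round(cfg.trial_len_ms / dt))
    pre_n = int(round(cfg.pre_cue_ms / dt))
    post_len = trial_len_n - pre_n
    n_samples = cfg.n_trials * trial_len_n
    time = np.arange(n_samples) * dt

    x = _ou_trace(n_samples, cfg.ou_sd, cfg.ou_tau, dt, rng)
    y = _ou_trace(n_samples, cfg.ou_sd, cfg.ou_tau, dt, rng)
    if cfg.drift_smooth_ms > dt:
        from scipy.ndimage import uniform_filter1d
        width = int(round(cfg.drift_smooth_ms / dt))
        x = uniform_filter1d(x, width, mode="nearest")
        y = uniform_filter1d(y, width, mode="nearest")

    # participant-level amplitude structure: a far-near trait shared across
    # scaffold conditions plus condition-specific jitter
    delta_p = rng.normal(0.0, cfg.participant_distance_sd)
    cond_jit = {s: rng.normal(0.0, cfg.participant_condition_sd)
                for s in DESIGNS[cfg.design]["scaffolds"]}
    amp_cell: Dict[CellKey, float] = {}
    for (s, dist), base in cfg.bias_amplitude.items():
        if s in cond_jit:
            half = (delta_p + cond_jit[s]) / 2.0
            amp_cell[(s, dist)] = base + (half if dist == "far" else -half)

    ramp = _logistic_ramp(np.arange(post_len) * dt, cfg.bias_onset, cfg.bias_full)
    sacc_mean = _expected_saccade_course(cfg, post_len, dt)
    # subtract the deterministic mean of the toward-saccade stream so the
    # expected towardness course is exactly amp * ramp
    amps = np.array([amp_cell[(s, d)] for s, d in
                     zip(trials["scaffold"], trials["cued_distance"])])
    signs = np.array([cue_sign(d) for d in trials["cued_direction"]], float)
    horiz = (trials["config_axis"] == "horizontal").to_numpy()
    contrib = signs[:, None] * (amps[:, None] * ramp[None, :] - sacc_mean[None, :])
    xt = x.reshape(cfg.n_trials, trial_len_n)
    yt = y.reshape(cfg.n_trials, trial_len_n)
    xt[horiz, pre_n:] += contrib[horiz]
    yt[~horiz, pre_n:] += contrib[~horiz]

    # microsaccades: fast ramp out, slow exponential drift back
    duration_s = n_samples * dt / 1000.0
    n_sacc = rng.poisson(cfg.saccade_rate * duration_s)
    sacc_t = np.sort(rng.uniform(0, n_samples * dt, n_sacc))
    kernel = _saccade_kernel(cfg, dt)
    sacc_amp = np.minimum(rng.lognormal(np.log(cfg.saccade_amp_median),
                                        cfg.saccade_amp_sigma, n_sacc),
                          cfg.saccade_amp_max)
    cue_onsets = trials["cue_onset_ms"].to_numpy()
    dir_angles = trials["cued_direction"].map(_DIR_ANGLE).to_numpy(float)
    trial_ids = trials["trial_id"].to_numpy()
    truth_sacc = []
    for j, t0 in enumerate(sacc_t):
        amp = float(sacc_amp[j])
        ti = min(int(t0 // cfg.trial_len_ms), cfg.n_trials - 1)
        post_cue = t0 >= cue_onsets[ti]
        if post_cue and rng.random() < cfg.toward_prob:
            angle = dir_angles[ti] + rng.normal(0, cfg.toward_jitter)
        else:
            angle = rng.uniform(0, 360.0)
        th = np.radians(angle)
        i0 = int(round(t0 / dt))
        stop = min(i0 + len(kernel), n_samples)
        kseg = kernel[: stop - i0]
        x[i0:stop] += amp * np.cos(th) * kseg
        y[i0:stop] += amp * np.sin(th) * kseg
        truth_sacc.append({"time_ms": i0 * dt, "amplitude": amp,
                           "angle_deg": angle, "trial_id": int(trial_ids[ti]),
                           "post_cue": bool(post_cue)})

    # blinks: pupil drops to 0, gaze missing
    pupil = 1000.0 + rng.normal(0, 10.0, n_samples)
    valid = np.ones(n_samples, bool)
    n_blinks = rng.poisson(cfg.blink_rate * duration_s)
    blink_spans = []
    for t0 in np.sort(rng.uniform(0, n_samples * dt, n_blinks)):
        dur = rng.uniform(*cfg.blink_duration)
        i0 = int(round(t0 / dt))
        i1 = min(i0 + int(round(dur / dt)), n_samples)
        valid[i0:i1] = False
        pupil[i0:i1] = 0.0
        blink_spans.append((i0 * dt, (i1 - 1) * dt))
    x[~valid] = np.nan
    y[~valid] = np.nan

    acc = trials["scaffold"].map(cfg.accuracy).to_numpy(float)
    trials = trials.assign(correct=rng.random(len(trials)) < acc)

    rec = GazeRecording(time=time, x=x, y=y, valid=valid, pupil=pupil,
                        sampling_rate=cfg.sampling_rate)
    truth = {"amplitudes": amp_cell, "saccades": pd.DataFrame(truth_sacc),
             "blink_spans": blink_spans, "delta_p": delta_p}
    return ParticipantData(participant=participant, recording=rec,
                           trials=trials, truth=truth)


def generate_dataset(cfg: GeneratorConfig) -> List[ParticipantData]:
    """Generate all participants of a study; deterministic under cfg.seed."""
    ss = np.random.SeedSequence(cfg.seed)
    children = ss.spawn(cfg.n_participants)
    return [generate_participant(cfg, p, np.random.default_rng(children[p]))
            for p in range(cfg.n_participants)]


def generate_null(cfg: GeneratorConfig) -> List[ParticipantData]:
    """Same generative model with every systematic bias removed.

    All cell amplitudes and participant traits are zero and post-cue
    saccades have no toward bias; used for type-I error studies.
    """
    null_cfg = replace(
        cfg,
        bias_amplitude={k: 0.0 for k in cfg.bias_amplitude},
        participant_distance_sd=0.0, participant_condition_sd=0.0,
        toward_prob=0.0)
    return generate_dataset(null_cfg)


def null_towardness_courses(n_participants: int, n_time: int, *,
                            n_trials: int = 200, ou_sd: float = 0.25,
                            ou_tau: float = 100.0, dt: float = 1.0,
                            rng: Optional[np.random.Generator] = None) -> np.ndarray:
    """Participant-average null towardness courses for type-I simulations.

    Each course emulates the trial average of ``n_trials`` independent OU
    drift traces (itself OU-distributed with SD shrunk by sqrt(n_trials)),
    which is the exchangeable null the cluster permutation test assumes.
    """
    rng = np.random.default_rng() if rng is None else rng
    sd = ou_sd / np.sqrt(n_trials)
    return np.stack([_ou_trace(n_time, sd, ou_tau, dt, rng)
                     for _ in range(n_participants)])
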