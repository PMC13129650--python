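"""Analysis configuration.

All fixed analysis constants live here: epoch/baseline/bias windows, the 2°
fixational-exclusion rule, blink padding, permutation settings and the Cauchy
prior scale for Bayes factors.  Time windows are half-open ``[start, end)``
in milliseconds so sample counts are unambiguous at 1,000 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Tuple

import yaml

Window = Tuple[float, float]


@dataclass
class AnalysisConfig:
    """Parameters of the gaze-bias analysis pipeline.

    Defaults follow the published protocol: cue-locked epochs from −1,000 to
    +2,000 ms, baseline −200 to 0 ms, gaze-bias window 400–1,000 ms,
    microsaccade window 200–600 ms, trials discarded when gaze strays more
    than 2° from fixation within 0–1,000 ms, blinks padded by 100 ms,
    10,000 sign-flip permutations at a two-sided alpha of 0.05, and a JZS
    Cauchy prior with scale r = 0.707.
    """

    epoch_window: Window = (-1000.0, 2000.0)
    baseline_window: Window = (-200.0, 0.0)
    bias_window: Window = (400.0, 1000.0)
    saccade_window: Window = (200.0, 600.0)
    exclusion_radius: float = 2.0
    exclusion_window: Window = (0.0, 1000.0)
    exclusion_metric: str = "euclidean"  # or "per_axis"
    blink_pad: float = 100.0
    n_permutations: int = 10_000
    alpha: float = 0.05
    cauchy_scale: float = 0.707
    rng_seed: int = 0
    # microsaccade detection
    velocity_threshold: float = 5.0  # multiples of the trial median speed
    velocity_estimator: str = "central"  # or "engbert"
    saccade_min_duration: float = 6.0  # ms
    saccade_merge_gap: float = 20.0  # ms
    toward_criterion: str = "axis_sign"  # or "cone"
    toward_cone_halfwidth: float = 45.0  # deg, used by the "cone" criterion
    # condition averaging
    axis_pooling: str = "per_trial"  # or "per_axis"

    def __post_init__(self) -> None:
        for name in ("epoch_window", "baseline_window", "bias_window",
                     "saccade_window", "exclusion_window"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"{name} must be ordered (start < end), got {(lo, hi)}")
        if self.exclusion_radius <= 0:
            raise ValueError("exclusion_radius must be > 0")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if self.exclusion_metric not in ("euclidean", "per_axis"):
            raise ValueError(f"unknown exclusion_metric {self.exclusion_metric!r}")
        if self.velocity_estimator not in ("central", "engbert"):
            raise ValueError(f"unknown velocity_estimator {self.velocity_estimator!r}")
        if self.toward_criterion not in ("axis_sign", "cone"):
            raise ValueError(f"unknown toward_criterion {self.toward_criterion!r}")
        if self.axis_pooling not in ("per_trial", "per_axis"):
            raise ValueError(f"unknown axis_pooling {self.axis_pooling!r}")

    def to_dict(self) -> dict:
        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        kwargs = dict(d)
        for name in ("epoch_window", "baseline_window", "bias_window",
                     "saccade_window", "exclusion_window"):
            if name in kwargs:
                kwargs[name] = tuple(kwargs[name])
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
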