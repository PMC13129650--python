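"""Cluster-based permutation inference on time courses.

Pointwise one-sample (or paired-difference) t tests are thresholded at a
two-sided alpha; maximal runs of same-sign suprathreshold t form clusters
whose mass is the sum of t values in the run.  The null distribution comes
from randomly sign-flipping each participant's time course (equivalent to
swapping condition labels in a paired design) and recording the largest
absolute cluster mass of each permutation.  A cluster's p value is the
proportion of permutations whose maximum reaches its observed mass,
with the ≥ convention so the smallest attainable p is 1/n_permutations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class Cluster:
    start: float  # ms (inclusive)
    end: float  # ms (inclusive, last suprathreshold sample)
    start_idx: int
    stop_idx: int  # exclusive
    mass: float
    sign: int
    p: Optional[float] = None


@dataclass
class ClusterResult:
    clusters: List[Cluster]
    observed_t: np.ndarray
    time: np.ndarray
    n_permutations: int
    alpha: float
    seed: Optional[int] = None
    max_null_mass: Optional[np.ndarray] = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{"start_ms": c.start, "end_ms": c.end,
                              "mass": c.mass, "sign": c.sign, "p": c.p}
                             for c in self.clusters])

    def significant(self, alpha: Optional[float] = None) -> List[Cluster]:
        a = self.alpha if alpha is None else alpha
        return [c for c in self.clusters if c.p is not None and c.p < a]


def pointwise_t(data: np.ndarray, against: Optional[np.ndarray] = None) -> np.ndarray:
    """One-sample t against zero (or paired t vs ``against``) per time point.

    Missing values are ignored; points with fewer than two contributing
    participants, or zero mean and zero variance, get t = 0 so they can
    never be suprathreshold.  Zero variance with nonzero mean gives ±inf.
    """
    d = np.asarray(data, float)
    if against is not None:
        against = np.asarray(against, float)
        if against.shape != d.shape:
            raise ValueError("paired shapes must match")
        d = d - against
    if d.ndim != 2 or d.shape[0] < 2:
        raise ValueError("need a (participants >= 2) x time matrix")
    n = np.isfinite(d).sum(axis=0)
    mean = np.where(n > 0, np.nansum(d, axis=0) / np.maximum(n, 1), 0.0)
    sq = np.nansum((d - mean) ** 2, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        var = sq / np.maximum(n - 1, 1)
        se = np.sqrt(var / np.maximum(n, 1))
        t = mean / se
    t = np.where(n < 2, 0.0, t)
    t = np.where((se == 0) & (mean == 0), 0.0, t)
    t = np.where((se == 0) & (mean != 0) & (n >= 2), np.sign(mean) * np.inf, t)
    return t


def find_clusters(t_course: np.ndarray, df: int, alpha: float = 0.05,
                  time: Optional[np.ndarray] = None) -> List[Cluster]:
    """Maximal same-sign runs of |t| above the two-sided critical value."""
    if df < 1:
        raise ValueError("df must be >= 1")
    crit = stats.t.ppf(1 - alpha / 2, df)
    t = np.asarray(t_course, float)
    if time is None:
        time = np.arange(len(t), dtype=float)
    clusters: List[Cluster] = []
    for sign in (1, -1):
        mask = (sign * t) > crit
        d = np.diff(np.concatenate(([0], mask.astype(int), [0])))
        for s, e in zip(np.flatnonzero(d == 1), np.flatnonzero(d == -1)):
            clusters.append(Cluster(start=float(time[s]), end=float(time[e - 1]),
                                    start_idx=int(s), stop_idx=int(e),
                                    mass=float(t[s:e].sum()), sign=sign))
    clusters.sort(key=lambda c: c.start_idx)
    return clusters


def _max_cluster_masses(t_mat: np.ndarray, crit: float) -> np.ndarray:
    """Largest |cluster mass| per row of a (perm x time) t matrix."""
    out = np.zeros(t_mat.shape[0])
    for i, t in enumerate(t_mat):
        best = 0.0
        for sign in (1.0, -1.0):
            mask = (sign * t) > crit
            if not mask.any():
                continue
            d = np.diff(np.concatenate(([0], mask.view(np.int8), [0])))
            starts = np.flatnonzero(d == 1)
            stops = np.flatnonzero(d == -1)
            cs = np.concatenate(([0.0], np.cumsum(t)))
            masses = np.abs(cs[stops] - cs[starts])
            best = max(best, float(masses.max()))
        out[i] = best
    return out


def permutation_test(data: np.ndarray, against: Optional[np.ndarray] = None, *,
                     n_permutations: int = 10_000, alpha: float = 0.05,
                     seed: Optional[int] = None,
                     time: Optional[np.ndarray] = None) -> ClusterResult:
    """Participant-level sign-flip cluster permutation test.

    ``data`` is a participants × time matrix (a towardness course per
    participant, or a per-participant condition difference when ``against``
    is given).  Reproducible for a fixed ``seed``.
    """
    d = np.asarray(data, float)
    if against is not None:
        d = d - np.asarray(against, float)
    if d.ndim != 2:
        raise ValueError("data must be participants x time")
    n = d.shape[0]
    if n < 2:
        raise ValueError("need at least 2 participants for a permutation test")
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    df = n - 1
    crit = stats.t.ppf(1 - alpha / 2, df)
    if time is None:
        time = np.arange(d.shape[1], dtype=float)

    t_obs = pointwise_t(d)
    clusters = find_clusters(t_obs, df, alpha, time)

    rng = np.random.default_rng(seed)
    signs = rng.choice(np.array([-1.0, 1.0]), size=(n_permutations, n))
    if np.isfinite(d).all():
        # sign flips leave per-participant squares unchanged, so the
        # permuted t courses come from the flipped means alone
        ssq = (d ** 2).sum(axis=0)
        means = signs @ d / n
        var = (ssq - n * means ** 2) / (n - 1)
        var = np.maximum(var, 0.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            t_perm = means / np.sqrt(var / n)
        t_perm = np.nan_to_num(t_perm, nan=0.0, posinf=np.inf, neginf=-np.inf)
    else:
        t_perm = np.empty((n_permutations, d.shape[1]))
        for i in range(n_permutations):
            t_perm[i] = pointwise_t(signs[i][:, None] * d)
    max_null = _max_cluster_masses(t_perm, crit)
    for c in clusters:
        count = int(np.count_nonzero(max_null >= abs(c.mass)))
        c.p = max(count, 1) / n_permutations
    return ClusterResult(clusters=clusters, observed_t=t_obs, time=np.asarray(time, float),
                         n_permutations=n_permutations, alpha=alpha, seed=seed,
                         max_null_mass=max_null)
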