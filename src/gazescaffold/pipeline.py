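"""End-to-end orchestration: raw recordings to condition-level statistics.

``process_participant`` runs blink masking → epoching → baseline →
fixational exclusion → towardness for one participant;  ``run_study``
aggregates participants into window-bias tables, the 2 × 2 repeated-measures
ANOVA with post hoc tests and Bayes factors, cluster-permutation tests on
the towardness courses, microsaccade size densities, and the
interaction-index/accuracy correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from .cluster import ClusterResult, permutation_test
from .config import AnalysisConfig
from .io import GazeRecording
from .preprocess import EpochSet, ExclusionReport, preprocess
from .saccades import SizeDensityCurve, detect_epoch_saccades, size_density
from .stats import (AnovaResult, BayesResult, CorrelationResult, TTestResult,
                    accuracy_correlation, bf01_paired, bias_matrix, paired_t,
                    rm_anova_2x2)
from .towardness import (TowardnessCourse, average_towardness, bias_table,
                         interaction_index_table, trial_towardness)


@dataclass
class ParticipantResult:
    participant: object
    epochs: EpochSet
    exclusion: ExclusionReport
    courses: Dict[tuple, TowardnessCourse]
    accuracy: Dict[str, float]
    saccade_events: Optional[list] = None


@dataclass
class StudyResult:
    bias: pd.DataFrame
    anova: Optional[AnovaResult]
    posthoc: Dict[str, TTestResult]
    bayes: Dict[str, BayesResult]
    cluster: Dict[str, ClusterResult]
    interaction: pd.DataFrame
    correlation: Optional[CorrelationResult]
    usable_fraction: float
    course_time: np.ndarray
    mean_courses: Dict[tuple, np.ndarray]
    size_density: Dict[str, SizeDensityCurve] = field(default_factory=dict)


def process_participant(recording: GazeRecording, trials: pd.DataFrame,
                        config: AnalysisConfig, participant=None,
                        detect_saccades: bool = False) -> ParticipantResult:
    ep, report = preprocess(recording, trials, config)
    tw = trial_towardness(ep)
    if config.axis_pooling == "per_axis":
        by_axis = average_towardness(
            tw, ep, participant,
            grouping=("scaffold", "cued_distance", "config_axis"))
        courses: Dict[tuple, TowardnessCourse] = {}
        for key in {k[:2] for k in by_axis}:
            parts = [c for k, c in by_axis.items() if k[:2] == key]
            mean = np.nanmean(np.stack([c.towardness for c in parts]), axis=0)
            courses[key] = TowardnessCourse(
                participant=participant, condition=key, time=ep.time,
                towardness=mean, n_trials=sum(c.n_trials for c in parts))
    else:
        courses = average_towardness(tw, ep, participant)
    accuracy = trials.groupby("scaffold")["correct"].mean().to_dict()
    events = detect_epoch_saccades(ep, config) if detect_saccades else None
    return ParticipantResult(participant=participant, epochs=ep,
                             exclusion=report, courses=courses,
                             accuracy=accuracy, saccade_events=events)


def _course_matrix(results: List[ParticipantResult], key: tuple) -> np.ndarray:
    return np.stack([r.courses[key].towardness for r in results if key in r.courses])


def run_study(participants: List[tuple], config: AnalysisConfig, *,
              cluster_tests: bool = True,
              saccade_analysis: bool = False,
              n_permutations: Optional[int] = None) -> StudyResult:
    """Full group analysis.

    ``participants`` is a list of ``(recording, trials)`` pairs (or
    ``ParticipantData`` from the generator).  Cluster tests cover each
    condition course against zero and the far-vs-near difference within
    each scaffold condition.
    """
    n_perm = config.n_permutations if n_permutations is None else n_permutations
    results: List[ParticipantResult] = []
    for pid, item in enumerate(participants):
        if hasattr(item, "recording"):
            rec, trials, pid = item.recording, item.trials, item.participant
        else:
            rec, trials = item
        results.append(process_participant(rec, trials, config, participant=pid,
                                           detect_saccades=saccade_analysis))

    bias_df = bias_table({r.participant: r.courses for r in results},
                         window=config.bias_window)
    usable = float(np.mean([r.exclusion.usable_fraction for r in results]))
    time = results[0].epochs.time

    scaffolds = sorted(bias_df["scaffold"].unique())
    two_by_two = len(scaffolds) == 2

    anova = None
    posthoc: Dict[str, TTestResult] = {}
    bayes: Dict[str, BayesResult] = {}
    if two_by_two:
        Y, _ = bias_matrix(bias_df)
        anova = rm_anova_2x2(Y, factor_names=("scaffold", "distance"))
        wide = bias_df.pivot_table(index="participant",
                                   columns=["scaffold", "cued_distance"],
                                   values="bias")
        for s in scaffolds:
            res = paired_t(wide[(s, "near")].to_numpy(),
                           wide[(s, "far")].to_numpy(), family_size=2)
            posthoc[f"near_vs_far[{s}]"] = res
            bayes[f"near_vs_far[{s}]"] = bf01_paired(res.t, res.df + 1,
                                                     config.cauchy_scale)
    else:
        wide = bias_df.pivot_table(index="participant",
                                   columns=["scaffold", "cued_distance"],
                                   values="bias")
        s = scaffolds[0]
        res = paired_t(wide[(s, "near")].to_numpy(),
                       wide[(s, "far")].to_numpy(), family_size=1)
        posthoc[f"near_vs_far[{s}]"] = res

    cluster: Dict[str, ClusterResult] = {}
    mean_courses: Dict[tuple, np.ndarray] = {}
    conditions = sorted({k for r in results for k in r.courses})
    for key in conditions:
        mat = _course_matrix(results, key)
        mean_courses[key] = np.nanmean(mat, axis=0)
        if cluster_tests:
            cluster[f"towardness[{key[0]},{key[1]}]"] = permutation_test(
                mat, n_permutations=n_perm, alpha=config.alpha,
                seed=config.rng_seed, time=time)
    if cluster_tests:
        for s in scaffolds:
            far = _course_matrix(results, (s, "far"))
            near = _course_matrix(results, (s, "near"))
            if far.shape == near.shape:
                cluster[f"far_vs_near[{s}]"] = permutation_test(
                    far, near, n_permutations=n_perm, alpha=config.alpha,
                    seed=config.rng_seed, time=time)

    interaction = interaction_index_table(bias_df) if two_by_two else pd.DataFrame()
    correlation = None
    if two_by_two and len(interaction) >= 3:
        acc = pd.DataFrame([{"participant": r.participant, **r.accuracy}
                            for r in results]).set_index("participant")
        acc_diff = (acc["direction_sufficient"]
                    - acc["direction_insufficient"])
        merged = interaction.set_index("participant").join(acc_diff.rename("acc_diff"))
        if merged["acc_diff"].std() > 0 and merged["interaction_index"].std() > 0:
            correlation = accuracy_correlation(
                merged["interaction_index"].to_numpy(),
                merged["acc_diff"].to_numpy())

    sd_curves: Dict[str, SizeDensityCurve] = {}
    if saccade_analysis:
        for key in conditions:
            events, n_trials = [], 0
            for r in results:
                keys_tr = r.epochs.trials[["scaffold", "cued_distance"]].apply(tuple, axis=1)
                rows = (keys_tr == key).to_numpy() & r.epochs.included
                ids = set(r.epochs.trials.loc[rows, "trial_id"])
                events.extend(ev for ev in r.saccade_events if ev.trial_id in ids)
                n_trials += int(rows.sum())
            if n_trials:
                sd_curves[f"{key[0]},{key[1]}"] = size_density(
                    events, n_trials, window=config.saccade_window,
                    condition=f"{key[0]},{key[1]}")

    return StudyResult(bias=bias_df, anova=anova, posthoc=posthoc, bayes=bayes,
                       cluster=cluster, interaction=interaction,
                       correlation=correlation, usable_fraction=usable,
                       course_time=time, mean_courses=mean_courses,
                       size_density=sd_curves)
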