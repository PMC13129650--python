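"""Group-level reproduction runner for externally deposited recordings.

The raw study data live in a public archive; once exported to this
package's tabular formats (one gaze samples table and one trial table per
participant) this runner reproduces the group numbers — window biases,
interaction F and partial η², post hoc t / Cohen's d, Bayes factors,
cluster p values and usable-trial rates — with the same pipeline the
synthetic studies use.

Expected layout::

    data_dir/
      sub-01_gaze.tsv   # samples_table dialect ("# units: deg" or px + screen.yaml)
      sub-01_trials.tsv
      sub-02_gaze.tsv
      ...

"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

from .config import AnalysisConfig
from .io import ScreenGeometry, read_gaze, read_trials
from .pipeline import StudyResult, run_study


def discover_participants(data_dir) -> list:
    """Pair ``*_gaze.tsv`` with ``*_trials.tsv`` files by shared prefix."""
    data_dir = Path(data_dir)
    pairs = []
    for gaze_path in sorted(data_dir.glob("*_gaze.tsv")):
        trial_path = gaze_path.with_name(gaze_path.name.replace("_gaze", "_trials"))
        if not trial_path.exists():
            raise FileNotFoundError(f"no trial table for {gaze_path.name}")
        pairs.append((gaze_path, trial_path))
    if not pairs:
        raise FileNotFoundError(f"no *_gaze.tsv files under {data_dir}")
    return pairs


def reproduce_group_stats(data_dir, config: Optional[AnalysisConfig] = None,
                          screen: Optional[ScreenGeometry] = None,
                          **run_kwargs) -> StudyResult:
    """Run the full group analysis on a directory of exported recordings."""
    config = config or AnalysisConfig()
    participants = []
    for gaze_path, trial_path in discover_participants(data_dir):
        rec = read_gaze(gaze_path, screen=screen)
        trials = read_trials(trial_path)
        participants.append((rec, trials))
    return run_study(participants, config, **run_kwargs)
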