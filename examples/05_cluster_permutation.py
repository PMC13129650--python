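"""Cluster-based permutation test on group towardness time courses.

Pointwise one-sample t values are thresholded at two-sided alpha = 0.05;
contiguous same-sign runs form clusters whose mass is the summed t.  The
null distribution of the largest cluster mass comes from sign-flipping
each participant's course; a cluster's p is the fraction of permutations
whose maximum reaches its mass.
"""

import numpy as np

from gazescaffold import (AnalysisConfig, GeneratorConfig, generate_dataset,
                         permutation_test, process_participant)

cfg = (GeneratorConfig(n_participants=12, seed=19)
       .scaled_down(160).with_segment(1600.0, 400.0))
analysis = AnalysisConfig(epoch_window=(-300, 1100))
data = generate_dataset(cfg)

courses = []
for pdat in data:
    res = process_participant(pdat.recording, pdat.trials, analysis,
                              participant=pdat.participant)
    courses.append(res.courses[("direction_insufficient", "far")].towardness)
courses = np.stack(courses)
time = np.arange(-300, 1100, dtype=float)

result = permutation_test(courses, n_permutations=2000, seed=0, time=time)
print(f"{len(result.clusters)} cluster(s) at alpha = {result.alpha}:")
for c in result.clusters:
    tag = "significant" if c.p < 0.05 else "n.s."
    print(f"  {c.start:6.0f}..{c.end:6.0f} ms  mass {c.mass:8.1f}  "
          f"p = {c.p:.4f}  ({tag})")
print("\nA positive significant cluster after cue onset is the gaze bias "
      "toward the cued far item; its p is family-wise corrected over time "
      "by construction.")
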