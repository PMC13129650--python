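"""2-D gaze density: the bias is fixational, not item-directed looking.

Gaze samples from 400-1000 ms post-cue are binned in overlapping
0.1 x 0.1 deg squares on a 0.05 deg lattice over +/-6 deg, normalised by
the total sample count, and smoothed with a 0.25 deg Gaussian.  The
left-minus-right cue difference map shows a dipole within ~1 deg of
fixation, far from the 3/6 deg item positions.
"""

import numpy as np

from gazescaffold import (AnalysisConfig, GeneratorConfig, generate_dataset,
                         opposing_cue_difference, preprocess)
from gazescaffold.density import mass_within

cfg = GeneratorConfig(n_participants=1, n_trials=320, trial_len_ms=1600.0,
                      pre_cue_ms=400.0, seed=11)
pdat = generate_dataset(cfg)[0]
analysis = AnalysisConfig(epoch_window=(-300, 1100))
ep, _ = preprocess(pdat.recording, pdat.trials, analysis)

diff = opposing_cue_difference(ep, axis="horizontal", window=(400, 1000))
gx = diff.grid_x[None, :] * np.ones_like(diff.density)
dipole = float((diff.density * np.sign(gx)).sum())
peak = diff.grid_x[np.unravel_index(np.abs(diff.density).argmax(),
                                    diff.density.shape)[1]]

print(f"difference map built from {diff.n_samples} gaze samples")
print(f"signed mass on the left-cue side minus right-cue side: {dipole:+.4f}")
print(f"|density| peak at x = {peak:+.2f} deg "
      "(sub-degree: a fixational bias, not a 3 or 6 deg look-back)")
print(f"fraction of |mass| within 1 deg of fixation: {mass_within(diff, 1.0):.1%}")
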