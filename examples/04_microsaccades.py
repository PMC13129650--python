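"""Microsaccade detection and toward-saccade size densities.

Saccades are detected where gaze speed exceeds 5x the trial's median
speed; "toward" saccades move away from fixation in the cued item's
direction.  Their rate per trial as a function of amplitude (0-2 deg,
sliding window 0.5 deg wide in 0.05 deg steps) is the size-density curve,
computed in the 200-600 ms post-cue window.
"""

import numpy as np

from gazescaffold import (AnalysisConfig, GeneratorConfig, generate_dataset,
                         preprocess, size_density)
from gazescaffold.saccades import detect_epoch_saccades

cfg = GeneratorConfig(n_participants=1, n_trials=320, trial_len_ms=1600.0,
                      pre_cue_ms=400.0, seed=13)
pdat = generate_dataset(cfg)[0]
analysis = AnalysisConfig(epoch_window=(-300, 1100))
ep, _ = preprocess(pdat.recording, pdat.trials, analysis)

events = detect_epoch_saccades(ep, analysis)
toward = [e for e in events if e.is_toward]
print(f"detected saccades: {len(events)}; toward the cued item: {len(toward)}")
amps = np.array([e.amplitude for e in toward])
if len(amps):
    print(f"toward-saccade amplitudes: median {np.median(amps):.2f} deg, "
          f"max {amps.max():.2f} deg (all < 2 deg: fixational)")

curve = size_density(events, n_trials=int(ep.included.sum()),
                     window=analysis.saccade_window)
peak_i = int(curve.density.argmax())
print(f"size density peaks at {curve.size_centers[peak_i]:.2f} deg with "
      f"{curve.density[peak_i]:.3f} toward saccades per trial per 0.5 deg window")
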