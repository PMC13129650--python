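# Methods

This note documents the models, estimators, parameters and numerical choices
behind `gazescaffold`, and what its synthetic studies do and do not show
about real eye-tracking data.

## Coordinate and time conventions

Analysis space is degrees of visual angle relative to the fixation point,
+x rightward and +y **upward**; screen-native y-down pixel data are flipped
at read time so "toward the top item" is always positive. Pixel data are
converted per axis with an arctangent using the monitor geometry and viewing
distance (default 65 cm); a small-angle linear conversion would already be
~0.4% off at 6°, so it is not used. All time windows are half-open
`[start, end)` milliseconds, which makes sample counts unambiguous at
1,000 Hz (the 400–1,000 ms bias window contains exactly 600 samples).

## Preprocessing

Blink seeds are samples flagged invalid by the source, or whose pupil signal
is missing/non-positive (the EyeLink convention). Seeds are dilated by
100 ms on each side and set to NaN; overlapping dilations merge, and the
operation is idempotent (a masked recording passes through unchanged).
Epochs span −1,000..+2,000 ms around the retro-cue; baseline correction
subtracts each trial's per-channel mean over −200..0 ms, ignoring missing
samples; trials whose baseline is fully missing are excluded. The
fixational-selection rule excludes trials whose gaze exceeds 2° from
fixation anywhere in 0–1,000 ms post-cue. The distance metric is Euclidean
√(x²+y²) by default; because the published rule ("gaze values larger than 2°
away from fixation") could also be read per axis, `exclusion_metric =
"per_axis"` provides max(|x|,|y|) behind the config. Missing samples never
trigger exclusion — an unknown position cannot exceed a threshold.

## Towardness

For each included trial the cued axis is read out (x for left/right cues,
y for top/bottom) and signed so that positive means gaze moved toward the
cued item (+1 for right/top, −1 for left/bottom). Conditions pool horizontal
and vertical trials by per-trial averaging (each trial weighs equally);
a per-axis-first pooling is available via `axis_pooling="per_axis"` for
designs with unbalanced axes. The scalar bias is the missing-aware mean of
the condition-average course over 400–1,000 ms. The per-participant
interaction index is (far − near) bias in the direction-insufficient
condition minus the same contrast in the direction-sufficient condition;
positive values mean distance mattered more when it was a useful scaffold.

## Gaze-density maps

Samples from 400–1,000 ms are collated across trials and time without
averaging; deviant trials are deliberately **not** excluded here, so the
maps show the full gaze distribution. Counting uses 0.1°-wide squares
centred on a −6..6° lattice in 0.05° steps — an overlapping binning
implemented as 2×2 sums over a fine 0.05° lattice, exactly equivalent to
per-sample point-in-square tests but O(n + grid). Densities are counts over
the total number of finite samples; samples beyond ±6° enter the normaliser
but no cell. Smoothing is a Gaussian with SD 0.25° per axis, truncated at
4 SD with zero padding; a `smoothed` flag forbids double smoothing.
Difference maps subtract opposite-direction cue conditions (left − right,
top − bottom) on identical grids.

## Microsaccades

Velocity is the 3-point central difference scaled to deg/s (a 5-sample
Engbert-style estimator is available via `velocity_estimator="engbert"`);
speed is the Euclidean norm. A trial's threshold is 5 × the median speed
over its valid samples. Suprathreshold runs closer than 20 ms merge, runs
shorter than 6 ms are dropped — both unreported in the source protocol and
chosen to suppress single-sample noise crossings; both are configurable.
Displacement is measured from the last sample before onset to the first
after offset so a step's full amplitude is recovered. A saccade is "toward"
when it moves gaze radially away from fixation **and** its displacement on
the cued axis has the cued item's sign; an angular-cone criterion (default
±45°) is available because the exact published criterion is not stated.
Size densities count toward saccades with onset in 200–600 ms whose
amplitude falls within a 0.5°-wide window slid in 0.05° steps over 0–2°,
normalised per trial.

## Cluster-based permutation test

Pointwise one-sample t values (participants × time; paired designs reduce
to differences) are thresholded at the two-sided critical t for alpha =
0.05; maximal same-sign runs form clusters with mass = Σt. The null
distribution sign-flips each participant's course (algebraically identical
to condition-label swaps for two conditions) 10,000 times by default and
records the largest absolute cluster mass. A cluster's p is the fraction of
permutations reaching its |mass| with the ≥ convention, floored at
1/n_permutations — the conservative choice since the tie-handling of the
original is unreported. Time points with fewer than two contributing
participants get t = 0 and can never be suprathreshold; zero-variance
points with nonzero mean count as suprathreshold with their sign. Because
sign flips leave per-participant squares unchanged, all permuted t courses
are computed from the flipped means alone — one matrix product per test.

## Condition-level statistics

The 2 × 2 repeated-measures ANOVA uses the classic within-subject
sum-of-squares decomposition with subject-by-effect error terms; every
effect has a single df, so each F equals the squared paired t of its
contrast (verified to 1e-10 in tests) and partial η² = F/(F + n − 1).
Sphericity is moot in a 2 × 2. Post hoc paired t tests report Cohen's
d = mean(Δ)/SD(Δ) and Bonferroni correction with family size = the number
of comparisons actually run (default 2: far vs near within each scaffold
condition). Effect/error sums of squares below 1e-12 of the total are
treated as exact zeros so degenerate inputs (identical conditions) return
F = 0 rather than 0/0 noise.

The JZS Bayes factor for a paired/one-sample t uses the Cauchy
effect-size prior with scale r = 0.707, computed as the g-integral with an
inverse-χ²(1) prior by adaptive quadrature (relative error < 1e-6; an
error estimate above that raises). At the published statistics it gives
BF01(t = −0.401, n = 25) = 4.407 and BF01(t = −0.55, n = 25) = 4.131.
The correlation Bayes factor uses pingouin's Jeffreys-prior Pearson BF
(stretched beta width 1, the common software default); different default
implementations of this quantity can differ by ~5%, which is within the
interpretation band used here.

## Synthetic generator

Each participant is a continuous 1,000 Hz recording of consecutive trial
segments (default 3,500 ms, cue at 1,200 ms). Its components:

- **Fixational drift**: an exact AR(1) discretisation of an
  Ornstein–Uhlenbeck process (stationary SD 0.25°, time constant 100 ms),
  low-passed with a 50 ms moving average. The smoothing keeps median
  sample-to-sample speed at the few-deg/s scale of real drift; raw 1 kHz
  AR(1) increments would exceed real microsaccade velocities and make the
  5×-median threshold useless.
- **Towardness ramp**: on each trial's cued axis, amplitude × a logistic
  ramp rising from 250 ms to a plateau by 400 ms after the cue (the
  single-trial dynamics are not observable in group data; the ramp shape is
  a convention and configurable). Default cell amplitudes are the published
  group means: 0.065/0.125° (insufficient near/far) and 0.093/0.097°
  (sufficient near/far).
- **Microsaccades**: Poisson (0.8 Hz), lognormal amplitudes (median 0.3°,
  σ = 0.7) capped at 2°, raised-cosine rise over 15 ms followed by an
  exponential drift back (τ = 200 ms). After the cue a fraction (0.3) aims
  at the cued item (±15° jitter). Because toward-biased saccades add a
  deterministic mean displacement, that analytic mean is subtracted from
  the additive course, so the configured amplitude is exactly the expected
  towardness plateau — the generator's ground truth for recovery tests.
- **Blinks**: Poisson (0.15 Hz), 100–300 ms, pupil 0 and gaze missing.
- **Accuracy**: Bernoulli per scaffold condition (0.74/0.77 for the
  two-condition design; 0.79/0.82 for the distance-matched variant).

**Effect-size calibration.** Across participants, each condition cell's
amplitude receives a far−near trait shared across scaffold conditions
(SD 0.085°) plus condition-specific jitter (SD 0.05°). These two SDs were
fixed once so that, at the full 800-trial design with the OU defaults, the
far-vs-near contrast in the direction-insufficient condition has Cohen's
d ≈ 0.57 and the 2 × 2 interaction is detected in ≈ 90% of replications at
n = 25 — the generator's definition of a "paper-like" effect. Purely
trial-level noise cannot produce this pattern: it would make the
interaction contrast √2 noisier than the simple contrast and drop its
power below 50%, so the participant-level trait structure is essential.

**Scaled runs.** `GeneratorConfig.scaled_down(n_trials)` shrinks the OU SD
and the saccade amplitude scale by √(n_trials/full) so the per-participant
bias-estimate noise — hence every Cohen's d — matches the full-size design;
`with_segment()` shortens trial segments when only the −200..+1,050 ms
analysis range is needed. Tests and the acceptance script use 96–320 trials
per participant and 1,000–2,000 permutations; these sizes are the package's
simulation-design choice and preserve the calibrated operating point.
Scaled configs are not meant for saccade-size analyses, whose amplitude
scale they deliberately alter.

**What the generator does not emulate**: main-sequence velocity–amplitude
coupling, binocular disconjugacy, pupil foreshortening artifacts, drift
toward targets during the inter-trial interval, response-time structure,
and any dependence of microsaccade *size* on condition. Passing tests
therefore validate the estimators and their error control under a
realistic stochastic model, not tracker-specific artifacts of real
recordings; real-data conclusions additionally require the reproduce
runner on exported recordings.

## Known limitations

- The ASC reader covers a minimal subset (sample, EBLINK, MSG lines);
  full EyeLink event parsing is out of scope.
- No interpolation across blinks; masked samples stay missing everywhere
  downstream.
- The cluster test assumes exchangeability across participants under the
  null; its family-wise error is verified by simulation at n = 25
  (within the 95% binomial interval of alpha over 200 null studies).
- BF01 values for correlations depend on the prior implementation of the
  library used; only the paired-t JZS factor is computed in-package to
  quadrature accuracy.
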