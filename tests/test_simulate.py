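"""Synthetic generator: determinism, designs, injected-structure recovery."""

import numpy as np
import pytest

from gazescaffold import (AnalysisConfig, GeneratorConfig, expected_cell_bias,
                          generate_dataset, generate_null, mask_blinks,
                          null_towardness_courses, process_participant)
from gazescaffold.simulate import DESIGNS, _ou_trace, generate_participant


def small_cfg(**kw):
    base = dict(design="exp2", n_participants=1, n_trials=32,
                trial_len_ms=1600.0, pre_cue_ms=400.0, seed=0)
    base.update(kw)
    return GeneratorConfig(**base)


SHORT_ANALYSIS = AnalysisConfig(epoch_window=(-300, 1100))


def test_design_trial_counts_and_balance():
    for name, spec in DESIGNS.items():
        cfg = GeneratorConfig(design=name, n_participants=1, seed=1,
                              trial_len_ms=1600.0, pre_cue_ms=400.0)
        assert cfg.n_trials == spec["n_trials"]
        pdat = generate_participant(cfg, 0, np.random.default_rng(0))
        counts = pdat.trials.groupby(
            ["scaffold", "cued_distance", "cued_direction"]).size()
        assert counts.nunique() == 1  # equal trials per cell
    with pytest.raises(ValueError, match="divisible"):
        GeneratorConfig(design="exp2", n_trials=33)


def test_exp1_is_horizontal_insufficient_only():
    cfg = GeneratorConfig(design="exp1", n_participants=1, n_trials=64,
                          trial_len_ms=1600.0, pre_cue_ms=400.0, seed=2)
    pdat = generate_participant(cfg, 0, np.random.default_rng(2))
    assert set(pdat.trials["scaffold"]) == {"direction_insufficient"}
    assert set(pdat.trials["config_axis"]) == {"horizontal"}


def test_seed_determinism_byte_identical():
    a = generate_dataset(small_cfg(seed=7))[0]
    b = generate_dataset(small_cfg(seed=7))[0]
    np.testing.assert_array_equal(a.recording.x, b.recording.x)
    np.testing.assert_array_equal(a.recording.valid, b.recording.valid)
    assert a.trials.equals(b.trials)
    c = generate_dataset(small_cfg(seed=8))[0]
    assert not np.array_equal(a.recording.x, c.recording.x, equal_nan=True)


def test_ou_noise_sd_within_five_percent():
    rng = np.random.default_rng(0)
    x = _ou_trace(200_000, sd=0.25, tau=100.0, dt=1.0, rng=rng)
    assert np.std(x) == pytest.approx(0.25, rel=0.05)


def test_injected_blink_spans_recovered_by_masking():
    cfg = small_cfg(seed=3, blink_rate=0.5, saccade_rate=0.0,
                    bias_amplitude={k: 0.0 for k in expected_cell_bias(small_cfg())})
    pdat = generate_dataset(cfg)[0]
    rec = mask_blinks(pdat.recording, pad=100)
    injected = np.zeros(len(rec), bool)
    for lo, hi in pdat.truth["blink_spans"]:
        injected[int(lo):int(hi) + 1] = True
    # dilate injected spans by the pad: that must equal the masked set
    pad = 100
    expected = np.zeros_like(injected)
    for i in np.flatnonzero(injected):
        expected[max(i - pad, 0):i + pad + 1] = True
    np.testing.assert_array_equal(~rec.valid, expected)


def test_null_dataset_towardness_consistent_with_zero():
    cfg = small_cfg(seed=11, n_participants=6, n_trials=96)
    biases = []
    for pdat in generate_null(cfg):
        res = process_participant(pdat.recording, pdat.trials, SHORT_ANALYSIS,
                                  participant=pdat.participant)
        from gazescaffold import window_bias
        for c in res.courses.values():
            biases.append(window_bias(c, SHORT_ANALYSIS.bias_window))
    biases = np.asarray(biases)
    t = biases.mean() / (biases.std(ddof=1) / np.sqrt(len(biases)))
    assert abs(t) < 3.5  # no systematic bias


def test_recovered_bias_tracks_injected_amplitude():
    """Mean recovered bias doubles (within noise) when amplitudes double."""
    recovered = []
    for scale in (1.0, 2.0):
        amps = {k: scale * v for k, v in
                GeneratorConfig(design="exp2").bias_amplitude.items()}
        cfg = small_cfg(seed=21, n_participants=4, n_trials=160,
                        bias_amplitude=amps, participant_distance_sd=0.0,
                        participant_condition_sd=0.0, toward_prob=0.0,
                        ou_sd=0.05)
        vals = []
        from gazescaffold import window_bias
        for pdat in generate_dataset(cfg):
            res = process_participant(pdat.recording, pdat.trials, SHORT_ANALYSIS,
                                      participant=pdat.participant)
            vals.append(np.mean([window_bias(c, SHORT_ANALYSIS.bias_window)
                                 for c in res.courses.values()]))
        recovered.append(np.mean(vals))
    mean_amp = np.mean(list(GeneratorConfig(design="exp2").bias_amplitude.values()))
    assert recovered[0] == pytest.approx(mean_amp, abs=0.01)
    assert recovered[1] / recovered[0] == pytest.approx(2.0, abs=0.15)


def test_monotone_bias_across_amplitude_grid():
    from gazescaffold import window_bias
    means = []
    for amp in (0.0, 0.05, 0.1, 0.2, 0.4):
        cfg = small_cfg(seed=31, n_trials=64,
                        bias_amplitude={k: amp for k in
                                        GeneratorConfig(design="exp2").bias_amplitude},
                        participant_distance_sd=0.0, participant_condition_sd=0.0,
                        toward_prob=0.0, ou_sd=0.05)
        pdat = generate_dataset(cfg)[0]
        res = process_participant(pdat.recording, pdat.trials, SHORT_ANALYSIS)
        means.append(np.mean([window_bias(c, SHORT_ANALYSIS.bias_window)
                              for c in res.courses.values()]))
    assert all(a < b for a, b in zip(means, means[1:]))


def test_generator_saccade_sizes_recovered():
    """Injected saccades above the detection floor are found with their
    amplitudes; the velocity-threshold detector recovers the generator's
    ground truth on low-drift recordings."""
    from gazescaffold import detect_saccades
    cfg = small_cfg(seed=51, n_trials=96, saccade_rate=1.5, toward_prob=0.0,
                    ou_sd=0.02, blink_rate=0.0,
                    bias_amplitude={k: 0.0 for k in
                                    GeneratorConfig(design="exp2").bias_amplitude})
    pdat = generate_dataset(cfg)[0]
    rec = pdat.recording
    events = detect_saccades(rec.x, rec.y, rec.time)
    truth = pdat.truth["saccades"]
    big = truth[truth["amplitude"] >= 0.3]
    errs, hits = [], 0
    onsets = np.array([e.onset for e in events])
    amps = np.array([e.amplitude for e in events])
    for t0, amp in zip(big["time_ms"], big["amplitude"]):
        near = np.abs(onsets - t0) <= 15
        if near.any():
            hits += 1
            errs.append(abs(amps[near][0] - amp))
    assert hits / len(big) >= 0.9
    assert np.median(errs) <= 0.05


def test_expected_cell_bias_plateau():
    cfg = small_cfg()
    exp = expected_cell_bias(cfg)
    for cell, amp in cfg.bias_amplitude.items():
        # ramp is at plateau over 400-1000 ms, so expectation ~ amplitude
        assert exp[cell] == pytest.approx(amp, rel=0.02)


def test_accuracy_rates_match_config():
    cfg = small_cfg(seed=41, n_trials=800, trial_len_ms=1600.0)
    pdat = generate_dataset(cfg)[0]
    acc = pdat.trials.groupby("scaffold")["correct"].mean()
    assert acc["direction_insufficient"] == pytest.approx(0.74, abs=0.06)
    assert acc["direction_sufficient"] == pytest.approx(0.77, abs=0.06)


def test_null_towardness_courses_shape_and_scale():
    rng = np.random.default_rng(0)
    courses = null_towardness_courses(25, 500, n_trials=200, ou_sd=0.25,
                                      rng=rng)
    assert courses.shape == (25, 500)
    assert np.std(courses) == pytest.approx(0.25 / np.sqrt(200), rel=0.15)
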