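"""Blink masking, epoching, baseline correction and the 2° exclusion rule."""

import numpy as np
import pandas as pd
import pytest

from gazescaffold import baseline_correct, epoch, exclude_deviant_trials, mask_blinks


from conftest import make_epochs, make_recording


def recording_with_blink(spans, n=5000):
    pupil = np.full(n, 1000.0)
    for lo, hi in spans:
        pupil[lo:hi + 1] = 0.0
    return make_recording(np.zeros(n), np.zeros(n), pupil=pupil)


def brute_force_pad(seeds: np.ndarray, pad: int) -> np.ndarray:
    """Per-sample dilation oracle for blink padding."""
    bad = np.zeros_like(seeds)
    for i in np.flatnonzero(seeds):
        bad[max(i - pad, 0): i + pad + 1] = True
    return bad


def test_blink_padding_exact_span():
    rec = recording_with_blink([(1000, 1200)])
    out = mask_blinks(rec, pad=100)
    invalid = ~out.valid
    assert invalid[900:1301].all()
    assert not invalid[:900].any() and not invalid[1301:].any()
    assert np.isnan(out.x[900:1301]).all()


def test_no_blinks_identity():
    rec = recording_with_blink([])
    out = mask_blinks(rec, pad=100)
    np.testing.assert_array_equal(out.valid, rec.valid)
    np.testing.assert_array_equal(out.x, rec.x)


@pytest.mark.parametrize("spans", [
    [(1000, 1100), (1150, 1250)],           # 50 ms apart -> merged
    [(100, 150), (600, 610), (620, 700)],
    [(0, 50), (4950, 4999)],                # clipped at the edges
])
def test_padding_matches_bruteforce_oracle(spans):
    rec = recording_with_blink(spans)
    out = mask_blinks(rec, pad=100)
    expected = brute_force_pad(~rec.valid | (rec.pupil <= 0), 100)
    np.testing.assert_array_equal(~out.valid, expected)
    if len(spans) == 2 and spans[0][1] + 2 * 100 >= spans[1][0]:
        # two blinks closer than twice the pad form one merged invalid run
        d = np.diff(np.concatenate(([0], (~out.valid).astype(int), [0])))
        assert (d == 1).sum() == 1


def test_mask_blinks_idempotent():
    rec = recording_with_blink([(2000, 2150)])
    once = mask_blinks(rec, pad=100)
    twice = mask_blinks(once, pad=100)
    np.testing.assert_array_equal(once.valid, twice.valid)


def test_mask_blinks_all_invalid_errors():
    rec = recording_with_blink([(0, 4999)])
    with pytest.raises(ValueError, match="zero valid"):
        mask_blinks(rec, pad=100)


def _one_trial(cue_onset):
    return pd.DataFrame({"trial_id": [0], "cue_onset_ms": [cue_onset],
                         "cued_direction": ["right"], "cued_distance": ["near"],
                         "scaffold": ["direction_insufficient"],
                         "config_axis": ["horizontal"], "correct": [True]})


def test_epoch_half_open_slicing():
    n = 10_000
    rec = make_recording(np.arange(n) * 1e-4, np.zeros(n))
    ep = epoch(rec, _one_trial(5000.0), window=(-1000, 2000))
    assert ep.x.shape == (1, 3000)
    assert ep.time[0] == -1000 and ep.time[-1] == 1999
    # covers recording samples 4000..6999
    np.testing.assert_allclose(ep.x[0, 0], 0.4)
    np.testing.assert_allclose(ep.x[0, -1], 0.6999)


def test_epoch_constant_trace():
    n = 8000
    rec = make_recording(np.full(n, 0.3), np.zeros(n))
    ep = epoch(rec, _one_trial(4000.0), window=(-1000, 2000))
    assert (ep.x == 0.3).all()


def test_epoch_out_of_bounds_names_trial():
    rec = make_recording(np.zeros(3000), np.zeros(3000))
    with pytest.raises(ValueError, match="trial 0"):
        epoch(rec, _one_trial(500.0), window=(-1000, 2000))


def test_baseline_constant_goes_to_zero():
    ep = make_epochs(np.full((1, 1000), 1.5), np.zeros((1, 1000)),
                     time=np.arange(-500, 500), baseline_applied=False)
    out = baseline_correct(ep, window=(-200, 0))
    np.testing.assert_allclose(out.x, 0.0, atol=1e-12)
    assert out.baseline_applied


def test_baseline_ramp_shifted_by_window_mean():
    time = np.arange(-500, 500, dtype=float)
    ramp = 0.001 * (time + 300)  # independent recomputation of the mean below
    expected_mean = np.mean(ramp[(time >= -200) & (time < 0)])
    ep = make_epochs(ramp[None, :], np.zeros((1, 1000)), time=time,
                     baseline_applied=False)
    out = baseline_correct(ep, window=(-200, 0))
    np.testing.assert_allclose(out.x[0], ramp - expected_mean, atol=1e-12)
    sl = out.window_slice((-200, 0))
    assert abs(np.nanmean(out.x[0, sl])) < 1e-12


def test_baseline_all_missing_trial_excluded(caplog):
    x = np.ones((2, 1000))
    x[1, :300] = np.nan  # baseline −200..0 fully missing for trial 1
    ep = make_epochs(x, np.zeros((2, 1000)), time=np.arange(-300, 700, dtype=float),
                     baseline_applied=False)
    with caplog.at_level("WARNING", logger="gazescaffold"):
        out = baseline_correct(ep, window=(-200, 0))
    assert "missing baseline" in caplog.text
    assert out.included.tolist() == [True, False]


def test_baseline_idempotent():
    rng = np.random.default_rng(0)
    ep = make_epochs(rng.normal(size=(3, 1000)), rng.normal(size=(3, 1000)),
                     time=np.arange(-500, 500, dtype=float), baseline_applied=False)
    once = baseline_correct(ep, window=(-200, 0))
    twice = baseline_correct(once, window=(-200, 0))
    np.testing.assert_allclose(once.x, twice.x, atol=1e-12)


def _epochs_with_peaks(peaks):
    """One trial per (value, t_ms) peak on x, time −1000..1999."""
    time = np.arange(-1000, 2000, dtype=float)
    x = np.zeros((len(peaks), len(time)))
    y = np.zeros_like(x)
    for i, (val, t) in enumerate(peaks):
        x[i, int(t + 1000)] = val
    return make_epochs(x, y, time=time)


def test_exclusion_threshold_and_window():
    ep = _epochs_with_peaks([(2.5, 300), (2.5, 1500), (1.9, 300)])
    out, report = exclude_deviant_trials(ep, radius=2.0, window=(0, 1000))
    assert out.included.tolist() == [False, True, True]
    assert report.n_excluded == 1
    assert report.usable_fraction == pytest.approx(2 / 3)


def test_exclusion_euclidean_distance():
    time = np.arange(-1000, 2000, dtype=float)
    x = np.zeros((1, len(time)))
    y = np.zeros_like(x)
    x[0, 1500] = 1.5
    y[0, 1500] = 1.5  # sqrt(1.5^2+1.5^2) ~ 2.12 > 2
    assert np.hypot(1.5, 1.5) > 2.0
    ep = make_epochs(x, y, time=time)
    out, _ = exclude_deviant_trials(ep, radius=2.0, window=(0, 1000))
    assert not out.included[0]
    # per-axis alternative keeps it (max |axis| = 1.5)
    out2, _ = exclude_deviant_trials(ep, radius=2.0, window=(0, 1000),
                                     metric="per_axis")
    assert out2.included[0]


def test_exclusion_missing_samples_never_count():
    time = np.arange(-1000, 2000, dtype=float)
    x = np.full((1, len(time)), np.nan)
    x[0, :100] = 0.0
    ep = make_epochs(x, np.zeros_like(x), time=time)
    out, _ = exclude_deviant_trials(ep, radius=2.0, window=(0, 1000))
    assert out.included[0]


def test_exclusion_monotone_in_radius():
    rng = np.random.default_rng(42)
    time = np.arange(-1000, 2000, dtype=float)
    x = rng.normal(0, 1.2, size=(40, len(time)))
    y = rng.normal(0, 1.2, size=(40, len(time)))
    ep = make_epochs(x, y, time=time)
    prev_excluded = None
    for radius in (1.0, 1.5, 2.0, 3.0, 4.0):
        out, _ = exclude_deviant_trials(ep, radius=radius, window=(0, 1000))
        excluded = set(np.flatnonzero(~out.included))
        if prev_excluded is not None:
            assert excluded <= prev_excluded
        prev_excluded = excluded


def test_exclusion_requires_baseline():
    ep = _epochs_with_peaks([(0.5, 100)])
    ep.baseline_applied = False
    with pytest.raises(ValueError, match="baseline"):
        exclude_deviant_trials(ep, 2.0, (0, 1000))
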