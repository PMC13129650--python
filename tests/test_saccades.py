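"""Velocity estimation, saccade detection, toward classification, densities."""

import numpy as np
import pytest

from gazescaffold import classify_toward, detect_saccades, gaze_velocity, size_density
from gazescaffold.saccades import SaccadeEvent


def step_trace(n=2000, t0=500, amp=0.5, rise=20):
    """Noise-free trace with one linear-ramp step on x."""
    x = np.zeros(n)
    x[t0:t0 + rise] = amp * np.arange(1, rise + 1) / rise
    x[t0 + rise:] = amp
    return x, np.zeros(n)


def test_velocity_linear_ramp():
    t = np.arange(3000, dtype=float)
    x = 0.001 * t  # 1 deg/s
    v = gaze_velocity(x, np.zeros_like(x))
    np.testing.assert_allclose(v[1:-1], 1.0, atol=1e-9)
    assert np.isnan(v[0]) and np.isnan(v[-1])


def test_velocity_constant_zero():
    v = gaze_velocity(np.full(100, 0.7), np.full(100, -0.2))
    np.testing.assert_allclose(v[1:-1], 0.0, atol=1e-12)


def test_velocity_circular_speed():
    # radius r at angular rate w -> speed r*w (closed form)
    r, f = 0.5, 2.0  # Hz
    t = np.arange(5000) / 1000.0
    w = 2 * np.pi * f
    v = gaze_velocity(r * np.cos(w * t), r * np.sin(w * t))
    np.testing.assert_allclose(v[1:-1], r * w, rtol=1e-4)


def test_detect_single_step():
    x, y = step_trace(amp=0.5)
    ev = detect_saccades(x, y, np.arange(len(x), dtype=float))
    assert len(ev) == 1
    assert ev[0].amplitude == pytest.approx(0.5, abs=0.05)
    assert 490 <= ev[0].onset <= 510


def test_constant_velocity_no_events():
    t = np.arange(2000, dtype=float)
    x = 0.0005 * t  # median speed = 0.5 deg/s, never above 5x median
    assert detect_saccades(x, np.zeros_like(x), t) == []


def test_two_injected_saccades():
    x1, _ = step_trace(n=2000, t0=500, amp=0.4)
    x2, _ = step_trace(n=2000, t0=800, amp=0.7)
    x = x1 + x2
    ev = detect_saccades(x, np.zeros(2000), np.arange(2000, dtype=float))
    assert len(ev) == 2
    assert ev[0].onset < ev[1].onset
    assert ev[0].amplitude == pytest.approx(0.4, abs=0.05)
    assert ev[1].amplitude == pytest.approx(0.7, abs=0.05)


def test_merge_gap_and_min_duration():
    x1, _ = step_trace(n=2000, t0=500, amp=0.4, rise=20)
    x2, _ = step_trace(n=2000, t0=530, amp=0.4, rise=20)
    ev = detect_saccades(x1 + x2, np.zeros(2000), np.arange(2000, dtype=float),
                         merge_gap=20)
    assert len(ev) == 1  # 10 ms gap between runs -> merged
    # single-sample glitch shorter than min duration is dropped
    g = np.zeros(2000)
    g[1000] = 0.3
    g += np.random.default_rng(0).normal(0, 1e-4, 2000)
    ev2 = detect_saccades(g, np.zeros(2000), np.arange(2000, dtype=float),
                          min_duration=6)
    assert ev2 == []


def test_threshold_monotone_in_k():
    # deterministic slow drift (median speed 0.5 deg/s) + steps of graded size
    t = np.arange(5000, dtype=float)
    x = 0.0005 * t
    for t0, amp in ((1000, 0.08), (2500, 0.3), (4000, 1.5)):
        s, _ = step_trace(n=5000, t0=t0, amp=amp)
        x = x + s
    prev = None
    for k in (3, 5, 8, 12):
        ev = detect_saccades(x, np.zeros(5000), t, k=k)
        onsets = {round(e.onset / 5) for e in ev}  # 5 ms tolerance on edges
        if prev is not None:
            assert onsets <= prev
        prev = onsets
    assert len(prev) < 3  # the smallest step drops out at high k


def test_detection_invariant_to_offset_and_reflection():
    x, y = step_trace(amp=0.6)
    t = np.arange(len(x), dtype=float)
    base = detect_saccades(x, y, t)
    shifted = detect_saccades(x + 3.0, y - 1.0, t)
    mirrored = detect_saccades(-x, y, t)
    assert len(base) == len(shifted) == len(mirrored) == 1
    assert shifted[0].amplitude == pytest.approx(base[0].amplitude)
    assert mirrored[0].dx == pytest.approx(-base[0].dx)


def _event(dx, dy, start=(0.0, 0.0)):
    return SaccadeEvent(trial_id=0, onset=300.0, offset=320.0, dx=dx, dy=dy,
                        amplitude=float(np.hypot(dx, dy)),
                        direction=float(np.degrees(np.arctan2(dy, dx))),
                        peak_velocity=50.0), start


@pytest.mark.parametrize("cued,dx,dy,start,expected", [
    ("right", 0.4, 0.0, (0.0, 0.0), True),    # away from fixation, cued sign
    ("right", -0.4, 0.0, (0.4, 0.0), False),  # back toward fixation
    ("top", 0.3, -0.2, (0.0, 0.0), False),    # wrong sign on cued axis
    ("left", -0.3, 0.1, (0.0, 0.0), True),
    ("bottom", 0.0, -0.5, (0.0, 0.0), True),
])
def test_classify_toward(cued, dx, dy, start, expected):
    ev, pos = _event(dx, dy, start)
    classify_toward([ev], cued, onset_position=pos)
    assert ev.is_toward is expected


def test_classify_toward_cone():
    ev, pos = _event(0.3, 0.25)  # 39.8 degrees off "right"
    classify_toward([ev], "right", onset_position=pos, criterion="cone",
                    cone_halfwidth=45)
    assert ev.is_toward
    classify_toward([ev], "right", onset_position=pos, criterion="cone",
                    cone_halfwidth=30)
    assert not ev.is_toward


def brute_force_size_density(amps, centers, width, n_trials):
    return np.array([sum(c - width / 2 <= a <= c + width / 2 for a in amps)
                     for c in centers]) / n_trials


def test_size_density_single_saccade_plateau():
    ev, _ = _event(1.0, 0.0)
    ev.is_toward = True
    curve = size_density([ev], n_trials=100, window=(200, 600))
    on = (curve.size_centers >= 0.75 - 1e-9) & (curve.size_centers <= 1.25 + 1e-9)
    np.testing.assert_allclose(curve.density[on], 0.01)
    np.testing.assert_allclose(curve.density[~on], 0.0)


def test_size_density_matches_bruteforce():
    rng = np.random.default_rng(4)
    events = []
    for amp in rng.uniform(0.05, 1.9, 40):
        ev, _ = _event(amp, 0.0)
        ev.is_toward = True
        ev.onset = float(rng.uniform(200, 600))
        events.append(ev)
    curve = size_density(events, n_trials=50)
    oracle = brute_force_size_density([e.amplitude for e in events],
                                      curve.size_centers, 0.5, 50)
    np.testing.assert_allclose(curve.density, oracle)


def test_size_density_window_and_toward_filters():
    inside, _ = _event(0.5, 0.0)
    inside.is_toward = True
    outside, _ = _event(0.5, 0.0)
    outside.is_toward = True
    outside.onset = 700.0
    away, _ = _event(0.5, 0.0)
    away.is_toward = False
    curve = size_density([inside, outside, away], n_trials=10)
    assert curve.n_saccades == 1
    assert curve.density.max() == pytest.approx(0.1)
    with pytest.raises(ValueError):
        size_density([inside], n_trials=0)
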