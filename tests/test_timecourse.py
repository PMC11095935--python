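import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from retrogaze.detect import SaccadeEvent
from retrogaze.timecourse import (
    RateTimecourse,
    TimecourseParams,
    classify_direction,
    magnitude_time_map,
    precue_axis_timecourse,
    shift_rate_timecourse,
    toward_minus_away,
)


def _params(**kw):
    return TimecourseParams(**kw)


def _brute_force_rate(onsets, n_trials, params):
    centres = params.window_centres()
    half = params.rate_window / 2
    rate = np.array(
        [sum(1 for o in onsets if c - half <= o < c + half) for c in centres]
    ) / (n_trials * params.rate_window / 1000.0)
    return centres, rate


# ---------------------------------------------------------------------------
# direction classification
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "disp,expected",
    [
        ((0.2, 0.0), "toward"),
        ((-0.2, 0.1), "away"),
        ((0.0, 0.3), "excluded"),  # exactly perpendicular to a rightward target
    ],
)
def test_classify_direction(disp, expected):
    assert classify_direction(np.array(disp), target=(4.0, 0.0), fixref=(0.0, 0.0)) == expected


def test_classify_direction_rejects_degenerate_target():
    with pytest.raises(ValueError):
        classify_direction(np.array([0.1, 0.0]), target=(0.0, 0.0), fixref=(0.0, 0.0))


# ---------------------------------------------------------------------------
# rate curves
# ---------------------------------------------------------------------------


def test_single_event_20hz_plateau():
    """One saccade in one trial: 1 event / 50 ms window = 20 Hz."""
    params = _params()
    tc = shift_rate_timecourse([300.0], n_trials=1, params=params)
    centres, oracle = _brute_force_rate([300.0], 1, params)
    np.testing.assert_array_equal(tc.rate, oracle)
    plateau = tc.time[tc.rate > 0]
    assert tc.rate.max() == pytest.approx(20.0)
    assert plateau.min() == 276.0 and plateau.max() == 325.0
    assert len(plateau) == 50  # 50 ms wide at 1 ms steps


def test_no_events_all_zero():
    tc = shift_rate_timecourse([], n_trials=5, params=_params())
    np.testing.assert_array_equal(tc.rate, 0.0)


def test_zero_trials_raises():
    with pytest.raises(ValueError):
        shift_rate_timecourse([300.0], n_trials=0, params=_params())


@given(st.lists(st.floats(-900, 1900), min_size=1, max_size=30))
def test_rate_linearity(onsets):
    params = _params()
    single = shift_rate_timecourse(onsets, n_trials=4, params=params)
    doubled = shift_rate_timecourse(onsets + onsets, n_trials=4, params=params)
    np.testing.assert_allclose(doubled.rate, 2 * single.rate)


def test_adding_empty_trial_rescales(rng):
    onsets = rng.uniform(-900, 1900, 40)
    params = _params()
    r4 = shift_rate_timecourse(onsets, n_trials=4, params=params)
    r5 = shift_rate_timecourse(onsets, n_trials=5, params=params)
    np.testing.assert_allclose(r5.rate, r4.rate * 4 / 5)


def test_rate_integral_matches_event_count(rng):
    """Integrating the rate curve over the epoch recovers events per trial."""
    n_trials = 8
    onsets = rng.uniform(-900, 1900, 60)  # away from epoch edges
    params = _params()
    tc = shift_rate_timecourse(onsets, n_trials=n_trials, params=params)
    integral = tc.rate.sum() * params.rate_step / 1000.0
    assert integral == pytest.approx(len(onsets) / n_trials, rel=0.01)


def test_toward_minus_away_identical_is_zero():
    params = _params()
    a = shift_rate_timecourse([100.0, 500.0], 2, params)
    b = shift_rate_timecourse([100.0, 500.0], 2, params)
    np.testing.assert_array_equal(toward_minus_away(a, b).rate, 0.0)


def test_toward_minus_away_antisymmetric():
    params = _params()
    a = shift_rate_timecourse([100.0], 1, params)
    b = shift_rate_timecourse([700.0], 1, params)
    d1 = toward_minus_away(a, b).rate
    d2 = toward_minus_away(b, a).rate
    np.testing.assert_array_equal(d1, -d2)
    assert d1.max() == pytest.approx(20.0)


def test_toward_minus_away_mismatched_axes():
    a = shift_rate_timecourse([0.0], 1, _params())
    b = shift_rate_timecourse([0.0], 1, _params(epoch_span=(-500, 1500)))
    with pytest.raises(ValueError):
        toward_minus_away(a, b)


def test_partition_toward_away_excluded_totals(rng):
    """Toward + away + excluded rates add up to the total start-saccade rate."""
    params = _params()
    onsets = rng.uniform(-900, 1900, 50)
    labels = rng.choice(["toward", "away", "excluded"], 50)
    total = shift_rate_timecourse(onsets, 10, params)
    parts = sum(
        shift_rate_timecourse(onsets[labels == lab], 10, params).rate
        for lab in ("toward", "away", "excluded")
    )
    np.testing.assert_allclose(parts, total.rate)


# ---------------------------------------------------------------------------
# magnitude-time map
# ---------------------------------------------------------------------------


def test_magnitude_map_single_event_bins():
    params = _params()
    edges, centres, m = magnitude_time_map([300.0], [0.3], ["toward"], 1, params)
    hot = np.flatnonzero(m.sum(axis=1) != 0)
    # oracle: brute-force bin membership for magnitude 0.3
    expected = np.flatnonzero([(lo <= 0.3 < lo + params.mag_bin_width) for lo in edges])
    np.testing.assert_array_equal(hot, expected)
    # bins with lower edge in (0.1, 0.3]
    assert edges[hot].min() > 0.1 and edges[hot].max() <= 0.3
    t_hot = centres[m[hot[0]] != 0]
    assert t_hot.min() == 276.0 and t_hot.max() == 325.0


def test_magnitude_map_empty_events():
    _, _, m = magnitude_time_map([], [], [], 3, _params())
    np.testing.assert_array_equal(m, 0.0)


def test_magnitude_map_partition_identity(rng):
    """Non-overlapping bins (width = step) sum to the 1-D difference curve."""
    params = _params(mag_bin_width=0.1, mag_bin_step=0.1)
    n = 40
    onsets = rng.uniform(-900, 1900, n)
    mags = rng.uniform(0.01, 1.99, n)
    labels = rng.choice(["toward", "away"], n)
    _, _, m = magnitude_time_map(onsets, mags, labels, 6, params)
    toward = shift_rate_timecourse(onsets[labels == "toward"], 6, params)
    away = shift_rate_timecourse(onsets[labels == "away"], 6, params)
    np.testing.assert_allclose(m.sum(axis=0), toward.rate - away.rate, atol=1e-12)


# ---------------------------------------------------------------------------
# pre-cue future-axis check
# ---------------------------------------------------------------------------


def _start_event(onset, dx, dy):
    ev = SaccadeEvent.from_positions(0, onset, (0.0, 0.0), (dx, dy))
    ev.is_start = True
    return ev


def test_precue_unbiased_events_average_near_zero(rng):
    future = np.array([4.0, 0.0])
    n_trials = 400
    trial_events, targets, fixrefs = [], [], []
    for _ in range(n_trials):
        evs = []
        if rng.random() < 0.5:
            ang = rng.uniform(0, 2 * np.pi)
            evs.append(_start_event(rng.uniform(-950, -50), 0.3 * np.cos(ang), 0.3 * np.sin(ang)))
        trial_events.append(evs)
        targets.append(future)
        fixrefs.append(np.zeros(2))
    tc = precue_axis_timecourse(trial_events, targets, fixrefs, n_trials)
    # the time-averaged difference is (N_toward - N_away) / (n_trials * span);
    # under the null that count difference has sd ~ sqrt(N_events)
    n_events = sum(len(e) for e in trial_events)
    span_s = 0.9  # window minus half a rate window at each edge
    se = np.sqrt(n_events) / (n_trials * span_s)
    assert abs(tc.rate.mean()) < 3 * se


def test_precue_injected_future_bias_positive(rng):
    future = np.array([4.0, 0.0])
    n_trials = 300
    trial_events, targets, fixrefs = [], [], []
    for _ in range(n_trials):
        toward = rng.random() < 0.8
        dx = 0.3 if toward else -0.3
        trial_events.append([_start_event(rng.uniform(-950, -50), dx, 0.0)])
        targets.append(future)
        fixrefs.append(np.zeros(2))
    tc = precue_axis_timecourse(trial_events, targets, fixrefs, n_trials)
    assert tc.rate.mean() > 0


def test_precue_window_too_short_raises():
    with pytest.raises(ValueError):
        precue_axis_timecourse([], [], [], 1, window=(-20.0, 0.0))
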