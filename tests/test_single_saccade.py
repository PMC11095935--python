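import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from retrogaze.detect import SaccadeEvent
from retrogaze.simulate import make_rule_table
from retrogaze.single_saccade import (
    AngularParams,
    RotatedSaccade,
    angular_distribution,
    common_frame_matrix,
    conditional_bias_profile,
    first_start_saccade,
    quadrant_percentages,
    rotate_to_common_frame,
)


def _event(onset, dx, dy, is_start=True):
    ev = SaccadeEvent.from_positions(0, onset, (0.0, 0.0), (dx, dy))
    ev.is_start = is_start
    return ev


def _rot(direction, magnitude=0.3, trial_id=0):
    th = np.radians(direction)
    d = magnitude * np.array([np.cos(th), np.sin(th)])
    return RotatedSaccade(trial_id, float(direction % 360), magnitude, d)


# ---------------------------------------------------------------------------
# first-saccade selection
# ---------------------------------------------------------------------------


def test_first_start_saccade_earliest_wins():
    evs = [_event(250, 0.3, 0), _event(400, 0, 0.3)]
    assert first_start_saccade(evs).onset == 250


def test_first_start_saccade_ignores_returns():
    assert first_start_saccade([_event(300, 0.3, 0, is_start=False)]) is None


@pytest.mark.parametrize("onset,found", [(199, False), (200, True), (600, True), (601, False)])
def test_selection_window_inclusive(onset, found):
    result = first_start_saccade([_event(onset, 0.3, 0)])
    assert (result is not None) is found


# ---------------------------------------------------------------------------
# rotation to the common frame
# ---------------------------------------------------------------------------


def test_rule1_top_item_toward_past_maps_to_zero():
    """Top item tested on the right: an upward (toward-past) shift lands at 0 deg."""
    ev = _event(300, 0.0, 0.3)
    rot = rotate_to_common_frame(ev, past=(0.0, 4.0), future=(4.0, 0.0))
    assert rot.direction_common == pytest.approx(0.0)
    assert rot.magnitude == pytest.approx(0.3)


def test_identity_frame():
    ev = _event(300, 0.3, 0.0)
    rot = rotate_to_common_frame(ev, past=(4.0, 0.0), future=(0.0, 4.0))
    assert rot.direction_common == pytest.approx(0.0)


@pytest.mark.parametrize("rule_id", [1, 2, 3, 4])
def test_rotation_is_isometry_for_every_rule(rule_id, rng):
    table = make_rule_table(rule_id)
    for past, future in table.items():
        for _ in range(20):
            d = rng.normal(0, 0.5, 2)
            ev = _event(300, *d)
            rot = rotate_to_common_frame(ev, past, future)
            assert rot.magnitude == pytest.approx(np.hypot(*d), abs=1e-12)
            np.testing.assert_allclose(np.hypot(*rot.displacement_common), np.hypot(*d))


def test_rotation_requires_orthogonal_axes():
    with pytest.raises(ValueError):
        common_frame_matrix((4.0, 0.0), (4.0, 1.0))


def test_rotation_toward_quadrant_assignment():
    # rule 2 (top -> left): a shift up-and-left is toward past AND toward future
    rot = rotate_to_common_frame(_event(300, -0.2, 0.2), past=(0, 4), future=(-4, 0))
    assert rot.displacement_common[0] > 0 and rot.displacement_common[1] > 0


# ---------------------------------------------------------------------------
# angular distribution
# ---------------------------------------------------------------------------


def test_single_saccade_occupies_21_centres():
    centres, p = angular_distribution([_rot(0.0)])
    hot = centres[p == 1.0]
    # oracle: explicit circular distance check against every centre
    expected = [c for c in range(360) if min(abs(c - 0), 360 - abs(c - 0)) <= 10]
    np.testing.assert_array_equal(np.sort(hot), np.sort(expected))
    assert set(p) <= {0.0, 1.0}


def test_uniform_directions_fill_bins(rng):
    n = 30000
    dirs = rng.uniform(0, 360, n)
    centres, p = angular_distribution([_rot(d) for d in dirs])
    expected = 20.0 / 360.0
    se = np.sqrt(expected * (1 - expected) / n)
    # per-bin agreement; 4.5 SE accounts for the 360 (correlated) bins tested
    assert np.abs(p - expected).max() < 4.5 * se


def test_bin_overlap_counting(rng):
    """Each non-boundary saccade falls in exactly width/step bins."""
    dirs = rng.uniform(0, 360, 50) + 0.123  # keep away from integer boundaries
    centres, p = angular_distribution([_rot(d) for d in dirs])
    assert p.sum() == pytest.approx(20.0)


def test_empty_input_raises():
    with pytest.raises(ValueError):
        angular_distribution([])


# ---------------------------------------------------------------------------
# conditional bias profiles
# ---------------------------------------------------------------------------


def test_symmetric_distribution_zero_past_bias():
    # mirror pairs across the future (vertical) axis
    sacc = [_rot(a) for pair in ((30, 150), (75, 105), (290, 250)) for a in pair]
    psi, bias = conditional_bias_profile(sacc, "past")
    np.testing.assert_allclose(bias, 0.0, atol=1e-12)


def test_joint_quadrant_bias_sign():
    psi, bias = conditional_bias_profile([_rot(45.0)], "past")
    assert bias[psi == 45.0] > 0
    assert bias[psi == -45.0] < 0
    # antisymmetry of the profile
    for a in (10, 45, 90, 133):
        assert bias[psi == a] == -bias[psi == -a]


def test_future_profile_mirrors_past_axis():
    psi, bias = conditional_bias_profile([_rot(45.0)], "future")
    assert bias[psi == 45.0] > 0
    assert bias[psi == -45.0] < 0


def test_profile_integrates_to_quadrant_difference(rng):
    """Summed bias / overlap factor equals toward% - away% (for saccades off-axis)."""
    # directions at least 11 deg away from both axes so every 20-deg bin
    # stays within one hemifield
    base = rng.uniform(15, 75, 40)
    quad = rng.choice([0, 90, 180, 270], 40)
    dirs = base + quad
    sacc = [_rot(d) for d in dirs]
    psi, bias = conditional_bias_profile(sacc, "past")
    toward = np.sum(np.cos(np.radians(dirs)) > 0) / len(dirs)
    away = 1 - toward
    total = bias[(psi > 0) & (psi < 180)].sum() / 20.0
    assert total == pytest.approx(toward - away, abs=1e-9)


# ---------------------------------------------------------------------------
# quadrant tables
# ---------------------------------------------------------------------------


def test_four_symmetric_saccades_quarter_each():
    (table,) = quadrant_percentages({"P01": [_rot(a) for a in (45, 135, 225, 315)]})
    np.testing.assert_allclose(table.pct, 25.0)
    assert table.pct.sum() == pytest.approx(100.0)


def test_all_joint_quadrant():
    (table,) = quadrant_percentages({"P01": [_rot(a) for a in (30, 45, 60)]})
    assert table.pct[0, 0] == pytest.approx(100.0)
    assert table.pct.sum() == pytest.approx(100.0)


def test_axis_aligned_saccades_excluded():
    (table,) = quadrant_percentages({"P01": [_rot(0.0), _rot(45.0)]})
    # the 0-degree saccade sits exactly on the past axis and is dropped
    assert table.n_saccades == 1
    assert table.pct[0, 0] == pytest.approx(100.0)


def test_participant_without_saccades_excluded():
    tables = quadrant_percentages({"P01": [], "P02": [_rot(45.0)]})
    assert [t.participant_id for t in tables] == ["P02"]


@given(st.lists(st.floats(0.5, 359.5), min_size=1, max_size=40))
def test_quadrant_rows_sum_to_100(dirs):
    sacc = [_rot(d) for d in dirs if abs(np.cos(np.radians(d))) > 1e-9 and abs(np.sin(np.radians(d))) > 1e-9]
    if not sacc:
        return
    (table,) = quadrant_percentages({"P": sacc})
    assert table.pct.sum() == pytest.approx(100.0)


def test_mixture_quadrants_recovered(rng):
    """Empirical quadrant shares of the direction mixture match the analytic values."""
    from retrogaze.simulate import mixture_quadrant_probabilities

    weights = (0.4, 0.2, 0.2, 0.2)
    kappa = 8.0
    n = 20000
    comps = rng.choice(4, size=n, p=weights)
    mus = {0: 45.0, 1: 0.0, 2: 90.0}
    dirs = np.where(
        comps == 3,
        rng.uniform(0, 360, n),
        np.degrees(rng.vonmises(np.radians([mus.get(c, 0) for c in comps]), kappa)),
    )
    (table,) = quadrant_percentages({"P": [_rot(d) for d in dirs]})
    expected = mixture_quadrant_probabilities(weights, kappa) * 100
    se = np.sqrt(expected / 100 * (1 - expected / 100) / n) * 100
    assert (np.abs(table.pct - expected) < 3.5 * se).all()
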