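"""Toward/away saccade-rate time courses.

A start saccade counts as *toward* a reference location (the past/encoded
or future/to-be-tested location of the cued item) when its displacement has
a positive projection on the fixation-to-target axis, *away* when negative
(the hemifield rule); exactly perpendicular shifts are excluded rather than
split.  Rates in Hz are computed with a sliding window over all trials:
``rate(t) = count of onsets in [t - w/2, t + w/2) / (n_trials * w)``.
Window centres are placed so that windows lie fully inside the epoch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .detect import SaccadeEvent

__all__ = [
    "TimecourseParams",
    "RateTimecourse",
    "classify_direction",
    "shift_rate_timecourse",
    "toward_minus_away",
    "magnitude_time_map",
    "precue_axis_timecourse",
]


@dataclass
class TimecourseParams:
    """Sliding-window and magnitude-binning settings.

    rate_window/rate_step : ms
        Width and advance of the sliding count window.
    epoch_span : (ms, ms)
        Time range of the epoch the events live on.
    mag_bin_width/mag_bin_step/mag_max : degrees
        Overlapping magnitude bins ``[m, m + width)`` stepped by
        ``mag_bin_step`` with lower edges up to ``mag_max - width``, for the
        time-magnitude decomposition.  ``mag_max`` of 2 degrees covers the
        microsaccade range.
    """

    rate_window: float = 50.0
    rate_step: float = 1.0
    epoch_span: tuple[float, float] = (-1000.0, 2000.0)
    mag_bin_width: float = 0.2
    mag_bin_step: float = 0.04
    mag_max: float = 2.0

    def __post_init__(self) -> None:
        if self.rate_window <= 0 or self.rate_step <= 0 or self.mag_bin_width <= 0:
            raise ValueError("rate_window, rate_step and mag_bin_width must be > 0")

    def window_centres(self, span: tuple[float, float] | None = None) -> np.ndarray:
        lo, hi = span if span is not None else self.epoch_span
        half = self.rate_window / 2.0
        if hi - lo < self.rate_window:
            raise ValueError("epoch span shorter than the rate window")
        return np.arange(lo + half, hi - half + self.rate_step / 2.0, self.rate_step)


@dataclass
class RateTimecourse:
    """A per-condition saccade-rate series (Hz) over epoch time (ms)."""

    time: np.ndarray
    rate: np.ndarray
    condition: str = ""
    reference: str = ""
    n_trials: int = 0


def classify_direction(event, target, fixref) -> str:
    """Toward/away/excluded relative to the fixation-to-target axis.

    ``event`` may be a :class:`SaccadeEvent` or a bare displacement vector.
    """
    disp = event.displacement if isinstance(event, SaccadeEvent) else np.asarray(event, float)
    axis = np.asarray(target, dtype=float) - np.asarray(fixref, dtype=float)
    if not np.any(axis):
        raise ValueError("target coincides with the fixation reference")
    proj = float(disp @ axis)
    if proj > 0:
        return "toward"
    if proj < 0:
        return "away"
    return "excluded"


def shift_rate_timecourse(
    onsets,
    n_trials: int,
    params: TimecourseParams | None = None,
    condition: str = "",
    reference: str = "",
    span: tuple[float, float] | None = None,
) -> RateTimecourse:
    """Sliding-window rate (Hz) of the given onsets pooled over trials.

    ``onsets`` are onset times (ms) of all qualifying saccades across the
    ``n_trials`` trials; the trial count only enters the denominator.
    """
    params = params or TimecourseParams()
    if n_trials < 1:
        raise ValueError("need at least one trial")
    centres = params.window_centres(span)
    on = np.sort(np.asarray(list(onsets), dtype=float))
    half = params.rate_window / 2.0
    lo = np.searchsorted(on, centres - half, side="left")
    hi = np.searchsorted(on, centres + half, side="left")
    rate = (hi - lo) / (n_trials * params.rate_window / 1000.0)
    return RateTimecourse(centres, rate, condition, reference, n_trials)


def toward_minus_away(tc_toward: RateTimecourse, tc_away: RateTimecourse) -> RateTimecourse:
    """Pointwise toward-minus-away rate difference (Hz)."""
    if len(tc_toward.time) != len(tc_away.time) or not np.allclose(
        tc_toward.time, tc_away.time
    ):
        raise ValueError("time axes do not match")
    return RateTimecourse(
        tc_toward.time.copy(),
        tc_toward.rate - tc_away.rate,
        condition="toward-away",
        reference=tc_toward.reference,
        n_trials=tc_toward.n_trials,
    )


def magnitude_time_map(
    onsets,
    magnitudes,
    labels,
    n_trials: int,
    params: TimecourseParams | None = None,
):
    """Time-magnitude decomposition of the toward-minus-away rate.

    For each overlapping magnitude bin ``[m, m + mag_bin_width)`` (lower
    edges from 0 to ``mag_max - mag_bin_width`` in steps of
    ``mag_bin_step``) the toward-minus-away rate curve is computed from the
    events whose magnitude falls in that bin.

    Parameters are parallel arrays of onset time (ms), magnitude (deg) and
    direction label (``'toward'``/``'away'``; others ignored).

    Returns ``(bin_lower_edges, window_centres, map)`` with ``map`` of shape
    ``(n_bins, n_centres)``.
    """
    params = params or TimecourseParams()
    onsets = np.asarray(list(onsets), dtype=float)
    magnitudes = np.asarray(list(magnitudes), dtype=float)
    labels = np.asarray(list(labels), dtype=object)
    centres = params.window_centres()
    n_edge = int(np.floor((params.mag_max - params.mag_bin_width) / params.mag_bin_step + 1e-9)) + 1
    edges = np.arange(n_edge) * params.mag_bin_step
    out = np.zeros((len(edges), len(centres)))
    for i, m0 in enumerate(edges):
        in_bin = (magnitudes >= m0) & (magnitudes < m0 + params.mag_bin_width)
        for sign, lab in ((1.0, "toward"), (-1.0, "away")):
            sel = in_bin & (labels == lab)
            if not sel.any():
                continue
            tc = shift_rate_timecourse(onsets[sel], n_trials, params)
            out[i] += sign * tc.rate
    return edges, centres, out


def precue_axis_timecourse(
    trial_events,
    future_targets,
    fixrefs,
    n_trials: int,
    params: TimecourseParams | None = None,
    window: tuple[float, float] = (-1000.0, 0.0),
) -> RateTimecourse:
    """Toward-minus-away rate along the future-rule axis before the cue.

    A remapping check: if memoranda were remapped to their future locations
    during the encoding-to-cue delay, start saccades in that period should
    already be biased along the future axis.  Uses the same sliding-window
    machinery restricted to the pre-cue window.

    Parameters
    ----------
    trial_events
        Per-trial lists of start :class:`SaccadeEvent`.
    future_targets, fixrefs
        Per-trial future location and fixation reference (2-vectors).
    """
    params = params or TimecourseParams()
    if window[1] - window[0] < params.rate_window:
        raise ValueError("pre-cue window shorter than the rate window")
    toward, away = [], []
    for events, target, fixref in zip(trial_events, future_targets, fixrefs):
        for ev in events:
            if not (window[0] <= ev.onset <= window[1]):
                continue
            cls = classify_direction(ev, target, fixref)
            if cls == "toward":
                toward.append(ev.onset)
            elif cls == "away":
                away.append(ev.onset)
    tc_t = shift_rate_timecourse(toward, n_trials, params, "toward", "future", span=window)
    tc_a = shift_rate_timecourse(away, n_trials, params, "away", "future", span=window)
    return toward_minus_away(tc_t, tc_a)
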