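"""Velocity-based gaze-shift (saccade/microsaccade) detection.

The detector follows the median-multiple rule: gaze speed is the Euclidean
distance between successive samples, smoothed with a Gaussian-weighted
moving average; a shift onset is the first sample after the smoothed speed
crosses ``threshold_multiplier`` times the per-trial median speed, with a
refractory period so one movement is not counted twice.  Each event is
characterised by the difference between mean gaze position in a pre-onset
and a post-onset window, and classified as a *start* saccade (moving away
from fixation) or a return saccade (moving back).

Velocity is expressed in degrees per sample at the native rate.  Because
the threshold is a multiple of the per-trial median, the choice of
deg/sample versus deg/s has no effect on which shifts are detected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import GazeEpoch

logger = logging.getLogger(__name__)

__all__ = [
    "DetectionParams",
    "SaccadeEvent",
    "gaussian_kernel",
    "compute_velocity",
    "detect_saccades",
    "characterize_saccade",
    "classify_start_saccade",
    "detect_epoch",
    "events_to_frame",
]


@dataclass
class DetectionParams:
    """Tunables of the velocity detector.

    smooth_window : ms
        Length of the Gaussian-weighted moving-average window (odd number
        of samples at 1000 Hz).  The Gaussian has standard deviation
        ``window / 5`` samples, truncated to the window and renormalised
        (the convention of common smoothing routines).
    threshold_multiplier
        Shift onset when smoothed speed exceeds this multiple of the
        per-trial median speed.
    refractory : ms
        Minimum delay between successive accepted onsets (onset-to-onset).
    pre_window, post_window : (ms, ms)
        Windows relative to onset over which pre-/post-saccade gaze position
        is averaged; sampled closed-open ``[a, b)``.
    min_valid_samples
        Trials with fewer valid (non-missing) velocity samples are excluded
        from all downstream counts.
    """

    smooth_window: float = 7.0
    threshold_multiplier: float = 5.0
    refractory: float = 100.0
    pre_window: tuple[float, float] = (-50.0, 0.0)
    post_window: tuple[float, float] = (50.0, 100.0)
    min_valid_samples: int = 500

    def __post_init__(self) -> None:
        if self.threshold_multiplier <= 0:
            raise ValueError("threshold_multiplier must be > 0")
        if self.refractory < 0:
            raise ValueError("refractory must be >= 0")
        for w in (self.pre_window, self.post_window):
            if w[1] <= w[0]:
                raise ValueError("pre/post windows must be non-empty")


@dataclass
class SaccadeEvent:
    """One detected gaze shift.

    ``direction`` is the planar angle of the displacement in degrees,
    0 = rightward, counter-clockwise positive, in [0, 360).
    """

    trial_id: int
    onset: float  # ms, cue-relative
    pre_pos: np.ndarray
    post_pos: np.ndarray
    displacement: np.ndarray
    magnitude: float
    direction: float
    is_start: bool = False

    @classmethod
    def from_positions(cls, trial_id, onset, pre_pos, post_pos, is_start=False):
        pre_pos = np.asarray(pre_pos, dtype=float)
        post_pos = np.asarray(post_pos, dtype=float)
        disp = post_pos - pre_pos
        mag = float(np.hypot(disp[0], disp[1]))
        direction = float(np.degrees(np.arctan2(disp[1], disp[0])) % 360.0)
        return cls(trial_id, float(onset), pre_pos, post_pos, disp, mag, direction, is_start)


def gaussian_kernel(n_samples: int) -> np.ndarray:
    """Gaussian weights over ``n_samples`` points, sd = window/5, renormalised."""
    if n_samples < 1:
        raise ValueError("kernel length must be >= 1")
    if n_samples == 1:
        return np.ones(1)
    half = (n_samples - 1) / 2.0
    pos = np.arange(n_samples) - half
    sd = n_samples / 5.0
    w = np.exp(-0.5 * (pos / sd) ** 2)
    return w / w.sum()


def compute_velocity(epoch: GazeEpoch, params: DetectionParams | None = None):
    """Smoothed gaze speed per sample.

    Raw speed at sample ``i`` is the Euclidean distance between samples
    ``i-1`` and ``i`` (NaN when either is missing; the first sample has no
    predecessor and is NaN).  Smoothing is a Gaussian-weighted moving
    average that omits missing values by renormalising the weights over
    valid neighbours; windows with no valid sample stay NaN.

    Returns ``(time, velocity)`` in ms and degrees/sample.
    """
    params = params or DetectionParams()
    if epoch.n_samples < 2:
        raise ValueError("epoch must have at least 2 samples")
    dx = np.diff(epoch.x)
    dy = np.diff(epoch.y)
    v = np.empty(epoch.n_samples)
    v[0] = np.nan
    v[1:] = np.hypot(dx, dy)
    valid = ~np.isnan(v)
    if not valid.any():
        return epoch.time, v
    dt = (epoch.time[-1] - epoch.time[0]) / (epoch.n_samples - 1)
    n_kernel = max(1, int(round(params.smooth_window / dt)))
    if n_kernel % 2 == 0:
        n_kernel += 1
    if n_kernel == 1:
        return epoch.time, v
    k = gaussian_kernel(n_kernel)
    filled = np.where(valid, v, 0.0)
    num = np.convolve(filled, k, mode="same")
    den = np.convolve(valid.astype(float), k, mode="same")
    with np.errstate(invalid="ignore", divide="ignore"):
        smoothed = np.where(den > 0, num / den, np.nan)
    smoothed[~valid] = np.nan
    return epoch.time, smoothed


def detect_saccades(time, velocity, params: DetectionParams | None = None):
    """Onset times of gaze shifts from a smoothed velocity series.

    The per-trial threshold is ``threshold_multiplier`` times the median of
    the non-missing velocity.  An onset is the first sample after an upward
    threshold crossing; crossings within ``refractory`` ms of the previously
    accepted onset are discarded.  A frozen trace (median velocity 0) yields
    no detections and a logged warning.
    """
    params = params or DetectionParams()
    v = np.asarray(velocity, dtype=float)
    valid = ~np.isnan(v)
    if not valid.any():
        return []
    med = float(np.median(v[valid]))
    if med == 0.0:
        logger.warning("median velocity is zero (frozen gaze); no detections")
        return []
    thr = params.threshold_multiplier * med
    above = np.zeros(len(v), dtype=bool)
    above[valid] = v[valid] > thr
    # first sample after an upward crossing: above[i] and not above[i-1]
    crossings = np.flatnonzero(above[1:] & ~above[:-1]) + 1
    onsets = []
    last = -np.inf
    for i in crossings:
        t = float(time[i])
        if t - last >= params.refractory:
            onsets.append(t)
            last = t
    return onsets


def _window_mean(epoch: GazeEpoch, lo: float, hi: float):
    """Mean (x, y) over the closed-open time window [lo, hi).

    Returns None if the window is not fully inside the epoch or contains
    any missing sample (events straddling a blink gap are discarded rather
    than interpolated).
    """
    if lo < epoch.time[0] or hi > epoch.time[-1] + 1e-9:
        return None
    i0 = int(np.searchsorted(epoch.time, lo, side="left"))
    i1 = int(np.searchsorted(epoch.time, hi, side="left"))
    if i1 <= i0:
        return None
    xs = epoch.x[i0:i1]
    ys = epoch.y[i0:i1]
    if np.isnan(xs).any() or np.isnan(ys).any():
        return None
    return np.array([xs.mean(), ys.mean()])


def characterize_saccade(
    epoch: GazeEpoch, onset: float, params: DetectionParams | None = None
) -> SaccadeEvent | None:
    """Magnitude and direction of the shift at ``onset``.

    Pre-/post-saccade gaze positions are arithmetic means over the
    ``pre_window`` and ``post_window`` relative to onset.  Returns None
    (event discarded, reason logged) when either window leaves the epoch or
    overlaps missing data.
    """
    params = params or DetectionParams()
    pre = _window_mean(epoch, onset + params.pre_window[0], onset + params.pre_window[1])
    post = _window_mean(epoch, onset + params.post_window[0], onset + params.post_window[1])
    if pre is None or post is None:
        logger.debug(
            "trial %s: event at %.0f ms discarded (window out of epoch or missing data)",
            epoch.trial.trial_id,
            onset,
        )
        return None
    return SaccadeEvent.from_positions(epoch.trial.trial_id, onset, pre, post)


def classify_start_saccade(event: SaccadeEvent, fixref: np.ndarray) -> bool:
    """True for a *start* saccade: one that moves gaze away from fixation.

    Compares post- and pre-saccade distance from the fixation reference;
    strict inequality, so an exact tie counts as non-start.
    """
    fixref = np.asarray(fixref, dtype=float)
    d_pre = float(np.linalg.norm(event.pre_pos - fixref))
    d_post = float(np.linalg.norm(event.post_pos - fixref))
    return d_post > d_pre


def detect_epoch(
    epoch: GazeEpoch, fixref: np.ndarray, params: DetectionParams | None = None
) -> list[SaccadeEvent]:
    """Full per-trial detection: velocity, onsets, characterisation, start flag.

    Returns the characterised events (events whose pre/post windows are
    unusable are dropped).  Trials with fewer than
    ``params.min_valid_samples`` valid velocity samples return an empty
    list; callers should exclude such trials from rate denominators.
    """
    params = params or DetectionParams()
    time, v = compute_velocity(epoch, params)
    if (~np.isnan(v)).sum() < params.min_valid_samples:
        logger.warning(
            "trial %s: only %d valid velocity samples; trial excluded",
            epoch.trial.trial_id,
            int((~np.isnan(v)).sum()),
        )
        return []
    events = []
    for onset in detect_saccades(time, v, params):
        ev = characterize_saccade(epoch, onset, params)
        if ev is None:
            continue
        ev.is_start = classify_start_saccade(ev, fixref)
        events.append(ev)
    return events


def events_to_frame(events, participant_id: str = "", session_id: str = "") -> pd.DataFrame:
    """Export detected events as a flat table."""
    rows = [
        {
            "participant": participant_id,
            "session": session_id,
            "trial_id": ev.trial_id,
            "onset_ms": ev.onset,
            "dx_deg": ev.displacement[0],
            "dy_deg": ev.displacement[1],
            "magnitude_deg": ev.magnitude,
            "direction_deg": ev.direction,
            "is_start": bool(ev.is_start),
        }
        for ev in events
    ]
    cols = [
        "participant",
        "session",
        "trial_id",
        "onset_ms",
        "dx_deg",
        "dy_deg",
        "magnitude_deg",
        "direction_deg",
        "is_start",
    ]
    return pd.DataFrame(rows, columns=cols)
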