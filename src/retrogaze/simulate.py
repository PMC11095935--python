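"""Synthetic oculomotor data with ground truth.

The generator emulates the structure of a retro-cue working-memory
experiment in which two items are encoded on one axis (vertical or
horizontal) at fixed eccentricity and tested on the orthogonal axis, with
the encoded-to-tested mapping fixed per session by one of four
counterbalanced *future rules*.  Each trial produces a raw-like 1000 Hz
gaze trace over the -1000..+2000 ms cue-aligned epoch containing

* band-limited fixational jitter plus slow random-walk drift,
* baseline (micro)saccades as a Poisson process with uniform directions,
* optionally one attention-driven start saccade in the post-cue response
  window whose direction is drawn, *in the common past-right/future-up
  frame*, from a four-component mixture (von Mises at 45 deg for a joint
  past+future bias, at 0 deg for past-only, at 90 deg for future-only,
  uniform otherwise) and then mapped back through the trial's rule
  geometry -- so the ground-truth joint-bias structure is identical across
  rules,
* a return saccade back to fixation after each outgoing saccade, and
* blinks recorded as exact-zero clusters, as eye trackers emit them.

Saccades are realised as raised-cosine displacement ramps over a fixed
duration, which gives the main-sequence-like property that peak velocity
scales with amplitude.  Every injected event is logged so detection and
bias recovery can be scored against ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import GazeEpoch, GazeRecording, TrialMeta
from .single_saccade import common_frame_matrix

__all__ = [
    "SimulationParams",
    "SessionData",
    "StudyData",
    "LOCATIONS",
    "RULES",
    "make_rule_table",
    "encoding_axis_for_rule",
    "simulate_trial",
    "simulate_session",
    "simulate_study",
    "mixture_quadrant_probabilities",
    "first_saccade_quadrant_probabilities",
    "expected_first_saccade_quadrants",
]

# canonical item positions (unit eccentricity = 4 degrees)
LOCATIONS = {
    "top": np.array([0.0, 1.0]),
    "bottom": np.array([0.0, -1.0]),
    "left": np.array([-1.0, 0.0]),
    "right": np.array([1.0, 0.0]),
}

# future rules: encoded location -> test location.  Rules 1/2 encode on the
# vertical axis and test on the horizontal; rules 3/4 the reverse.  The
# text-level definition fixes rules 1 and 2 (top->right/bottom->left and
# top->left/bottom->right); rules 3/4 follow the same logic for horizontal
# encoding and are fixed here as left->top/right->bottom and
# left->bottom/right->top.
RULES = {
    1: {"top": "right", "bottom": "left"},
    2: {"top": "left", "bottom": "right"},
    3: {"left": "top", "right": "bottom"},
    4: {"left": "bottom", "right": "top"},
}


def make_rule_table(rule_id: int, eccentricity: float = 4.0) -> dict:
    """Mapping encoded-location vector -> test-location vector for a rule."""
    if rule_id not in RULES:
        raise ValueError(f"invalid rule_id {rule_id}")
    return {
        tuple(LOCATIONS[enc] * eccentricity): tuple(LOCATIONS[tst] * eccentricity)
        for enc, tst in RULES[rule_id].items()
    }


def encoding_axis_for_rule(rule_id: int) -> str:
    return "vertical" if rule_id in (1, 2) else "horizontal"


@dataclass
class SimulationParams:
    """Generative settings; defaults emulate the study conditions.

    The structural defaults (25 participants, 4 sessions of 5 blocks of 32
    trials, 4 degree eccentricity, 200-600 ms response window, ~70%
    accuracy, mean RT ~1218 ms) mirror the experimental design the
    pipeline targets.  Oculomotor noise (``noise_sd`` 0.01 deg RMS
    band-limited jitter, ``drift_sd`` 0.001 deg/sample random walk), microsaccade
    amplitudes (log-normal around 0.5 deg) and a 0.3 Hz baseline shift
    rate are set to values typical of fixational eye movements; the
    mixture weights and concentration define the injected joint
    past+future bias.
    """

    n_participants: int = 25
    n_sessions: int = 4
    n_blocks_per_session: int = 5
    n_trials_per_block: int = 32
    noise_sd: float = 0.01  # deg RMS of band-limited fixational jitter
    jitter_timescale: float = 20.0  # ms correlation scale of the jitter
    drift_sd: float = 0.001  # deg/sample random-walk increments
    blink_rate: float = 0.05  # Hz
    base_saccade_rate: float = 0.3  # Hz, Poisson baseline shifts
    response_prob: float = 0.9  # P(attentional first saccade in window)
    response_window: tuple[float, float] = (200.0, 600.0)
    mixture_weights: tuple[float, float, float, float] = (0.5, 0.15, 0.15, 0.2)
    kappa: float = 8.0  # von Mises concentration of direction scatter
    amplitude_logmean: float = math.log(0.5)
    amplitude_logsd: float = 0.35
    accuracy_p: float = 0.70
    rt_logmean: float = math.log(1218.0) - 0.35**2 / 2  # mean RT ~= 1218 ms
    rt_logsd: float = 0.35
    saccade_duration: float = 20.0  # ms displacement ramp
    return_delay: tuple[float, float] = (150.0, 400.0)
    return_saccades: bool = True
    blink_duration: tuple[float, float] = (100.0, 300.0)
    eccentricity: float = 4.0
    epoch_window: tuple[float, float] = (-1000.0, 2000.0)
    seed: int = 0

    def __post_init__(self) -> None:
        w = np.asarray(self.mixture_weights, dtype=float)
        if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("mixture_weights must be non-negative and sum to 1")
        if not 0 <= self.response_prob <= 1 or not 0 <= self.accuracy_p <= 1:
            raise ValueError("probabilities must be in [0, 1]")
        for rate in (self.blink_rate, self.base_saccade_rate):
            if rate < 0:
                raise ValueError("rates must be >= 0")

    @property
    def n_trials_per_session(self) -> int:
        return self.n_blocks_per_session * self.n_trials_per_block


MIXTURE_CATEGORIES = (
    "attentional-joint",
    "attentional-past",
    "attentional-future",
    "attentional-uniform",
)
MIXTURE_MEANS_DEG = (45.0, 0.0, 90.0, None)  # None = uniform


@dataclass
class SessionData:
    recording: GazeRecording
    trials: list  # TrialMeta
    truth: pd.DataFrame  # injected saccades, cue-relative onsets
    blinks: pd.DataFrame  # injected blink intervals, cue-relative


@dataclass
class StudyData:
    sessions: list
    behaviour: pd.DataFrame
    params: SimulationParams

    @property
    def truth(self) -> pd.DataFrame:
        return pd.concat([s.truth for s in self.sessions], ignore_index=True)


def _raised_cosine(n: int) -> np.ndarray:
    return 0.5 * (1.0 - np.cos(np.pi * np.arange(n + 1) / n))


def _band_limited_jitter(n, sd, timescale, rng, n_channels=2):
    """Fixational jitter: white noise low-passed to a given correlation scale.

    Gaze position noise at 1000 Hz is strongly correlated sample-to-sample
    (tremor and tracker filtering are band-limited); modelling it as
    low-passed white noise keeps sample-to-sample velocity far below
    saccadic peak velocity, which is what makes a median-multiple velocity
    threshold workable on real data.  The low-pass is a cascade of three
    moving-average (box) filters, a close and O(n) approximation to a
    Gaussian kernel with standard deviation ``timescale`` samples.  ``sd``
    is the RMS position noise in degrees.  Returns an ``(n_channels, n)``
    array.
    """
    if sd <= 0:
        return np.zeros((n_channels, n))
    sigma = max(float(timescale), 0.5)
    w = max(2, int(round(2.0 * sigma)))  # triple box of width w ~ Gaussian sd w/2

    def _box(a):
        cs = np.cumsum(a, axis=-1)
        out = np.empty((a.shape[0], a.shape[1] - w + 1))
        out[:, 0] = cs[:, w - 1]
        out[:, 1:] = cs[:, w:] - cs[:, :-w]
        return out / w

    kernel = np.ones(w) / w
    kernel = np.convolve(np.convolve(kernel, kernel), kernel)
    white = rng.normal(0.0, 1.0, (n_channels, n + 3 * (w - 1)))
    smoothed = _box(_box(_box(white)))
    return smoothed * (sd / np.linalg.norm(kernel))


def _inject(x, y, i0, dur, dx, dy):
    """Add a raised-cosine displacement ramp starting at sample index i0."""
    n = len(x)
    if i0 >= n:
        return
    ramp = _raised_cosine(dur)
    j = min(n, i0 + dur + 1)
    x[i0:j] += dx * ramp[: j - i0]
    y[i0:j] += dy * ramp[: j - i0]
    if i0 + dur + 1 < n:
        x[i0 + dur + 1 :] += dx
        y[i0 + dur + 1 :] += dy


def simulate_trial(
    meta: TrialMeta,
    params: SimulationParams,
    rng: np.random.Generator,
    events=None,
    background=None,
):
    """Generate one trial's raw cue-aligned trace plus its ground truth.

    ``events`` overrides the stochastic event model: a list of
    ``(onset_ms, dx, dy)`` displacements to inject verbatim (no baseline
    process, no attentional draw), which is how detector benchmarks build
    trials with known separations and magnitudes.  ``background`` supplies
    a pre-generated ``(x, y)`` noise floor (used by
    :func:`simulate_session` to keep jitter and drift continuous across a
    whole recording); otherwise jitter and drift are generated here.

    Returns ``(epoch, truth_rows, blink_intervals)`` where ``truth_rows``
    are dicts describing every injected saccade (onsets snapped to the
    sample grid) and ``blink_intervals`` are cue-relative (start, end) ms.
    """
    lo, hi = params.epoch_window
    n = int(round(hi - lo)) + 1
    time = np.arange(lo, hi + 0.5)
    if background is not None:
        x = np.array(background[0], dtype=float)
        y = np.array(background[1], dtype=float)
    else:
        jitter = _band_limited_jitter(n, params.noise_sd, params.jitter_timescale, rng)
        x, y = jitter[0].copy(), jitter[1].copy()
        if params.drift_sd > 0:
            x += np.cumsum(rng.normal(0.0, params.drift_sd, n))
            y += np.cumsum(rng.normal(0.0, params.drift_sd, n))

    dur = int(round(params.saccade_duration))
    injected = []  # (onset_ms, dx, dy, category)
    if events is not None:
        for onset, dx, dy in events:
            injected.append((float(onset), float(dx), float(dy), "manual"))
    else:
        # baseline Poisson shifts, uniform directions
        span_lo, span_hi = lo, hi - 400.0  # leave room for ramp + return
        span_s = (span_hi - span_lo) / 1000.0
        n_base = rng.poisson(params.base_saccade_rate * span_s)
        for _ in range(n_base):
            onset = rng.uniform(span_lo, span_hi)
            ang = rng.uniform(0.0, 2.0 * np.pi)
            amp = rng.lognormal(params.amplitude_logmean, params.amplitude_logsd)
            injected.append((onset, amp * np.cos(ang), amp * np.sin(ang), "baseline"))
        # attentional saccade, direction drawn in the common frame
        if rng.random() < params.response_prob:
            onset = rng.uniform(*params.response_window)
            comp = rng.choice(4, p=params.mixture_weights)
            mu = MIXTURE_MEANS_DEG[comp]
            if mu is None:
                theta = rng.uniform(0.0, 2.0 * np.pi)
            else:
                theta = rng.vonmises(np.radians(mu), params.kappa)
            amp = rng.lognormal(params.amplitude_logmean, params.amplitude_logsd)
            d_common = amp * np.array([np.cos(theta), np.sin(theta)])
            R = common_frame_matrix(meta.past_location, meta.future_location)
            d_screen = R.T @ d_common  # inverse frame transform (orthogonal)
            injected.append(
                (onset, float(d_screen[0]), float(d_screen[1]), MIXTURE_CATEGORIES[comp])
            )

    truth_rows = []
    for onset, dx, dy, category in sorted(injected):
        i0 = int(round(onset - lo))
        if not 0 <= i0 < n:
            continue
        _inject(x, y, i0, dur, dx, dy)
        truth_rows.append(
            {
                "trial_id": meta.trial_id,
                "onset_ms": time[i0],
                "dx_deg": dx,
                "dy_deg": dy,
                "magnitude_deg": float(np.hypot(dx, dy)),
                "category": category,
            }
        )
        if params.return_saccades:
            r0 = i0 + dur + int(round(rng.uniform(*params.return_delay)))
            if r0 < n:
                _inject(x, y, r0, dur, -dx, -dy)
                truth_rows.append(
                    {
                        "trial_id": meta.trial_id,
                        "onset_ms": time[r0],
                        "dx_deg": -dx,
                        "dy_deg": -dy,
                        "magnitude_deg": float(np.hypot(dx, dy)),
                        "category": "return",
                    }
                )

    blink_intervals = []
    if params.blink_rate > 0:
        n_blinks = rng.poisson(params.blink_rate * (n / 1000.0))
        for _ in range(n_blinks):
            b0 = rng.uniform(lo, hi - params.blink_duration[1])
            b_dur = rng.uniform(*params.blink_duration)
            i0 = int(round(b0 - lo))
            i1 = min(n, i0 + int(round(b_dur)) + 1)
            x[i0:i1] = 0.0
            y[i0:i1] = 0.0
            blink_intervals.append((float(time[i0]), float(time[i1 - 1])))

    epoch = GazeEpoch(trial=meta, time=time, x=x, y=y)
    return epoch, truth_rows, blink_intervals


def _draw_trial_meta(trial_id, rule_id, cue_onset, params, rng) -> TrialMeta:
    encoded = rng.choice(sorted(RULES[rule_id]))
    past = LOCATIONS[encoded] * params.eccentricity
    future = LOCATIONS[RULES[rule_id][encoded]] * params.eccentricity
    return TrialMeta(
        trial_id=int(trial_id),
        rule_id=int(rule_id),
        cue_onset=float(cue_onset),
        past_location=past,
        future_location=future,
        encoding_axis=encoding_axis_for_rule(rule_id),
        correct=bool(rng.random() < params.accuracy_p),
        rt=float(rng.lognormal(params.rt_logmean, params.rt_logsd)),
    )


def simulate_session(
    participant_id: str,
    session_id: str,
    rule_id: int,
    params: SimulationParams,
    rng: np.random.Generator,
    n_trials: int | None = None,
    trial_id_start: int = 0,
) -> SessionData:
    """One session: a continuous recording with cue-aligned trials stitched in.

    Trials are laid out with a stride of 3200 ms (3001-sample epoch plus a
    199-sample inter-trial gap of plain fixation noise), cue onsets at
    1000, 4200, ... ms in recording time.
    """
    if n_trials is None:
        n_trials = params.n_trials_per_session
    lo, hi = params.epoch_window
    ep_len = int(round(hi - lo)) + 1
    gap = 199
    stride = ep_len + gap
    total = stride * n_trials
    time = np.arange(total, dtype=float)
    # jitter and drift are continuous across the whole recording
    x, y = _band_limited_jitter(total, params.noise_sd, params.jitter_timescale, rng)
    if params.drift_sd > 0:
        x = x + np.cumsum(rng.normal(0.0, params.drift_sd, total))
        y = y + np.cumsum(rng.normal(0.0, params.drift_sd, total))

    trials, truth_rows, blink_rows = [], [], []
    for i in range(n_trials):
        cue = i * stride - lo  # epoch starts at i*stride
        meta = _draw_trial_meta(trial_id_start + i, rule_id, cue, params, rng)
        seg = slice(i * stride, i * stride + ep_len)
        epoch, rows, blinks = simulate_trial(
            meta, params, rng, background=(x[seg], y[seg])
        )
        x[seg] = epoch.x
        y[seg] = epoch.y
        trials.append(meta)
        truth_rows.extend(rows)
        blink_rows.extend(
            {"trial_id": meta.trial_id, "start_ms": b0, "end_ms": b1} for b0, b1 in blinks
        )
    truth = pd.DataFrame(
        truth_rows,
        columns=["trial_id", "onset_ms", "dx_deg", "dy_deg", "magnitude_deg", "category"],
    )
    blinks = pd.DataFrame(blink_rows, columns=["trial_id", "start_ms", "end_ms"])
    for df in (truth, blinks):
        df.insert(0, "session", session_id)
        df.insert(0, "participant", participant_id)
    recording = GazeRecording(
        participant_id=participant_id,
        session_id=session_id,
        time=time,
        x=x,
        y=y,
    )
    return SessionData(recording, trials, truth, blinks)


def simulate_study(params: SimulationParams | None = None) -> StudyData:
    """Full participant x session x block x trial study with ground truth.

    Future rules are counterbalanced across sessions with the starting
    rule rotated across participants.  Behavioural correctness is
    Bernoulli(``accuracy_p``) and reaction times log-normal.  With a fixed
    seed the output is bit-identical on re-run.
    """
    params = params or SimulationParams()
    ss = np.random.SeedSequence(params.seed)
    children = ss.spawn(params.n_participants * params.n_sessions)
    sessions = []
    behaviour_rows = []
    trial_counter = 0
    for p in range(params.n_participants):
        pid = f"P{p + 1:02d}"
        for s in range(params.n_sessions):
            rule = (p + s) % 4 + 1
            rng = np.random.default_rng(children[p * params.n_sessions + s])
            sess = simulate_session(
                pid, f"S{s + 1}", rule, params, rng, trial_id_start=trial_counter
            )
            trial_counter += len(sess.trials)
            sessions.append(sess)
            behaviour_rows.extend(
                {
                    "participant": pid,
                    "session": f"S{s + 1}",
                    "trial_id": m.trial_id,
                    "rule_id": m.rule_id,
                    "correct": int(m.correct),
                    "rt_ms": m.rt,
                }
                for m in sess.trials
            )
    behaviour = pd.DataFrame(
        behaviour_rows,
        columns=["participant", "session", "trial_id", "rule_id", "correct", "rt_ms"],
    )
    return StudyData(sessions, behaviour, params)


# ---------------------------------------------------------------------------
# analytic expectations of the generative model
# ---------------------------------------------------------------------------


def mixture_quadrant_probabilities(
    weights=None, kappa: float = 8.0, n_grid: int = 200_000
) -> np.ndarray:
    """Exact quadrant probabilities of the attentional direction mixture.

    Returns a 2x2 array in the quadrant-table convention (rows past
    toward/away, columns future toward/away) obtained by integrating the
    mixture density over each quadrant of the common frame.
    """
    if weights is None:
        weights = SimulationParams().mixture_weights
    weights = np.asarray(weights, dtype=float)
    theta = (np.arange(n_grid) + 0.5) * (2.0 * np.pi / n_grid)
    dens = np.zeros(n_grid)
    for w, mu in zip(weights[:3], MIXTURE_MEANS_DEG[:3]):
        mu_r = np.radians(mu)
        dens += w * np.exp(kappa * np.cos(theta - mu_r)) / (2 * np.pi * np.i0(kappa))
    dens += weights[3] / (2.0 * np.pi)
    dens /= dens.sum()
    cos_pos = np.cos(theta) > 0
    sin_pos = np.sin(theta) > 0
    out = np.array(
        [
            [dens[cos_pos & sin_pos].sum(), dens[cos_pos & ~sin_pos].sum()],
            [dens[~cos_pos & sin_pos].sum(), dens[~cos_pos & ~sin_pos].sum()],
        ]
    )
    return out / out.sum()


def expected_first_saccade_quadrants(
    params: SimulationParams,
    n_samples: int = 100_000,
    seed: int = 12345,
    refractory: float = 100.0,
) -> np.ndarray:
    """Monte-Carlo expectation of the first-start-saccade quadrant table.

    Replays the event-level generative model (baseline Poisson starts with
    their returns, the attentional saccade, onset-to-onset refractory
    suppression) without generating traces, assuming an ideal detector and
    start/return classifier.  Returns the 2x2 quadrant probabilities of
    the first start saccade in the response window, conditional on one
    existing.  This refines :func:`first_saccade_quadrant_probabilities`,
    which ignores refractory interactions.
    """
    rng = np.random.default_rng(seed)
    lo, hi = params.epoch_window
    span_lo, span_hi = lo, hi - 400.0
    lam = params.base_saccade_rate
    w0, w1 = params.response_window
    dur = params.saccade_duration
    q_counts = np.zeros((2, 2))
    weights = np.asarray(params.mixture_weights)
    for _ in range(n_samples):
        events = []  # (onset, is_start, is_attentional)
        n_base = rng.poisson(lam * (span_hi - span_lo) / 1000.0)
        for _b in range(n_base):
            onset = rng.uniform(span_lo, span_hi)
            events.append((onset, True, False))
            if params.return_saccades:
                events.append((onset + dur + rng.uniform(*params.return_delay), False, False))
        att_onset = None
        if rng.random() < params.response_prob:
            att_onset = rng.uniform(w0, w1)
            events.append((att_onset, True, True))
            if params.return_saccades:
                events.append(
                    (att_onset + dur + rng.uniform(*params.return_delay), False, False)
                )
        events.sort()
        first = None
        last_accepted = -np.inf
        for onset, is_start, is_att in events:
            if onset - last_accepted < refractory:
                continue
            last_accepted = onset
            if is_start and w0 <= onset <= w1:
                first = (onset, is_att)
                break
        if first is None:
            continue
        if first[1]:
            comp = rng.choice(4, p=weights)
            mu = MIXTURE_MEANS_DEG[comp]
            theta = (
                rng.uniform(0.0, 2.0 * np.pi)
                if mu is None
                else rng.vonmises(np.radians(mu), params.kappa)
            )
        else:
            theta = rng.uniform(0.0, 2.0 * np.pi)
        i = 0 if np.cos(theta) > 0 else 1
        j = 0 if np.sin(theta) > 0 else 1
        q_counts[i, j] += 1
    return q_counts / q_counts.sum()


def first_saccade_quadrant_probabilities(params: SimulationParams) -> np.ndarray:
    """Expected quadrant probabilities of the *first* start saccade in the window.

    The first start saccade in the response window is the attentional one
    unless a baseline shift happens to precede it.  With baseline rate
    ``lam`` (Hz), window length ``W`` (s), response probability ``r`` and
    the attentional onset uniform over the window, the chance that no
    baseline shift precedes the attentional one is
    ``g = (1 - exp(-lam W)) / (lam W)``, so conditional on any first
    saccade existing the quadrant distribution is the corresponding
    mixture of the attentional-direction quadrants and the uniform 1/4.
    (First-order: ignores refractory suppression by pre-window events,
    which :func:`expected_first_saccade_quadrants` captures.)
    """
    lam = params.base_saccade_rate
    w0, w1 = params.response_window
    W = (w1 - w0) / 1000.0
    r = params.response_prob
    if lam == 0:
        g = 1.0
        p_any_base = 0.0
    else:
        g = (1.0 - math.exp(-lam * W)) / (lam * W)
        p_any_base = 1.0 - math.exp(-lam * W)
    p_att = r * g
    p_base = r * (1.0 - g) + (1.0 - r) * p_any_base
    p_exists = p_att + p_base
    q_mix = mixture_quadrant_probabilities(params.mixture_weights, params.kappa)
    return (p_att * q_mix + p_base * 0.25) / p_exists
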