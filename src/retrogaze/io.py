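"""Reading, blink masking and epoching of gaze recordings.

Gaze is processed in visual degrees throughout; any pixel-to-degree
calibration is an input-preparation concern and happens before data enter
the pipeline.  Missing samples (blinks, tracking loss) are represented as
NaN.  Time is in milliseconds on an integer grid at the native sampling
rate (1000 Hz by default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GazeRecording",
    "TrialMeta",
    "GazeEpoch",
    "GazeIOError",
    "ReferenceUnavailableError",
    "EpochBoundsError",
    "load_gaze_table",
    "load_gaze_tables",
    "load_trial_table",
    "write_gaze_table",
    "write_trial_table",
    "mask_blinks",
    "epoch_trials",
    "fixation_reference",
    "epochs_to_frame",
    "frame_to_epochs",
]


class GazeIOError(ValueError):
    """Malformed or inconsistent gaze/trial input."""


class ReferenceUnavailableError(ValueError):
    """No valid samples to compute a fixation reference; trial is excluded."""


class EpochBoundsError(ValueError):
    """Requested epoch window falls outside the recording."""


@dataclass
class GazeRecording:
    """A continuous single-eye gaze trace for one participant and session.

    Parameters
    ----------
    participant_id, session_id
        Free-form labels.
    time
        Sample times in ms, strictly increasing.
    x, y
        Gaze position in visual degrees relative to the fixation dot at the
        screen centre; NaN marks missing samples.
    sampling_rate
        Samples per second (default 1000).
    """

    participant_id: str
    session_id: str
    time: np.ndarray
    x: np.ndarray
    y: np.ndarray
    sampling_rate: float = 1000.0

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (len(self.time) == len(self.x) == len(self.y)):
            raise GazeIOError("time, x, y must have equal length")
        if self.sampling_rate <= 0:
            raise GazeIOError("sampling_rate must be positive")
        dt = np.diff(self.time)
        if np.any(dt <= 0):
            i = int(np.argmax(dt <= 0))
            raise GazeIOError(
                f"timestamps not strictly increasing at sample {i + 1} "
                f"(t={self.time[i + 1]:g} after t={self.time[i]:g})"
            )

    @property
    def n_samples(self) -> int:
        return len(self.time)


@dataclass
class TrialMeta:
    """Task structure for one trial.

    ``past_location`` is where the cued item was encoded;
    ``future_location`` is where it will be tested, as dictated by the
    session's future rule.  The task design places both at the same
    eccentricity on orthogonal axes.
    """

    trial_id: int
    rule_id: int
    cue_onset: float  # ms, in recording time
    past_location: np.ndarray  # (x, y) degrees
    future_location: np.ndarray  # (x, y) degrees
    encoding_axis: str = "vertical"
    correct: bool | None = None
    rt: float | None = None

    def __post_init__(self) -> None:
        self.past_location = np.asarray(self.past_location, dtype=float)
        self.future_location = np.asarray(self.future_location, dtype=float)

    def validate(self, atol: float = 1e-6) -> None:
        """Check the task-design invariants (orthogonal, nonzero locations)."""
        if self.rule_id not in (1, 2, 3, 4):
            raise GazeIOError(f"trial {self.trial_id}: invalid rule_id {self.rule_id}")
        np_, nf = np.linalg.norm(self.past_location), np.linalg.norm(self.future_location)
        if np_ == 0 or nf == 0:
            raise GazeIOError(f"trial {self.trial_id}: zero-length item location")
        if abs(float(self.past_location @ self.future_location)) > atol * np_ * nf:
            raise GazeIOError(
                f"trial {self.trial_id}: past and future locations not orthogonal"
            )


@dataclass
class GazeEpoch:
    """One trial's cue-aligned gaze trace.

    ``time`` is in ms relative to retro-cue onset; NaNs mark missing samples.
    """

    trial: TrialMeta
    time: np.ndarray
    x: np.ndarray
    y: np.ndarray
    participant_id: str = ""
    session_id: str = ""

    @property
    def n_samples(self) -> int:
        return len(self.time)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

GAZE_COLUMNS = ["participant", "session", "time_ms", "x_deg", "y_deg"]
TRIAL_COLUMNS = [
    "participant",
    "session",
    "trial_id",
    "rule_id",
    "cue_onset_ms",
    "past_x",
    "past_y",
    "future_x",
    "future_y",
    "correct",
    "rt_ms",
]


def _sniff_delimiter(path) -> str:
    with open(path) as fh:
        header = fh.readline()
    for cand in ("\t", ",", ";"):
        if cand in header:
            return cand
    return r"\s+"


def _read_table(path, required):
    sep = _sniff_delimiter(path)
    kwargs = {"float_precision": "round_trip"} if sep != r"\s+" else {"engine": "python"}
    try:
        # the round_trip parser preserves float64 values exactly
        df = pd.read_csv(path, sep=sep, **kwargs)
    except Exception as exc:  # pragma: no cover - passthrough of pandas message
        raise GazeIOError(f"could not parse {path}: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise GazeIOError(f"{path}: missing columns {missing}")
    return df


def _parse_asc_minimal(path) -> pd.DataFrame:
    """Parse the minimal EyeLink ASC sample-line dialect.

    Sample lines are ``<time> <x> <y> <pupil>`` with whitespace separation;
    lines whose first token is not numeric (tracker events, messages) are
    ignored.  Missing-data dots (``.``) become NaN.
    """
    times, xs, ys = [], [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            try:
                t = float(parts[0])
            except ValueError:
                continue  # event/message line
            if len(parts) < 3:
                raise GazeIOError(f"{path}:{lineno}: sample line has <3 fields")
            def _val(tok):
                return np.nan if tok == "." else float(tok)
            try:
                xv, yv = _val(parts[1]), _val(parts[2])
            except ValueError as exc:
                raise GazeIOError(f"{path}:{lineno}: malformed sample line") from exc
            times.append(t)
            xs.append(xv)
            ys.append(yv)
    return pd.DataFrame({"time_ms": times, "x_deg": xs, "y_deg": ys})


def load_gaze_table(
    path,
    dialect: str = "tabular",
    participant_id: str | None = None,
    session_id: str | None = None,
    sampling_rate: float = 1000.0,
) -> GazeRecording:
    """Load a single-recording gaze file.

    ``dialect='tabular'`` expects delimiter-separated columns
    ``participant, session, time_ms, x_deg, y_deg`` (a single participant and
    session per file); ``dialect='asc-minimal'`` expects EyeLink ASC sample
    lines ``<time> <x> <y> <pupil>``.

    Raises
    ------
    GazeIOError
        On malformed rows, duplicate or out-of-order timestamps, or if a
        tabular file contains more than one participant/session.
    """
    if dialect == "asc-minimal":
        df = _parse_asc_minimal(path)
        pid = participant_id or "asc"
        sid = session_id or "0"
    elif dialect == "tabular":
        df = _read_table(path, ["time_ms", "x_deg", "y_deg"])
        if "participant" in df.columns:
            pids = df["participant"].astype(str).unique()
            sids = df["session"].astype(str).unique() if "session" in df.columns else ["0"]
            if len(pids) > 1 or len(sids) > 1:
                raise GazeIOError(
                    f"{path}: multiple recordings in file; use load_gaze_tables"
                )
            pid, sid = pids[0], str(sids[0])
        else:
            pid = participant_id or "unknown"
            sid = session_id or "0"
    else:
        raise GazeIOError(f"unknown dialect {dialect!r}")
    t = df["time_ms"].to_numpy(dtype=float)
    if len(t) and np.any(np.diff(t) == 0):
        raise GazeIOError(f"{path}: duplicate timestamps")
    return GazeRecording(
        participant_id=str(pid),
        session_id=str(sid),
        time=t,
        x=df["x_deg"].to_numpy(dtype=float),
        y=df["y_deg"].to_numpy(dtype=float),
        sampling_rate=sampling_rate,
    )


def load_gaze_tables(path, sampling_rate: float = 1000.0) -> list[GazeRecording]:
    """Load a tabular gaze file holding one or more (participant, session) recordings."""
    df = _read_table(path, GAZE_COLUMNS)
    out = []
    for (pid, sid), grp in df.groupby(["participant", "session"], sort=True):
        t = grp["time_ms"].to_numpy(dtype=float)
        if np.any(np.diff(t) == 0):
            raise GazeIOError(f"{path}: duplicate timestamps for {pid}/{sid}")
        out.append(
            GazeRecording(
                participant_id=str(pid),
                session_id=str(sid),
                time=t,
                x=grp["x_deg"].to_numpy(dtype=float),
                y=grp["y_deg"].to_numpy(dtype=float),
                sampling_rate=sampling_rate,
            )
        )
    return out


def write_gaze_table(recordings, path) -> None:
    """Write recordings as long-format delimiter-separated text (round-trips exactly)."""
    if isinstance(recordings, GazeRecording):
        recordings = [recordings]
    frames = []
    for rec in recordings:
        frames.append(
            pd.DataFrame(
                {
                    "participant": rec.participant_id,
                    "session": rec.session_id,
                    "time_ms": rec.time,
                    "x_deg": rec.x,
                    "y_deg": rec.y,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(
        path, sep="\t", index=False, float_format="%.17g"
    )


def load_trial_table(path, validate: bool = True) -> pd.DataFrame:
    """Load trial metadata; returns a DataFrame with a ``meta`` column of TrialMeta.

    Expected columns: ``trial_id, rule_id, cue_onset_ms, past_x, past_y,
    future_x, future_y, correct, rt_ms`` plus optional ``participant`` and
    ``session``.
    """
    df = _read_table(
        path,
        ["trial_id", "rule_id", "cue_onset_ms", "past_x", "past_y", "future_x", "future_y"],
    )
    metas = []
    for _, row in df.iterrows():
        past = np.array([row["past_x"], row["past_y"]], dtype=float)
        future = np.array([row["future_x"], row["future_y"]], dtype=float)
        axis = "vertical" if abs(past[1]) >= abs(past[0]) else "horizontal"
        meta = TrialMeta(
            trial_id=int(row["trial_id"]),
            rule_id=int(row["rule_id"]),
            cue_onset=float(row["cue_onset_ms"]),
            past_location=past,
            future_location=future,
            encoding_axis=axis,
            correct=bool(row["correct"]) if "correct" in df.columns else None,
            rt=float(row["rt_ms"]) if "rt_ms" in df.columns else None,
        )
        if validate:
            meta.validate()
        metas.append(meta)
    df = df.copy()
    df["meta"] = metas
    return df


def write_trial_table(trials, path, participant_id: str = "", session_id: str = "") -> None:
    """Write a list of :class:`TrialMeta` as delimiter-separated text."""
    rows = []
    for m in trials:
        rows.append(
            {
                "participant": participant_id,
                "session": session_id,
                "trial_id": m.trial_id,
                "rule_id": m.rule_id,
                "cue_onset_ms": m.cue_onset,
                "past_x": m.past_location[0],
                "past_y": m.past_location[1],
                "future_x": m.future_location[0],
                "future_y": m.future_location[1],
                "correct": int(m.correct) if m.correct is not None else "",
                "rt_ms": m.rt if m.rt is not None else "",
            }
        )
    pd.DataFrame(rows, columns=TRIAL_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# pre-processing
# ---------------------------------------------------------------------------


def mask_blinks(rec: GazeRecording, pad: float = 100.0, zero_tol: float = 0.0) -> GazeRecording:
    """Mask blink artefacts recorded as zero-valued clusters.

    Eye trackers report (0, 0) gaze coordinates while the pupil is lost
    during a blink.  Every maximal run of samples with ``|x| <= zero_tol``
    and ``|y| <= zero_tol`` simultaneously is expanded by ``pad`` ms on both
    sides and set to NaN, removing residual artefacts from lid closure and
    re-opening.  All other samples are unchanged; the operation is
    idempotent (NaN samples never match the zero criterion again).
    """
    if pad < 0:
        raise ValueError("pad must be >= 0")
    x = rec.x.copy()
    y = rec.y.copy()
    with np.errstate(invalid="ignore"):
        zero = (np.abs(rec.x) <= zero_tol) & (np.abs(rec.y) <= zero_tol)
    if zero.any():
        t = rec.time
        idx = np.flatnonzero(zero)
        # maximal runs of consecutive indices
        breaks = np.flatnonzero(np.diff(idx) > 1)
        starts = np.concatenate(([0], breaks + 1))
        ends = np.concatenate((breaks, [len(idx) - 1]))
        mask = np.zeros(rec.n_samples, dtype=bool)
        for s, e in zip(starts, ends):
            lo = t[idx[s]] - pad
            hi = t[idx[e]] + pad
            mask |= (t >= lo) & (t <= hi)
        x[mask] = np.nan
        y[mask] = np.nan
    return GazeRecording(
        participant_id=rec.participant_id,
        session_id=rec.session_id,
        time=rec.time,
        x=x,
        y=y,
        sampling_rate=rec.sampling_rate,
    )


def epoch_trials(
    rec: GazeRecording,
    trials,
    window: tuple[float, float] = (-1000.0, 2000.0),
) -> list[GazeEpoch]:
    """Cut cue-aligned epochs out of a continuous recording.

    The epoch covers ``cue_onset + window[0]`` to ``cue_onset + window[1]``,
    endpoints inclusive.  Sample values are copied and missingness is
    preserved.  A trial whose window is not fully covered by the recording
    raises :class:`EpochBoundsError` naming the trial.
    """
    lo, hi = window
    if hi <= lo:
        raise ValueError("window must be increasing")
    dt = 1000.0 / rec.sampling_rate
    n_expected = int(round((hi - lo) / dt)) + 1
    epochs = []
    for meta in trials:
        t0 = meta.cue_onset + lo
        t1 = meta.cue_onset + hi
        i0 = int(np.searchsorted(rec.time, t0 - dt / 4, side="left"))
        i1 = int(np.searchsorted(rec.time, t1 + dt / 4, side="right"))
        seg = slice(i0, i1)
        if i1 - i0 != n_expected:
            raise EpochBoundsError(
                f"trial {meta.trial_id}: epoch [{t0:g}, {t1:g}] ms not fully "
                f"covered by recording ({i1 - i0} of {n_expected} samples)"
            )
        epochs.append(
            GazeEpoch(
                trial=meta,
                time=rec.time[seg] - meta.cue_onset,
                x=rec.x[seg].copy(),
                y=rec.y[seg].copy(),
                participant_id=rec.participant_id,
                session_id=rec.session_id,
            )
        )
    return epochs


def fixation_reference(
    epoch: GazeEpoch, window: tuple[float, float] = (-800.0, -200.0)
) -> np.ndarray:
    """Median gaze position in the pre-cue fixation period.

    The component-wise median over non-missing samples in ``window``
    (endpoints inclusive) defines where this trial's gaze rested at
    fixation; it anchors the start/return saccade classification and is
    robust to brief excursions.  Raises
    :class:`ReferenceUnavailableError` when the window holds no valid
    sample (the trial is then excluded downstream, not imputed).
    """
    sel = (epoch.time >= window[0]) & (epoch.time <= window[1])
    xs = epoch.x[sel]
    ys = epoch.y[sel]
    valid = ~(np.isnan(xs) | np.isnan(ys))
    if not valid.any():
        raise ReferenceUnavailableError(
            f"trial {epoch.trial.trial_id}: no valid samples in fixation window"
        )
    return np.array([np.median(xs[valid]), np.median(ys[valid])])


# ---------------------------------------------------------------------------
# epoch caching
# ---------------------------------------------------------------------------


def epochs_to_frame(epochs) -> pd.DataFrame:
    """Serialise epochs to a single long-format table for caching."""
    frames = []
    for ep in epochs:
        frames.append(
            pd.DataFrame(
                {
                    "participant": ep.participant_id,
                    "session": ep.session_id,
                    "trial_id": ep.trial.trial_id,
                    "time_ms": ep.time,
                    "x_deg": ep.x,
                    "y_deg": ep.y,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def frame_to_epochs(df: pd.DataFrame, trials_by_id: dict) -> list[GazeEpoch]:
    """Rebuild epochs from :func:`epochs_to_frame` output given trial metadata."""
    out = []
    for (pid, sid, tid), grp in df.groupby(
        ["participant", "session", "trial_id"], sort=True
    ):
        out.append(
            GazeEpoch(
                trial=trials_by_id[int(tid)],
                time=grp["time_ms"].to_numpy(dtype=float),
                x=grp["x_deg"].to_numpy(dtype=float),
                y=grp["y_deg"].to_numpy(dtype=float),
                participant_id=str(pid),
                session_id=str(sid),
            )
        )
    return out
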