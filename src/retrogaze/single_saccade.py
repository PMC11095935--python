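"""Single-saccade analysis in the rotated common frame.

Because the future rule counterbalances the geometry across sessions, the
first post-cue start saccade of every trial is rotated into a common
coordinate system in which the past (encoded) location lies at 0 degrees
(rightward = toward past) and the future (to-be-tested) location at 90
degrees (upward = toward future).  In this frame the joint past+future
bias shows up as an excess of saccades in the upper-right quadrant, which
the 2x2 quadrant table quantifies per participant.

For two of the four rules the past/future pair is left-handed, so the
common-frame transform necessarily includes a reflection.  This is applied
silently: the analysis concerns toward/away components, not rotational
handedness, and a pure rotation cannot map all four rules onto one frame.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .detect import SaccadeEvent

logger = logging.getLogger(__name__)

__all__ = [
    "AngularParams",
    "RotatedSaccade",
    "QuadrantTable",
    "first_start_saccade",
    "rotate_to_common_frame",
    "common_frame_matrix",
    "angular_distribution",
    "conditional_bias_profile",
    "quadrant_percentages",
    "quadrant_frame",
]

QUADRANT_LABELS = [
    ("toward", "toward"),
    ("toward", "away"),
    ("away", "toward"),
    ("away", "away"),
]  # (past, future)


@dataclass
class AngularParams:
    """Selection window and overlapping angular-bin settings.

    selection_window : (ms, ms)
        Post-cue window (endpoints inclusive) in which the first start
        saccade is taken; 200-600 ms is where attention-driven
        microsaccade biases are expressed.
    bin_width, bin_step : degrees
        Overlapping angular bins: a saccade contributes to every bin centre
        within ``bin_width / 2`` (circular distance, inclusive).
    """

    selection_window: tuple[float, float] = (200.0, 600.0)
    bin_width: float = 20.0
    bin_step: float = 1.0

    def __post_init__(self) -> None:
        if self.bin_width <= 0 or self.bin_step <= 0:
            raise ValueError("bin_width and bin_step must be > 0")

    def bin_centres(self) -> np.ndarray:
        return np.arange(0.0, 360.0, self.bin_step)


@dataclass
class RotatedSaccade:
    """A saccade in the common frame: 0 deg = toward past, 90 deg = toward future."""

    trial_id: int
    direction_common: float  # degrees in [0, 360)
    magnitude: float
    displacement_common: np.ndarray


@dataclass
class QuadrantTable:
    """Per-participant 2x2 percentages of first saccades.

    ``pct[i, j]``: rows index past (0 toward, 1 away), columns future
    (0 toward, 1 away).  Entries sum to 100 up to axis-aligned exclusions.
    """

    participant_id: str
    pct: np.ndarray  # shape (2, 2)
    n_saccades: int = 0

    def as_dict(self) -> dict:
        return {
            f"past_{p}_future_{f}": float(self.pct[i // 2, i % 2])
            for i, (p, f) in enumerate(QUADRANT_LABELS)
        }


def first_start_saccade(trial_events, params: AngularParams | None = None):
    """Earliest start saccade with onset inside the selection window, else None."""
    params = params or AngularParams()
    lo, hi = params.selection_window
    best = None
    for ev in trial_events:
        if ev.is_start and lo <= ev.onset <= hi:
            if best is None or ev.onset < best.onset:
                best = ev
    return best


def common_frame_matrix(past, future, fixref=(0.0, 0.0), atol: float = 1e-8) -> np.ndarray:
    """Orthogonal matrix mapping unit(past-fixref) to (1,0) and unit(future-fixref) to (0,1).

    ``past`` and ``future`` are the task-defined item locations; they must
    be orthogonal about the fixation point (the task design guarantees
    this, and a violation raises).  The transform is a rotation or, for
    left-handed rules, a rotation composed with a reflection; either way
    it is an isometry.
    """
    p = np.asarray(past, dtype=float) - np.asarray(fixref, dtype=float)
    f = np.asarray(future, dtype=float) - np.asarray(fixref, dtype=float)
    np_, nf = np.linalg.norm(p), np.linalg.norm(f)
    if np_ == 0 or nf == 0:
        raise ValueError("past/future location coincides with fixation")
    u = p / np_
    v = f / nf
    if abs(float(u @ v)) > atol:
        raise ValueError("past and future axes are not orthogonal")
    return np.vstack([u, v])


def rotate_to_common_frame(
    event: SaccadeEvent, past, future, fixref=(0.0, 0.0)
) -> RotatedSaccade:
    """Express a saccade's displacement in the common past-right/future-up frame."""
    R = common_frame_matrix(past, future, fixref)
    d = R @ event.displacement
    direction = float(np.degrees(np.arctan2(d[1], d[0])) % 360.0)
    return RotatedSaccade(event.trial_id, direction, float(np.hypot(*d)), d)


def _circular_distance(a, b):
    return np.abs((np.asarray(a) - np.asarray(b) + 180.0) % 360.0 - 180.0)


def angular_distribution(rotated, params: AngularParams | None = None):
    """Proportion of saccades per overlapping angular bin.

    For every centre c (0, step, 2*step, ... < 360) the proportion of
    saccades whose circular distance to c is at most ``bin_width / 2``.
    Because bins overlap, the proportions sum to about
    ``bin_width / bin_step`` (exactly, for saccades not on a bin boundary).

    Returns ``(centres, proportions)``.  Raises on empty input.
    """
    params = params or AngularParams()
    dirs = np.asarray(
        [r.direction_common if isinstance(r, RotatedSaccade) else float(r) for r in rotated],
        dtype=float,
    )
    if dirs.size == 0:
        raise ValueError("no saccades")
    centres = params.bin_centres()
    half = params.bin_width / 2.0
    d = _circular_distance(dirs[:, None], centres[None, :])
    prop = (d <= half).sum(axis=0) / dirs.size
    return centres, prop


def conditional_bias_profile(rotated, reference: str, params: AngularParams | None = None):
    """Signed toward-minus-away bias as a function of saccade angle.

    With ``reference='past'`` the profile gives, at each angle ``psi`` from
    the future axis, the difference between the proportion of saccades on
    the toward-past side (common direction ``90 - psi``) and the mirrored
    away-past direction (``90 + psi``): positive values mean a past bias
    among saccades at that angle relative to the future location.
    ``reference='future'`` mirrors across the past axis instead
    (``psi`` measured from the past axis; ``psi`` vs ``-psi``).

    Returns ``(psi, bias)`` with ``psi`` spanning -180..180 (exclusive of
    -180) in steps of ``bin_step``; the profile is antisymmetric in ``psi``.
    """
    params = params or AngularParams()
    centres, p = angular_distribution(rotated, params)
    lookup = dict(zip(np.round(centres, 9) % 360.0, p))

    def p_at(angle):
        return lookup[round(angle % 360.0, 9)]

    psi = np.arange(-180.0 + params.bin_step, 180.0 + params.bin_step / 2, params.bin_step)
    if reference == "past":
        bias = np.array([p_at(90.0 - a) - p_at(90.0 + a) for a in psi])
    elif reference == "future":
        bias = np.array([p_at(a) - p_at(-a) for a in psi])
    else:
        raise ValueError("reference must be 'past' or 'future'")
    return psi, bias


def _quadrant(d: np.ndarray):
    """Quadrant index of a common-frame displacement, or None on an axis."""
    if d[0] == 0.0 or d[1] == 0.0:
        return None
    i = 0 if d[0] > 0 else 1  # past: toward/away
    j = 0 if d[1] > 0 else 1  # future: toward/away
    return i, j


def quadrant_percentages(rotated_by_participant: dict) -> list[QuadrantTable]:
    """Binarised 2x2 quadrant percentages, one table per participant.

    ``rotated_by_participant`` maps participant label to its list of
    :class:`RotatedSaccade` first saccades.  Saccades exactly on an axis
    are excluded and logged; participants with no qualifying saccade are
    excluded with a warning.
    """
    tables = []
    for pid, saccades in rotated_by_participant.items():
        counts = np.zeros((2, 2))
        excluded = 0
        for r in saccades:
            q = _quadrant(r.displacement_common)
            if q is None:
                excluded += 1
                continue
            counts[q] += 1
        n = counts.sum()
        if excluded:
            logger.info("participant %s: %d axis-aligned saccades excluded", pid, excluded)
        if n == 0:
            logger.warning("participant %s: no qualifying first saccades; excluded", pid)
            continue
        tables.append(QuadrantTable(str(pid), 100.0 * counts / n, int(n)))
    return tables


def quadrant_frame(tables) -> pd.DataFrame:
    """Long-format export of quadrant tables (one row per participant x cell)."""
    rows = []
    for t in tables:
        for i, past in enumerate(("toward", "away")):
            for j, future in enumerate(("toward", "away")):
                rows.append(
                    {
                        "participant": t.participant_id,
                        "past": past,
                        "future": future,
                        "pct": float(t.pct[i, j]),
                        "n_saccades": t.n_saccades,
                    }
                )
    return pd.DataFrame(rows, columns=["participant", "past", "future", "pct", "n_saccades"])
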