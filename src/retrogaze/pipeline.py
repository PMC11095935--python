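"""End-to-end orchestration: preprocessing -> detection -> bias analyses -> stats.

``run_pipeline`` executes the full analysis on either simulated or loaded
data and returns a report dictionary; when given an output directory it
also writes all intermediate tables, the per-participant difference
curves, and a JSON/text report embedding the seed and a hash of the
configuration so that a run can be reproduced exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import io as gio
from .detect import DetectionParams, detect_epoch, events_to_frame
from .io import ReferenceUnavailableError
from .simulate import SimulationParams, StudyData, simulate_study
from .single_saccade import (
    AngularParams,
    first_start_saccade,
    quadrant_frame,
    quadrant_percentages,
    rotate_to_common_frame,
)
from .stats import (
    PermutationParams,
    cluster_permutation_test,
    paired_t_bonferroni,
    rm_anova_2x2,
)
from .timecourse import (
    TimecourseParams,
    classify_direction,
    shift_rate_timecourse,
    toward_minus_away,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "StageError"]


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage and trial context."""


@dataclass
class PipelineConfig:
    """All pipeline settings in one place; defaults follow the study analysis."""

    seed: int = 0
    blink_pad: float = 100.0
    epoch_window: tuple[float, float] = (-1000.0, 2000.0)
    fixation_window: tuple[float, float] = (-800.0, -200.0)
    run_cluster_tests: bool = True
    detection: DetectionParams = field(default_factory=DetectionParams)
    timecourse: TimecourseParams = field(default_factory=TimecourseParams)
    angular: AngularParams = field(default_factory=AngularParams)
    permutation: PermutationParams = field(default_factory=PermutationParams)
    simulation: SimulationParams = field(default_factory=SimulationParams)
    gaze_path: str | None = None
    trials_path: str | None = None

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        kwargs = dict(d)
        for key, sub in (
            ("detection", DetectionParams),
            ("timecourse", TimecourseParams),
            ("angular", AngularParams),
            ("permutation", PermutationParams),
            ("simulation", SimulationParams),
        ):
            if key in kwargs and isinstance(kwargs[key], dict):
                sub_kwargs = {
                    k: tuple(v) if isinstance(v, list) else v
                    for k, v in kwargs[key].items()
                }
                kwargs[key] = sub(**sub_kwargs)
        for key in ("epoch_window", "fixation_window"):
            if key in kwargs and isinstance(kwargs[key], list):
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(_jsonable(self.to_dict()), fh, sort_keys=True)


@dataclass
class TrialResult:
    meta: object
    fixref: np.ndarray | None
    events: list
    included: bool
    reason: str = ""


def process_session(recording, trials, config: PipelineConfig) -> list[TrialResult]:
    """Blink masking, epoching, fixation reference and detection for one session."""
    masked = gio.mask_blinks(recording, pad=config.blink_pad)
    epochs = gio.epoch_trials(masked, trials, window=config.epoch_window)
    results = []
    for epoch in epochs:
        try:
            fixref = gio.fixation_reference(epoch, window=config.fixation_window)
        except ReferenceUnavailableError as exc:
            logger.warning("%s", exc)
            results.append(TrialResult(epoch.trial, None, [], False, "no-fixation-reference"))
            continue
        events = detect_epoch(epoch, fixref, config.detection)
        valid = np.count_nonzero(~(np.isnan(epoch.x) | np.isnan(epoch.y)))
        if valid < config.detection.min_valid_samples:
            results.append(TrialResult(epoch.trial, fixref, [], False, "too-few-valid-samples"))
            continue
        results.append(TrialResult(epoch.trial, fixref, events, True))
    return results


def _participant_difference_curves(trial_results, config):
    """Toward-minus-away rate curves (past and future reference) for one participant."""
    included = [tr for tr in trial_results if tr.included]
    n_trials = len(included)
    curves = {}
    if n_trials == 0:
        return None
    for reference in ("past", "future"):
        onsets = {"toward": [], "away": []}
        for tr in included:
            target = (
                tr.meta.past_location if reference == "past" else tr.meta.future_location
            )
            for ev in tr.events:
                if not ev.is_start:
                    continue
                cls = classify_direction(ev, target, tr.fixref)
                if cls in onsets:
                    onsets[cls].append(ev.onset)
        tc_t = shift_rate_timecourse(
            onsets["toward"], n_trials, config.timecourse, "toward", reference
        )
        tc_a = shift_rate_timecourse(
            onsets["away"], n_trials, config.timecourse, "away", reference
        )
        curves[reference] = toward_minus_away(tc_t, tc_a)
    return curves


def analyse_study(trial_results_by_participant: dict, config: PipelineConfig) -> dict:
    """Group-level analyses given per-participant per-trial detection results."""
    report: dict = {}

    # --- time courses + cluster statistics -------------------------------
    diff_matrices = {"past": [], "future": []}
    time_axis = None
    curve_rows = []
    for pid, trial_results in trial_results_by_participant.items():
        curves = _participant_difference_curves(trial_results, config)
        if curves is None:
            continue
        for reference, tc in curves.items():
            diff_matrices[reference].append(tc.rate)
            time_axis = tc.time
            curve_rows.append(
                pd.DataFrame(
                    {
                        "participant": pid,
                        "reference": reference,
                        "time_ms": tc.time,
                        "rate_hz": tc.rate,
                    }
                )
            )
    report["curves"] = pd.concat(curve_rows, ignore_index=True) if curve_rows else pd.DataFrame()

    report["cluster_tests"] = {}
    if config.run_cluster_tests:
        for reference, mat in diff_matrices.items():
            if len(mat) < 2:
                report["cluster_tests"][reference] = "skipped: fewer than 2 participants"
                continue
            res = cluster_permutation_test(
                np.vstack(mat),
                config.permutation,
                times=time_axis,
            )
            report["cluster_tests"][reference] = {
                "threshold_t": res.threshold,
                "n_perm": res.n_perm,
                "seed": res.seed,
                "clusters": [
                    {
                        "start_ms": c.start,
                        "end_ms": c.end,
                        "mass": c.mass,
                        "p": c.p,
                        "sign": c.sign,
                    }
                    for c in res.clusters
                ],
            }

    # --- single-saccade quadrant analysis --------------------------------
    rotated_by_participant = {}
    first_rows = []
    for pid, trial_results in trial_results_by_participant.items():
        rotated = []
        for tr in trial_results:
            if not tr.included:
                continue
            ev = first_start_saccade(tr.events, config.angular)
            if ev is None:
                continue
            rot = rotate_to_common_frame(
                ev, tr.meta.past_location, tr.meta.future_location
            )
            rotated.append(rot)
            first_rows.append(
                {
                    "participant": pid,
                    "trial_id": ev.trial_id,
                    "onset_ms": ev.onset,
                    "direction_common_deg": rot.direction_common,
                    "magnitude_deg": rot.magnitude,
                }
            )
        rotated_by_participant[pid] = rotated
    report["first_saccades"] = pd.DataFrame(
        first_rows,
        columns=["participant", "trial_id", "onset_ms", "direction_common_deg", "magnitude_deg"],
    )

    tables = quadrant_percentages(rotated_by_participant)
    report["quadrant_tables"] = tables
    if len(tables) >= 2:
        anova = rm_anova_2x2(tables)
        report["anova"] = {
            k: {
                "F": v.F,
                "df": list(v.df),
                "p": v.p,
                "partial_eta_sq": v.partial_eta_sq,
            }
            for k, v in anova.items()
        }
        pct = np.array([t.pct for t in tables])  # (n, 2, 2)
        followups = {}
        for i, label in enumerate(("past_toward", "past_away")):
            try:
                res = paired_t_bonferroni(pct[:, i, 0], pct[:, i, 1], m=2)
                followups[label] = {
                    "t": res.t,
                    "df": res.df,
                    "p_bonferroni": res.p_corrected,
                    "cohen_d": res.cohen_d,
                }
            except ValueError as exc:
                followups[label] = f"skipped: {exc}"
        report["followup_t_tests"] = followups
    else:
        report["anova"] = "skipped: fewer than 2 participants with quadrant data"
        report["followup_t_tests"] = {}

    # --- exclusions -------------------------------------------------------
    tally: Counter = Counter()
    for trial_results in trial_results_by_participant.values():
        for tr in trial_results:
            tally[tr.reason if not tr.included else "included"] += 1
    report["trial_tally"] = dict(tally)
    return report


def study_quadrant_tables(study, config: PipelineConfig | None = None):
    """Run preprocessing + detection + first-saccade rotation on a study and
    return the per-participant quadrant tables (the input to the 2x2 ANOVA)."""
    config = config or PipelineConfig()
    rotated_by_participant: dict[str, list] = {}
    for sess in study.sessions:
        results = process_session(sess.recording, sess.trials, config)
        rotated = rotated_by_participant.setdefault(sess.recording.participant_id, [])
        for tr in results:
            if not tr.included:
                continue
            ev = first_start_saccade(tr.events, config.angular)
            if ev is None:
                continue
            rotated.append(
                rotate_to_common_frame(ev, tr.meta.past_location, tr.meta.future_location)
            )
    return quadrant_percentages(rotated_by_participant)


def _load_study(config: PipelineConfig):
    recordings = gio.load_gaze_tables(config.gaze_path)
    trial_df = gio.load_trial_table(config.trials_path)
    sessions = []
    for rec in recordings:
        if "participant" in trial_df.columns:
            sel = (trial_df["participant"].astype(str) == rec.participant_id) & (
                trial_df["session"].astype(str) == rec.session_id
            )
            metas = list(trial_df.loc[sel, "meta"])
        else:
            metas = list(trial_df["meta"])
        sessions.append((rec, metas))
    behaviour = None
    if "correct" in trial_df.columns:
        behaviour = trial_df.rename(columns={"rt_ms": "rt_ms"})[
            [c for c in ("participant", "session", "trial_id", "correct", "rt_ms") if c in trial_df]
        ]
    return sessions, behaviour


def run_pipeline(config: PipelineConfig | None = None, study=None, outdir=None) -> dict:
    """Execute all stages and return (and optionally write) the report.

    Data come from, in order of precedence: the ``study`` argument (a
    :class:`~retrogaze.simulate.StudyData`), the file paths in the config,
    or a fresh simulation with the config's simulation parameters.
    """
    config = config or PipelineConfig()
    behaviour = None
    if study is None:
        if config.gaze_path and config.trials_path:
            sessions, behaviour = _load_study(config)
        else:
            sim_params = dataclasses.replace(config.simulation, seed=config.seed)
            study = simulate_study(sim_params)
    if study is not None:
        sessions = [(s.recording, s.trials) for s in study.sessions]
        behaviour = study.behaviour

    trial_results_by_participant: dict[str, list] = {}
    all_events_frames = []
    for recording, metas in sessions:
        try:
            results = process_session(recording, metas, config)
        except Exception as exc:
            raise StageError(
                f"stage preprocess/detect failed for participant "
                f"{recording.participant_id} session {recording.session_id}: {exc}"
            ) from exc
        trial_results_by_participant.setdefault(recording.participant_id, []).extend(results)
        for tr in results:
            if tr.events:
                all_events_frames.append(
                    events_to_frame(tr.events, recording.participant_id, recording.session_id)
                )

    report = analyse_study(trial_results_by_participant, config)
    report["events"] = (
        pd.concat(all_events_frames, ignore_index=True)
        if all_events_frames
        else pd.DataFrame()
    )

    if behaviour is not None and len(behaviour):
        acc = behaviour.groupby("participant")["correct"].mean() * 100.0
        rt = behaviour.groupby("participant")["rt_ms"].mean()
        report["behaviour"] = {
            "accuracy_pct_mean": float(acc.mean()),
            "accuracy_pct_sem": float(acc.sem()) if len(acc) > 1 else 0.0,
            "rt_ms_mean": float(rt.mean()),
            "rt_ms_sem": float(rt.sem()) if len(rt) > 1 else 0.0,
            "n_participants": int(len(acc)),
        }

    report["config_hash"] = config.config_hash()
    report["seed"] = config.seed
    report["n_participants"] = len(trial_results_by_participant)

    if outdir is not None:
        _write_report(report, config, outdir)
    return report


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def _write_report(report: dict, config: PipelineConfig, outdir) -> None:
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for key, fname in (
        ("events", "events.tsv"),
        ("curves", "curves.tsv"),
        ("first_saccades", "first_saccades.tsv"),
    ):
        df = report.get(key)
        if isinstance(df, pd.DataFrame) and len(df):
            df.to_csv(outdir / fname, sep="\t", index=False)
    tables = report.get("quadrant_tables", [])
    if tables:
        quadrant_frame(tables).to_csv(outdir / "quadrants.tsv", sep="\t", index=False)
    config.to_yaml(outdir / "config.yaml")

    stats_section = {
        k: report.get(k)
        for k in (
            "cluster_tests",
            "anova",
            "followup_t_tests",
            "behaviour",
            "trial_tally",
            "config_hash",
            "seed",
            "n_participants",
        )
    }
    with open(outdir / "report.json", "w") as fh:
        json.dump(_jsonable(stats_section), fh, indent=2, sort_keys=True)
        fh.write("\n")
    with open(outdir / "report.txt", "w") as fh:
        fh.write(format_report(report))


def format_report(report: dict) -> str:
    """Human-readable summary of the statistics section."""
    lines = [
        f"retrogaze report (config {report.get('config_hash', '?')}, "
        f"seed {report.get('seed', '?')})",
        f"participants: {report.get('n_participants', '?')}",
        "",
    ]
    beh = report.get("behaviour")
    if beh:
        lines.append(
            f"behaviour: accuracy {beh['accuracy_pct_mean']:.1f}% "
            f"(SEM {beh['accuracy_pct_sem']:.1f}), "
            f"mean RT {beh['rt_ms_mean']:.0f} ms"
        )
    for ref, res in (report.get("cluster_tests") or {}).items():
        if isinstance(res, str):
            lines.append(f"cluster test ({ref}): {res}")
            continue
        if not res["clusters"]:
            lines.append(f"cluster test ({ref}): no clusters")
        for c in res["clusters"]:
            lines.append(
                f"cluster test ({ref}): [{c['start_ms']:.0f}, {c['end_ms']:.0f}] ms, "
                f"mass {c['mass']:.1f}, p = {c['p']:.4g}"
            )
    anova = report.get("anova")
    if isinstance(anova, dict):
        for effect, res in anova.items():
            lines.append(
                f"ANOVA {effect}: F({res['df'][0]}, {res['df'][1]}) = {res['F']:.2f}, "
                f"p = {res['p']:.4g}, partial eta^2 = {res['partial_eta_sq']:.2f}"
            )
    elif anova:
        lines.append(f"ANOVA: {anova}")
    for label, res in (report.get("followup_t_tests") or {}).items():
        if isinstance(res, str):
            lines.append(f"t-test ({label}): {res}")
        else:
            lines.append(
                f"t-test ({label}): t({res['df']}) = {res['t']:.2f}, "
                f"p_bonferroni = {res['p_bonferroni']:.4g}, d = {res['cohen_d']:.2f}"
            )
    tally = report.get("trial_tally")
    if tally:
        lines.append(f"trials: {tally}")
    return "\n".join(lines) + "\n"
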