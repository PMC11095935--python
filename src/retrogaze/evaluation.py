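"""Validation benchmarks: ground-truth recovery and statistical calibration.

These routines exercise the pipeline against the synthetic generator's
ground truth and against analytic/oracle values: detector recall and false
alarms on injected shifts, refractory behaviour, rate-curve arithmetic,
common-frame geometry, family-wise error calibration of the cluster
permutation test, the ANOVA algebraic identities, and full end-to-end
recovery of an injected joint past+future bias.  Each returns a flat dict
of plain numbers so results can be serialised directly.
"""

from __future__ import annotations

import numpy as np
import scipy.stats

from .detect import compute_velocity, detect_saccades
from .io import TrialMeta
from .pipeline import PipelineConfig, study_quadrant_tables
from .simulate import (
    SimulationParams,
    expected_first_saccade_quadrants,
    make_rule_table,
    simulate_study,
    simulate_trial,
)
from .single_saccade import RotatedSaccade, quadrant_percentages, rotate_to_common_frame
from .stats import PermutationParams, cluster_permutation_test, rm_anova_2x2
from .timecourse import TimecourseParams, shift_rate_timecourse

__all__ = [
    "detection_benchmark",
    "refractory_benchmark",
    "rate_plateau_check",
    "rotation_check",
    "quadrant_partition_check",
    "cluster_test_calibration",
    "anova_identity_check",
    "end_to_end_recovery",
    "scaled_study_params",
]


def _quiet_params(noise_sd=0.02, **kw):
    return SimulationParams(
        noise_sd=noise_sd,
        drift_sd=0.0,
        blink_rate=0.0,
        base_saccade_rate=0.0,
        response_prob=0.0,
        return_saccades=False,
        **kw,
    )


def _trial_meta(trial_id=0, rule_id=1):
    table = make_rule_table(rule_id)
    past, future = next(iter(table.items()))
    return TrialMeta(
        trial_id=trial_id,
        rule_id=rule_id,
        cue_onset=1000.0,
        past_location=np.asarray(past),
        future_location=np.asarray(future),
    )


def detection_benchmark(n_trials: int = 30, noise_sd: float = 0.02, seed: int = 0) -> dict:
    """Recall, false alarms and onset error for injected shifts on quiet traces.

    Shifts of 0.1-1.0 degrees with random directions are injected at known
    onsets separated by 250 ms on traces with band-limited jitter (drift
    off); a detection matches a ground-truth onset when it falls within
    10 ms.  Returns recall as a percentage, the total false-alarm count
    and the maximum absolute onset error over all matches.
    """
    params = _quiet_params(noise_sd=noise_sd)
    rng = np.random.default_rng(seed)
    onset_grid = np.arange(-800.0, 1701.0, 250.0)
    magnitudes = np.array([0.1, 0.15, 0.25, 0.4, 0.7, 1.0])
    n_hit = n_gt = n_fa = 0
    max_err = 0.0
    for i in range(n_trials):
        mags = magnitudes[(np.arange(len(onset_grid)) + i) % len(magnitudes)]
        angles = rng.uniform(0, 2 * np.pi, len(onset_grid))
        events = [
            (float(o), float(m * np.cos(a)), float(m * np.sin(a)))
            for o, m, a in zip(onset_grid, mags, angles)
        ]
        epoch, truth, _ = simulate_trial(_trial_meta(i), params, rng, events=events)
        t, v = compute_velocity(epoch)
        onsets = np.asarray(detect_saccades(t, v))
        gt = np.asarray([row["onset_ms"] for row in truth])
        n_gt += len(gt)
        matched = np.zeros(len(onsets), dtype=bool)
        for g in gt:
            err = np.abs(onsets - g) if len(onsets) else np.array([np.inf])
            j = int(np.argmin(err))
            if err[j] <= 10.0 and not matched[j]:
                matched[j] = True
                n_hit += 1
                max_err = max(max_err, float(err[j]))
        n_fa += int((~matched).sum())
    return {
        "recall_pct": 100.0 * n_hit / n_gt,
        "false_alarms": n_fa,
        "max_onset_error_ms": max_err,
        "n_injected": n_gt,
    }


def refractory_benchmark(seed: int = 0) -> dict:
    """Detection counts for two injected shifts 50 ms vs 150 ms apart."""
    params = _quiet_params(noise_sd=0.002)
    out = {}
    for gap in (50.0, 150.0):
        rng = np.random.default_rng(seed)
        epoch, _, _ = simulate_trial(
            _trial_meta(),
            params,
            rng,
            events=[(300.0, 0.4, 0.0), (300.0 + gap, 0.0, 0.4)],
        )
        t, v = compute_velocity(epoch)
        out[f"detections_{int(gap)}ms_apart"] = len(detect_saccades(t, v))
    return out


def rate_plateau_check() -> dict:
    """A single saccade in a single trial must yield a 20 Hz, 50 ms plateau."""
    params = TimecourseParams()
    tc = shift_rate_timecourse([300.0], n_trials=1, params=params)
    half = params.rate_window / 2
    brute = np.array(
        [1.0 if c - half <= 300.0 < c + half else 0.0 for c in tc.time]
    ) / (params.rate_window / 1000.0)
    plateau = tc.time[tc.rate > 0]
    return {
        "plateau_rate_hz": float(tc.rate.max()),
        "plateau_width_ms": float(plateau.max() - plateau.min() + params.rate_step),
        "max_diff_vs_brute_force": float(np.abs(tc.rate - brute).max()),
    }


def rotation_check(n_per_rule: int = 50, seed: int = 0) -> dict:
    """Isometry of the common-frame transform across all four future rules."""
    from .detect import SaccadeEvent

    rng = np.random.default_rng(seed)
    max_err = 0.0
    for rule_id in (1, 2, 3, 4):
        for past, future in make_rule_table(rule_id).items():
            for _ in range(n_per_rule):
                d = rng.normal(0, 0.5, 2)
                ev = SaccadeEvent.from_positions(0, 300.0, (0.0, 0.0), d)
                rot = rotate_to_common_frame(ev, past, future)
                max_err = max(max_err, abs(rot.magnitude - float(np.hypot(*d))))
    ev = SaccadeEvent.from_positions(0, 300.0, (0.0, 0.0), (0.0, 0.3))
    rot = rotate_to_common_frame(ev, (0.0, 4.0), (4.0, 0.0))  # rule 1, top item
    return {
        "max_magnitude_error_deg": max_err,
        "rule1_toward_past_direction_deg": rot.direction_common,
    }


def quadrant_partition_check() -> dict:
    """Four symmetric saccades give 25% per quadrant; rows always sum to 100."""
    def rot(angle):
        th = np.radians(angle)
        return RotatedSaccade(0, angle % 360, 0.3, 0.3 * np.array([np.cos(th), np.sin(th)]))

    (symmetric,) = quadrant_percentages({"P": [rot(a) for a in (45, 135, 225, 315)]})
    rng = np.random.default_rng(0)
    (random_tbl,) = quadrant_percentages(
        {"P": [rot(a) for a in rng.uniform(0.01, 359.9, 37)]}
    )
    return {
        "symmetric_cell_pct": float(symmetric.pct[0, 0]),
        "symmetric_spread": float(np.ptp(symmetric.pct)),
        "random_table_sum_pct": float(random_tbl.pct.sum()),
    }


def cluster_test_calibration(
    n_datasets: int = 1000,
    n_participants: int = 25,
    n_timepoints: int = 500,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Family-wise false-positive rate of the cluster test under a pure null.

    Each dataset is i.i.d. standard-normal participant x time noise; a
    false positive is any cluster with p below ``alpha``.  For a
    well-calibrated test the rate sits at ``alpha`` up to Monte-Carlo
    error.
    """
    rng = np.random.default_rng(seed)
    hits = 0
    for i in range(n_datasets):
        X = rng.normal(0.0, 1.0, (n_participants, n_timepoints))
        res = cluster_permutation_test(
            X, PermutationParams(n_perm=n_perm, seed=int(rng.integers(2**31)))
        )
        hits += any(c.p < alpha for c in res.clusters)
    return {
        "false_positive_rate": hits / n_datasets,
        "n_datasets": n_datasets,
        "mc_ci_halfwidth": 1.96 * float(np.sqrt(alpha * (1 - alpha) / n_datasets)),
    }


def _brute_force_interaction(X: np.ndarray):
    """Explicit sums-of-squares for the 2x2 within-subject interaction."""
    n = X.shape[0]
    cells = X.reshape(n, 2, 2)
    grand = cells.mean()
    subj = cells.mean(axis=(1, 2))
    a = cells.mean(axis=(0, 2))
    b = cells.mean(axis=(0, 1))
    ab = cells.mean(axis=0)
    ss_int = n * np.sum((ab - a[:, None] - b[None, :] + grand) ** 2)
    sa = cells.mean(axis=2)
    sb = cells.mean(axis=1)
    resid = (
        cells - ab[None] - sa[:, :, None] - sb[:, None, :]
        + a[None, :, None] + b[None, None, :] + subj[:, None, None] - grand
    )
    ss_err = float(np.sum(resid**2))
    return ss_int / (ss_err / (n - 1)), ss_int / (ss_int + ss_err)


def anova_identity_check(n_datasets: int = 100, seed: int = 0) -> dict:
    """Interaction F vs the sums-of-squares oracle and the t^2 identity."""
    rng = np.random.default_rng(seed)
    max_f_diff = max_t_diff = 0.0
    for _ in range(n_datasets):
        n = int(rng.integers(4, 13))
        X = rng.normal(25.0, 5.0, (n, 4))
        res = rm_anova_2x2(list(X.reshape(-1, 2, 2)))
        F = res["interaction"].F
        F_bf, _ = _brute_force_interaction(X)
        dd = (X[:, 0] - X[:, 1]) - (X[:, 2] - X[:, 3])
        t = float(scipy.stats.ttest_1samp(dd, 0.0).statistic)
        max_f_diff = max(max_f_diff, abs(F - F_bf) / max(F_bf, 1e-12))
        max_t_diff = max(max_t_diff, abs(F - t**2) / max(t**2, 1e-12))
    return {
        "max_rel_diff_vs_brute_force": max_f_diff,
        "max_rel_diff_vs_t_squared": max_t_diff,
        "n_datasets": n_datasets,
    }


def scaled_study_params(seed: int, **overrides) -> SimulationParams:
    """The scaled-down study used for end-to-end checks: 10 participants,
    160 trials each (4 sessions x 1 block x 40 trials, rules counterbalanced)."""
    kw = dict(
        n_participants=10,
        n_sessions=4,
        n_blocks_per_session=1,
        n_trials_per_block=40,
        seed=seed,
    )
    kw.update(overrides)
    return SimulationParams(**kw)


def end_to_end_recovery(
    n_studies: int = 100,
    n_null_studies: int = 50,
    seed: int = 0,
    alpha: float = 0.05,
) -> dict:
    """Full-pipeline recovery of the injected joint past+future bias.

    Runs three checks on scaled-down studies (raw traces -> detection ->
    first-saccade rotation -> quadrant ANOVA):

    * one study's group-mean quadrant percentages against the generative
      model's Monte-Carlo expectation (per-cell t-statistics across
      participants);
    * the interaction detection rate over ``n_studies`` studies with the
      default joint-bias mixture (w_joint = 0.5);
    * the interaction rejection rate over ``n_null_studies`` studies with
      w_joint = 0 and equal independent past/future biases, which should
      stay near ``alpha``.
    """
    config = PipelineConfig()
    rng = np.random.default_rng(seed)

    # --- single-study quadrant recovery ----------------------------------
    params0 = scaled_study_params(int(rng.integers(2**31)))
    tables0 = study_quadrant_tables(simulate_study(params0), config)
    pct = np.array([t.pct for t in tables0])
    expected = expected_first_saccade_quadrants(params0) * 100.0
    mean = pct.mean(axis=0)
    sem = pct.std(axis=0, ddof=1) / np.sqrt(pct.shape[0])
    tstat = np.abs(mean - expected) / sem
    quadrant = {
        "quadrant_toward_toward_pct": float(mean[0, 0]),
        "quadrant_toward_toward_expected_pct": float(expected[0, 0]),
        "quadrant_max_abs_t_vs_expected": float(tstat.max()),
        "n_first_saccades": int(sum(t.n_saccades for t in tables0)),
        "n_participants": pct.shape[0],
    }

    # --- detection power with the joint bias ------------------------------
    sig = 0
    for _ in range(n_studies):
        params = scaled_study_params(int(rng.integers(2**31)))
        res = rm_anova_2x2(study_quadrant_tables(simulate_study(params), config))
        sig += res["interaction"].p < alpha
    power = {
        "interaction_detection_rate_pct": 100.0 * sig / n_studies,
        "n_studies": n_studies,
    }

    # --- null regime: independent past and future biases ------------------
    null_sig = 0
    for _ in range(n_null_studies):
        params = scaled_study_params(
            int(rng.integers(2**31)), mixture_weights=(0.0, 0.3, 0.3, 0.4)
        )
        res = rm_anova_2x2(study_quadrant_tables(simulate_study(params), config))
        null_sig += res["interaction"].p < alpha
    null = {
        "null_interaction_rejection_rate_pct": 100.0 * null_sig / n_null_studies,
        "n_null_studies": n_null_studies,
    }
    return {**quadrant, **power, **null}
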