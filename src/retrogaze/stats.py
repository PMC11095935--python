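"""Statistical inference for participant-level gaze measures.

Three tools cover the analyses in this pipeline:

* a cluster-based sign-permutation test for time-resolved difference
  curves, controlling the family-wise error over time points by comparing
  observed cluster masses (sums of pointwise t-values in contiguous
  supra-threshold, same-signed runs) against the permutation distribution
  of the maximum absolute cluster mass under per-participant sign flips;
* a 2x2 repeated-measures ANOVA (factors past toward/away and future
  toward/away) with partial eta squared, and
* Bonferroni-corrected paired t-tests with Cohen's d for follow-ups.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

logger = logging.getLogger(__name__)

__all__ = [
    "PermutationParams",
    "Cluster",
    "ClusterResult",
    "AnovaResult",
    "TTestResult",
    "cluster_permutation_test",
    "rm_anova_2x2",
    "paired_t_bonferroni",
]


@dataclass
class PermutationParams:
    """Settings of the sign-permutation cluster test.

    ``alpha_cluster_forming`` is the two-sided pointwise alpha that turns
    t-values into supra-threshold runs; the cluster-level p-value uses the
    (b + 1) / (n_perm + 1) estimator, which never returns zero.
    """

    n_perm: int = 10000
    alpha_cluster_forming: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if not 0 < self.alpha_cluster_forming < 1:
            raise ValueError("alpha_cluster_forming must be in (0, 1)")


@dataclass
class Cluster:
    start: float  # time (or index when no time axis given) of first sample
    end: float  # time of last sample, inclusive
    mass: float  # sum of t-values in the cluster
    p: float
    sign: int


@dataclass
class ClusterResult:
    clusters: list
    observed_t: np.ndarray
    threshold: float
    n_perm: int
    seed: int

    def significant(self, alpha: float = 0.05) -> list:
        return [c for c in self.clusters if c.p < alpha]


def _one_sample_t(X: np.ndarray) -> np.ndarray:
    n = X.shape[0]
    m = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(sd > 0, m / (sd / np.sqrt(n)), 0.0)
    return t


def _find_clusters(t: np.ndarray, tcrit: float):
    """Maximal runs of same-signed supra-threshold t-values: (i0, i1, mass, sign)."""
    sgn = np.where(t > tcrit, 1, np.where(t < -tcrit, -1, 0))
    out = []
    i = 0
    T = len(t)
    while i < T:
        if sgn[i] == 0:
            i += 1
            continue
        j = i
        while j + 1 < T and sgn[j + 1] == sgn[i]:
            j += 1
        out.append((i, j, float(t[i : j + 1].sum()), int(sgn[i])))
        i = j + 1
    return out


def _max_abs_cluster_mass_rows(tmat: np.ndarray, tcrit: float) -> np.ndarray:
    """Per-row maximum absolute cluster mass, vectorised over permutations.

    Rows are separated by an inserted zero column so runs never straddle
    row boundaries.
    """
    P, T = tmat.shape
    sgn = np.where(tmat > tcrit, 1, np.where(tmat < -tcrit, -1, 0))
    vals = np.where(sgn != 0, tmat, 0.0)
    padded_s = np.zeros((P, T + 1), dtype=np.int8)
    padded_s[:, :T] = sgn
    padded_v = np.zeros((P, T + 1))
    padded_v[:, :T] = vals
    flat_s = padded_s.ravel()
    flat_v = padded_v.ravel()
    change = np.flatnonzero(np.diff(flat_s) != 0) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [flat_s.size]))
    cs = np.concatenate(([0.0], np.cumsum(flat_v)))
    masses = cs[ends] - cs[starts]
    signs = flat_s[starts]
    keep = signs != 0
    out = np.zeros(P)
    if keep.any():
        rows = starts[keep] // (T + 1)
        np.maximum.at(out, rows, np.abs(masses[keep]))
    return out


def cluster_permutation_test(
    series,
    params: PermutationParams | None = None,
    times=None,
) -> ClusterResult:
    """Cluster-based sign-permutation test of a participant x time matrix vs 0.

    Pointwise one-sample t-tests against zero define clusters as maximal
    contiguous runs of same-signed t-values exceeding the two-sided
    cluster-forming threshold.  The null distribution is the maximum
    absolute cluster mass over per-participant whole-series sign flips
    (equivalent to swapping toward/away labels within participant), so
    observed clusters of either sign are compared against a common
    two-sided reference.  With a fixed seed the result is bit-reproducible.
    """
    params = params or PermutationParams()
    X = np.asarray(series, dtype=float)
    if X.ndim != 2:
        raise ValueError("series must be a 2-D participant x time matrix")
    n, T = X.shape
    if n < 2:
        raise ValueError("need at least 2 participants")
    if np.isnan(X).any():
        raise ValueError("missing time points are not supported")
    if times is None:
        times = np.arange(T)
    times = np.asarray(times, dtype=float)
    tcrit = float(scipy.stats.t.ppf(1.0 - params.alpha_cluster_forming / 2.0, n - 1))
    t_obs = _one_sample_t(X)
    raw_clusters = _find_clusters(t_obs, tcrit)

    rng = np.random.default_rng(params.seed)
    signs = rng.integers(0, 2, size=(params.n_perm, n)).astype(np.float64) * 2.0 - 1.0
    M = signs @ X / n
    ss = (X * X).sum(axis=0)  # invariant under sign flips
    var = (ss - n * M**2) / (n - 1)
    np.maximum(var, 0.0, out=var)
    with np.errstate(invalid="ignore", divide="ignore"):
        tmat = np.where(var > 0, M / np.sqrt(var / n), 0.0)
    null_max = _max_abs_cluster_mass_rows(tmat, tcrit)

    clusters = []
    for i0, i1, mass, sign in raw_clusters:
        b = int(np.sum(null_max >= abs(mass)))
        p = (b + 1) / (params.n_perm + 1)
        clusters.append(Cluster(float(times[i0]), float(times[i1]), mass, p, sign))
    return ClusterResult(clusters, t_obs, tcrit, params.n_perm, params.seed)


@dataclass
class AnovaResult:
    effect: str
    F: float
    df: tuple[int, int]
    p: float
    partial_eta_sq: float


def _tables_to_matrix(tables) -> np.ndarray:
    """Stack quadrant tables to an (n, 4) matrix: columns TT, TA, AT, AA."""
    arr = np.asarray(
        [t.pct.ravel() if hasattr(t, "pct") else np.asarray(t, float).ravel() for t in tables],
        dtype=float,
    )
    if arr.ndim != 2 or arr.shape[1] != 4:
        raise ValueError("each table must provide a complete 2x2 of percentages")
    return arr


def rm_anova_2x2(tables) -> dict[str, AnovaResult]:
    """Two-way repeated-measures ANOVA on the 2x2 quadrant percentages.

    Factors are past (toward/away) and future (toward/away); the
    interaction term carries the joint-bias question: a future bias
    confined to past-toward saccades produces a cell-specific excess that
    main effects cannot express.  Each effect has df (1, n - 1) and partial
    eta squared SS_effect / (SS_effect + SS_error).

    The fit is delegated to :func:`pingouin.rm_anova`; effects whose
    within-participant contrast has zero variance are degenerate and are
    reported as F = 0 (p = 1) with a warning rather than failing.
    """
    import pingouin as pg

    X = _tables_to_matrix(tables)
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least 2 participants")
    if np.isnan(X).any():
        raise ValueError("incomplete 2x2 cell")
    # contrast per effect: past = (TT+TA)-(AT+AA), future = (TT+AT)-(TA+AA),
    # interaction = (TT-TA)-(AT-AA)
    contrasts = {
        "past": X[:, 0] + X[:, 1] - X[:, 2] - X[:, 3],
        "future": X[:, 0] - X[:, 1] + X[:, 2] - X[:, 3],
        "interaction": X[:, 0] - X[:, 1] - X[:, 2] + X[:, 3],
    }
    degenerate = {k: np.std(v, ddof=1) == 0 for k, v in contrasts.items()}

    results: dict[str, AnovaResult] = {}
    if not all(degenerate.values()):
        long = pd.DataFrame(
            {
                "participant": np.repeat(np.arange(n), 4),
                "past": np.tile(["toward", "toward", "away", "away"], n),
                "future": np.tile(["toward", "away", "toward", "away"], n),
                "pct": X.ravel(),
            }
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            aov = pg.rm_anova(
                dv="pct", within=["past", "future"], subject="participant",
                data=long, detailed=True, effsize="np2",
            )
        source_map = {"past": "past", "future": "future", "past * future": "interaction"}
        p_col = "p_unc" if "p_unc" in aov.columns else "p-unc"
        for _, row in aov.iterrows():
            key = source_map.get(row["Source"])
            if key is None:
                continue
            results[key] = AnovaResult(
                effect=key,
                F=float(row["F"]),
                df=(int(row["ddof1"]), int(row["ddof2"])),
                p=float(row[p_col]),
                partial_eta_sq=float(row["np2"]),
            )
    for key, is_degen in degenerate.items():
        if not is_degen:
            continue
        mean = float(np.mean(contrasts[key]))
        warnings.warn(
            f"rm_anova_2x2: zero error variance for effect '{key}'; "
            "reporting degenerate F",
            RuntimeWarning,
            stacklevel=2,
        )
        if mean == 0.0:
            results[key] = AnovaResult(key, 0.0, (1, n - 1), 1.0, 0.0)
        else:
            results[key] = AnovaResult(key, float("inf"), (1, n - 1), 0.0, 1.0)
    return results


@dataclass
class TTestResult:
    t: float
    df: int
    p: float
    p_corrected: float
    cohen_d: float


def paired_t_bonferroni(a, b, m: int = 1) -> TTestResult:
    """Paired t-test with Bonferroni correction over ``m`` tests.

    Cohen's d is mean(a - b) / sd(a - b) (paired-differences convention).
    Raises on zero variance of the differences.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("a and b must be equal-length 1-D arrays with n >= 2")
    if m < 1:
        raise ValueError("m must be >= 1")
    d = a - b
    sd = d.std(ddof=1)
    if sd == 0:
        if np.all(d == 0):  # identical inputs: no effect, not an error
            return TTestResult(0.0, len(a) - 1, 1.0, 1.0, 0.0)
        raise ValueError("zero variance of paired differences")
    res = scipy.stats.ttest_rel(a, b)
    return TTestResult(
        t=float(res.statistic),
        df=len(a) - 1,
        p=float(res.pvalue),
        p_corrected=min(1.0, m * float(res.pvalue)),
        cohen_d=float(d.mean() / sd),
    )
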