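import numpy as np
import pytest
import scipy.stats

from retrogaze.stats import (
    PermutationParams,
    cluster_permutation_test,
    paired_t_bonferroni,
    rm_anova_2x2,
)


# ---------------------------------------------------------------------------
# cluster permutation
# ---------------------------------------------------------------------------


def test_all_zero_input_no_clusters():
    res = cluster_permutation_test(np.zeros((6, 50)), PermutationParams(n_perm=100, seed=0))
    assert res.clusters == []


def test_constructed_effect_hits_p_floor(rng):
    n, T = 12, 500
    X = rng.normal(0, 0.01, (n, T))
    X[:, 300:501] += 1.0
    res = cluster_permutation_test(
        X, PermutationParams(n_perm=999, seed=3), times=np.arange(T)
    )
    sig = [c for c in res.clusters if c.p < 0.05]
    assert len(sig) == 1
    c = sig[0]
    assert c.sign == 1
    assert abs(c.start - 300) <= 2 and c.end == 499
    assert c.p == pytest.approx(1.0 / (999 + 1))  # the (b+1)/(n+1) floor


def test_sign_flip_symmetry(rng):
    X = rng.normal(0, 1, (10, 120))
    X[:, 40:70] += 0.9
    params = PermutationParams(n_perm=500, seed=7)
    res_pos = cluster_permutation_test(X, params)
    res_neg = cluster_permutation_test(-X, params)
    assert len(res_pos.clusters) == len(res_neg.clusters)
    for a, b in zip(res_pos.clusters, res_neg.clusters):
        assert a.p == b.p
        assert a.mass == pytest.approx(-b.mass)
        assert a.sign == -b.sign


def test_matches_mne_cluster_test(rng):
    """Independent implementation check on identical data and threshold."""
    from mne.stats import permutation_cluster_1samp_test

    X = rng.normal(0, 1, (10, 80))
    X[:, 20:45] += 0.8
    n = X.shape[0]
    tcrit = scipy.stats.t.ppf(0.975, n - 1)
    t_obs, clusters, pv, _ = permutation_cluster_1samp_test(
        X,
        threshold=tcrit,
        n_permutations=1024,  # exhaustive for n = 10
        tail=0,
        out_type="indices",
        seed=0,
        verbose=False,
    )
    mne_clusters = sorted(
        (int(idx[0].min()), int(idx[0].max()), float(t_obs[idx[0]].sum()), float(p))
        for idx, p in zip(clusters, pv)
    )
    res = cluster_permutation_test(X, PermutationParams(n_perm=4000, seed=11))
    ours = sorted((int(c.start), int(c.end), c.mass, c.p) for c in res.clusters)
    assert len(ours) == len(mne_clusters)
    for (s1, e1, m1, p1), (s2, e2, m2, p2) in zip(ours, mne_clusters):
        assert (s1, e1) == (s2, e2)
        assert m1 == pytest.approx(m2, rel=1e-9)
        assert p1 == pytest.approx(p2, abs=0.03)


def test_single_timepoint_matches_exact_sign_test(rng):
    """With one time point the cluster p approximates the exact sign-flip p."""
    n = 8
    x = rng.normal(1.2, 0.8, (n, 1))
    tcrit = scipy.stats.t.ppf(0.975, n - 1)

    def tval(v):
        return v.mean() / (v.std(ddof=1) / np.sqrt(n))

    t_obs = tval(x[:, 0])
    mass_obs = abs(t_obs) if abs(t_obs) > tcrit else 0.0
    count = 0
    for bits in range(2**n):
        signs = np.array([1 if bits >> i & 1 else -1 for i in range(n)])
        t_perm = tval(signs * x[:, 0])
        mass = abs(t_perm) if abs(t_perm) > tcrit else 0.0
        count += mass >= mass_obs
    p_exact = count / 2**n
    res = cluster_permutation_test(x, PermutationParams(n_perm=5000, seed=2))
    assert len(res.clusters) == 1
    assert res.clusters[0].p == pytest.approx(p_exact, abs=0.02)


def test_seed_reproducibility(rng):
    X = rng.normal(0, 1, (8, 60))
    a = cluster_permutation_test(X, PermutationParams(n_perm=300, seed=42))
    b = cluster_permutation_test(X, PermutationParams(n_perm=300, seed=42))
    assert [(c.start, c.end, c.mass, c.p) for c in a.clusters] == [
        (c.start, c.end, c.mass, c.p) for c in b.clusters
    ]


def test_too_few_participants():
    with pytest.raises(ValueError):
        cluster_permutation_test(np.zeros((1, 10)), PermutationParams(n_perm=10, seed=0))


# ---------------------------------------------------------------------------
# repeated-measures ANOVA
# ---------------------------------------------------------------------------


def _brute_force_2x2(X):
    """Textbook within-subject sums-of-squares for a 2x2 design.

    X has shape (n, 4) with columns (TT, TA, AT, AA); returns the
    interaction F and partial eta squared.
    """
    n = X.shape[0]
    cells = X.reshape(n, 2, 2)
    grand = cells.mean()
    subj_mean = cells.mean(axis=(1, 2))
    a_mean = cells.mean(axis=(0, 2))  # past levels
    b_mean = cells.mean(axis=(0, 1))  # future levels
    ab_mean = cells.mean(axis=0)
    ss_int = n * np.sum(
        (ab_mean - a_mean[:, None] - b_mean[None, :] + grand) ** 2
    )
    # interaction error: residual after removing all main/subject terms
    sa = cells.mean(axis=2)  # subject x past
    sb = cells.mean(axis=1)  # subject x future
    resid = (
        cells
        - ab_mean[None]
        - sa[:, :, None]
        - sb[:, None, :]
        + a_mean[None, :, None]
        + b_mean[None, None, :]
        + subj_mean[:, None, None]
        - grand
    )
    ss_err = np.sum(resid**2)
    F = ss_int / (ss_err / (n - 1))
    return F, ss_int / (ss_int + ss_err)


def test_identical_tables_degenerate(recwarn):
    tables = [np.full((2, 2), 25.0) for _ in range(6)]
    with pytest.warns(RuntimeWarning, match="zero error variance"):
        res = rm_anova_2x2(tables)
    assert res["interaction"].F == 0.0
    assert res["interaction"].p == 1.0


def test_interaction_matches_brute_force_and_t_squared(rng):
    for _ in range(100):
        n = rng.integers(4, 12)
        X = rng.normal(25, 5, (int(n), 4))
        res = rm_anova_2x2(list(X.reshape(-1, 2, 2)))
        F_bf, np2_bf = _brute_force_2x2(X)
        assert res["interaction"].F == pytest.approx(F_bf, rel=1e-8)
        assert res["interaction"].partial_eta_sq == pytest.approx(np2_bf, rel=1e-8)
        # algebraic identity: F equals the squared paired t on double-differences
        dd = (X[:, 0] - X[:, 1]) - (X[:, 2] - X[:, 3])
        t = scipy.stats.ttest_1samp(dd, 0.0).statistic
        assert res["interaction"].F == pytest.approx(t**2, rel=1e-8)
        assert res["interaction"].df == (1, int(n) - 1)


def test_hand_dataset_brute_force(rng):
    X = np.array(
        [
            [40.0, 20.0, 25.0, 15.0],
            [35.0, 25.0, 18.0, 20.0],
            [45.0, 15.0, 31.0, 10.0],
            [30.0, 30.0, 15.0, 22.0],
        ]
    )
    res = rm_anova_2x2(list(X.reshape(-1, 2, 2)))
    F_bf, _ = _brute_force_2x2(X)
    assert res["interaction"].F == pytest.approx(F_bf, rel=1e-10)


def test_incomplete_cell_rejected():
    X = np.full((4, 4), 25.0)
    X[1, 2] = np.nan
    with pytest.raises(ValueError):
        rm_anova_2x2(list(X.reshape(-1, 2, 2)))


# ---------------------------------------------------------------------------
# paired t with Bonferroni
# ---------------------------------------------------------------------------


def test_identical_samples():
    res = paired_t_bonferroni([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], m=3)
    assert res.t == 0.0 and res.p_corrected == 1.0 and res.cohen_d == 0.0


def test_constant_nonzero_difference_raises():
    with pytest.raises(ValueError):
        paired_t_bonferroni([2.0, 3.0, 4.0], [1.0, 2.0, 3.0])


def test_hand_example_matches_formula():
    a = np.array([10.0, 12.0, 9.0, 14.0, 11.0])
    b = np.array([8.0, 11.0, 9.0, 10.0, 12.0])
    d = a - b
    t_hand = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
    res = paired_t_bonferroni(a, b, m=2)
    assert res.t == pytest.approx(t_hand)
    assert res.df == 4
    assert res.cohen_d == pytest.approx(d.mean() / d.std(ddof=1))
    p_hand = 2 * scipy.stats.t.sf(abs(t_hand), 4)
    assert res.p_corrected == pytest.approx(min(1.0, 2 * p_hand))


def test_bonferroni_saturates_at_one(rng):
    a = rng.normal(0, 1, 10)
    b = a + rng.normal(0, 1, 10) * 0.9
    res = paired_t_bonferroni(a, b, m=50)
    if 50 * res.p >= 1:
        assert res.p_corrected == 1.0
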