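"""Statistical layer: oracles, identities and Monte-Carlo behaviour.

The heavier calibration studies (type-I error at study sample sizes, DeLong
CI coverage) live in the acceptance suite; here each routine is checked
against brute-force oracles and closed-form cases.
"""

import numpy as np
import pytest
from scipy import stats as sps

from octquant.stats import (chi_square_2x2, compare_groups,
                            delong_paired_compare, ks_normality, pearson_r,
                            roc_auc_delong)


def brute_force_u(x: np.ndarray, y: np.ndarray) -> float:
    """All-pairs count of (x_i > y_j) plus half-ties: the U of sample x."""
    diff = x[:, None] - y[None, :]
    return float((diff > 0).sum() + 0.5 * (diff == 0).sum())


# ---------------------------------------------------------------------------
# normality gate

def test_ks_normality_requires_variation_and_size():
    with pytest.raises(ValueError):
        ks_normality(np.array([1.0, 1.0, 1.0, 1.0, 1.0]))
    with pytest.raises(ValueError):
        ks_normality(np.array([1.0, 2.0, 3.0]))


def test_ks_normality_detects_exponential(rng):
    """Lilliefors rejects an exponential sample of n=200 almost always."""
    rejected = sum(ks_normality(rng.exponential(size=200)) < 0.05
                   for _ in range(200))
    assert rejected / 200 > 0.95


def test_ks_normality_calibrated_under_the_null(rng):
    """Rejection rate at alpha=0.05 on normal samples stays within binomial
    error of the nominal level."""
    reps = 1000
    rejected = sum(ks_normality(rng.normal(size=500)) < 0.05
                   for _ in range(reps))
    se = np.sqrt(0.05 * 0.95 / reps)
    assert abs(rejected / reps - 0.05) < 3 * se


# ---------------------------------------------------------------------------
# two-sample comparison

def test_identical_samples_compare_equal():
    x = np.array([3.0, 1.0, 7.0, 2.0, 9.0, 4.0])
    res = compare_groups(x, x.copy())
    assert res.p == pytest.approx(1.0)
    assert res.mean_x == res.mean_y


def test_compare_groups_symmetric_under_swap(rng):
    x = rng.normal(0, 1, 30)
    y = rng.normal(0.4, 1, 30)
    a = compare_groups(x, y)
    b = compare_groups(y, x)
    assert a.p == pytest.approx(b.p, rel=1e-12)
    assert a.test == b.test


def test_normal_data_routes_to_t_and_skewed_to_mwu(rng):
    x, y = rng.normal(size=60), rng.normal(size=60)
    assert compare_groups(x, y).test == "t"
    x, y = rng.exponential(size=60), rng.exponential(size=60)
    assert compare_groups(x, y).test == "MWU"


def test_mwu_statistic_matches_brute_force_count(rng):
    """Scipy-backed U equals the all-pairs oracle on 1000 random small-n
    vectors, ties included."""
    for _ in range(1000):
        nx, ny = rng.integers(4, 11, size=2)
        x = rng.integers(0, 8, size=nx).astype(float)  # integer -> many ties
        y = rng.integers(0, 8, size=ny).astype(float)
        if np.ptp(np.concatenate([x, y])) == 0:
            continue
        res = sps.mannwhitneyu(x, y, alternative="two-sided",
                               method="asymptotic", use_continuity=False)
        assert res.statistic == pytest.approx(brute_force_u(x, y))


def test_mean_sd_formatting_matches_table_style():
    x = np.array([33.1, 34.2, 32.9, 34.8, 33.5])
    y = np.array([37.3, 38.1, 37.7, 38.4, 38.0])
    fx, fy, fp = compare_groups(x, y).formatted()
    assert fx == f"{x.mean():.2f}±{x.std(ddof=1):.2f}"
    assert len(fp.split(".")[1]) == 3


# ---------------------------------------------------------------------------
# correlation and chi-square

def test_pearson_perfect_correlations(rng):
    x = rng.normal(size=20)
    assert pearson_r(x, x)[0] == pytest.approx(1.0)
    assert pearson_r(x, -x)[0] == pytest.approx(-1.0)
    with pytest.raises(ValueError):
        pearson_r(x, np.zeros(20))


def test_pearson_estimates_population_correlation(rng):
    """rho = 0.4 at the study's n = 38 is recovered on average."""
    rho, n, reps = 0.4, 38, 500
    cov = np.array([[1.0, rho], [rho, 1.0]])
    rs = []
    for _ in range(reps):
        xy = rng.multivariate_normal([0, 0], cov, size=n)
        rs.append(pearson_r(xy[:, 0], xy[:, 1])[0])
    se = (1 - rho ** 2) / np.sqrt(n) / np.sqrt(reps)
    assert abs(np.mean(rs) - rho) < 4 * se + 0.01


def test_chi_square_balanced_table_is_null():
    chi2, p = chi_square_2x2([[10, 10], [10, 10]])
    assert chi2 == 0.0
    assert p == pytest.approx(1.0)


def test_chi_square_sex_table_not_significant():
    """The 21/17 vs 19/20 male/female split is far from significance."""
    _, p = chi_square_2x2([[21, 17], [19, 20]])
    assert p > 0.05


def test_chi_square_agrees_with_permutation_oracle(rng):
    """Asymptotic p within 0.02 of a label-permutation null (mid-p, which
    handles the discrete atom at the observed statistic) on the study's own
    sex-count table."""
    table = np.array([[21, 17], [19, 20]])
    chi2_obs, p_asym = chi_square_2x2(table)
    labels = np.repeat([0, 1], table.sum(axis=1))
    outcome = np.concatenate([np.repeat([0, 1], table[0]),
                              np.repeat([0, 1], table[1])])
    reps = 8000
    greater = equal = 0
    for _ in range(reps):
        perm = rng.permutation(labels)
        t = np.array([[np.sum((perm == g) & (outcome == o)) for o in (0, 1)]
                      for g in (0, 1)])
        if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
            continue
        s = chi_square_2x2(t)[0]
        if s > chi2_obs + 1e-9:
            greater += 1
        elif abs(s - chi2_obs) <= 1e-9:
            equal += 1
    assert abs((greater + 0.5 * equal) / reps - p_asym) < 0.02


def test_chi_square_zero_marginal_rejected():
    with pytest.raises(ValueError, match="marginal"):
        chi_square_2x2([[0, 0], [5, 5]])


# ---------------------------------------------------------------------------
# ROC / DeLong

def test_perfect_separation_gives_auc_one():
    values = np.array([1.0, 2.0, 3.0, 10.0, 11.0, 12.0])
    labels = np.array([False, False, False, True, True, True])
    roc = roc_auc_delong(values, labels)
    assert roc.auc == 1.0
    assert roc.p == 0.0


def test_auc_equals_u_over_n1n2_always(rng):
    """The Mann-Whitney identity AUC = U/(n1*n2) holds on every input,
    ties included."""
    for _ in range(300):
        n1, n2 = rng.integers(4, 15, size=2)
        values = np.concatenate([rng.integers(0, 6, n1),
                                 rng.integers(0, 6, n2)]).astype(float)
        labels = np.concatenate([np.ones(n1, bool), np.zeros(n2, bool)])
        roc = roc_auc_delong(values, labels, orientation="greater")
        u = brute_force_u(values[labels], values[~labels])
        assert roc.auc == pytest.approx(u / (n1 * n2), abs=1e-12)


def test_auto_orientation_reports_flip(rng):
    values = np.concatenate([rng.normal(0, 1, 30), rng.normal(1.5, 1, 30)])
    labels = np.concatenate([np.ones(30, bool), np.zeros(30, bool)])
    roc = roc_auc_delong(values, labels)  # positives are LOWER here
    assert roc.orientation == "less"
    assert roc.auc >= 0.5


def test_single_class_rejected():
    with pytest.raises(ValueError):
        roc_auc_delong(np.arange(5.0), np.ones(5, bool))


def test_delong_se_sanity_against_literature_scale(rng):
    """DeLong SE at n=38/39 and AUC ~0.75 sits near the study's ~0.055."""
    values = np.concatenate([rng.normal(1.0, 1, 38), rng.normal(0, 1, 39)])
    labels = np.concatenate([np.ones(38, bool), np.zeros(39, bool)])
    roc = roc_auc_delong(values, labels)
    assert 0.02 < roc.se < 0.09


def test_variable_compared_with_itself_is_null(rng):
    values = rng.normal(size=40)
    labels = rng.random(40) < 0.5
    labels[:2] = [True, False]
    ra = roc_auc_delong(values, labels, orientation="greater")
    rb = roc_auc_delong(values.copy(), labels, orientation="greater")
    cmp = delong_paired_compare(ra, rb)
    assert cmp.delta == 0.0
    assert cmp.p == 1.0


def test_paired_variance_bounded_by_marginals(rng):
    """For positively correlated predictors the paired variance never
    exceeds the sum of the marginal DeLong variances."""
    for _ in range(50):
        s = rng.normal(size=50)
        a = s + rng.normal(0, 0.5, 50)
        b = s + rng.normal(0, 0.5, 50)
        labels = s + rng.normal(0, 1, 50) > 0
        if labels.all() or not labels.any():
            continue
        ra = roc_auc_delong(a, labels, orientation="greater")
        rb = roc_auc_delong(b, labels, orientation="greater")
        cmp = delong_paired_compare(ra, rb)
        assert cmp.se ** 2 <= ra.se ** 2 + rb.se ** 2 + 1e-12


def test_paired_compare_requires_same_subjects(rng):
    values = rng.normal(size=20)
    labels = np.repeat([True, False], 10)
    ra = roc_auc_delong(values, labels)
    rb = roc_auc_delong(values[:-2], labels[:-2])
    with pytest.raises(ValueError, match="same|identical"):
        delong_paired_compare(ra, rb)
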