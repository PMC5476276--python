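"""Statistical layer: normality-gated two-sample tests, correlation,
chi-square, and ROC analysis with DeLong variances.

Test routing follows the study design this package reproduces: every
variable is screened with a Kolmogorov–Smirnov normality test (Lilliefors
correction, since mean and SD are estimated from the sample); variables
normal in both groups are compared with the unpaired t-test, the rest with
the Mann–Whitney U. The Mann–Whitney asymptotic path applies the tie
correction but no continuity correction (the convention of the statistical
package the study used); small tie-free samples are enumerated exactly.

The DeLong structural-components estimator provides AUC standard errors and
the paired z-test for comparing two correlated AUCs computed on the same
subjects; it is implemented here (midrank algorithm) and cross-checked in
the test suite against the brute-force all-pairs U statistic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.diagnostic import lilliefors


def ks_normality(sample: np.ndarray) -> float:
    """Lilliefors-corrected one-sample KS p-value against a fitted normal."""
    x = np.asarray(sample, dtype=float)
    if x.size < 4:
        raise ValueError("need at least 4 observations for the normality test")
    if np.ptp(x) == 0:
        raise ValueError("sample is constant; normality test undefined")
    return float(lilliefors(x, dist="norm", pvalmethod="table")[1])


@dataclass
class GroupComparison:
    """Two-group comparison with the normality-gated test choice."""

    variable: str
    mean_x: float
    sd_x: float
    mean_y: float
    sd_y: float
    test: str  # "t" | "MWU"
    statistic: float
    p: float
    normality_p: tuple[float, float]

    def formatted(self, decimals: int = 2) -> tuple[str, str, str]:
        """Mean±SD strings and p, in the study's table style."""
        fx = f"{self.mean_x:.{decimals}f}±{self.sd_x:.{decimals}f}"
        fy = f"{self.mean_y:.{decimals}f}±{self.sd_y:.{decimals}f}"
        return fx, fy, f"{self.p:.3f}"


def _mwu(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided Mann–Whitney U: exact for small tie-free samples, otherwise
    normal approximation with tie correction and no continuity correction."""
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    if np.ptp(pooled) == 0:
        return float(x.size * y.size / 2.0), 1.0
    if not has_ties and max(x.size, y.size) <= 20:
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
    else:
        res = sps.mannwhitneyu(x, y, alternative="two-sided",
                               method="asymptotic", use_continuity=False)
    return float(res.statistic), float(res.pvalue)


def compare_groups(x: np.ndarray, y: np.ndarray, alpha_normality: float = 0.05,
                   variable: str = "", equal_var: bool = True) -> GroupComparison:
    """Compare two independent samples with the KS-gated t / Mann–Whitney rule.

    ``equal_var=True`` gives the classic unpaired t-test (the study's
    unqualified "unpaired t-test"); set False for Welch.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 4 or y.size < 4:
        raise ValueError("need at least 4 observations per group")
    try:
        p_nx, p_ny = ks_normality(x), ks_normality(y)
    except ValueError:
        p_nx = p_ny = 0.0  # constant sample: clearly not normal, use MWU
    if p_nx > alpha_normality and p_ny > alpha_normality:
        if np.ptp(np.concatenate([x, y])) == 0:
            stat, p = 0.0, 1.0
        else:
            stat, p = sps.ttest_ind(x, y, equal_var=equal_var)
        test = "t"
    else:
        stat, p = _mwu(x, y)
        test = "MWU"
    return GroupComparison(
        variable=variable, mean_x=float(x.mean()), sd_x=float(x.std(ddof=1)),
        mean_y=float(y.mean()), sd_y=float(y.std(ddof=1)), test=test,
        statistic=float(stat), p=float(p), normality_p=(p_nx, p_ny))


def pearson_r(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson correlation and its two-sided t-based p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need paired samples of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input; correlation undefined")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def chi_square_2x2(table: np.ndarray) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 table, no continuity correction."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("table must be 2x2 with non-negative counts")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("zero marginal; chi-square undefined")
    chi2, p = sps.chi2_contingency(t, correction=False)[:2]
    return float(chi2), float(p)


# ---------------------------------------------------------------------------
# DeLong ROC machinery

def _delong_components(scores: np.ndarray, positive: np.ndarray
                       ) -> tuple[np.ndarray, np.ndarray]:
    """AUCs and their DeLong covariance for k predictors on shared subjects.

    ``scores`` has shape (k, n); ``positive`` is the boolean class vector.
    Returns (aucs, covariance matrix) via the midrank structural-components
    algorithm.
    """
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    positive = np.asarray(positive, dtype=bool)
    m = int(positive.sum())
    n = int((~positive).sum())
    if m == 0 or n == 0:
        raise ValueError("both classes must be present")
    pos = scores[:, positive]
    neg = scores[:, ~positive]
    k = scores.shape[0]
    v01 = np.empty((k, m))
    v10 = np.empty((k, n))
    aucs = np.empty(k)
    for r in range(k):
        tx = sps.rankdata(pos[r])
        ty = sps.rankdata(neg[r])
        tz = sps.rankdata(np.concatenate([pos[r], neg[r]]))
        aucs[r] = (tz[:m].sum() - m * (m + 1) / 2.0) / (m * n)
        v01[r] = (tz[:m] - tx) / n          # per-positive structural components
        v10[r] = 1.0 - (tz[m:] - ty) / m    # per-negative structural components
    s01 = np.cov(v01, ddof=1) if m > 1 else np.zeros((k, k))
    s10 = np.cov(v10, ddof=1) if n > 1 else np.zeros((k, k))
    cov = np.atleast_2d(s01) / m + np.atleast_2d(s10) / n
    return aucs, cov


@dataclass
class ROCResult:
    """AUC with DeLong standard error for one predictor."""

    variable: str
    auc: float
    se: float
    ci95: tuple[float, float]
    z: float        # against the chance AUC of 0.5
    p: float
    orientation: str  # "greater": larger values indicate the positive class
    scores: np.ndarray  # oriented scores, retained for paired comparisons
    labels: np.ndarray

    def formatted(self) -> str:
        return f"{self.auc:.3f}({self.se:.4f})"


def roc_auc_delong(values: np.ndarray, labels: np.ndarray,
                   orientation: str = "auto", variable: str = "") -> ROCResult:
    """AUC via the Mann–Whitney identity with DeLong variance.

    ``labels`` is boolean (True = positive class). ``orientation`` "auto"
    flips the score sign when the raw AUC is below 0.5 so the reported
    training-direction AUC is >= 0.5; the flip is recorded.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if labels.all() or not labels.any():
        raise ValueError("both classes must be present")
    auc, cov = _delong_components(values[None, :], labels)
    flip = orientation == "less" or (orientation == "auto" and auc[0] < 0.5)
    scores = -values if flip else values
    if flip:
        auc, cov = _delong_components(scores[None, :], labels)
    se = float(np.sqrt(max(cov[0, 0], 0.0)))
    a = float(auc[0])
    ci = (max(0.0, a - 1.96 * se), min(1.0, a + 1.96 * se))
    if se > 0:
        z = (a - 0.5) / se
        p = 2.0 * sps.norm.sf(abs(z))
    else:
        z, p = (np.inf if a > 0.5 else 0.0), (0.0 if a > 0.5 else 1.0)
    return ROCResult(variable=variable, auc=a, se=se, ci95=ci, z=float(z),
                     p=float(p), orientation="less" if flip else "greater",
                     scores=scores, labels=labels)


@dataclass
class PairedAUCComparison:
    delta: float
    se: float
    z: float
    p: float
    ci95: tuple[float, float]


def delong_paired_compare(roc_a: ROCResult, roc_b: ROCResult
                          ) -> PairedAUCComparison:
    """DeLong z-test for the difference of two correlated AUCs.

    Both ROC results must come from the same subjects (identical label
    vectors); the paired covariance of the structural components accounts
    for the correlation between the two predictors.
    """
    if roc_a.labels.shape != roc_b.labels.shape or \
            not np.array_equal(roc_a.labels, roc_b.labels):
        raise ValueError("paired AUC comparison requires identical subject labels")
    aucs, cov = _delong_components(
        np.vstack([roc_a.scores, roc_b.scores]), roc_a.labels)
    delta = float(aucs[0] - aucs[1])
    var = float(cov[0, 0] + cov[1, 1] - 2.0 * cov[0, 1])
    if var <= 1e-15:
        se, z, p = 0.0, 0.0, 1.0
        if abs(delta) > 0:
            z, p = np.inf, 0.0
    else:
        se = float(np.sqrt(var))
        z = delta / se
        p = float(2.0 * sps.norm.sf(abs(z)))
    ci = (delta - 1.96 * se, delta + 1.96 * se)
    return PairedAUCComparison(delta=delta, se=se, z=float(z), p=float(p), ci95=ci)
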