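"""Biomarker statistic and cohort-level inference.

The central statistic is ``R_day_n``: the percentage of the donor-derived
sDNAM-1 exposure (area under the concentration curve over the first ``n``
days) attributable to the transient source,

    R_day_n = 100 * AUC(x1; 0..n) / (AUC(x1; 0..n) + AUC(x2; 0..n)),

the recipient-derived residual x3 being excluded by construction.  Around it
sit the cohort-level procedures: Welch/Wilcoxon group comparisons, the exact
binomial test on model-preference counts with a Clopper-Pearson interval,
2x2 Fisher tests for the covariate table, and ROC analysis with the
closest-to-(0,1) cutoff and a DeLong confidence interval for the AUC.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import integrate, stats
from sklearn.metrics import roc_curve

from .model import ModelParameters, persistent_solution, transient_solution

__all__ = [
    "RdayValue",
    "GroupComparison",
    "RocResult",
    "BinomialTestResult",
    "compute_rday",
    "half_life",
    "compare_groups",
    "binomial_preference_test",
    "roc_analysis",
    "fisher_2x2",
]


@dataclass(frozen=True)
class RdayValue:
    patient_id: str
    day_n: float
    auc_x1: float
    auc_x2: float

    @property
    def r_day_n(self) -> float:
        """Transient share of donor-derived exposure, in percent [0, 100]."""
        return 100.0 * (self.auc_x1 / (self.auc_x1 + self.auc_x2))


@dataclass(frozen=True)
class GroupComparison:
    horizon: float
    n_neg: int
    n_pos: int
    mean_neg: float
    mean_pos: float
    sd_neg: float
    sd_pos: float
    diff_mean: float
    ci_low: float
    ci_high: float
    p_t: float
    p_w: float


@dataclass(frozen=True)
class BinomialTestResult:
    k: int
    n: int
    proportion: float
    p_value: float
    ci_low: float
    ci_high: float


@dataclass(frozen=True)
class RocResult:
    horizon: float
    auc: float
    auc_ci_low: float
    auc_ci_high: float
    cutoff: float
    sensitivity: float
    specificity: float
    accuracy: float
    tp: int
    tn: int
    fp: int
    fn: int


def compute_rday(params: ModelParameters, day_n: float,
                 patient_id: str = "") -> RdayValue:
    """Integrate x1 and x2 over [0, day_n] by adaptive quadrature and form R_day_n.

    Raises ``ValueError`` when both AUCs vanish (lam = 0 and x2_0 = 0: the
    ratio is undefined).
    """
    if not day_n > 0:
        raise ValueError("day_n must be > 0")
    auc1 = 0.0
    if params.lam > 0:
        # integrand peaks near the gamma-kernel mode; pass it as a breakpoint
        peak = (params.k - 1.0) * params.theta
        pts = [peak] if 0.0 < peak < day_n else None
        auc1, _ = integrate.quad(
            lambda s: float(transient_solution(s, params)[0]),
            0.0, day_n, epsrel=1e-8, epsabs=1e-12, limit=200, points=pts,
        )
    auc2 = 0.0
    if params.x2_0 > 0:
        auc2, _ = integrate.quad(
            lambda s: float(persistent_solution(s, params)[0]),
            0.0, day_n, epsrel=1e-8, epsabs=1e-12, limit=200,
        )
    if auc1 + auc2 <= 0.0:
        raise ValueError(
            "R_day_n undefined: both donor-derived AUCs are zero "
            "(lam = 0 and x2_0 = 0)"
        )
    return RdayValue(patient_id=patient_id, day_n=day_n,
                     auc_x1=float(auc1), auc_x2=float(auc2))


def half_life(mu: float) -> float:
    """Serum half-life ln(2)/mu in days, for clearance rate mu > 0 per day."""
    if not mu > 0:
        raise ValueError(f"mu must be > 0, got {mu}")
    return math.log(2.0) / mu


def compare_groups(values, labels, horizon: float = float("nan")) -> GroupComparison:
    """Welch t-test, Wilcoxon rank-sum and Welch 95% CI of the mean difference.

    ``labels`` are boolean (True = GVHD+); the difference is pos - neg.  The
    rank-sum test uses midranks for ties and the exact distribution when both
    groups are small (n <= 50) and tie-free, otherwise the continuity-corrected
    normal approximation.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    pos, neg = values[labels], values[~labels]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both groups must be nonempty")
    if pos.size < 2 or neg.size < 2:
        raise ValueError("each group needs >= 2 values for the t-test and CI")
    tt = stats.ttest_ind(pos, neg, equal_var=False)
    ci = tt.confidence_interval(0.95)
    exact_ok = (pos.size <= 50 and neg.size <= 50
                and np.unique(values).size == values.size)
    mw = stats.mannwhitneyu(
        pos, neg, alternative="two-sided",
        method="exact" if exact_ok else "asymptotic",
        use_continuity=True,
    )
    return GroupComparison(
        horizon=horizon, n_neg=int(neg.size), n_pos=int(pos.size),
        mean_neg=float(neg.mean()), mean_pos=float(pos.mean()),
        sd_neg=float(neg.std(ddof=1)), sd_pos=float(pos.std(ddof=1)),
        diff_mean=float(pos.mean() - neg.mean()),
        ci_low=float(ci.low), ci_high=float(ci.high),
        p_t=float(tt.pvalue), p_w=float(mw.pvalue),
    )


def binomial_preference_test(k: int, n: int) -> BinomialTestResult:
    """Exact two-sided binomial test of k/n against 0.5 with Clopper-Pearson CI.

    The two-sided p-value sums all outcome probabilities not exceeding that of
    the observed count (the convention of standard statistical software).
    """
    if not (0 <= k <= n) or n < 1:
        raise ValueError("need 0 <= k <= n and n >= 1")
    bt = stats.binomtest(k, n, 0.5, alternative="two-sided")
    ci = bt.proportion_ci(confidence_level=0.95, method="exact")
    return BinomialTestResult(
        k=k, n=n, proportion=k / n, p_value=float(bt.pvalue),
        ci_low=float(ci.low), ci_high=float(ci.high),
    )


def fisher_2x2(table) -> float:
    """Two-sided Fisher's exact p for a 2x2 count table.

    Sums hypergeometric probabilities <= the observed table's probability.
    A degenerate table (a zero row or column margin) carries no information
    about association and returns 1.0 with a warning.
    """
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or np.any(t < 0):
        raise ValueError("table must be 2x2 with nonnegative counts")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        warnings.warn("degenerate 2x2 margin; p = 1.0", RuntimeWarning, stacklevel=2)
        return 1.0
    return float(stats.fisher_exact(t, alternative="two-sided")[1])


def _delong_auc_variance(pos: np.ndarray, neg: np.ndarray) -> tuple[float, float]:
    """AUC and its DeLong variance from the placement structural components."""
    m, n = pos.size, neg.size
    allv = np.concatenate([pos, neg])
    # midranks handle ties exactly as in DeLong's estimator
    ranks = stats.rankdata(allv)
    rpos, rneg = ranks[:m], ranks[m:]
    auc = (rpos.sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (rpos - stats.rankdata(pos)) / n - auc  # components over positives
    v01 = 1.0 - (rneg - stats.rankdata(neg)) / m - auc  # over negatives
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return float(auc), float(s10 / m + s01 / n)


def roc_analysis(values, labels, horizon: float = float("nan")) -> RocResult:
    """Empirical ROC, DeLong 95% CI, and the closest-to-(0,1) operating point.

    Positive call convention: ``value >= cutoff`` predicts GVHD(+).  Among all
    distinct thresholds, the cutoff minimizes the Euclidean distance
    sqrt((1-sens)^2 + (1-spec)^2) to the ideal corner (0, 1); distance ties
    break toward the higher-specificity (larger) cutoff.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    pos, neg = values[labels], values[~labels]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be present")
    auc, var = _delong_auc_variance(pos, neg)
    se = math.sqrt(var)
    lo, hi = auc - 1.959963984540054 * se, auc + 1.959963984540054 * se
    fpr, tpr, thr = roc_curve(labels.astype(int), values, drop_intermediate=False)
    # drop the (0,0) sentinel threshold inf; candidate cutoffs are the data values
    finite = np.isfinite(thr)
    fpr, tpr, thr = fpr[finite], tpr[finite], thr[finite]
    dist = np.sqrt((1.0 - tpr) ** 2 + fpr**2)
    # argmin over distance; among ties prefer higher specificity = lower fpr,
    # then the larger cutoff
    order = np.lexsort((-thr, fpr, dist))
    best = order[0]
    cutoff = float(thr[best])
    pred = values >= cutoff
    tp = int(np.sum(pred & labels))
    tn = int(np.sum(~pred & ~labels))
    fp = int(np.sum(pred & ~labels))
    fn = int(np.sum(~pred & labels))
    return RocResult(
        horizon=horizon, auc=auc,
        auc_ci_low=max(lo, 0.0), auc_ci_high=min(hi, 1.0),
        cutoff=cutoff,
        sensitivity=tp / (tp + fn), specificity=tn / (tn + fp),
        accuracy=(tp + tn) / (tp + tn + fp + fn),
        tp=tp, tn=tn, fp=fp, fn=fn,
    )
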