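"""Statistical evaluation of longitudinal biomarkers and classifiers.

Covers the power/sensitivity analyses used to compare biomarkers:
minimum sample size from longitudinal change, 24-month change rates,
paired tests with paired Cohen's d, Pearson correlation of change rates
against clinical scores, rank-based ROC/AUC with bootstrap confidence
intervals, confusion-matrix classification metrics, and ICV head-size
normalization of regional volumes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from sklearn.metrics import roc_curve

# (z_{0.975} + z_{0.80})^2: 80% power at two-sided alpha = 0.05
C_DEFAULT = float((sps.norm.ppf(0.975) + sps.norm.ppf(0.80)) ** 2)


@dataclass
class LongitudinalSeries:
    """Paired per-subject biomarker totals at baseline and 24 months."""

    subjects: list[str]
    baseline: np.ndarray
    followup: np.ndarray
    group: str = ""

    def __post_init__(self) -> None:
        self.baseline = np.asarray(self.baseline, dtype=float)
        self.followup = np.asarray(self.followup, dtype=float)
        if self.baseline.shape != self.followup.shape or len(self.subjects) != self.baseline.size:
            raise ValueError("baseline and follow-up must pair the same subjects")


@dataclass
class MetricsReport:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def acc(self) -> float:
        return (self.tp + self.tn) / max(self.tp + self.tn + self.fp + self.fn, 1)

    @property
    def sen(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else float("nan")

    @property
    def spe(self) -> float:
        return self.tn / (self.tn + self.fp) if self.tn + self.fp else float("nan")


def min_sample_size(
    baseline, followup=None, C: float = C_DEFAULT
) -> int:
    """Minimum group size N = ceil(C sigma^2 / (m - b)^2) from paired change.

    sigma is the (ddof=1) standard deviation of the per-subject 24-month
    change and (m - b) its mean.  The default C corresponds to 80% power at
    two-sided alpha = 0.05; a smaller N means a more sensitive biomarker.
    Accepts either a :class:`LongitudinalSeries` or two paired arrays.
    """
    if followup is None:
        series = baseline
        baseline, followup = series.baseline, series.followup
    b = np.asarray(baseline, dtype=float)
    m = np.asarray(followup, dtype=float)
    if b.size < 2 or b.shape != m.shape:
        raise ValueError("need >= 2 paired observations")
    change = m - b
    effect = change.mean()
    if effect == 0:
        raise ZeroDivisionError("mean change is zero; sample size undefined")
    sigma = change.std(ddof=1)
    return int(math.ceil(C * sigma**2 / effect**2))


def change_rate(first: float, second: float) -> float:
    """Relative change (second - first) / first."""
    if first == 0:
        raise ZeroDivisionError("baseline value is zero; rate undefined")
    return (second - first) / first


def paired_test(baseline, followup) -> tuple[float, float]:
    """Two-sided paired t-test p-value and paired Cohen's d.

    d = mean(diff) / sd(diff); sign follows follow-up minus baseline.
    """
    b = np.asarray(baseline, dtype=float)
    m = np.asarray(followup, dtype=float)
    if b.size < 2 or b.shape != m.shape:
        raise ValueError("need >= 2 paired observations")
    diff = m - b
    sd = diff.std(ddof=1)
    if sd == 0:
        raise ZeroDivisionError("zero variance of paired differences")
    p = float(sps.ttest_rel(m, b).pvalue)
    return p, float(diff.mean() / sd)


def pearson_corr(x, y) -> tuple[float, float]:
    """Pearson correlation coefficient and its two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3 or x.shape != y.shape:
        raise ValueError("need >= 3 paired observations")
    if x.std() == 0 or y.std() == 0:
        raise ZeroDivisionError("zero variance input")
    r = sps.pearsonr(x, y)
    return float(r.statistic), float(r.pvalue)


def mann_whitney_auc(scores, labels) -> float:
    """AUC via the rank (Mann-Whitney) formulation; ties count 1/2."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = sps.rankdata(s)
    u = ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def roc_auc(
    scores,
    labels,
    n_boot: int = 2000,
    seed: int = 0,
    ci_level: float = 0.95,
) -> dict:
    """AUC, bootstrap CI and ROC curve points for a binary discrimination.

    AUC uses the rank formulation; the confidence interval is a stratified
    bootstrap (resampling positives and negatives separately) percentile
    interval with ``n_boot`` replicates.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    auc = mann_whitney_auc(s, y)
    pos = np.flatnonzero(y == 1)
    neg = np.flatnonzero(y == 0)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for i in range(n_boot):
        bp = rng.choice(pos, size=pos.size, replace=True)
        bn = rng.choice(neg, size=neg.size, replace=True)
        idx = np.concatenate([bp, bn])
        boots[i] = mann_whitney_auc(s[idx], y[idx])
    alpha = (1.0 - ci_level) / 2.0
    lo, hi = np.quantile(boots, [alpha, 1.0 - alpha])
    fpr, tpr, thresholds = roc_curve(y, s)
    return {
        "auc": auc,
        "ci": (float(lo), float(hi)),
        "fpr": fpr,
        "tpr": tpr,
        "thresholds": thresholds,
    }


def classification_report(predicted, truth, positive_class) -> MetricsReport:
    """Confusion counts and ACC/SEN/SPE for a binary decision."""
    pred = np.asarray(predicted)
    true = np.asarray(truth)
    if pred.shape != true.shape:
        raise ValueError("predicted and truth lengths differ")
    if positive_class not in true:
        raise ValueError(f"positive class {positive_class!r} absent from truth")
    p = pred == positive_class
    t = true == positive_class
    return MetricsReport(
        tp=int((p & t).sum()),
        tn=int((~p & ~t).sum()),
        fp=int((p & ~t).sum()),
        fn=int((~p & t).sum()),
    )


def icv_adjust(volumes, icv: float) -> np.ndarray:
    """Normalize regional volumes by intracranial vault volume (volume/ICV)."""
    if icv <= 0:
        raise ValueError("ICV must be positive")
    return np.asarray(volumes, dtype=float) / icv
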