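"""Diagnostic accuracy and cohort comparison statistics.

Confusion-matrix metrics carry 95% confidence intervals: exact
Clopper-Pearson for sensitivity, specificity and accuracy; standard-logit
(Mercaldo) intervals for the predictive values PPV/NPV, falling back to
Clopper-Pearson when the logit variance is undefined at a boundary
(sens or spec of 0/100%); and the Simel log method for likelihood
ratios.  The binary-prediction AUC equals (sens + spec)/2 and is
reported with a Hanley-McNeil interval.

The planning-group comparison layer provides Welch's t-test with a
Mann-Whitney U companion, standardized mean differences, and 1:k greedy
nearest-neighbour propensity matching without replacement under a
caliper expressed in standard deviations of the logit propensity score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.linear_model import LogisticRegression
from statsmodels.stats.proportion import proportion_confint

Z95 = sps.norm.ppf(0.975)


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 confusion counts at a fixed decision threshold."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.total == 0:
            raise ValueError("confusion table is empty")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @classmethod
    def from_predictions(cls, predictions: Sequence[int], labels: Sequence[int]) -> "ConfusionCounts":
        p = np.asarray(predictions, dtype=int)
        y = np.asarray(labels, dtype=int)
        return cls(
            tp=int(((p == 1) & (y == 1)).sum()),
            fp=int(((p == 1) & (y == 0)).sum()),
            tn=int(((p == 0) & (y == 0)).sum()),
            fn=int(((p == 0) & (y == 1)).sum()),
        )


@dataclass(frozen=True)
class MetricEstimate:
    """Point estimate with a 95% CI (None when undefined)."""

    value: float
    ci: Optional[tuple[float, float]]
    method: str

    def __str__(self) -> str:
        if self.ci is None:
            return f"{self.value:.3g}"
        return f"{self.value:.3g} ({self.ci[0]:.1f}-{self.ci[1]:.1f})"


def _clopper_pearson(x: int, n: int) -> tuple[float, float]:
    lo, hi = proportion_confint(x, n, alpha=0.05, method="beta")
    return float(lo) * 100.0, float(hi) * 100.0


def _logit_predictive_ci(pv: float, var_logit: float) -> tuple[float, float]:
    lg = np.log(pv / (1.0 - pv))
    lo = 1.0 / (1.0 + np.exp(-(lg - Z95 * np.sqrt(var_logit))))
    hi = 1.0 / (1.0 + np.exp(-(lg + Z95 * np.sqrt(var_logit))))
    return lo * 100.0, hi * 100.0


@dataclass
class DiagnosticReport:
    """Sensitivity/specificity/PPV/NPV/accuracy/LR+-/AUC with 95% CIs.

    Proportions are reported in percent; likelihood ratios and AUC on
    their natural scales.  Metrics with a zero denominator are None.
    """

    counts: ConfusionCounts
    sensitivity: Optional[MetricEstimate] = None
    specificity: Optional[MetricEstimate] = None
    ppv: Optional[MetricEstimate] = None
    npv: Optional[MetricEstimate] = None
    accuracy: Optional[MetricEstimate] = None
    lr_positive: Optional[MetricEstimate] = None
    lr_negative: Optional[MetricEstimate] = None
    auc: Optional[MetricEstimate] = None

    def as_dict(self) -> dict:
        out = {"counts": {"tp": self.counts.tp, "fp": self.counts.fp,
                          "tn": self.counts.tn, "fn": self.counts.fn}}
        for name in ("sensitivity", "specificity", "ppv", "npv", "accuracy",
                     "lr_positive", "lr_negative", "auc"):
            m = getattr(self, name)
            out[name] = None if m is None else {
                "value": m.value,
                "ci95": None if m.ci is None else list(m.ci),
                "method": m.method,
            }
        return out

    def format_table(self) -> str:
        rows = [
            ("Sensitivity", self.sensitivity, "%"),
            ("Specificity", self.specificity, "%"),
            ("Area under the curve", self.auc, ""),
            ("Positive likelihood ratio", self.lr_positive, ""),
            ("Negative likelihood ratio", self.lr_negative, ""),
            ("Positive predictive value", self.ppv, "%"),
            ("Negative predictive value", self.npv, "%"),
            ("Accuracy", self.accuracy, "%"),
        ]
        lines = [f"{'Statistic':<28s}Value (95% CI)"]
        for name, m, unit in rows:
            if m is None:
                lines.append(f"{name:<28s}undefined")
            elif m.ci is None:
                lines.append(f"{name:<28s}{m.value:.3g}{unit}")
            else:
                lines.append(
                    f"{name:<28s}{m.value:.3g}{unit} ({m.ci[0]:.1f}-{m.ci[1]:.1f})"
                )
        return "\n".join(lines)


def confusion_metrics(c: ConfusionCounts) -> DiagnosticReport:
    """Full diagnostic-accuracy report from 2x2 counts (percent scale)."""
    n1 = c.tp + c.fn  # diseased
    n0 = c.tn + c.fp  # non-diseased
    rep = DiagnosticReport(counts=c)

    se = c.tp / n1 if n1 else None
    sp = c.tn / n0 if n0 else None
    if se is not None:
        rep.sensitivity = MetricEstimate(se * 100, _clopper_pearson(c.tp, n1), "clopper-pearson")
    if sp is not None:
        rep.specificity = MetricEstimate(sp * 100, _clopper_pearson(c.tn, n0), "clopper-pearson")
    rep.accuracy = MetricEstimate(
        (c.tp + c.tn) / c.total * 100, _clopper_pearson(c.tp + c.tn, c.total), "clopper-pearson"
    )

    if c.tp + c.fp > 0:
        ppv = c.tp / (c.tp + c.fp)
        if se not in (None, 0.0) and sp not in (None, 1.0) and 0.0 < ppv < 1.0:
            var = (1.0 - se) / (se * n1) + sp / ((1.0 - sp) * n0)
            rep.ppv = MetricEstimate(ppv * 100, _logit_predictive_ci(ppv, var), "std-logit")
        else:
            rep.ppv = MetricEstimate(ppv * 100, _clopper_pearson(c.tp, c.tp + c.fp),
                                     "clopper-pearson")
    if c.tn + c.fn > 0:
        npv = c.tn / (c.tn + c.fn)
        if se not in (None, 1.0) and sp not in (None, 0.0) and 0.0 < npv < 1.0:
            var = se / ((1.0 - se) * n1) + (1.0 - sp) / (sp * n0)
            rep.npv = MetricEstimate(npv * 100, _logit_predictive_ci(npv, var), "std-logit")
        else:
            rep.npv = MetricEstimate(npv * 100, _clopper_pearson(c.tn, c.tn + c.fn),
                                     "clopper-pearson")

    if se is not None and sp is not None:
        if sp < 1.0:
            lr_pos = se / (1.0 - sp)
            if c.tp > 0 and c.fp > 0:
                var = (1.0 / c.tp - 1.0 / n1) + (1.0 / c.fp - 1.0 / n0)
                half = Z95 * np.sqrt(var)
                ci = (lr_pos * np.exp(-half), lr_pos * np.exp(half))
            else:
                ci = None
            rep.lr_positive = MetricEstimate(lr_pos, ci, "log")
        if sp > 0.0:
            lr_neg = (1.0 - se) / sp
            if c.fn > 0 and c.tn > 0:
                var = (1.0 / c.fn - 1.0 / n1) + (1.0 / c.tn - 1.0 / n0)
                half = Z95 * np.sqrt(var)
                ci = (lr_neg * np.exp(-half), lr_neg * np.exp(half))
            else:
                ci = None  # LR- = 0 exactly when FN = 0
            rep.lr_negative = MetricEstimate(lr_neg, ci, "log")
        rep.auc = _binary_auc_estimate(c, se, sp)
    return rep


def _binary_auc_estimate(c: ConfusionCounts, se: float, sp: float) -> MetricEstimate:
    auc = (se + sp) / 2.0
    n1, n0 = c.tp + c.fn, c.tn + c.fp
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc**2 / (1.0 + auc)
    var = (
        auc * (1.0 - auc) + (n1 - 1) * (q1 - auc**2) + (n0 - 1) * (q2 - auc**2)
    ) / (n1 * n0)
    half = Z95 * np.sqrt(max(var, 0.0))
    return MetricEstimate(
        auc, (max(0.0, auc - half), min(1.0, auc + half)), "hanley-mcneil"
    )


def binary_auc(c: ConfusionCounts) -> float:
    """AUC of the binary prediction used as a score.

    AUC = [TP*TN + 0.5*(TP*FP + FN*TN)] / [(TP+FN)*(TN+FP)], which equals
    (sensitivity + specificity)/2.
    """
    n1, n0 = c.tp + c.fn, c.tn + c.fp
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    return (c.tp * c.tn + 0.5 * (c.tp * c.fp + c.fn * c.tn)) / (n1 * n0)


@dataclass
class GroupComparison:
    """Two-group summary with Welch t and Mann-Whitney U tests."""

    mean_pos: float
    sd_pos: float
    n_pos: int
    mean_neg: float
    sd_neg: float
    n_neg: int
    t_stat: float
    p_welch: float
    u_stat: float
    p_mannwhitney: float

    def as_dict(self) -> dict:
        return {
            "positive": {"mean": self.mean_pos, "sd": self.sd_pos, "n": self.n_pos},
            "negative": {"mean": self.mean_neg, "sd": self.sd_neg, "n": self.n_neg},
            "welch_t": {"t": self.t_stat, "p": self.p_welch},
            "mann_whitney": {"u": self.u_stat, "p": self.p_mannwhitney},
        }


def compare_eri_groups(pos: Sequence[float], neg: Sequence[float]) -> GroupComparison:
    """Welch two-tailed t-test of ERI between groups, with a rank-test companion."""
    pos = np.asarray(pos, dtype=float)
    neg = np.asarray(neg, dtype=float)
    if len(pos) < 2 or len(neg) < 2:
        raise ValueError("each group needs at least 2 observations")
    if pos.std(ddof=1) == 0 and neg.std(ddof=1) == 0 and pos.mean() == neg.mean():
        t_stat, p_t = 0.0, 1.0
    else:
        t_stat, p_t = sps.ttest_ind(pos, neg, equal_var=False)
    try:
        u_stat, p_u = sps.mannwhitneyu(pos, neg, alternative="two-sided")
    except ValueError:  # all values identical
        u_stat, p_u = len(pos) * len(neg) / 2.0, 1.0
    return GroupComparison(
        mean_pos=float(pos.mean()), sd_pos=float(pos.std(ddof=1)), n_pos=len(pos),
        mean_neg=float(neg.mean()), sd_neg=float(neg.std(ddof=1)), n_neg=len(neg),
        t_stat=float(t_stat), p_welch=float(p_t),
        u_stat=float(u_stat), p_mannwhitney=float(p_u),
    )


def smd(treated: Sequence[float], control: Sequence[float], kind: str = "continuous") -> float:
    """Standardized mean difference between two arms.

    continuous: (m1 - m2) / sqrt((s1^2 + s2^2)/2)
    binary:     (p1 - p2) / sqrt((p1(1-p1) + p2(1-p2))/2)
    """
    t = np.asarray(treated, dtype=float)
    ctrl = np.asarray(control, dtype=float)
    if kind == "binary":
        p1, p2 = t.mean(), ctrl.mean()
        pooled = (p1 * (1 - p1) + p2 * (1 - p2)) / 2.0
        diff = p1 - p2
    elif kind == "continuous":
        if len(t) < 2 or len(ctrl) < 2:
            raise ValueError("continuous SMD needs n >= 2 per arm")
        diff = t.mean() - ctrl.mean()
        pooled = (t.var(ddof=1) + ctrl.var(ddof=1)) / 2.0
    else:
        raise ValueError(f"unknown SMD kind {kind!r}")
    if pooled == 0:
        if diff == 0:
            return 0.0
        warnings.warn("zero pooled variance with unequal means: SMD infinite",
                      stacklevel=2)
        return float(np.inf) * np.sign(diff)
    return float(diff / np.sqrt(pooled))


@dataclass
class MatchResult:
    """Outcome of 1:k caliper propensity matching without replacement."""

    treated_ids: list
    control_ids: dict  # treated id -> list of matched control ids
    propensity: pd.Series
    caliper: float
    ratio: int
    smd_before: pd.Series
    smd_after: pd.Series
    dropped_treated: list

    @property
    def n_matched(self) -> int:
        return len(self.control_ids)

    def matched_index(self) -> list:
        out = list(self.control_ids.keys())
        for v in self.control_ids.values():
            out.extend(v)
        return out


def propensity_match(
    frame: pd.DataFrame,
    covariates: Sequence[str],
    group_col: str = "group",
    ratio: int = 3,
    caliper_sd: float = 0.2,
    binary_covariates: Optional[set] = None,
) -> MatchResult:
    """1:k greedy nearest-neighbour matching on the logit propensity score.

    The propensity of belonging to the treated arm (``group_col == 1``)
    is a logistic regression on ``covariates``.  Treated units are
    processed in descending propensity order; each receives its ``ratio``
    nearest unused controls on the logit scale, all within the caliper
    (``caliper_sd`` x SD of the logit propensity).  Treated units that
    cannot be given ``ratio`` in-caliper controls are dropped with a
    warning.  Standardized mean differences are reported before and
    after matching.
    """
    if binary_covariates is None:
        binary_covariates = set()
    y = frame[group_col].to_numpy(dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("both groups must be present for matching")
    X = frame[list(covariates)].to_numpy(dtype=float)
    Xs = (X - X.mean(axis=0)) / np.where(X.std(axis=0) == 0, 1.0, X.std(axis=0))
    clf = LogisticRegression(C=1e4, solver="lbfgs", max_iter=5000)
    clf.fit(Xs, y)
    ps = np.clip(clf.predict_proba(Xs)[:, 1], 1e-12, 1 - 1e-12)
    logit = np.log(ps / (1.0 - ps))
    caliper = caliper_sd * float(np.std(logit, ddof=1))

    ids = frame.index.to_numpy()
    treated = ids[y == 1]
    control = ids[y == 0]
    logit_s = pd.Series(logit, index=frame.index)
    order = treated[np.argsort(-logit_s[treated].to_numpy())]

    available = set(control)
    matches: dict = {}
    dropped = []
    for t_id in order:
        avail = np.array([c for c in control if c in available])
        if len(avail) < ratio:
            dropped.append(t_id)
            continue
        dist = np.abs(logit_s[avail].to_numpy() - logit_s[t_id])
        in_cal = dist <= caliper
        if in_cal.sum() < ratio:
            dropped.append(t_id)
            continue
        pick = avail[np.argsort(dist, kind="stable")[:ratio]]
        if np.any(np.abs(logit_s[pick].to_numpy() - logit_s[t_id]) > caliper):
            dropped.append(t_id)
            continue
        matches[t_id] = list(pick)
        available.difference_update(pick)
    if dropped:
        warnings.warn(
            f"{len(dropped)} treated unit(s) dropped: fewer than {ratio} "
            "in-caliper controls available",
            stacklevel=2,
        )

    def _smds(t_ids, c_ids) -> pd.Series:
        out = {}
        for cov in covariates:
            kind = "binary" if cov in binary_covariates else "continuous"
            out[cov] = smd(frame.loc[t_ids, cov], frame.loc[c_ids, cov], kind=kind)
        return pd.Series(out)

    smd_before = _smds(list(treated), list(control))
    if matches:
        matched_t = list(matches.keys())
        matched_c = [c for v in matches.values() for c in v]
        smd_after = _smds(matched_t, matched_c)
    else:
        smd_after = pd.Series(dtype=float)
    return MatchResult(
        treated_ids=list(treated),
        control_ids=matches,
        propensity=pd.Series(ps, index=frame.index, name="propensity"),
        caliper=caliper,
        ratio=ratio,
        smd_before=smd_before,
        smd_after=smd_after,
        dropped_treated=dropped,
    )
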