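"""Phenotyping accuracy: confusion matrices, sensitivity/specificity with
confidence intervals, mean-accuracy comparison, and discrepancy analysis.

Given patient-level binary flags from two labeling sources (e.g. an
administrative ICD coding and the note-extraction pipeline) and a gold
standard from manual review, this module computes the standard validation
statistics: per-condition sensitivity = TP/(TP+FN) and specificity =
TN/(TN+FP) with 95% intervals, condition-weighted means with standard
errors, and a two-sample t-test between the per-condition accuracy
columns of two sources.

The default interval is the Wilson score interval, which stays well
behaved at proportions near 0 and 1 — exactly where note-extraction
sensitivities tend to live. A t-quantile normal-approximation interval
(``t_normal``) and the exact Clopper–Pearson interval (``exact``) are
also available; the normal approximation is known to misbehave near the
boundaries and is provided for comparability with analyses that used it.

A recurring discrepancy pattern gets first-class treatment: a comparator
false negative on a patient whose condition is chronic/historical (coders
often omit chronic conditions from index-admission codes). These are
tagged ``chronic_omission`` and tallied per condition.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from notepheno.errors import KeyMismatchError, UndefinedMetricError

CI_METHODS = ("wilson", "t_normal", "exact")


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 tally of predicted vs gold binary flags."""

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.fp + other.fp,
            self.fn + other.fn, self.tn + other.tn,
        )


@dataclass(frozen=True)
class AccuracyEstimate:
    """A proportion (sensitivity or specificity) with its interval."""

    metric: str
    point: float
    ci_low: float
    ci_high: float
    level: float
    method: str
    k: int
    m: int

    def __str__(self) -> str:
        return (
            f"{self.metric}={self.point:.2f} "
            f"({self.ci_low:.2f}-{self.ci_high:.2f}, {self.level:.0%} {self.method})"
        )


def confusion(pred: dict[str, int], gold: dict[str, int]) -> ConfusionCounts:
    """Tally predicted against gold flags over an identical patient key set."""
    pk, gk = set(pred), set(gold)
    if pk != gk:
        raise KeyMismatchError(pk - gk, gk - pk)
    tp = fp = fn = tn = 0
    for key, g in gold.items():
        p = pred[key]
        if g and p:
            tp += 1
        elif g and not p:
            fn += 1
        elif not g and p:
            fp += 1
        else:
            tn += 1
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)


def _interval(k: int, m: int, level: float, method: str) -> tuple[float, float]:
    if method == "wilson":
        lo, hi = proportion_confint(k, m, alpha=1 - level, method="wilson")
    elif method == "exact":
        lo, hi = proportion_confint(k, m, alpha=1 - level, method="beta")
    elif method == "t_normal":
        p = k / m
        se = np.sqrt(p * (1 - p) / m)
        q = stats.t.ppf((1 + level) / 2, df=max(m - 1, 1))
        lo, hi = p - q * se, p + q * se
    else:
        raise ValueError(f"unknown CI method {method!r}; choose from {CI_METHODS}")
    # the degenerate proportions have mathematically exact bounds
    if k == m:
        hi = 1.0
    if k == 0:
        lo = 0.0
    return float(np.clip(lo, 0.0, 1.0)), float(np.clip(hi, 0.0, 1.0))


def proportion_estimate(
    k: int, m: int, metric: str, level: float = 0.95, method: str = "wilson"
) -> AccuracyEstimate:
    """Point estimate k/m with a ``level`` confidence interval."""
    if m <= 0:
        raise UndefinedMetricError(f"{metric} undefined: zero denominator")
    lo, hi = _interval(k, m, level, method)
    return AccuracyEstimate(
        metric=metric, point=k / m, ci_low=lo, ci_high=hi,
        level=level, method=method, k=k, m=m,
    )


def sens_spec(
    c: ConfusionCounts, level: float = 0.95, method: str = "wilson"
) -> tuple[AccuracyEstimate, AccuracyEstimate]:
    """Sensitivity and specificity with confidence intervals."""
    sens = proportion_estimate(c.tp, c.tp + c.fn, "sensitivity", level, method)
    spec = proportion_estimate(c.tn, c.tn + c.fp, "specificity", level, method)
    return sens, spec


@dataclass(frozen=True)
class MeanAccuracy:
    """Condition-weighted mean of per-condition point estimates."""

    mean: float
    sem: float
    n: int


def mean_accuracy(values: Sequence[float]) -> MeanAccuracy:
    """Arithmetic mean and SEM of per-condition accuracies.

    Conditions are weighted equally (not pooled over patients): the mean
    answers "how accurate is this source for a typical study question",
    not "for a typical patient".
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("mean_accuracy needs at least one value")
    sem = float(stats.sem(arr)) if arr.size > 1 else 0.0
    return MeanAccuracy(mean=float(arr.mean()), sem=sem, n=arr.size)


def compare_means(
    a: Sequence[float], b: Sequence[float], equal_var: bool = True
) -> tuple[float, float]:
    """Two-sample t-test between two per-condition accuracy columns.

    Pooled (equal-variance) by default; set ``equal_var=False`` for
    Welch's correction. Returns (t statistic, two-sided p).
    """
    if len(a) < 2 or len(b) < 2:
        raise ValueError("compare_means needs at least two values per sample")
    res = stats.ttest_ind(np.asarray(a, float), np.asarray(b, float), equal_var=equal_var)
    return float(res.statistic), float(res.pvalue)


@dataclass(frozen=True)
class DiscrepancyRecord:
    """One patient whose comparator flag disagrees with the gold standard."""

    patient_id: str
    condition: str
    comparator_flag: int
    note_flag: Optional[int]
    gold_flag: int
    reason_tag: str  # chronic_omission | other | unreviewed


def discrepancy_breakdown(
    comparator: dict[str, int],
    gold: dict[str, int],
    condition: str,
    note: Optional[dict[str, int]] = None,
    chronic: Optional[dict[str, bool]] = None,
) -> tuple[list[DiscrepancyRecord], int]:
    """All comparator/gold disagreements, with chronic-omission tagging.

    A comparator false negative (comparator 0, gold 1) on a patient with
    chronic/historical status is tagged ``chronic_omission``; with known
    non-chronic status, ``other``; with unknown status, ``unreviewed``.
    Comparator false positives are always ``other``. Returns the records
    and the chronic-omission count for ``condition``.
    """
    ck, gk = set(comparator), set(gold)
    if ck != gk:
        raise KeyMismatchError(ck - gk, gk - ck)
    chronic = chronic or {}
    records: list[DiscrepancyRecord] = []
    n_chronic_omission = 0
    for pid in sorted(gold):
        g, c = gold[pid], comparator[pid]
        if g == c:
            continue
        if c == 0 and g == 1:
            if pid not in chronic:
                tag = "unreviewed"
            elif chronic[pid]:
                tag = "chronic_omission"
                n_chronic_omission += 1
            else:
                tag = "other"
        else:
            tag = "other"
        records.append(
            DiscrepancyRecord(
                patient_id=pid,
                condition=condition,
                comparator_flag=c,
                note_flag=None if note is None else note.get(pid),
                gold_flag=g,
                reason_tag=tag,
            )
        )
    return records, n_chronic_omission
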