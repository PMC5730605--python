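"""Evaluation statistics for detection and robot performance.

Conventions: the erroneous trial is the positive class everywhere, so
TPR is the fraction of errors flagged and TNR the fraction of correct
trials passed; balanced accuracy is their arithmetic mean.  Robot action
accuracy is 100 x (total - errors) / total, with an optional truncation
mode at two decimals for reproducing tabulated values that were truncated
rather than rounded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "MetricsReport",
    "balanced_accuracy",
    "action_accuracy",
    "pearson",
    "signed_rank_test",
    "session_report",
]


@dataclass
class MetricsReport:
    """Bundle of the quantities reported for one session or dataset."""

    tpr: float | None = None
    tnr: float | None = None
    bacc: float | None = None
    accumulated_errors: list[int] = field(default_factory=list)
    accumulated_regret: list[int] = field(default_factory=list)
    accuracy_pct: float | None = None
    corr_r: float | None = None
    wilcoxon_p: float | None = None

    def to_dict(self) -> dict:
        return {
            "tpr": self.tpr,
            "tnr": self.tnr,
            "bacc": self.bacc,
            "accumulated_errors": self.accumulated_errors,
            "accumulated_regret": self.accumulated_regret,
            "accuracy_pct": self.accuracy_pct,
            "corr_r": self.corr_r,
            "wilcoxon_p": self.wilcoxon_p,
        }


def balanced_accuracy(decisions, labels) -> tuple[float, float, float]:
    """(TPR, TNR, bACC) of binary decisions against binary labels.

    ``decisions`` and ``labels`` are truthy for the positive (erroneous /
    ErrP) class.  Raises when only one class is present, since one of the
    two rates is then undefined.
    """
    d = np.asarray([bool(v) for v in decisions])
    y = np.asarray([bool(v) for v in labels])
    if d.shape != y.shape:
        raise ValueError("decisions and labels must have the same length")
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to compute TPR and TNR")
    tpr = float((d & y).sum() / n_pos)
    tnr = float((~d & ~y).sum() / n_neg)
    return tpr, tnr, (tpr + tnr) / 2.0


def action_accuracy(errors: int, total: int, mode: str = "round") -> float:
    """Robot action accuracy in percent, to two decimals.

    ``mode='truncate'`` chops (rather than rounds) at the second decimal,
    matching tabulations that print e.g. 78.88 for 19 errors in 90 trials.
    """
    if total <= 0:
        raise ValueError("total must be positive")
    if not 0 <= errors <= total:
        raise ValueError("errors must lie in [0, total]")
    pct = 100.0 * (total - errors) / total
    if mode == "truncate":
        return math.floor(pct * 100) / 100.0
    if mode == "round":
        return round(pct, 2)
    raise ValueError(f"unknown rounding mode {mode!r}")


def pearson(x, y) -> float:
    """Pearson correlation coefficient of two equal-length samples."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and of equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant input")
    return float(stats.pearsonr(x, y)[0])


def _exact_signed_rank_p(ranks: np.ndarray, w_pos: float) -> float:
    """Exact two-sided p for the signed-rank statistic by dynamic
    programming over all 2^n sign assignments (midranks allowed)."""
    # Work on doubled ranks so midranks (k + 0.5) become integers.
    r2 = np.rint(2 * ranks).astype(int)
    total = int(r2.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    counts /= counts.sum()
    w2 = int(round(2 * w_pos))
    p_le = counts[: w2 + 1].sum()
    p_ge = counts[w2:].sum()
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def signed_rank_test(first_half, second_half) -> float:
    """Two-sided Wilcoxon signed-rank p for paired samples.

    Zero differences are dropped (Wilcoxon's convention) and tied absolute
    differences receive midranks.  The null distribution is enumerated
    exactly (all 2^n sign assignments, via dynamic programming) for n <= 25
    and approximated normally beyond.
    """
    x = np.asarray(first_half, dtype=float)
    y = np.asarray(second_half, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("paired samples must be 1-D and of equal length")
    if len(x) < 5:
        raise ValueError("need at least 5 pairs")
    diff = x - y
    diff = diff[diff != 0]
    if len(diff) == 0:
        raise ValueError("all paired differences are zero; test degenerate")
    ranks = stats.rankdata(np.abs(diff))
    w_pos = float(ranks[diff > 0].sum())
    if len(diff) <= 25:
        return _exact_signed_rank_p(ranks, w_pos)
    return float(stats.wilcoxon(diff, zero_method="wilcox", correction=True, mode="approx")[1])


def session_report(records) -> MetricsReport:
    """Summarise one closed-loop session's trial records.

    Detection rates are computed against the ground-truth correctness of
    the robot's actions, using the fused decision (reward = 0 counts as an
    ErrP detection).
    """
    total = len(records)
    if total == 0:
        return MetricsReport(accumulated_errors=[], accumulated_regret=[], accuracy_pct=None)
    errors = [r.errors_cum for r in records]
    regret = [r.regret_cum for r in records]
    report = MetricsReport(
        accumulated_errors=errors,
        accumulated_regret=regret,
        accuracy_pct=action_accuracy(errors[-1], total),
    )
    detected = [r.reward == 0 for r in records]
    true_err = [not r.correct for r in records]
    if any(true_err) and not all(true_err):
        report.tpr, report.tnr, report.bacc = balanced_accuracy(detected, true_err)
    return report
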