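"""Per-subject reference values from the seven-subject validation study
this package's simulator emulates.

Two scenarios were run, each with seven subjects: a simulated robot
(90 test actions per subject) and a real robot arm (60 test actions).
For each subject the study tabulated the online ErrP detection rates
(TPR, TNR — erroneous trial is the positive class) and the robot's
accumulated number of wrong actions.  These columns are raw inputs for
the evaluation statistics in :mod:`errpbandit.metrics` (balanced
accuracy, action accuracy, the TPR-vs-errors correlation) and provide
realistic operating points for the ``binary_noise`` feedback channel.
"""

from __future__ import annotations

__all__ = [
    "SIM_TPR",
    "SIM_TNR",
    "SIM_ERRORS",
    "SIM_TOTAL_ACTIONS",
    "REAL_TPR",
    "REAL_TNR",
    "REAL_ERRORS",
    "REAL_TOTAL_ACTIONS",
    "reproduce_reference_tables",
]

# Simulated robot scenario (7 subjects, 90 test actions each)
SIM_TPR = (1.00, 0.86, 0.92, 0.89, 1.00, 1.00, 1.00)
SIM_TNR = (0.98, 0.96, 0.83, 0.79, 0.73, 0.98, 0.77)
SIM_ERRORS = (6, 7, 13, 19, 6, 5, 11)
SIM_TOTAL_ACTIONS = 90

# Real robot scenario (7 subjects, 60 test actions each)
REAL_TPR = (1.00, 0.50, 1.00, 0.57, 1.00, 1.00, 1.00)
REAL_TNR = (0.96, 0.96, 0.89, 0.89, 0.89, 0.96, 0.95)
REAL_ERRORS = (5, 6, 4, 7, 4, 4, 4)
REAL_TOTAL_ACTIONS = 60


def _summary(values) -> dict:
    """Mean, standard error, and 95% t-interval margin, recomputed from raw
    per-subject values (tabulated summary rows are not trusted)."""
    import numpy as np
    from scipy import stats

    v = np.asarray(values, dtype=float)
    n = len(v)
    sem = float(v.std(ddof=1) / np.sqrt(n))
    margin = float(stats.t.ppf(0.975, n - 1) * sem)
    return {"mean": float(v.mean()), "sem": sem, "ci95_margin": margin}


def reproduce_reference_tables() -> dict:
    """Recompute every derived column of the reference tables from their
    raw columns: the bACC column from (TPR, TNR), the accuracy column from
    error counts, and mean/SEM/CI summary rows."""
    from .metrics import action_accuracy, pearson

    out: dict = {}
    for name, tpr, tnr, errors, total in (
        ("simulated", SIM_TPR, SIM_TNR, SIM_ERRORS, SIM_TOTAL_ACTIONS),
        ("real", REAL_TPR, REAL_TNR, REAL_ERRORS, REAL_TOTAL_ACTIONS),
    ):
        bacc = [round((p + n) / 2, 2) for p, n in zip(tpr, tnr)]
        acc = [action_accuracy(e, total, mode="truncate") for e in errors]
        out[name] = {
            "bacc": bacc,
            "accuracy_pct": acc,
            "tpr_summary": _summary(tpr),
            "tnr_summary": _summary(tnr),
            "bacc_summary": _summary(bacc),
            "errors_summary": _summary(errors),
            "mean_accuracy_pct": action_accuracy(
                # mean accuracy from the raw error counts, then truncated as
                # in the per-subject column
                errors=sum(errors) / len(errors),
                total=total,
                mode="truncate",
            ),
        }
    out["real"]["tpr_errors_pearson_r"] = pearson(REAL_TPR, REAL_ERRORS)
    return out
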