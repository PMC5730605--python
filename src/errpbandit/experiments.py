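"""Reproducible study harnesses tying the modules together.

These functions bundle the canonical experiment shapes — observation-task
training followed by interaction-task testing (classifier transfer), and
batteries of closed-loop sessions under configurable feedback channels —
so that examples, tests and reporting scripts all run the same procedures.
All randomness is derived from one integer seed via ``SeedSequence``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errp import ErrPDetector
from .loop import FeedbackChannel, SessionConfig, half_split, pretrain_bandit, run_session
from .metrics import balanced_accuracy
from .synthdata import DEFAULT_SNR, DEFAULT_SRATE, gen_epoch_set, gen_schedule

__all__ = [
    "TransferResult",
    "classifier_transfer",
    "run_sessions",
    "session_error_stats",
]


@dataclass
class TransferResult:
    """Outcome of one observation-to-interaction transfer experiment."""

    tpr: float
    tnr: float
    bacc: float
    detector: ErrPDetector


def classifier_transfer(
    snr: float = DEFAULT_SNR,
    seed: int = 0,
    n_train_sets: int = 4,
    train_trials: int = 90,
    train_err: int = 10,
    test_trials: int = 90,
    test_err: int = 10,
    n_channels: int = 64,
    srate: float = DEFAULT_SRATE,
) -> TransferResult:
    """Train the ErrP detector on observation-style epoch sets and evaluate
    the fused decision on freshly generated interaction-style epochs.

    Training keeps the 1:8 erroneous:correct ratio (default 4 sets of 10
    Err + 80 Corr trials).  The reported rates treat the fused decision
    (reward = 0) as an ErrP detection, with Err as the positive class.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    train: list = []
    for _ in range(n_train_sets):
        schedule = gen_schedule("training", train_trials, train_err, rng=rng)
        train.extend(gen_epoch_set(schedule, snr=snr, n_channels=n_channels, srate=srate, rng=rng))
    detector = ErrPDetector(seed=seed).fit(train)
    schedule = gen_schedule("test", test_trials, test_err, rng=rng)
    test = gen_epoch_set(schedule, snr=snr, n_channels=n_channels, srate=srate, rng=rng)
    detected = [detector.reward(e) == 0 for e in test]
    labels = [e.label == "Err" for e in test]
    tpr, tnr, bacc = balanced_accuracy(detected, labels)
    return TransferResult(tpr=tpr, tnr=tnr, bacc=bacc, detector=detector)


def run_sessions(
    channel: FeedbackChannel,
    config: SessionConfig | None = None,
    n_seeds: int = 30,
    seed: int = 0,
) -> list[list]:
    """Run ``n_seeds`` independent closed-loop sessions (fresh pre-trained
    bandit each) and return their trial-record lists."""
    config = SessionConfig() if config is None else config
    out = []
    for child in np.random.SeedSequence(seed).spawn(n_seeds):
        rng = np.random.default_rng(child)
        bandit = pretrain_bandit(config, rng=rng)
        out.append(run_session(config, bandit, channel, rng))
    return out


def session_error_stats(sessions: list[list], split: int | None = None) -> dict:
    """Mean total / first-half / second-half error counts over sessions."""
    totals = [s[-1].errors_cum if s else 0 for s in sessions]
    halves = [half_split(s, split=split) for s in sessions]
    n_trials = len(sessions[0]) if sessions else 0
    mean_errors = float(np.mean(totals))
    return {
        "mean_errors": mean_errors,
        "mean_first_half": float(np.mean([h[0] for h in halves])),
        "mean_second_half": float(np.mean([h[1] for h in halves])),
        "mean_accuracy_pct": 100.0 * (n_trials - mean_errors) / n_trials if n_trials else float("nan"),
    }
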