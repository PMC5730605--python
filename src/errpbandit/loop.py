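"""Closed-loop session simulator.

Each trial: a gesture is drawn, its 4-D feature vector becomes the bandit
context, the bandit selects a robot action, ground-truth correctness is
whether the action matches the gesture's designated action, and a feedback
channel converts that (possibly noisily, via simulated EEG) into the
binary reward the bandit learns from.  Regret bookkeeping follows the
reward channel, not the ground truth: every trial with r = 0 adds one unit
of regret, so missed errors (false negatives) leave regret untouched while
false alarms increase it.

Feedback channels
-----------------
``oracle``
    Perfect feedback: r = 1 iff the action was correct.
``binary_noise``
    Each of the two window decisions independently flags an error with
    probability TPR (erroneous trial) or 1 - TNR (correct trial); the two
    decisions are fused as in the EEG pipeline.  With ``fused=True`` the
    given rates are instead interpreted as the already-fused decision
    rates and a single decision is drawn.
``eeg_pipeline``
    A synthetic EEG epoch is generated for the trial's true correctness
    and classified by a fitted :class:`~errpbandit.errp.ErrPDetector`.

Context scaling
---------------
Gesture vectors are normalised to a fixed Euclidean norm c = 0.3 before
they reach the bandit.  The norm is a genuine design parameter once the
exploration weight is fixed at alpha = 2: the initial exploration bonus
alpha * c must not dwarf the maximum payoff of 1 (or the bandit explores
blindly for most of a 90-trial session), and an arm that is being rewarded
on only a fraction q of its selections (false positives suppress rewards)
must keep its UCB above the ~alpha * c bonus of a never-selected arm,
which requires roughly c < q / alpha for the worst realistic fused
true-negative rate (~0.7).  At the other end c must be large enough that
the ~30 within-session updates per arm outweigh the identity prior in
A_a.  c = 0.3 sits comfortably inside that band.  See docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .bandit import DEFAULT_ALPHA, LinUCB
from .errp import ErrPDetector, fuse_decisions
from .synthdata import (
    ARCHETYPES,
    DEFAULT_GESTURE_NOISE_SD,
    DEFAULT_JITTER_SD,
    DEFAULT_SNR,
    DEFAULT_SPAN,
    DEFAULT_SRATE,
    GESTURE_IDS,
    gen_epoch,
    gen_gesture,
)

__all__ = [
    "CONTEXT_NORM",
    "DEFAULT_DONOR_OFFSET_SD",
    "FeedbackChannel",
    "SessionConfig",
    "TrialRecord",
    "gesture_context",
    "emit_feedback",
    "pretrain_bandit",
    "run_session",
    "half_split",
    "records_to_frame",
]

#: Euclidean norm given to every bandit context (see module docstring).
CONTEXT_NORM = 0.3

#: Standard deviation of the per-component offset between the pre-training
#: donor's gesture archetypes and the session user's.  The donor is a
#: different person: raw palm-normal/grab features for the "same" gesture
#: differ substantially across people (hand size, orientation, which hand
#: performs it), so pre-trained knowledge transfers only coarsely and the
#: early session still commits exploration errors.  Calibrated so that
#: closed-loop accuracy under realistic detection rates lands in the
#: high-80s to low-90s percent range; see docs/methods.md.
DEFAULT_DONOR_OFFSET_SD = 1.0


def gesture_context(vector: np.ndarray, norm: float = CONTEXT_NORM) -> np.ndarray:
    """Scale a raw gesture feature vector to the fixed context norm."""
    v = np.asarray(vector, dtype=float)
    length = np.linalg.norm(v)
    if length == 0:
        raise ValueError("cannot build a context from a zero gesture vector")
    return norm * v / length


@dataclass
class FeedbackChannel:
    """Pluggable reward source for the closed loop."""

    mode: str = "oracle"  # "oracle" | "binary_noise" | "eeg_pipeline"
    tpr: float = 1.0  # P(flag | erroneous trial), per window unless fused
    tnr: float = 1.0  # P(pass | correct trial), per window unless fused
    fused: bool = False  # interpret (tpr, tnr) as fused-decision rates
    detector: ErrPDetector | None = None
    snr: float = DEFAULT_SNR
    jitter_sd: float = DEFAULT_JITTER_SD
    n_channels: int = 64
    srate: float = DEFAULT_SRATE
    span: tuple[float, float] = DEFAULT_SPAN

    def __post_init__(self) -> None:
        if self.mode not in ("oracle", "binary_noise", "eeg_pipeline"):
            raise ValueError(f"unknown feedback mode {self.mode!r}")
        if not (0 <= self.tpr <= 1 and 0 <= self.tnr <= 1):
            raise ValueError("tpr and tnr must be probabilities")
        if self.mode == "eeg_pipeline" and self.detector is None:
            raise ValueError("eeg_pipeline mode requires a fitted ErrPDetector")


def emit_feedback(
    channel: FeedbackChannel,
    true_error: bool,
    rng: np.random.Generator | None = None,
) -> tuple[bool, bool, int]:
    """Produce the two window decisions and the fused reward for one trial.

    Returns ``(d1, d2, r)`` where a decision is True when an ErrP is
    flagged and ``r = 1`` only when both decisions are NoErrP.
    """
    if channel.mode == "oracle":
        d1 = d2 = bool(true_error)
    elif channel.mode == "binary_noise":
        if rng is None:
            raise ValueError("binary_noise mode needs an rng")
        p_flag = channel.tpr if true_error else 1.0 - channel.tnr

        def draw() -> bool:
            # Degenerate probabilities consume no randomness, so a
            # noise-free channel leaves the rng stream identical to the
            # oracle channel's.
            if p_flag <= 0.0:
                return False
            if p_flag >= 1.0:
                return True
            return bool(rng.random() < p_flag)

        if channel.fused:
            d1 = d2 = draw()
        else:
            d1 = draw()
            d2 = draw()
    else:  # eeg_pipeline
        if rng is None:
            raise ValueError("eeg_pipeline mode needs an rng")
        epoch = gen_epoch(
            "Err" if true_error else "Corr",
            snr=channel.snr,
            jitter_sd=channel.jitter_sd,
            n_channels=channel.n_channels,
            srate=channel.srate,
            span=channel.span,
            rng=rng,
        )
        d1, d2 = channel.detector.detect(epoch)
    return d1, d2, fuse_decisions(d1, d2)


@dataclass
class TrialRecord:
    """Everything logged for one closed-loop trial."""

    t: int
    gesture_id: str
    context: np.ndarray
    arm: str
    correct: bool
    d1: bool
    d2: bool
    reward: int
    regret_increment: int
    errors_cum: int
    regret_cum: int


@dataclass
class SessionConfig:
    """Study conditions for one closed-loop session."""

    n_trials: int = 90  # 90 simulated-scenario / 60 real-scenario actions
    gesture_noise_sd: float = DEFAULT_GESTURE_NOISE_SD
    pretrain_reps: int = 3
    donor_offset_sd: float = DEFAULT_DONOR_OFFSET_SD
    alpha: float = DEFAULT_ALPHA
    context_norm: float = CONTEXT_NORM
    arms: tuple[str, ...] = GESTURE_IDS
    half_split: int | None = None  # default: floor(n_trials / 2)

    def __post_init__(self) -> None:
        if self.n_trials < 0:
            raise ValueError("n_trials must be >= 0")


def pretrain_bandit(
    config: SessionConfig,
    rng: np.random.Generator | None = None,
) -> LinUCB:
    """Build a bandit and pre-train it on a donor gesture set.

    The donor set emulates gestures recorded from an additional subject:
    one feature vector per gesture type — each the user's archetype plus a
    per-component Gaussian offset of sd ``config.donor_offset_sd`` —
    replayed ``pretrain_reps`` times with simulated perfect feedback.
    With ``donor_offset_sd = 0`` the donor matches the session archetypes
    exactly (the idealised noiseless condition).
    """
    rng = np.random.default_rng() if rng is None else rng
    bandit = LinUCB(arms=config.arms, d=4, alpha=config.alpha)
    donors = {}
    for g in config.arms:
        raw = ARCHETYPES[g] + rng.normal(0.0, config.donor_offset_sd, size=4)
        donors[g] = gesture_context(raw, config.context_norm)
    bandit.pretrain(donors, reps=config.pretrain_reps)
    return bandit


def run_session(
    config: SessionConfig,
    bandit: LinUCB,
    channel: FeedbackChannel,
    rng: np.random.Generator,
) -> list[TrialRecord]:
    """Run one closed-loop session, mutating ``bandit`` in place.

    Gestures are drawn uniformly over the gesture types (the human chose
    freely; uniformity is the neutral stand-in).  An action is correct
    when the selected arm equals the gesture's identity (the designated
    mapping).
    """
    records: list[TrialRecord] = []
    errors = 0
    regret = 0
    for t in range(config.n_trials):
        gesture_id = config.arms[rng.integers(len(config.arms))]
        gesture = gen_gesture(gesture_id, noise_sd=config.gesture_noise_sd, rng=rng)
        x = gesture_context(gesture.as_vector(), config.context_norm)
        arm = bandit.select_action(x)
        correct = arm == gesture_id
        d1, d2, r = emit_feedback(channel, true_error=not correct, rng=rng)
        bandit.update(arm, x, r)
        errors += int(not correct)
        regret += 1 - r
        records.append(
            TrialRecord(
                t=t,
                gesture_id=gesture_id,
                context=x,
                arm=arm,
                correct=correct,
                d1=d1,
                d2=d2,
                reward=r,
                regret_increment=1 - r,
                errors_cum=errors,
                regret_cum=regret,
            )
        )
    return records


def half_split(records: list[TrialRecord], split: int | None = None) -> tuple[int, int]:
    """Error counts in trials [0, split) and [split, T).

    ``split`` defaults to floor(T / 2); the 60-trial real-robot scenario
    uses split = 45 so its first bucket is comparable to the simulated
    scenario's first half.
    """
    if len(records) < 2:
        raise ValueError("need at least two trials to split")
    t_total = len(records)
    if split is None:
        split = t_total // 2
    if not 0 < split < t_total:
        raise ValueError(f"split {split} outside (0, {t_total})")
    first = sum(int(not rec.correct) for rec in records[:split])
    second = sum(int(not rec.correct) for rec in records[split:])
    return first, second


def records_to_frame(records: list[TrialRecord]) -> pd.DataFrame:
    """Tabulate trial records for CSV logging."""
    return pd.DataFrame(
        {
            "t": [r.t for r in records],
            "gesture": [r.gesture_id for r in records],
            "arm": [r.arm for r in records],
            "correct": [int(r.correct) for r in records],
            "d1": [int(r.d1) for r in records],
            "d2": [int(r.d2) for r in records],
            "reward": [r.reward for r in records],
            "regret_cum": [r.regret_cum for r in records],
            "errors_cum": [r.errors_cum for r in records],
        }
    )


def save_records(path: str | Path, records: list[TrialRecord]) -> None:
    records_to_frame(records).to_csv(path, index=False)
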