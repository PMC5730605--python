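"""Disjoint-arm LinUCB contextual bandit with asymmetric binary rewards.

The learner maps a shared 4-D gesture context x_t to one of three robot
actions (arms).  Because the action itself carries no features, each arm
``a`` keeps its own ridge design matrix ``A_a`` (initialised to the
identity) and payoff vector ``b_a``; the arm with the highest upper
confidence bound

    UCB_a = theta_a^T x + alpha * sqrt(x^T A_a^{-1} x),   theta_a = A_a^{-1} b_a

is selected (ties broken by fixed arm order).  Updates are asymmetric, as
suits a reward channel whose positive feedback is far more reliable than
its negative feedback: the context update ``A_a += x x^T`` is applied on
every trial, while the payoff update ``b_a += r x`` only has an effect on
positive feedback (r = 1).

Pre-training replays a donor gesture set (one feature vector per gesture
type) a fixed number of times with simulated perfect feedback, so the
session does not start from a uniformly ignorant state.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

__all__ = ["LinUCB", "DEFAULT_ALPHA"]

#: Exploration weight on the confidence term.
DEFAULT_ALPHA = 2.0


class LinUCB:
    """Modified (shared-context, disjoint-arm) LinUCB bandit."""

    def __init__(self, arms: Sequence[str] = ("left", "right", "forward"), d: int = 4, alpha: float = DEFAULT_ALPHA):
        if d < 1:
            raise ValueError("context dimension d must be >= 1")
        if not arms:
            raise ValueError("need at least one arm")
        self.arms = tuple(arms)
        self.d = d
        self.alpha = float(alpha)
        self.A = {a: np.eye(d) for a in self.arms}
        self.b = {a: np.zeros(d) for a in self.arms}

    # -- core algorithm ----------------------------------------------------

    def theta(self, arm: str) -> np.ndarray:
        """Ridge estimate of the arm's payoff coefficients."""
        return np.linalg.solve(self.A[arm], self.b[arm])

    def ucb_scores(self, x: np.ndarray) -> dict[str, float]:
        """Mean payoff estimate plus exploration bonus, per arm."""
        x = self._check_context(x)
        scores = {}
        for arm in self.arms:
            a_inv_x = np.linalg.solve(self.A[arm], x)
            mean = float(self.b[arm] @ np.linalg.solve(self.A[arm], x))
            width = self.alpha * float(np.sqrt(x @ a_inv_x))
            scores[arm] = mean + width
        return scores

    def select_action(self, x: np.ndarray) -> str:
        """Arm with the highest UCB; ties broken by arm order."""
        scores = self.ucb_scores(x)
        best = self.arms[0]
        for arm in self.arms[1:]:
            if scores[arm] > scores[best]:
                best = arm
        return best

    def update(self, arm: str, x: np.ndarray, r: int) -> None:
        """Context update always; payoff update only effective when r = 1."""
        if r not in (0, 1):
            raise ValueError(f"reward must be 0 or 1, got {r!r}")
        x = self._check_context(x)
        self.A[arm] = self.A[arm] + np.outer(x, x)
        self.b[arm] = self.b[arm] + r * x

    def pretrain(self, donor_contexts: Mapping[str, np.ndarray], reps: int = 3) -> "LinUCB":
        """Replay one donor context per arm ``reps`` times with perfect feedback.

        Each cycle selects an action (mimicking the online procedure) and
        then applies one positive update to the *designated* arm for that
        gesture, regardless of what was selected — the perfect-feedback
        interpretation: exactly ``reps x n_arms`` updates, all landing on
        the correct arms.
        """
        if reps < 0:
            raise ValueError("reps must be >= 0")
        for _ in range(reps):
            for arm in self.arms:
                x = np.asarray(donor_contexts[arm], dtype=float)
                self.select_action(x)  # exploration bookkeeping only
                self.update(arm, x, 1)
        return self

    # -- plumbing ----------------------------------------------------------

    def _check_context(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if x.shape != (self.d,):
            raise ValueError(f"context must have shape ({self.d},), got {x.shape}")
        return x

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "arms": list(self.arms),
            "d": self.d,
            "alpha": self.alpha,
            "A": {a: self.A[a].tolist() for a in self.arms},
            "b": {a: self.b[a].tolist() for a in self.arms},
        }
        text = json.dumps(payload)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "LinUCB":
        if isinstance(source, Path):
            text = source.read_text()
        else:
            text = str(source)
            if not text.lstrip().startswith("{"):
                text = Path(text).read_text()
        d = json.loads(text)
        bandit = cls(arms=d["arms"], d=d["d"], alpha=d["alpha"])
        bandit.A = {a: np.array(m) for a, m in d["A"].items()}
        bandit.b = {a: np.array(v) for a, v in d["b"].items()}
        return bandit
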