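"""Run closed-loop sessions: the bandit learns gesture-action mappings
from noisy binary feedback.

First a noise-free reference (perfect feedback, matching donor set): the
pre-trained bandit commits no errors.  Then a realistic channel with
TPR 0.89 / TNR 0.79 — errors concentrate in the first half of the session
and fall off as the mapping is learned, the pattern summarised by the
half-split error counts.
"""

import numpy as np

from errpbandit import FeedbackChannel, SessionConfig, half_split, pretrain_bandit, run_session
from errpbandit.metrics import session_report

# noise-free reference
cfg = SessionConfig(gesture_noise_sd=0.0, donor_offset_sd=0.0)
rng = np.random.default_rng(0)
bandit = pretrain_bandit(cfg, rng=rng)
records = run_session(cfg, bandit, FeedbackChannel(mode="oracle"), rng)
print(f"oracle feedback, noiseless: {records[-1].errors_cum} errors in {len(records)} trials")

# realistic detection rates (fused), default donor mismatch and gesture noise
cfg = SessionConfig()
channel = FeedbackChannel(mode="binary_noise", tpr=0.89, tnr=0.79, fused=True)
rng = np.random.default_rng(5)
bandit = pretrain_bandit(cfg, rng=rng)
records = run_session(cfg, bandit, channel, rng)
report = session_report(records)
first, second = half_split(records)
print(f"\nnoisy feedback (TPR 0.89 / TNR 0.79):")
print(f"  accumulated errors {records[-1].errors_cum}, accumulated regret {records[-1].regret_cum}")
print(f"  robot action accuracy {report.accuracy_pct:.2f}%")
print(f"  errors first half {first}, second half {second}  (learning shows as first > second)")
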