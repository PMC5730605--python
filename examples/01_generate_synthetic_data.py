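"""Generate the three kinds of synthetic inputs and look at their structure.

Builds gesture feature vectors, a training schedule, and labelled EEG
epochs, then recovers the error-potential's peak latency from a small
grand average — the sanity check an EEG practitioner would run first.
"""

import numpy as np

from errpbandit import gen_epoch, gen_gesture, gen_schedule
from errpbandit.synthdata import erp_topography

rng = np.random.default_rng(0)

for gid in ("left", "right", "forward"):
    g = gen_gesture(gid, rng=rng)
    print(f"{gid:8s} gesture -> palm_normal {np.round(g.palm_normal, 2)}, grab {g.grab_strength:.2f}")

schedule = gen_schedule("training", n_trials=90, n_err=10, rng=rng)
print(f"\ntraining schedule: {schedule.n_trials} trials, {schedule.n_err} erroneous "
      f"at positions {sorted(schedule.err_positions)}")

# grand-average 60 erroneous epochs on 16 channels; the biphasic deflection
# peaks near 0.30 s on the fronto-central channels despite per-trial jitter
acc = None
for _ in range(60):
    ep = gen_epoch("Err", n_channels=16, rng=rng)
    acc = ep.data if acc is None else acc + ep.data
grand = acc / 60
best_channel = int(np.argmax(erp_topography(16)))
times = -0.1 + np.arange(grand.shape[1]) / 250
peak = times[np.argmax(grand[best_channel])]
print(f"\ngrand-average positive peak on channel {best_channel}: {peak:.3f} s after action onset")
print("(the generator places it at 0.30 s; jitter averages out)")
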