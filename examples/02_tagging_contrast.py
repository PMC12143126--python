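"""Frequency-tagging contrast: measured 4.5 vs 8 Hz power in 4.5 Hz trials.

Simulates a small cohort, epochs cue-locked, computes Morlet power at the
two measured frequencies, expresses it as relative change against the
-350..-150 ms pre-cue baseline, and runs the pointwise paired contrast
with FDR control at the tagged (posterior) electrodes.
"""
import warnings

import numpy as np

from thetaflow import preprocess, synthio, tf

warnings.filterwarnings("ignore")

task = synthio.TaskConfig(n_trials=24, trials_per_freq=(12, 12))
head = synthio.make_toy_leadfield(16, (6, 6, 6), seed=0)
net = synthio.default_network()
tagged = head.posterior_sensors(6)

maps_45, maps_8 = [], []
for subject in range(10):
    raw, _ = synthio.simulate_tagged_eeg(task, head, net, ssvep_amp=3.0,
                                         snr=3.0, seed=300 + subject,
                                         fs=256.0)
    epochs = preprocess.epoch(raw, "S  1", (-2000, 2000))  # 4.5 Hz trials
    tfr = tf.morlet_tfr(epochs, [4.5, 8.0], n_cycles=5)
    rel = tf.relative_power_change(tfr, (-350, -150))
    maps_45.append(rel.relchange[:, 0, :])
    maps_8.append(rel.relchange[:, 1, :])

times = -2000.0 + np.arange(maps_45[0].shape[1]) / 256.0 * 1000.0
window = (times >= 0) & (times < 2000)
a = np.stack(maps_45)[:, tagged][:, :, window]
b = np.stack(maps_8)[:, tagged][:, :, window]
res = tf.pointwise_paired_contrast(a, b, alpha=0.05)

print(f"mean relative change at 4.5 Hz (tagging window): {a.mean():.1f}")
print(f"mean relative change at 8 Hz  (tagging window): {b.mean():.1f}")
print(f"FDR-significant fraction of electrode x time points: "
      f"{res['mask'].mean():.2f}")
# A large 4.5 Hz relative change with a significant mask at posterior
# electrodes is the frequency-tagging signature: neural activity tracks
# the anticipated action effect's flicker frequency after the cue.
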