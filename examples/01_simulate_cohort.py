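"""Simulate a small cohort of the three-emotion elicitation session.

Each subject follows the protocol: 3 min of relaxing music before each of
three 4-min picture blocks (neutral, negative, positive), with ECG at
400 Hz and BVP/GSR at 201 Hz.  The stress (negative) state is generated
with a faster heart rate, lower pulse-wave amplitude and more frequent,
larger skin-conductance responses.
"""

import numpy as np

import transfeat as tf

config = tf.CohortSimConfig(n_subjects=2, seed=42)
cohort = tf.simulate_cohort(config)

for subject in cohort:
    rr = subject.truth["rr_s"]
    print(f"subject {subject.subject_id}:")
    for channel, rec in subject.recordings.items():
        print(f"  {channel}: {len(rec.samples)} samples at {rec.rate_hz:g} Hz "
              f"({rec.duration_s:.0f} s)")
    print(f"  planted beats: {len(rr)}, mean RR {np.mean(rr):.3f} s, "
          f"planted SCR events: {len(subject.truth['scr_events'])}")

# The per-state physiology is what downstream feature selection must find:
for label in ("neutral", "negative", "positive"):
    eff = config.state_effects[label]
    print(f"{label:>8}: mean RR {eff.mean_rr_s:.3f} s "
          f"(HR {60 / eff.mean_rr_s:.1f} bpm), pulse amp {eff.pulse_amp_mean:.2f}, "
          f"SCR rate {eff.scr_rate_per_min:g}/min")
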